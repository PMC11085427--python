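# Default include/exclude phrase rules for curating vascular-dysfunction
# traits from a GWAS-Catalog association export.  Matching is
# case-insensitive substring on the trait string.
hypertension:
  include:
    - hypertension
  exclude:
    - early-onset hypertension
    - pulmonary arterial hypertension
    - pseudotumor cerebri
    - treatment-resistant hypertension
    - preeclampsia
    - chemotherapy-induced hypertension
    - short sleep duration
atherosclerosis:
  include:
    - atherosclerosis
  exclude:
    - air pollution
arterial_stiffness:
  include:
    - arterial stiffness
  exclude: []
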