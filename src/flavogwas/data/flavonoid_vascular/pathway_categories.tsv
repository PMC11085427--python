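set_id	category
VEGFA-VEGFR2 Signaling Pathway	vascular dysfunction
Regulation of actin cytoskeleton	vascular dysfunction
Adherens junction	vascular dysfunction
Angiopoietin Like Protein 8 Regulatory Pathway	vascular dysfunction
ECM-receptor interaction	vascular dysfunction
Focal adhesion	vascular dysfunction
Apelin signaling pathway	vascular dysfunction
Cholesterol metabolism	vascular dysfunction
Composition of Lipid Particles	vascular dysfunction
Fluid shear stress and atherosclerosis	vascular dysfunction
Glycerolipid metabolism	vascular dysfunction
Metabolic pathway of LDL, HDL and TG, including diseases	vascular dysfunction
Platelet activation	vascular dysfunction
Statin Pathway	vascular dysfunction
Chemokine signaling pathway	inflammation
Cytokine-cytokine receptor interaction	inflammation
NF-kappa B signaling pathway	inflammation
Regulation of toll-like receptor signaling pathway	inflammation
B cell receptor signaling pathway	inflammation
Interleukin-11 Signaling Pathway	inflammation
Natural killer cell mediated cytotoxicity	inflammation
Structural Pathway of Interleukin 1 (IL-1)	inflammation
TNF signaling pathway	inflammation
Toll-like receptor signaling pathway	inflammation
MAPK signaling pathway	cell signaling
PI3K-Akt signaling pathway	cell signaling
EGF/EGFR Signaling Pathway	cell signaling
Insulin signaling pathway	cell signaling
Sterol Regulatory Element-Binding Proteins (SREBP) signalling	cell signaling
cGMP-PKG signaling pathway	cell signaling
FoxO signaling pathway	cell signaling
Jak-STAT signaling pathway	cell signaling
Phospholipase D signaling pathway	cell signaling
Wnt Signaling Pathway and Pluripotency	cell signaling
NRF2 pathway	antioxidant protection
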