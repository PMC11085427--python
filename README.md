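# flavogwas

Integrative prioritization of candidate genes for nutrigenetic studies on
dietary flavonoids and vascular health.

Human intervention studies show that flavonoids (flavanones, flavanols,
anthocyanins) improve vascular function, but the response varies widely
between individuals, and genetic polymorphism is one of the least-studied
sources of that variability.  `flavogwas` implements a reproducible,
file-based pipeline that nominates the genes whose variants are most likely
to shape the vascular response to flavonoid intake, by integrating:

1. **Transcriptomics** — differentially expressed gene (DEG) lists from
   peripheral-blood studies of flavonoid interventions with positive
   vascular outcomes, plus their predicted upstream regulators (URs);
2. **Genetics** — GWAS-Catalog association exports curated into trait gene
   sets for hypertension, atherosclerosis, and arterial stiffness;
3. **Function** — placement of candidate genes in curated KEGG /
   WikiPathways canonical pathways, via over-representation analysis;
4. **Literature** — PubMed publication counts linking gene polymorphisms to
   cardiovascular disease and to nutrition.

## Model

Candidate DEGs are the study-by-trait intersections `DEGs(s) ∩ genes(t)`;
candidate URs are the per-study intersections of UR lists with the pooled
GWAS vascular gene set.  Pathway over-representation uses the right-tail
hypergeometric probability

P(X ≥ k),  X ~ Hypergeom(N, K, n),

with N the background universe, K the pathway genes, n the query genes and
k the observed overlap, Benjamini–Hochberg-adjusted across pathways; the
same statistic drives the upstream-regulator overlap scan across a
regulator→target network.  Per-gene boolean evidence flags
(`is_candidate_deg`, `is_candidate_ur`, `recurrent_ge2`, `recurrent_ge3`,
`in_pathway_table`, `top_lit`) feed six intersection criteria (a)–(f); the
priority set is their union, ranked by the number of criteria satisfied.
See `docs/methods.md` for the full treatment.

The package ships the curated gene lists of five published flavonoid
intervention studies (P1–P5) and their GWAS integration as bundled
fixtures, so the full prioritization is reproducible offline; the
synthetic-data module generates complete inputs with planted ground truth
for every stage.

## Worked example

Rerun the bundled curated evidence through the six-criteria prioritization:

```python
from flavogwas.datasets import load_curated, curated_priority_report

report = curated_priority_report(load_curated())
print(len(report.genes))                  # 20
print(report.to_frame().head(8).to_string(index=False))
```

```
20
   gene  n_criteria  criterion_a  criterion_b  criterion_c  criterion_d  criterion_e  criterion_f
   LDLR           3        False        False         True         True         True        False
   NCR3           3         True         True        False        False         True        False
 TCF7L2           3        False        False         True         True         True        False
  ALDH2           1        False        False         True        False        False        False
   APOE           1        False        False        False         True        False        False
 CAPZA1           1        False        False        False        False        False         True
CYP11B2           1        False        False        False         True        False        False
  GNA13           1         True        False        False        False        False        False
```

The 20-gene priority set is the union of the six criteria: genes such as
*LDLR*, *NCR3* and *TCF7L2* satisfy three criteria each (e.g. *NCR3* is a
recurrent candidate DEG placed in the natural-killer-cell cytotoxicity
pathway and is also a candidate UR), while genes such as *CAPZA1* enter on
a single strong criterion (a candidate DEG recurring in three or more
studies).

The same run is available from the shell via a config file:

```bash
flavogwas run-all --config run.yaml      # prints: priority genes n=20: ...
flavogwas simulate --seed 1 --out sim/   # synthetic bundle + truth.json
```

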