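# Supplementary full-study gene lists (user-supplied)

The full differential-expression lists of the five source studies and the
complete curated GWAS trait gene lists are supplementary material of the
original publications and are not redistributed with this package.  The
regression test `test_supplementary_full_study_regressions` runs only when
the following files are placed in this directory (one uppercase gene symbol
per line, `#` comments allowed):

- `degs_P1.txt` … `degs_P5.txt` — the DEG lists of studies P1–P5
- `trait_hypertension.txt` — curated hypertension-associated genes
- `trait_atherosclerosis.txt` — curated atherosclerosis-associated genes
- `trait_arterial_stiffness.txt` — curated arterial-stiffness-associated genes

With these files present, the test checks the full-list regressions:
pooled DEG count, >=2-study and >=3-study recurrence counts, the pooled
candidate-DEG count, and the size of the recurrence x candidate-DEG
intersection.  Without them the test is reported as skipped.
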