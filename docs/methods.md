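# Methods

## Problem setting

Dietary flavonoids improve vascular function in humans, with marked
interindividual variability.  The pipeline nominates genes whose
polymorphisms could underlie that variability by requiring two independent
kinds of evidence for each candidate: the gene responds transcriptionally
to flavonoid intake (or regulates genes that do), and its variants are
associated with vascular dysfunction in published GWAS.  Functional
(pathway) placement and literature evidence then concentrate the candidate
pool into a small priority set suitable for designing nutrigenetic studies.

## Inputs and curation

**Study DEG lists.**  Each source study contributes a set of gene symbols,
optionally with a direction of change.  Probe-level duplicates are
collapsed with set semantics (microarray probes map many-to-one onto
genes); rows with conflicting directions keep the gene but drop the
direction, with a warning.  The direction plays no role in any downstream
statistic, so this choice only affects reporting.

**Symbol normalization.**  All ingestion trims, uppercases and resolves
symbols through an editable two-column alias map.  The shipped map seeds
the variants that occur in the bundled curated lists (`PPRG→PPARG`,
`IL8→CXCL8`, `MCP-1→CCL2`).  Resolution iterates to a fixed point, making
normalization idempotent even for chained aliases.

**GWAS curation.**  Associations are kept when the trait string contains at
least one include phrase and no exclude phrase (case-insensitive
substring).  The shipped rules cover hypertension (excluding early-onset,
pulmonary-arterial, treatment-resistant and chemotherapy-induced forms,
pseudotumor cerebri, preeclampsia, and short-sleep interaction studies),
atherosclerosis (excluding an air-pollution interaction study) and
arterial stiffness.  Mapped-gene fields split on `" - "`, `";"`, `","` and
the SNP×SNP interaction separator `" x "`; both interaction sides
contribute their parsable genes, and placeholder tokens ("no mapped
genes", intergenic markers) contribute nothing.  Every curated gene keeps
provenance (accession, rsID) back to its surviving associations.  Which
mapped-gene column convention a catalog export uses, and how multi-gene
entries should split, is catalog-version-dependent; the separator set and
non-gene markers are therefore exposed in configuration.  Pooled gene
counts drift with catalog releases, so no absolute pooled count is ever
asserted in tests.

## Statistics

**Over-representation.**  For a query of n genes in a universe of N, a
pathway with K members in the universe and overlap k, the score is the
right tail P(X ≥ k) of the hypergeometric law, evaluated through the
survival function (log-space accumulation; k = 0 returns exactly 1, and
results are clipped into (0, 1]).  P-values are Benjamini–Hochberg
adjusted across the pathway collection.  The default universe is the union
of all genes in the loaded collection, overridable by a background gene
list — enrichment services differ in their backgrounds, and making the
universe explicit keeps runs comparable.  Reporting threshold q ≤ 0.05 by
default.

**Upstream-regulator scan.**  The same statistic scores each regulator's
target set against a study's DEG list within the universe, BH-adjusted
across regulators, default q ≤ 0.01.  Commercial regulator predictions
rest on proprietary curated networks and activation z-scores; this package
deliberately replaces them with a transparent overlap statistic over a
user-supplied network, and equally accepts precomputed per-study UR gene
lists.  Non-gene regulators (chemical compounds, drugs, miRNAs) are
dropped at ingestion by a symbol-validity filter: a token must already
look like an uppercase HGNC symbol (`^[A-Z][A-Z0-9_-]{0,14}$`) before case
folding.  The GWAS intersection downstream makes non-gene molecules
irrelevant in any case.

**Recurrence.**  The k study sets are partitioned into 2^k − 1 Venn
regions by exact membership signature; region sizes must sum to the union
size and this is asserted on every construction.  k is capped at 8, far
above the 5 studies the analysis needs, keeping region enumeration
trivial.

## Evidence matrix and priority criteria

Per-gene boolean flags: `is_candidate_deg` (DEG ∩ pooled GWAS set),
`is_candidate_ur`, `recurrent_ge2`/`recurrent_ge3` (shared by ≥2/≥3
studies; ≥3 implies ≥2, enforced), `in_pathway_table` (member of a
pathway row retaining ≥ `min_hits` candidate genes; default 2, the
smallest hit count in the curated placement table), and `top_lit`.

`top_lit` operationalizes "most-published gene": publication counts arrive
as a (gene, category, count) table for two query categories —
polymorphism × cardiovascular disease and polymorphism × nutrition — and a
gene is a top gene when its count reaches the category threshold.  The
shipped thresholds (34 and 5 for candidate DEGs, 24 and 5 for candidate
URs) are reverse-engineered from the published top-gene lists, flagged as
such, and exposed in configuration.  Counts are date-dependent, so live
querying is out of scope; the query templates ship as documentation
(see `flavogwas/evidence.py`).

Six intersection criteria are evaluated:

| criterion | definition |
|---|---|
| a | recurrent_ge2 ∧ is_candidate_deg ∧ in_pathway_table |
| b | recurrent_ge2 ∧ is_candidate_deg ∧ is_candidate_ur |
| c | is_candidate_deg ∧ top_lit |
| d | is_candidate_ur ∧ top_lit |
| e | in_pathway_table ∧ is_candidate_ur |
| f | is_candidate_deg ∧ recurrent_ge3 |

The priority set is the plain union of (a)–(f), ranked by the number of
criteria satisfied, ties alphabetical.  The union rule is the package's
operationalization of "a gene occupying central positions in the
integrative analyses"; it reproduces the curated 20-gene reference set
exactly from the bundled lists, which we treat as confirmation.  A
stricter "≥ m criteria" mode is available behind a flag.  Criterion (e)
evaluates pathway membership over the candidate-DEG placement table (the
table's gene universe), not over raw pathway membership of arbitrary
genes.

Variant annotation is pass-through: per-gene variants rank by population
frequency (descending, ties by rsID ascending, missing frequencies
appended last and flagged); clinical significance and pharmacology columns
are carried verbatim, never computed.

## Synthetic data

The generator emulates the statistical shape of the real inputs — it makes
no attempt at expression-level simulation, linkage structure, or realistic
gene nomenclature:

* **Studies**: five sets of 1693/717/554/2231/1401 genes over a
  20,000-gene universe; a small shared core (default 10) recurs in all
  studies and planted priority genes (default 8) are each placed in ≥2
  randomly chosen studies; the remainder is an independent uniform fill,
  so pairwise overlaps match the n_i·n_j/N expectation plus the core.
* **GWAS**: trait sets of 375/69/58 genes wrapped in a catalog-dialect
  export, with decoy rows whose trait strings match the default exclusion
  rules; a `planted_trait_overlap` fraction of planted genes is inserted
  into trait sets (1.0 by default, 0 removes them).
* **Pathways/network**: background sets and regulator targets are uniform;
  planted pathways oversample DEGs by `enrichment_factor` (default 5) and,
  when the factor exceeds 1, contain the planted priority genes so that
  planted signal survives the placement filter; planted regulators'
  targets oversample the DEG union by `bias_factor` (default 5).  Factor 1
  everywhere yields pure null structure.
* **Literature counts**: background counts follow a truncated geometric
  tail capped one below the category threshold, planted genes sit at or
  above it — the threshold rule separates them by construction.

Each stage draws from its own stream (seed + fixed stage index via
`SeedSequence`), so identical (params, seed) reproduce identical bytes on
disk and regenerating one stage never perturbs another.

Because trait decoys are always filterable, literature separation is
guaranteed, and planted genes are forced into ≥2 studies, passing recovery
tests demonstrates the plumbing and the statistics, not robustness to
messy real data: real exports contain unparsable trait strings, ambiguous
mapped-gene fields and symbol drift that only the alias map and the
curation rules can partially absorb.

## Calibration and test problem sizes

The suite verifies the hypergeometric tail against explicit subset
enumeration for every (N ≤ 12, K, n, k) at 1e-12, BH against hand-applied
step-up ramps, and null calibration of the UR scan: 250 scans of 8
regulators with uniform targets (400–1200 of a 4,000-gene universe,
2,000-gene DEG lists) must keep the fraction of regulators at p ≤ 0.05
within a binomial 3σ band of 0.05.  The test-statistic lattice makes the
attained size of a discrete test sit slightly below its nominal level, so
these null parameters are chosen dense enough (expected rate ≈ 0.046) for
the band to hold; sparser designs would fail for that structural reason,
not because of an implementation error.  Planted-signal recovery runs the
full pipeline at the generator's default parameters over 50 seeds.  These
problem sizes were chosen to exercise the asymptotics the pipeline
actually operates in while keeping the suite quick on a laptop.

## Known limitations

* The per-source pathway tallies of the curated placement table (KEGG vs
  WikiPathways under the asterisk legend) recount to 27/26, one above the
  published 26/25 per source; the 33-gene placement union is consistent
  and is the only quantity asserted.
* The upstream-regulator scan is an overlap statistic; it does not infer
  activation state or direction and cannot reproduce proprietary
  knowledge-base predictions beyond membership.
* GWAS curation is phrase-based; it cannot recover study-level exclusions
  that are invisible in the trait string, and positional/LD gene mapping
  is out of scope.
* Literature thresholds are fixture-derived, not principled cutoffs; use
  `top_k` rules where a principled count is unavailable.
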