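"""Bundled curated inputs from the flavonoid-vascular-health integrative analysis.

The package ships the published candidate-gene lists of the five human
flavonoid intervention studies and their GWAS integration: the curated
pathway-placement collection (KEGG / WikiPathways source tags), per-study
candidate upstream-regulator lists, the cross-study recurrence sets, the
literature-evidence counts, and the variant annotations of the top-priority
genes.  :func:`load_curated` assembles them into ready-to-use objects and
:func:`curated_priority_report` reruns the full six-criteria prioritization
from them.

The five full differential-expression tables themselves are not bundled
(they are supplementary material of the source studies); analyses that need
them accept user-provided files.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

from .core_io import (
    GeneSetCollection,
    GeneSymbol,
    VariantRecord,
    read_gene_list,
    read_gmt,
    read_variants,
)
from .evidence import LiteratureCounts, read_lit_counts, top_genes
from .prioritize import EvidenceMatrix, PriorityReport, build_evidence_matrix, priority_set
from .regulators import candidate_urs

STUDY_IDS = ("P1", "P2", "P3", "P4", "P5")

#: Minimum publication counts that delimit the "top literature evidence"
#: gene sets, per (gene pool, search category).  These are reverse-engineered
#: from the published top-gene lists and exposed in run configuration.
DEFAULT_LIT_RULES: Mapping[tuple[str, str], int] = {
    ("deg", "cvd_snp"): 34,
    ("deg", "nutrition_snp"): 5,
    ("ur", "cvd_snp"): 24,
    ("ur", "nutrition_snp"): 5,
}


def data_dir() -> Path:
    """Filesystem path of the bundled curated inputs."""
    return Path(str(resources.files("flavogwas").joinpath("data", "flavonoid_vascular")))


@dataclass(frozen=True)
class CuratedInputs:
    """The bundled evidence, one attribute per prioritization ingredient."""

    pathway_collection: GeneSetCollection
    pathway_categories: Mapping[str, str]
    ur_lists: Mapping[str, frozenset[GeneSymbol]]
    recurrent_ge2: frozenset[GeneSymbol]
    recurrent_ge3: frozenset[GeneSymbol]
    deg_lit_counts: LiteratureCounts
    ur_lit_counts: LiteratureCounts
    variants: tuple[VariantRecord, ...]

    def candidate_ur_pool(self) -> frozenset[GeneSymbol]:
        """Pooled candidate URs (the per-study lists are already GWAS-curated)."""
        return candidate_urs(self.ur_lists, gwas_genes=None).pooled

    def candidate_deg_pool(self) -> frozenset[GeneSymbol]:
        """Every published candidate DEG: the recurrence lists, the
        pathway-placed genes, and the literature-searched candidate DEGs."""
        return frozenset(
            self.recurrent_ge2
            | self.recurrent_ge3
            | self.pathway_collection.all_genes()
            | self.deg_lit_counts.genes()
        )

    def lit_top_sets(
        self, rules: Mapping[tuple[str, str], int] = DEFAULT_LIT_RULES
    ) -> dict[str, frozenset[GeneSymbol]]:
        counts = {"deg": self.deg_lit_counts, "ur": self.ur_lit_counts}
        return {
            f"{pool}_{category}": top_genes(counts[pool], category, min_count=threshold)
            for (pool, category), threshold in rules.items()
        }


def load_curated() -> CuratedInputs:
    d = data_dir()
    categories = {}
    for line in (d / "pathway_categories.tsv").read_text().splitlines()[1:]:
        set_id, _, category = line.partition("\t")
        categories[set_id] = category
    return CuratedInputs(
        pathway_collection=read_gmt(d / "pathways_placement.gmt"),
        pathway_categories=categories,
        ur_lists={
            sid: read_gene_list(d / f"candidate_urs_{sid}.txt") for sid in STUDY_IDS
        },
        recurrent_ge2=read_gene_list(d / "recurrent_ge2.txt"),
        recurrent_ge3=read_gene_list(d / "recurrent_ge3.txt"),
        deg_lit_counts=read_lit_counts(d / "lit_counts.tsv", pool="deg"),
        ur_lit_counts=read_lit_counts(d / "lit_counts.tsv", pool="ur"),
        variants=tuple(read_variants(d / "variants_top10.tsv")),
    )


def load_gwas_variants():
    """GWAS-reported variants of the top-priority genes (catalog-dialect
    mapped-gene strings, trait, accessions, global frequency, gene role)."""
    import pandas as pd

    return pd.read_csv(data_dir() / "gwas_variants.tsv", sep="\t", dtype=str)


def curated_evidence_matrix(
    inputs: CuratedInputs | None = None,
    min_hits: int = 2,
    lit_rules: Mapping[tuple[str, str], int] = DEFAULT_LIT_RULES,
) -> EvidenceMatrix:
    from .enrichment import placement_table

    if inputs is None:
        inputs = load_curated()
    deg_pool = inputs.candidate_deg_pool()
    placement = placement_table(deg_pool, inputs.pathway_collection, min_hits=min_hits)
    urs = candidate_urs(inputs.ur_lists, gwas_genes=None)
    ur_prov = {
        gene: [sid for sid, members in urs.per_study.items() if gene in members]
        for gene in urs.pooled
    }
    return build_evidence_matrix(
        candidate_deg_pool=deg_pool,
        candidate_ur_pool=urs.pooled,
        recurrence_sets={2: inputs.recurrent_ge2, 3: inputs.recurrent_ge3},
        placement_union=placement.gene_union,
        lit_top_sets=inputs.lit_top_sets(lit_rules),
        ur_provenance=ur_prov,
    )


def curated_priority_report(inputs: CuratedInputs | None = None) -> PriorityReport:
    """Rerun the six-criteria prioritization on the bundled curated evidence."""
    matrix = curated_evidence_matrix(inputs)
    return priority_set(matrix, manifest={"inputs": "bundled curated evidence"})
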