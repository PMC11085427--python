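"""Candidate-gene integration, the evidence matrix, and the six-way priority set.

The integration step intersects each study's DEG list with each GWAS trait
gene set (candidate DEGs).  Per-gene boolean evidence flags are then
assembled into an :class:`EvidenceMatrix`:

* ``is_candidate_deg``  — DEG in >=1 study and in the pooled GWAS set
* ``is_candidate_ur``   — upstream regulator intersecting the GWAS set
* ``recurrent_ge2/ge3`` — DEG shared by >=2 / >=3 of the source studies
* ``in_pathway_table``  — placed in a retained curated-pathway row
* ``top_lit``           — among the top literature-evidence genes

Six intersection criteria are evaluated over the flags:

  (a) recurrent_ge2 & is_candidate_deg & in_pathway_table
  (b) recurrent_ge2 & is_candidate_deg & is_candidate_ur
  (c) is_candidate_deg & top_lit
  (d) is_candidate_ur & top_lit
  (e) in_pathway_table & is_candidate_ur
  (f) is_candidate_deg & recurrent_ge3

A gene occupying any of these central positions enters the priority set;
genes are ranked by how many criteria they satisfy, ties alphabetical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from .core_io import GeneSymbol, StudyGeneSet
from .errors import UsageError
from .gwas import TraitGeneSet

log = logging.getLogger(__name__)

FLAG_NAMES = (
    "is_candidate_deg",
    "is_candidate_ur",
    "recurrent_ge2",
    "recurrent_ge3",
    "in_pathway_table",
    "top_lit",
)

CRITERIA = ("a", "b", "c", "d", "e", "f")


@dataclass(frozen=True)
class CandidateDegs:
    """Per study-by-trait intersection cells and their pooled union."""

    cells: Mapping[tuple[str, str], frozenset[GeneSymbol]]
    pooled: frozenset[GeneSymbol]
    #: (study_id, gene) -> trait labels, for genes hit by >=2 traits in one study
    multi_trait: Mapping[tuple[str, GeneSymbol], frozenset[str]]


def candidate_degs(
    studies: Sequence[StudyGeneSet],
    trait_sets: Mapping[str, TraitGeneSet],
) -> CandidateDegs:
    """Intersect every study DEG list with every trait gene set."""
    cells: dict[tuple[str, str], frozenset[str]] = {}
    pooled: set[str] = set()
    per_study_gene_traits: dict[tuple[str, str], set[str]] = {}
    for study in studies:
        for trait_label, ts in trait_sets.items():
            hit = frozenset(study.genes & ts.genes)
            cells[(study.study_id, trait_label)] = hit
            pooled |= hit
            for gene in hit:
                per_study_gene_traits.setdefault((study.study_id, gene), set()).add(
                    trait_label
                )
    multi = {
        key: frozenset(traits)
        for key, traits in per_study_gene_traits.items()
        if len(traits) >= 2
    }
    return CandidateDegs(cells=cells, pooled=frozenset(pooled), multi_trait=multi)


@dataclass
class GeneEvidence:
    flags: dict[str, bool] = field(default_factory=lambda: {f: False for f in FLAG_NAMES})
    provenance: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def set(self, flag: str, provenance: Sequence[str]) -> None:
        if flag not in self.flags:
            raise UsageError(f"unknown evidence flag {flag!r}")
        if not provenance:
            raise UsageError(f"flag {flag!r} set without provenance")
        self.flags[flag] = True
        self.provenance[flag] = tuple(sorted(set(provenance)))


@dataclass
class EvidenceMatrix:
    genes: dict[GeneSymbol, GeneEvidence]
    multi_trait_flags: Mapping[GeneSymbol, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self):
        for gene, ev in self.genes.items():
            if ev.flags["recurrent_ge3"] and not ev.flags["recurrent_ge2"]:
                raise UsageError(f"{gene}: recurrent_ge3 implies recurrent_ge2")

    def with_flag(self, flag: str) -> frozenset[GeneSymbol]:
        return frozenset(g for g, ev in self.genes.items() if ev.flags[flag])

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "gene": gene,
                **{f: ev.flags[f] for f in FLAG_NAMES},
                "provenance": "|".join(
                    f"{flag}:{','.join(prov)}"
                    for flag, prov in sorted(ev.provenance.items())
                ),
            }
            for gene, ev in sorted(self.genes.items())
        ]
        return pd.DataFrame(rows, columns=["gene", *FLAG_NAMES, "provenance"])


def build_evidence_matrix(
    candidate_deg_pool: frozenset[GeneSymbol],
    candidate_ur_pool: frozenset[GeneSymbol],
    recurrence_sets: Mapping[int, frozenset[GeneSymbol]],
    placement_union: frozenset[GeneSymbol],
    lit_top_sets: Mapping[str, frozenset[GeneSymbol]],
    deg_provenance: Optional[Mapping[GeneSymbol, Sequence[str]]] = None,
    ur_provenance: Optional[Mapping[GeneSymbol, Sequence[str]]] = None,
    multi_trait_flags: Optional[Mapping[GeneSymbol, frozenset[str]]] = None,
) -> EvidenceMatrix:
    """Assemble per-gene flags over the union of all evidence pools.

    ``recurrence_sets`` maps minimum study counts (2 and 3) to gene sets;
    ``lit_top_sets`` maps a label (e.g. ``deg_cvd_snp``) to the top
    literature genes for that pool/category.  Provenance maps are optional;
    flags without richer provenance carry their source pool name.
    """
    ge2 = recurrence_sets.get(2, frozenset())
    ge3 = recurrence_sets.get(3, frozenset())
    if not ge3 <= ge2:
        raise UsageError("recurrence_sets: >=3-study genes must be a subset of >=2")
    lit_union: dict[str, set[str]] = {}
    for label, genes in lit_top_sets.items():
        for g in genes:
            lit_union.setdefault(g, set()).add(label)
    universe = (
        set(candidate_deg_pool)
        | set(candidate_ur_pool)
        | set(ge2)
        | set(placement_union)
        | set(lit_union)
    )
    matrix: dict[str, GeneEvidence] = {}
    for gene in universe:
        ev = GeneEvidence()
        if gene in candidate_deg_pool:
            prov = (deg_provenance or {}).get(gene) or ["candidate_deg_pool"]
            ev.set("is_candidate_deg", prov)
        if gene in candidate_ur_pool:
            prov = (ur_provenance or {}).get(gene) or ["candidate_ur_pool"]
            ev.set("is_candidate_ur", prov)
        if gene in ge2:
            ev.set("recurrent_ge2", ["recurrent_in_ge2_studies"])
        if gene in ge3:
            ev.set("recurrent_ge3", ["recurrent_in_ge3_studies"])
        if gene in placement_union:
            ev.set("in_pathway_table", ["placement_table"])
        if gene in lit_union:
            ev.set("top_lit", sorted(lit_union[gene]))
        matrix[gene] = ev
    return EvidenceMatrix(genes=matrix, multi_trait_flags=multi_trait_flags or {})


def criteria_intersections(matrix: EvidenceMatrix) -> dict[str, frozenset[GeneSymbol]]:
    """Evaluate the six intersection criteria (a)-(f) over the matrix."""
    if not matrix.genes:
        raise UsageError("criteria_intersections: empty evidence matrix")
    deg = matrix.with_flag("is_candidate_deg")
    ur = matrix.with_flag("is_candidate_ur")
    ge2 = matrix.with_flag("recurrent_ge2")
    ge3 = matrix.with_flag("recurrent_ge3")
    path = matrix.with_flag("in_pathway_table")
    lit = matrix.with_flag("top_lit")
    return {
        "a": ge2 & deg & path,
        "b": ge2 & deg & ur,
        "c": deg & lit,
        "d": ur & lit,
        "e": path & ur,
        "f": deg & ge3,
    }


@dataclass(frozen=True)
class PriorityReport:
    criteria_sets: Mapping[str, frozenset[GeneSymbol]]
    #: (gene, number of criteria satisfied, per-criterion membership)
    priority_genes: tuple[tuple[GeneSymbol, int, Mapping[str, bool]], ...]
    manifest: Mapping = field(default_factory=dict)

    @property
    def genes(self) -> frozenset[GeneSymbol]:
        return frozenset(g for g, _, _ in self.priority_genes)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "gene": gene,
                "n_criteria": n,
                **{f"criterion_{c}": flags[c] for c in CRITERIA},
            }
            for gene, n, flags in self.priority_genes
        ]
        return pd.DataFrame(
            rows, columns=["gene", "n_criteria", *(f"criterion_{c}" for c in CRITERIA)]
        )


def priority_set(
    matrix: EvidenceMatrix,
    mode: str = "union",
    min_criteria: int = 2,
    manifest: Optional[Mapping] = None,
) -> PriorityReport:
    """Union of the six criteria sets, ranked by criteria count then symbol.

    ``mode="union"`` (default) admits any gene satisfying >=1 criterion;
    ``mode="at_least"`` requires >= ``min_criteria``.
    """
    if mode not in {"union", "at_least"}:
        raise UsageError(f"unknown priority mode {mode!r}")
    crits = criteria_intersections(matrix)
    union: set[str] = set()
    for genes in crits.values():
        union |= genes
    entries = []
    for gene in union:
        flags = {c: gene in crits[c] for c in CRITERIA}
        n = sum(flags.values())
        if mode == "at_least" and n < min_criteria:
            continue
        entries.append((gene, n, flags))
    entries.sort(key=lambda e: (-e[1], e[0]))
    report = PriorityReport(
        criteria_sets=crits,
        priority_genes=tuple(entries),
        manifest=dict(manifest or {}),
    )
    if mode == "union":
        assert report.genes == frozenset(union), "priority set must equal the criteria union"
    return report
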