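"""Literature-count evidence sets and per-gene variant ranking.

Literature evidence arrives as a (gene, category, count) table — counts of
PubMed hits for gene-polymorphism queries against cardiovascular-disease or
nutrition terms.  Live querying is out of scope because such counts are
date-dependent; the query templates are shipped as documentation so the
tables can be regenerated by hand:

* cvd_snp:        ((GENE[Title/Abstract]) AND ((SNP[Title/Abstract] OR
                  polymorphism[Title/Abstract]))) AND
                  (cardiovascular[Title/Abstract] OR atherosclerosis[Title/Abstract])
* nutrition_snp:  ((SNP[Title/Abstract]) AND ((nutrition[Title/Abstract] OR
                  nutrient[Title/Abstract] OR diet[Title/Abstract]))) AND
                  (GENE[Title/Abstract])

Variant annotation is pass-through: clinical significance and pharmacology
columns are carried, never computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from .core_io import GeneSymbol, VariantRecord, normalize_symbol
from .errors import FormatError, UsageError

log = logging.getLogger(__name__)

CATEGORIES = ("cvd_snp", "nutrition_snp")


@dataclass(frozen=True)
class LiteratureCounts:
    """Per-(gene, category) publication counts."""

    counts: Mapping[tuple[GeneSymbol, str], int]
    query_template: str = ""

    def __post_init__(self):
        for (gene, category), count in self.counts.items():
            if count < 0:
                raise FormatError(f"negative count for ({gene}, {category})")
            if category not in CATEGORIES:
                raise FormatError(
                    f"unknown category {category!r} (expected one of {CATEGORIES})"
                )

    def genes(self, category: Optional[str] = None) -> frozenset[GeneSymbol]:
        return frozenset(
            g for (g, c) in self.counts if category is None or c == category
        )

    def get(self, gene: GeneSymbol, category: str) -> int:
        return self.counts.get((gene, category), 0)


def read_lit_counts(
    path, sep: str = "\t", alias_map=None, pool: Optional[str] = None
) -> LiteratureCounts:
    """Read a (gene, category, count) TSV; an optional ``pool`` column
    restricts to one gene pool (e.g. ``deg`` or ``ur``)."""
    df = pd.read_csv(path, sep=sep, dtype={"gene": str, "category": str})
    needed = {"gene", "category", "count"}
    if not needed <= set(df.columns):
        raise FormatError(f"{path}: literature counts need columns {sorted(needed)}")
    if pool is not None:
        if "pool" not in df.columns:
            raise FormatError(f"{path}: no 'pool' column but pool={pool!r} requested")
        df = df[df["pool"] == pool]
    counts: dict[tuple[str, str], int] = {}
    for _, row in df.iterrows():
        key = (normalize_symbol(row["gene"], alias_map), str(row["category"]))
        counts[key] = counts.get(key, 0) + int(row["count"])
    return LiteratureCounts(counts=counts)


def top_genes(
    counts: LiteratureCounts,
    category: str,
    min_count: Optional[int] = None,
    top_k: Optional[int] = None,
) -> frozenset[GeneSymbol]:
    """Genes with the largest publication counts in one category.

    Exactly one of ``min_count`` (count >= threshold) or ``top_k`` (the k
    largest, ties broken by count descending then symbol ascending) must be
    given.
    """
    if (min_count is None) == (top_k is None):
        raise UsageError("top_genes: give exactly one of min_count or top_k")
    ranked = sorted(
        ((g, c) for (g, cat), c in counts.counts.items() if cat == category),
        key=lambda gc: (-gc[1], gc[0]),
    )
    if min_count is not None:
        return frozenset(g for g, c in ranked if c >= min_count)
    return frozenset(g for g, _ in ranked[:top_k])


def rank_variants(
    variants: Sequence[VariantRecord],
    gene: GeneSymbol,
    k: int = 10,
) -> list[VariantRecord]:
    """The gene's k most frequent variants.

    Records with a known frequency are sorted frequency descending, ties by
    rsid ascending; missing-frequency records are appended (rsid ascending,
    with a logged flag) only if fewer than k remain.  An unknown gene yields
    an empty list with a warning.
    """
    if k < 1:
        raise UsageError(f"k must be >= 1, got {k}")
    gene = normalize_symbol(gene)
    mine = [v for v in variants if v.gene == gene]
    if not mine:
        log.warning("rank_variants: no records for gene %s", gene)
        return []
    with_freq = sorted(
        (v for v in mine if v.frequency is not None),
        key=lambda v: (-v.frequency, v.rsid),
    )
    out = with_freq[:k]
    if len(out) < k:
        missing = sorted(
            (v for v in mine if v.frequency is None), key=lambda v: v.rsid
        )
        if missing:
            log.info(
                "rank_variants(%s): padding with %d missing-frequency record(s)",
                gene,
                min(len(missing), k - len(out)),
            )
        out = out + missing[: k - len(out)]
    return out


def variants_frame(variants: Sequence[VariantRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": v.gene,
                "rsid": v.rsid,
                "consequence": v.consequence,
                "frequency": v.frequency,
                "clinical_significance": v.clinical_significance or "",
            }
            for v in variants
        ],
        columns=["gene", "rsid", "consequence", "frequency", "clinical_significance"],
    )
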