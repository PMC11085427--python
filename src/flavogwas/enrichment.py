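"""Over-representation analysis (hypergeometric + BH-FDR) and pathway placement.

The ORA statistic is the standard right-tail hypergeometric probability of
the observed overlap between a query gene set and each pathway set within a
background universe (by default, the union of all genes in the loaded
collection).  The placement table is the complementary per-pathway view:
which query genes sit in which curated pathway, filtered by a minimum hit
count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import GeneSetCollection, GeneSymbol
from .errors import UsageError

log = logging.getLogger(__name__)


def hypergeom_right_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), evaluated stably.

    N is the universe size, K the marked (pathway) genes, n the draw (query)
    size, and k the observed overlap.  k = 0 returns exactly 1.
    """
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise UsageError(
            f"hypergeometric domain violation: N={N}, K={K}, n={n}, k={k}"
        )
    if k == 0:
        return 1.0
    # sf(k-1) accumulates the upper tail in log space internally
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return min(max(p, np.nextafter(0.0, 1.0)), 1.0)


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted values, in input order, clipped to <=1."""
    pvals = np.asarray(list(pvalues), dtype=float)
    if pvals.size == 0:
        return []
    if np.any(~np.isfinite(pvals)) or np.any(pvals <= 0) or np.any(pvals > 1):
        raise UsageError("bh_adjust: all p-values must lie in (0, 1]")
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    return [float(q) for q in qvals]


@dataclass(frozen=True)
class EnrichmentResult:
    set_id: str
    source_tag: str
    N: int
    K: int
    n: int
    k: int
    p_right: float
    q_bh: float
    hits: frozenset[GeneSymbol]


def run_ora(
    query: frozenset[GeneSymbol],
    collection: GeneSetCollection,
    universe: Optional[frozenset[GeneSymbol]] = None,
) -> list[EnrichmentResult]:
    """One hypergeometric test per pathway set, BH-adjusted across sets.

    Query genes outside the universe are dropped (with a logged count);
    results are sorted by p ascending, ties broken by set_id.
    """
    if universe is None:
        universe = collection.universe or collection.all_genes()
    if not universe:
        raise UsageError("run_ora: empty universe")
    dropped = len(query - universe)
    if dropped:
        log.info("run_ora: dropped %d query gene(s) outside the universe", dropped)
    query_in = frozenset(query) & universe
    N, n = len(universe), len(query_in)
    partial = []
    for s in collection:
        members = s.genes & universe
        hits = frozenset(query_in & members)
        p = hypergeom_right_tail(N, len(members), n, len(hits))
        partial.append((s, members, hits, p))
    qvals = bh_adjust([p for *_, p in partial]) if partial else []
    results = [
        EnrichmentResult(
            set_id=s.set_id,
            source_tag=s.source_tag,
            N=N,
            K=len(members),
            n=n,
            k=len(hits),
            p_right=p,
            q_bh=q,
            hits=hits,
        )
        for (s, members, hits, p), q in zip(partial, qvals)
    ]
    results.sort(key=lambda r: (r.p_right, r.set_id))
    return results


def enrichment_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "set_id": r.set_id,
                "source_tag": r.source_tag,
                "N": r.N,
                "K": r.K,
                "n": r.n,
                "k": r.k,
                "p_right": r.p_right,
                "q_bh": r.q_bh,
                "hits": ";".join(sorted(r.hits)),
            }
            for r in results
        ],
        columns=["set_id", "source_tag", "N", "K", "n", "k", "p_right", "q_bh", "hits"],
    )


@dataclass(frozen=True)
class PlacementTable:
    """Pathway rows retaining >= min_hits query genes, plus their gene union."""

    table: pd.DataFrame
    gene_union: frozenset[GeneSymbol]
    min_hits: int


def placement_table(
    query: frozenset[GeneSymbol],
    collection: GeneSetCollection,
    min_hits: int = 2,
) -> PlacementTable:
    """Tabulate which query genes are placed in which curated pathway.

    Rows with hit_count >= min_hits are kept, sorted by hit_count descending
    then set_id; the deduplicated union of hit genes across retained rows is
    reported alongside.
    """
    if min_hits < 1:
        raise UsageError(f"min_hits must be >= 1, got {min_hits}")
    rows = []
    union: set[str] = set()
    for s in collection:
        hits = frozenset(query) & s.genes
        if len(hits) >= min_hits:
            rows.append(
                {
                    "set_id": s.set_id,
                    "source_tag": s.source_tag,
                    "hit_count": len(hits),
                    "hit_genes": ";".join(sorted(hits)),
                }
            )
            union |= hits
    rows.sort(key=lambda r: (-r["hit_count"], r["set_id"]))
    table = pd.DataFrame(
        rows, columns=["set_id", "source_tag", "hit_count", "hit_genes"]
    )
    return PlacementTable(table=table, gene_union=frozenset(union), min_hits=min_hits)
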