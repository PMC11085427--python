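"""Upstream-regulator overlap enrichment and UR x GWAS intersection.

Two entry points mirror the two ways regulator evidence can arrive:

* :func:`ur_overlap_scan` — an open overlap statistic over a user-supplied
  regulator -> target network: for each regulator, the hypergeometric
  right-tail probability that its targets overlap the DEG list as much as
  observed, BH-adjusted across regulators.
* :func:`candidate_urs` — intersection of precomputed per-study UR gene
  lists with the pooled GWAS vascular gene set, which is how curated
  regulator lists from commercial tools are consumed.

Non-gene regulators (chemical compounds, drugs, miRNAs) are dropped at
ingestion by a symbol-validity filter: a regulator token must already look
like an uppercase HGNC symbol before case folding.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import GeneSymbol, RegulatorNetwork, StudyGeneSet, normalize_symbol
from .enrichment import bh_adjust
from .errors import UsageError
from .gwas import TraitGeneSet

log = logging.getLogger(__name__)

#: A plausible gene symbol: uppercase alphanumeric (dash/underscore allowed),
#: starting with a letter, at most 15 characters.  Chemicals ("curcumin"),
#: drugs and miRNAs ("miR-155") fail this before case folding.
_SYMBOL_RE = re.compile(r"^[A-Z][A-Z0-9_-]{0,14}$")


def is_gene_symbol(token: str) -> bool:
    return bool(_SYMBOL_RE.match(token.strip()))


def read_ur_list(path, alias_map=None) -> frozenset[GeneSymbol]:
    """One regulator per line; non-gene molecules are silently dropped."""
    genes = set()
    n_dropped = 0
    for line in Path(path).read_text().splitlines():
        token = line.strip()
        if not token or token.startswith("#"):
            continue
        if not is_gene_symbol(token):
            n_dropped += 1
            continue
        genes.add(normalize_symbol(token, alias_map))
    if n_dropped:
        log.info("%s: dropped %d non-gene regulator token(s)", path, n_dropped)
    return frozenset(genes)


@dataclass(frozen=True)
class URResult:
    regulator: GeneSymbol
    n_targets_in_universe: int
    overlap_k: int
    p_right: float
    q_bh: float
    is_also_deg: bool


def ur_overlap_scan(
    degs: StudyGeneSet,
    network: RegulatorNetwork,
    universe: frozenset[GeneSymbol],
    alpha: float = 0.01,
) -> list[URResult]:
    """Hypergeometric overlap scan of every regulator against a DEG list.

    For each regulator with >=1 target inside the universe the right-tail
    probability of its target/DEG overlap is computed, then BH-adjusted
    across regulators.  ``alpha`` is carried for downstream thresholding of
    q_bh; it does not affect the returned list.  Results are sorted by p
    ascending, ties by regulator symbol.
    """
    if not network.edges:
        raise UsageError("ur_overlap_scan: empty network")
    if not universe:
        raise UsageError("ur_overlap_scan: empty universe")
    deg_in = degs.genes & universe
    N, n = len(universe), len(deg_in)
    by_reg = network.targets_by_regulator()
    regs, Ks, ks = [], [], []
    for reg in sorted(by_reg):
        targets = by_reg[reg] & universe
        if not targets:
            continue
        regs.append(reg)
        Ks.append(len(targets))
        ks.append(len(targets & deg_in))
    if not regs:
        return []
    Ks_arr = np.array(Ks)
    ks_arr = np.array(ks)
    pvals = stats.hypergeom.sf(ks_arr - 1, N, Ks_arr, n)
    pvals = np.clip(pvals, np.nextafter(0.0, 1.0), 1.0)
    pvals[ks_arr == 0] = 1.0
    qvals = bh_adjust(pvals)
    results = [
        URResult(
            regulator=reg,
            n_targets_in_universe=int(K),
            overlap_k=int(k),
            p_right=float(p),
            q_bh=float(q),
            is_also_deg=reg in degs.genes,
        )
        for reg, K, k, p, q in zip(regs, Ks, ks, pvals, qvals)
    ]
    results.sort(key=lambda r: (r.p_right, r.regulator))
    return results


def significant_urs(results: Sequence[URResult], alpha: float = 0.01) -> frozenset[GeneSymbol]:
    return frozenset(r.regulator for r in results if r.q_bh <= alpha)


def ur_frame(results: Sequence[URResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "regulator": r.regulator,
                "n_targets_in_universe": r.n_targets_in_universe,
                "overlap_k": r.overlap_k,
                "p_right": r.p_right,
                "q_bh": r.q_bh,
                "is_also_deg": r.is_also_deg,
            }
            for r in results
        ],
        columns=[
            "regulator",
            "n_targets_in_universe",
            "overlap_k",
            "p_right",
            "q_bh",
            "is_also_deg",
        ],
    )


@dataclass(frozen=True)
class CandidateURs:
    per_study: Mapping[str, frozenset[GeneSymbol]]
    pooled: frozenset[GeneSymbol]


def candidate_urs(
    ur_gene_lists: Mapping[str, frozenset[GeneSymbol]],
    gwas_genes: Optional[TraitGeneSet | frozenset[GeneSymbol]] = None,
) -> CandidateURs:
    """Intersect per-study UR lists with the GWAS vascular gene set and pool.

    ``gwas_genes`` may be a TraitGeneSet, a plain gene set, or None when the
    input lists are already curated against GWAS (then the intersection is
    the identity).  The pooled set always equals the union of the per-study
    sets.
    """
    if isinstance(gwas_genes, TraitGeneSet):
        restrict = gwas_genes.genes
    else:
        restrict = gwas_genes
    per_study = {}
    pooled: set[str] = set()
    for study_id, urs in ur_gene_lists.items():
        hit = frozenset(urs) if restrict is None else frozenset(urs) & restrict
        per_study[study_id] = hit
        pooled |= hit
    out = CandidateURs(per_study=per_study, pooled=frozenset(pooled))
    assert out.pooled == frozenset().union(*out.per_study.values()) if per_study else True
    return out
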