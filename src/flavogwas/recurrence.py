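"""Multi-set Venn partitioning and cross-study recurrence of DEG sets.

A :class:`VennPartition` assigns every gene in the union of k study sets to
exactly one membership signature (a k-bit pattern ordered by input study
order).  Region sizes therefore sum to the union size, which is asserted on
every construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .core_io import GeneSymbol, StudyGeneSet
from .errors import FormatError, UsageError

log = logging.getLogger(__name__)

MAX_STUDIES = 8


@dataclass(frozen=True)
class VennPartition:
    """Disjoint signature regions over k study sets (all-zero pattern excluded)."""

    signatures: Mapping[str, frozenset[GeneSymbol]]
    study_ids: tuple[str, ...]

    @property
    def k(self) -> int:
        return len(self.study_ids)

    def __post_init__(self):
        union: set[str] = set()
        total = 0
        for sig, genes in self.signatures.items():
            if len(sig) != self.k or set(sig) - {"0", "1"} or "1" not in sig:
                raise UsageError(f"bad signature {sig!r} for k={self.k}")
            if union & genes:
                raise UsageError(f"region {sig} overlaps another region")
            union |= genes
            total += len(genes)
        assert total == len(union), "region sizes must sum to the union size"

    def region(self, signature: str) -> frozenset[GeneSymbol]:
        return self.signatures.get(signature, frozenset())

    def label(self, signature: str) -> str:
        members = [s for s, bit in zip(self.study_ids, signature) if bit == "1"]
        return "∩".join(members)

    def union(self) -> frozenset[GeneSymbol]:
        out: set[str] = set()
        for genes in self.signatures.values():
            out |= genes
        return frozenset(out)

    def membership_counts(self) -> dict[GeneSymbol, int]:
        return {
            g: sig.count("1")
            for sig, genes in self.signatures.items()
            for g in genes
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "signature": sig,
                "label": self.label(sig),
                "region_size": len(genes),
                "genes": ";".join(sorted(genes)),
            }
            for sig, genes in sorted(self.signatures.items())
        ]
        return pd.DataFrame(rows, columns=["signature", "label", "region_size", "genes"])


def venn_partition(studies: Sequence[StudyGeneSet]) -> VennPartition:
    """Classify every union gene by its exact membership pattern."""
    ids = [s.study_id for s in studies]
    if len(ids) != len(set(ids)):
        raise UsageError(f"duplicate study_id among {ids}")
    k = len(studies)
    if not 2 <= k <= MAX_STUDIES:
        raise UsageError(f"venn_partition supports 2..{MAX_STUDIES} studies, got {k}")
    if k > 6:
        log.warning("venn_partition over %d studies: %d regions", k, 2**k - 1)
    regions: dict[str, set[str]] = {}
    union: set[str] = set()
    for s in studies:
        union |= s.genes
    for gene in union:
        sig = "".join("1" if gene in s.genes else "0" for s in studies)
        regions.setdefault(sig, set()).add(gene)
    return VennPartition(
        signatures={sig: frozenset(g) for sig, g in regions.items()},
        study_ids=tuple(ids),
    )


def genes_in_at_least(studies: Sequence[StudyGeneSet], m: int) -> frozenset[GeneSymbol]:
    """Genes present in at least ``m`` of the study sets (m=1 is the union)."""
    k = len(studies)
    if not 1 <= m <= k:
        raise UsageError(f"m must be in 1..{k}, got {m}")
    counts: dict[str, int] = {}
    for s in studies:
        for gene in s.genes:
            counts[gene] = counts.get(gene, 0) + 1
    return frozenset(g for g, c in counts.items() if c >= m)


def export_setlists(studies: Sequence[StudyGeneSet], path) -> Path:
    """Write one named gene list per study in the plain list-exchange layout
    used by set-comparison web tools (``name: gene,gene,...``)."""
    path = Path(path)
    lines = [
        f"{s.study_id}:{','.join(sorted(s.genes))}"
        for s in studies
    ]
    path.write_text("\n".join(lines) + "\n")
    return path


def read_setlists(path) -> list[StudyGeneSet]:
    """Round-trip reader for :func:`export_setlists` output."""
    studies = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        if ":" not in line:
            raise FormatError(f"{path}:{lineno}: expected 'name:gene,gene,...'")
        name, _, genes = line.partition(":")
        members = frozenset(g.strip() for g in genes.split(",") if g.strip())
        studies.append(StudyGeneSet(study_id=name.strip(), genes=members))
    return studies
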