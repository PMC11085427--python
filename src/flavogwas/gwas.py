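"""Curation of GWAS-Catalog-style association exports into trait gene sets.

Associations are filtered by case-insensitive substring rules on the trait
string (the catalog describes traits verbally, so exclusions are phrase
lists, not accession arithmetic), mapped-gene strings are split into
symbols, and each surviving gene carries provenance back to the association
rows (accession, rsID) it came from.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
import yaml

from .core_io import GeneSymbol, normalize_symbol
from .errors import FormatError, UsageError

log = logging.getLogger(__name__)

#: Tokens in a mapped-gene field that do not denote a gene.
DEFAULT_NON_GENE_MARKERS = frozenset(
    {"no mapped genes", "intergenic", "nr", "n/a", "na", "-", "none"}
)

#: Separators seen in catalog mapped-gene fields.  " x " joins the two sides
#: of a SNP-by-SNP interaction; both sides contribute their parsable genes.
_SEPARATOR_RE = re.compile(r"\s+x\s+|\s-\s|;|,", flags=re.IGNORECASE)

TRAIT_LABELS = ("hypertension", "atherosclerosis", "arterial_stiffness", "other")


@dataclass(frozen=True)
class GwasAssociation:
    accession: str
    trait: str
    rsid: str
    mapped_gene_raw: str
    p_value: Optional[float] = None

    def __post_init__(self):
        if not self.accession:
            raise FormatError("association with empty accession")
        if not self.trait:
            raise FormatError("association with empty trait")


@dataclass(frozen=True)
class TraitGeneSet:
    """Genes mapped from curated associations for one trait, with provenance."""

    trait_label: str
    genes: frozenset[GeneSymbol]
    provenance: Mapping[GeneSymbol, frozenset[tuple[str, str]]]
    n_associations: int
    by_trait: Mapping[str, frozenset[GeneSymbol]] = field(default_factory=dict)

    def __post_init__(self):
        orphans = [g for g in self.genes if not self.provenance.get(g)]
        if orphans:
            raise UsageError(f"genes without provenance: {sorted(orphans)[:5]}")


@dataclass(frozen=True)
class GwasColumns:
    trait: str = "DISEASE/TRAIT"
    mapped_gene: str = "MAPPED_GENE"
    snps: str = "SNPS"
    accession: str = "STUDY ACCESSION"
    p_value: str = "P-VALUE"


def read_gwas_export(
    path, columns: GwasColumns = GwasColumns(), sep: str = "\t"
) -> list[GwasAssociation]:
    """Read a GWAS-Catalog association export (tab-delimited, header row)."""
    df = pd.read_csv(path, sep=sep, dtype=str)
    needed = [columns.trait, columns.mapped_gene, columns.snps, columns.accession]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    out = []
    for _, row in df.iterrows():
        pval = None
        if columns.p_value in df.columns and not pd.isna(row[columns.p_value]):
            try:
                pval = float(row[columns.p_value])
            except ValueError:
                pval = None
        raw = row[columns.mapped_gene]
        out.append(
            GwasAssociation(
                accession=str(row[columns.accession]).strip(),
                trait=str(row[columns.trait]).strip(),
                rsid=str(row[columns.snps]).strip(),
                mapped_gene_raw="" if pd.isna(raw) else str(raw).strip(),
                p_value=pval,
            )
        )
    return out


def parse_mapped_genes(
    raw: str,
    alias_map: Optional[Mapping[str, str]] = None,
    non_gene_markers: frozenset[str] = DEFAULT_NON_GENE_MARKERS,
) -> frozenset[GeneSymbol]:
    """Split a mapped-gene field into normalized symbols.

    Splits on `` - ``, ``;``, ``,`` and the interaction separator `` x ``;
    drops placeholder tokens ("no mapped genes", intergenic markers).  An
    empty result is valid: intergenic-only rows contribute nothing.
    """
    if raw is None or not str(raw).strip():
        return frozenset()
    genes = set()
    for token in _SEPARATOR_RE.split(str(raw)):
        token = token.strip()
        if not token or token.lower() in non_gene_markers:
            continue
        genes.add(normalize_symbol(token, alias_map))
    return frozenset(genes)


def filter_associations(
    associations: Sequence[GwasAssociation],
    include_terms: Sequence[str],
    exclude_terms: Sequence[str] = (),
) -> list[GwasAssociation]:
    """Keep associations whose trait matches >=1 include term and no exclude term.

    Matching is case-insensitive substring; input order is preserved and the
    operation is idempotent.
    """
    if not include_terms:
        raise UsageError("filter_associations: include_terms must be non-empty")
    inc = [t.lower() for t in include_terms]
    exc = [t.lower() for t in exclude_terms]
    kept = []
    for a in associations:
        trait = a.trait.lower()
        if any(t in trait for t in inc) and not any(t in trait for t in exc):
            kept.append(a)
    return kept


def build_trait_gene_set(
    filtered: Sequence[GwasAssociation],
    trait_label: str,
    alias_map: Optional[Mapping[str, str]] = None,
) -> TraitGeneSet:
    """Union the mapped genes of curated associations into one trait set."""
    provenance: dict[str, set[tuple[str, str]]] = {}
    for a in filtered:
        for gene in parse_mapped_genes(a.mapped_gene_raw, alias_map):
            provenance.setdefault(gene, set()).add((a.accession, a.rsid))
    genes = frozenset(provenance)
    if not filtered:
        log.warning("trait %s: zero associations after filtering", trait_label)
    return TraitGeneSet(
        trait_label=trait_label,
        genes=genes,
        provenance={g: frozenset(v) for g, v in provenance.items()},
        n_associations=len(filtered),
        by_trait={trait_label: genes},
    )


def union_trait_sets(
    trait_sets: Sequence[TraitGeneSet], label: str = "vascular_dysfunction"
) -> TraitGeneSet:
    """Pool per-trait gene sets, merging provenance and keeping per-trait membership."""
    if not trait_sets:
        raise UsageError("union_trait_sets: need >=1 input set")
    provenance: dict[str, set[tuple[str, str]]] = {}
    by_trait: dict[str, frozenset[str]] = {}
    n_assoc = 0
    for ts in trait_sets:
        n_assoc += ts.n_associations
        for trait, genes in ts.by_trait.items():
            by_trait[trait] = frozenset(by_trait.get(trait, frozenset()) | genes)
        for gene, prov in ts.provenance.items():
            provenance.setdefault(gene, set()).update(prov)
    return TraitGeneSet(
        trait_label=label,
        genes=frozenset(provenance),
        provenance={g: frozenset(v) for g, v in provenance.items()},
        n_associations=n_assoc,
        by_trait=by_trait,
    )


def load_trait_rules(path: Optional[Path] = None) -> dict[str, dict[str, list[str]]]:
    """Load per-trait include/exclude phrase rules (shipped defaults if no path)."""
    if path is None:
        text = resources.files("flavogwas").joinpath("data", "trait_rules.yaml").read_text()
    else:
        text = Path(path).read_text()
    rules = yaml.safe_load(text)
    for trait, rule in rules.items():
        rule.setdefault("include", [trait.replace("_", " ")])
        rule.setdefault("exclude", [])
    return rules


def curate_traits(
    associations: Sequence[GwasAssociation],
    rules: Optional[Mapping[str, Mapping[str, Iterable[str]]]] = None,
    alias_map=None,
) -> tuple[dict[str, TraitGeneSet], TraitGeneSet]:
    """Apply the per-trait rules and pool the results.

    Returns (per-trait sets, pooled vascular-dysfunction set).
    """
    if rules is None:
        rules = load_trait_rules()
    per_trait = {}
    for trait_label, rule in rules.items():
        kept = filter_associations(
            associations, list(rule["include"]), list(rule["exclude"])
        )
        per_trait[trait_label] = build_trait_gene_set(kept, trait_label, alias_map)
    pooled = union_trait_sets(list(per_trait.values()))
    return per_trait, pooled
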