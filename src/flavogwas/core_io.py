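"""Domain types, gene-symbol normalization, and file readers/writers.

Gene symbols are HGNC-style uppercase tokens.  All ingestion funnels through
:func:`normalize_symbol`, which trims, uppercases, and resolves aliases via a
shipped two-column alias map (seeded with the symbol variants that occur in
the curated source lists, e.g. ``PPRG -> PPARG`` and ``IL8 -> CXCL8``).
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd

from .errors import FormatError, InvalidSymbolError, UsageError

log = logging.getLogger(__name__)

GeneSymbol = str

SOURCE_TAGS = ("KEGG", "WikiPathways", "both")

_RSID_RE = re.compile(r"^rs\d+$")
_ALIAS_MAP_CACHE: Optional[dict[str, str]] = None


def _data_path(*parts: str):
    return resources.files("flavogwas").joinpath("data", *parts)


def load_alias_map(path: Optional[Path] = None) -> dict[str, GeneSymbol]:
    """Read a two-column (alias, canonical) TSV into an uppercase-keyed map."""
    if path is None:
        text = _data_path("alias_map.tsv").read_text()
    else:
        text = Path(path).read_text()
    mapping: dict[str, str] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise FormatError(f"alias map line must have 2 columns: {line!r}")
        mapping[fields[0].strip().upper()] = fields[1].strip().upper()
    return mapping


def default_alias_map() -> dict[str, GeneSymbol]:
    global _ALIAS_MAP_CACHE
    if _ALIAS_MAP_CACHE is None:
        _ALIAS_MAP_CACHE = load_alias_map()
    return _ALIAS_MAP_CACHE


def normalize_symbol(
    raw: str, alias_map: Optional[Mapping[str, GeneSymbol]] = None
) -> GeneSymbol:
    """Trim and uppercase ``raw``, then resolve it through the alias map.

    Alias resolution iterates to a fixed point so that normalization is
    idempotent even for chained aliases.
    """
    if alias_map is None:
        alias_map = default_alias_map()
    symbol = str(raw).strip().upper()
    if not symbol:
        raise InvalidSymbolError(f"empty gene symbol: {raw!r}")
    for _ in range(10):
        resolved = alias_map.get(symbol, symbol)
        if resolved == symbol:
            break
        symbol = resolved
    return symbol


def normalize_symbols(
    raws: Iterable[str], alias_map: Optional[Mapping[str, GeneSymbol]] = None
) -> frozenset[GeneSymbol]:
    return frozenset(normalize_symbol(r, alias_map) for r in raws)


@dataclass(frozen=True)
class StudyGeneSet:
    """One study's deduplicated DEG symbols with optional per-gene direction."""

    study_id: str
    genes: frozenset[GeneSymbol]
    description: str = ""
    direction: Mapping[GeneSymbol, int] = field(default_factory=dict)

    def __post_init__(self):
        extra = set(self.direction) - set(self.genes)
        if extra:
            raise UsageError(
                f"direction keys not in gene set for {self.study_id}: {sorted(extra)[:5]}"
            )

    @property
    def n_degs(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    name: str
    source_tag: str
    genes: frozenset[GeneSymbol]


@dataclass
class GeneSetCollection:
    """Named pathway sets with source tags and an optional background universe."""

    sets: list[GeneSet]
    universe: Optional[frozenset[GeneSymbol]] = None

    def __post_init__(self):
        ids = [s.set_id for s in self.sets]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"duplicate set_id(s): {dupes}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def all_genes(self) -> frozenset[GeneSymbol]:
        out: set[str] = set()
        for s in self.sets:
            out |= s.genes
        return frozenset(out)

    def get(self, set_id: str) -> GeneSet:
        for s in self.sets:
            if s.set_id == set_id:
                return s
        raise KeyError(set_id)


@dataclass(frozen=True)
class RegulatorNetwork:
    """Regulator -> target edges with an optional sign (+1 activation, -1 inhibition)."""

    edges: frozenset[tuple[GeneSymbol, GeneSymbol, Optional[int]]]

    def regulators(self) -> frozenset[GeneSymbol]:
        return frozenset(e[0] for e in self.edges)

    def targets_of(self, regulator: GeneSymbol) -> frozenset[GeneSymbol]:
        return frozenset(t for r, t, _ in self.edges if r == regulator)

    def targets_by_regulator(self) -> dict[GeneSymbol, frozenset[GeneSymbol]]:
        out: dict[str, set[str]] = {}
        for r, t, _ in self.edges:
            out.setdefault(r, set()).add(t)
        return {r: frozenset(v) for r, v in out.items()}


@dataclass(frozen=True)
class VariantRecord:
    gene: GeneSymbol
    rsid: str
    consequence: str = ""
    frequency: Optional[float] = None
    clinical_significance: Optional[str] = None

    def __post_init__(self):
        if not _RSID_RE.match(self.rsid):
            raise FormatError(f"not an rs number: {self.rsid!r}")
        if self.frequency is not None and not (0.0 <= self.frequency <= 1.0):
            raise FormatError(f"frequency out of [0,1]: {self.frequency}")


def _parse_direction(value) -> Optional[int]:
    token = str(value).strip().lower()
    if token in {"1", "+1", "up", "u"}:
        return 1
    if token in {"-1", "down", "d"}:
        return -1
    return None


def read_study_table(
    path,
    study_id: str,
    gene_col: str = "gene",
    direction_col: Optional[str] = None,
    sep: str = "\t",
    description: str = "",
    alias_map: Optional[Mapping[str, str]] = None,
) -> StudyGeneSet:
    """Read a delimited DEG table into a :class:`StudyGeneSet`.

    Duplicate gene rows collapse to set semantics (microarray probes map
    many-to-one); rows with conflicting directions resolve to "unset" with a
    warning.
    """
    try:
        df = pd.read_csv(path, sep=sep, dtype=str)
    except OSError as exc:
        raise FormatError(f"cannot read study table {path}: {exc}") from exc
    if gene_col not in df.columns:
        raise FormatError(
            f"{path}: missing gene column {gene_col!r} (columns: {list(df.columns)})"
        )
    genes: set[str] = set()
    direction: dict[str, int] = {}
    conflicted: set[str] = set()
    for _, row in df.iterrows():
        raw = row[gene_col]
        if pd.isna(raw) or not str(raw).strip():
            continue
        symbol = normalize_symbol(raw, alias_map)
        genes.add(symbol)
        if direction_col is not None and direction_col in df.columns:
            d = _parse_direction(row[direction_col])
            if d is None:
                continue
            if symbol in direction and direction[symbol] != d:
                conflicted.add(symbol)
            elif symbol not in conflicted:
                direction[symbol] = d
    for symbol in conflicted:
        direction.pop(symbol, None)
        log.warning("%s: conflicting directions for %s; direction unset", study_id, symbol)
    if not genes:
        raise FormatError(f"{path}: no genes parsed")
    n_dup = len(df) - len(genes)
    if n_dup > 0:
        log.info("%s: collapsed %d duplicate gene row(s)", study_id, n_dup)
    return StudyGeneSet(
        study_id=study_id,
        genes=frozenset(genes),
        description=description,
        direction=direction,
    )


def read_gene_list(path, alias_map=None) -> frozenset[GeneSymbol]:
    """One symbol per line; blank lines and ``#`` comments ignored."""
    genes = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        genes.add(normalize_symbol(line, alias_map))
    return frozenset(genes)


def read_gmt(
    path,
    source_tags: tuple[str, ...] = SOURCE_TAGS,
    alias_map: Optional[Mapping[str, str]] = None,
) -> GeneSetCollection:
    """Parse a GMT file (set_id, description, members...) into a collection.

    The description field doubles as the source-tag carrier: when it matches a
    configured tag (``KEGG``, ``WikiPathways``, ``both``) the set is tagged
    accordingly, otherwise the tag is ``other``.
    """
    tag_lookup = {t.lower(): t for t in source_tags}
    sets: list[GeneSet] = []
    seen: set[str] = set()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: GMT line has <3 fields")
        set_id, description = fields[0].strip(), fields[1].strip()
        if set_id in seen:
            raise FormatError(f"{path}:{lineno}: duplicate set_id {set_id!r}")
        seen.add(set_id)
        tag = tag_lookup.get(description.lower(), "other")
        genes = frozenset(
            normalize_symbol(g, alias_map) for g in fields[2:] if g.strip()
        )
        sets.append(GeneSet(set_id=set_id, name=set_id, source_tag=tag, genes=genes))
    return GeneSetCollection(sets=sets)


def read_network(path, sep: str = "\t", alias_map=None) -> RegulatorNetwork:
    """Read a 2-3 column (regulator, target[, sign]) edge list."""
    df = pd.read_csv(path, sep=sep, dtype=str)
    cols = list(df.columns)
    if len(cols) < 2:
        raise FormatError(f"{path}: network needs >=2 columns, got {cols}")
    edges: set[tuple[str, str, Optional[int]]] = set()
    for _, row in df.iterrows():
        reg = normalize_symbol(row[cols[0]], alias_map)
        tgt = normalize_symbol(row[cols[1]], alias_map)
        sign = _parse_direction(row[cols[2]]) if len(cols) >= 3 else None
        edges.add((reg, tgt, sign))
    return RegulatorNetwork(edges=frozenset(edges))


def read_variants(path, sep: str = "\t", alias_map=None) -> list[VariantRecord]:
    """Read a variant-annotation TSV (gene, rsid, consequence, frequency, clinical_significance)."""
    df = pd.read_csv(path, sep=sep, dtype=str)
    required = {"gene", "rsid"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: variant table needs columns {sorted(required)}")
    records = []
    for _, row in df.iterrows():
        freq = row.get("frequency")
        freq = None if pd.isna(freq) or str(freq).strip() == "" else float(freq)
        clin = row.get("clinical_significance")
        clin = None if pd.isna(clin) or str(clin).strip() == "" else str(clin)
        cons = row.get("consequence")
        cons = "" if pd.isna(cons) else str(cons)
        records.append(
            VariantRecord(
                gene=normalize_symbol(row["gene"], alias_map),
                rsid=str(row["rsid"]).strip(),
                consequence=cons,
                frequency=freq,
                clinical_significance=clin,
            )
        )
    return records


def _sorted_frame(df: pd.DataFrame) -> pd.DataFrame:
    if len(df) == 0 or len(df.columns) == 0:
        return df
    return df.sort_values(by=list(df.columns), kind="mergesort").reset_index(drop=True)


def write_report(
    tables: Mapping[str, pd.DataFrame], out_dir, format: str = "tsv"
) -> dict[str, Path]:
    """Write each table deterministically (rows sorted by all columns, in order).

    Returns a map from table name to the written path.  JSON output
    round-trips losslessly through :func:`read_report`.
    """
    if not tables:
        raise UsageError("write_report: no tables given")
    if format not in {"tsv", "json"}:
        raise UsageError(f"unknown report format {format!r} (expected tsv or json)")
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise FormatError(f"cannot create output directory {out_dir}: {exc}") from exc
    paths: dict[str, Path] = {}
    for name, df in tables.items():
        df = _sorted_frame(df)
        path = out_dir / f"{name}.{format}"
        if format == "tsv":
            df.to_csv(path, sep="\t", index=False, lineterminator="\n")
        else:
            payload = {"columns": list(df.columns), "data": df.values.tolist()}
            path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
        paths[name] = path
    return paths


def read_report(path) -> pd.DataFrame:
    """Read back a table written by :func:`write_report`."""
    path = Path(path)
    if path.suffix == ".json":
        payload = json.loads(path.read_text())
        return pd.DataFrame(payload["data"], columns=payload["columns"])
    return pd.read_csv(path, sep="\t")
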