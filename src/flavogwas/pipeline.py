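"""End-to-end orchestration: curation -> recurrence -> integration ->
placement -> UR intersection -> evidence matrix -> priority set.

A run is driven by a single YAML configuration.  Two input modes are
supported and can be mixed:

* full mode — per-study DEG tables plus a GWAS association export; the
  pipeline computes recurrence and the candidate-DEG intersection itself;
* curated-list mode — precomputed recurrence sets, candidate-DEG gene
  lists and per-study candidate-UR lists (the form in which evidence from
  curated/commercial tools arrives).

Every run writes deterministic stage TSVs, an evidence-matrix JSON, and a
reproducibility manifest (config hash, input checksums, package version).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd
import yaml

from . import __version__
from .core_io import (
    read_gene_list,
    read_gmt,
    read_study_table,
    write_report,
)
from .enrichment import enrichment_frame, placement_table, run_ora
from .errors import ConfigError, StageError
from .evidence import read_lit_counts, top_genes
from .gwas import curate_traits, load_trait_rules, read_gwas_export
from .prioritize import (
    PriorityReport,
    build_evidence_matrix,
    candidate_degs,
    priority_set,
)
from .recurrence import genes_in_at_least, venn_partition
from .regulators import candidate_urs, read_ur_list, significant_urs, ur_frame, ur_overlap_scan
from .synthetic import SyntheticBundle

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    out_dir: Path
    #: full mode: [{path, study_id, gene_col?, direction_col?}, ...]
    studies: list[dict] = field(default_factory=list)
    gwas_path: Optional[Path] = None
    trait_rules_path: Optional[Path] = None
    #: curated-list mode
    candidate_deg_paths: list[Path] = field(default_factory=list)
    recurrent_ge2_path: Optional[Path] = None
    recurrent_ge3_path: Optional[Path] = None
    #: study_id -> path of precomputed candidate-UR lists (already
    #: GWAS-curated); mutually exclusive with network_path
    candidate_ur_lists: dict[str, Path] = field(default_factory=dict)
    network_path: Optional[Path] = None
    gmt_path: Optional[Path] = None
    #: optional background gene list (one symbol per line) for ORA and UR scans
    universe_path: Optional[Path] = None
    lit_counts_path: Optional[Path] = None
    #: (pool, category) -> min_count rules for the top-literature sets
    lit_rules: dict = field(default_factory=dict)
    min_hits: int = 2
    ora_q: float = 0.05
    ur_q: float = 0.01
    priority_mode: str = "union"
    min_criteria: int = 2
    alias_map_path: Optional[Path] = None
    seed: Optional[int] = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw, base=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: Mapping, base: Optional[Path] = None) -> "RunConfig":
        def _p(value):
            if value is None:
                return None
            p = Path(value)
            return p if p.is_absolute() or base is None else base / p

        try:
            cfg = cls(
                out_dir=_p(raw["out_dir"]),
                studies=[
                    {**s, "path": _p(s["path"])} for s in raw.get("studies", [])
                ],
                gwas_path=_p(raw.get("gwas_path")),
                trait_rules_path=_p(raw.get("trait_rules_path")),
                candidate_deg_paths=[_p(p) for p in raw.get("candidate_deg_paths", [])],
                recurrent_ge2_path=_p(raw.get("recurrent_ge2_path")),
                recurrent_ge3_path=_p(raw.get("recurrent_ge3_path")),
                candidate_ur_lists={
                    k: _p(v) for k, v in raw.get("candidate_ur_lists", {}).items()
                },
                network_path=_p(raw.get("network_path")),
                gmt_path=_p(raw.get("gmt_path")),
                universe_path=_p(raw.get("universe_path")),
                lit_counts_path=_p(raw.get("lit_counts_path")),
                lit_rules=dict(raw.get("lit_rules", {})),
                min_hits=int(raw.get("min_hits", 2)),
                ora_q=float(raw.get("ora_q", 0.05)),
                ur_q=float(raw.get("ur_q", 0.01)),
                priority_mode=str(raw.get("priority_mode", "union")),
                min_criteria=int(raw.get("min_criteria", 2)),
                alias_map_path=_p(raw.get("alias_map_path")),
                seed=raw.get("seed"),
            )
        except KeyError as exc:
            raise ConfigError(f"missing required config key: {exc}") from exc
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.gmt_path is None:
            raise ConfigError("config requires gmt_path (pathway collection)")
        paths = [self.gmt_path, self.gwas_path, self.trait_rules_path,
                 self.recurrent_ge2_path, self.recurrent_ge3_path,
                 self.network_path, self.lit_counts_path, self.alias_map_path,
                 self.universe_path,
                 *self.candidate_deg_paths, *self.candidate_ur_lists.values(),
                 *[s["path"] for s in self.studies]]
        for p in paths:
            if p is not None and not Path(p).exists():
                raise ConfigError(f"input path does not exist: {p}")
        if not (0 < self.ora_q <= 1) or not (0 < self.ur_q <= 1):
            raise ConfigError("ora_q and ur_q must lie in (0, 1]")
        if self.min_hits < 1:
            raise ConfigError("min_hits must be >= 1")
        if self.studies:
            if self.gwas_path is None:
                raise ConfigError("full mode (studies given) requires gwas_path")
        else:
            if not self.candidate_deg_paths:
                raise ConfigError(
                    "curated-list mode requires candidate_deg_paths"
                )
            if self.recurrent_ge2_path is None:
                raise ConfigError("curated-list mode requires recurrent_ge2_path")
        if not self.candidate_ur_lists and self.network_path is None:
            raise ConfigError("provide candidate_ur_lists or network_path")

    def manifest(self) -> dict:
        payload = {}
        for f in dataclasses.fields(self):
            value = getattr(self, f.name)
            if isinstance(value, Path):
                value = str(value)
            elif isinstance(value, list):
                value = [
                    {k: str(v) for k, v in item.items()} if isinstance(item, dict)
                    else str(item)
                    for item in value
                ]
            elif isinstance(value, dict):
                value = {str(k): str(v) for k, v in value.items()}
            payload[f.name] = value
        blob = json.dumps(payload, sort_keys=True)
        checksums = {}
        for s in self.studies:
            checksums[str(s["path"])] = _sha256(s["path"])
        for p in [self.gwas_path, self.gmt_path, self.recurrent_ge2_path,
                  self.recurrent_ge3_path, self.network_path,
                  self.lit_counts_path, *self.candidate_deg_paths,
                  *self.candidate_ur_lists.values()]:
            if p is not None:
                checksums[str(p)] = _sha256(p)
        return {
            "config": payload,
            "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
            "input_sha256": checksums,
            "flavogwas_version": __version__,
            "seed": self.seed,
        }


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass
class PipelineResult:
    report: PriorityReport
    out_dir: Path
    tables: dict[str, Path]


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute all stages; any stage failure raises :class:`StageError`."""
    config.validate()
    from .core_io import load_alias_map

    alias = load_alias_map(config.alias_map_path) if config.alias_map_path else None
    tables: dict[str, pd.DataFrame] = {}
    stage = "load-pathways"
    try:
        collection = read_gmt(config.gmt_path, alias_map=alias)
        universe = (
            read_gene_list(config.universe_path, alias)
            if config.universe_path is not None
            else (collection.universe or collection.all_genes())
        )

        stage = "curate"
        trait_sets = None
        if config.gwas_path is not None:
            associations = read_gwas_export(config.gwas_path)
            rules = load_trait_rules(config.trait_rules_path)
            trait_sets, pooled_gwas = curate_traits(associations, rules, alias)
            tables["trait_sets"] = pd.DataFrame(
                [
                    {"trait": t, "n_genes": len(ts.genes),
                     "n_associations": ts.n_associations,
                     "genes": ";".join(sorted(ts.genes))}
                    for t, ts in trait_sets.items()
                ]
            )

        stage = "recurrence"
        studies = []
        if config.studies:
            for s in config.studies:
                studies.append(
                    read_study_table(
                        s["path"], s["study_id"],
                        gene_col=s.get("gene_col", "gene"),
                        direction_col=s.get("direction_col"),
                        alias_map=alias,
                    )
                )
            partition = venn_partition(studies)
            tables["venn_regions"] = partition.to_frame()
            ge2 = genes_in_at_least(studies, 2)
            ge3 = genes_in_at_least(studies, 3)
        else:
            ge2 = read_gene_list(config.recurrent_ge2_path, alias)
            ge3 = (
                read_gene_list(config.recurrent_ge3_path, alias)
                if config.recurrent_ge3_path
                else frozenset()
            )

        stage = "integrate"
        deg_prov = None
        if studies and trait_sets is not None:
            cdeg = candidate_degs(studies, trait_sets)
            deg_pool = cdeg.pooled
            deg_prov = {
                gene: sorted(
                    f"{s}:{t}" for (s, t), cell in cdeg.cells.items() if gene in cell
                )
                for gene in deg_pool
            }
            tables["candidate_deg_cells"] = pd.DataFrame(
                [
                    {"study": s, "trait": t, "n_genes": len(cell),
                     "genes": ";".join(sorted(cell))}
                    for (s, t), cell in sorted(cdeg.cells.items())
                ]
            )
            multi_trait = {
                g: traits for (_, g), traits in cdeg.multi_trait.items()
            }
        else:
            deg_pool = frozenset().union(
                *[read_gene_list(p, alias) for p in config.candidate_deg_paths]
            )
            multi_trait = {}
        # recurrence restricted to candidate genes
        ge2 = frozenset(ge2)
        ge3 = frozenset(ge3)

        stage = "enrich"
        ora = run_ora(deg_pool, collection, frozenset(universe))
        tables["enrichment"] = enrichment_frame(ora)
        placement = placement_table(deg_pool, collection, min_hits=config.min_hits)
        tables["placement"] = placement.table

        stage = "urs"
        if config.candidate_ur_lists:
            ur_lists = {
                sid: read_ur_list(p, alias)
                for sid, p in config.candidate_ur_lists.items()
            }
            gwas_restrict = None
        else:
            from .core_io import read_network

            network = read_network(config.network_path, alias_map=alias)
            ur_lists = {}
            for s in studies:
                scan = ur_overlap_scan(s, network, frozenset(universe))
                ur_lists[s.study_id] = significant_urs(scan, config.ur_q)
                tables[f"ur_scan_{s.study_id}"] = ur_frame(scan)
            gwas_restrict = (
                frozenset().union(*[ts.genes for ts in trait_sets.values()])
                if trait_sets
                else None
            )
        urs = candidate_urs(ur_lists, gwas_restrict)
        tables["candidate_urs"] = pd.DataFrame(
            [
                {"study": sid, "n_candidate_urs": len(genes),
                 "genes": ";".join(sorted(genes))}
                for sid, genes in sorted(urs.per_study.items())
            ]
        )
        ur_prov = {
            gene: sorted(s for s, members in urs.per_study.items() if gene in members)
            for gene in urs.pooled
        }

        stage = "literature"
        lit_top_sets = {}
        if config.lit_counts_path is not None:
            rules = config.lit_rules or {
                "deg/cvd_snp": 34, "deg/nutrition_snp": 5,
                "ur/cvd_snp": 24, "ur/nutrition_snp": 5,
            }
            for key, threshold in rules.items():
                pool_name, _, category = key.partition("/")
                try:
                    counts = read_lit_counts(
                        config.lit_counts_path, alias_map=alias, pool=pool_name
                    )
                except Exception:
                    counts = read_lit_counts(config.lit_counts_path, alias_map=alias)
                pool_genes = deg_pool if pool_name == "deg" else urs.pooled
                lit_top_sets[key.replace("/", "_")] = (
                    top_genes(counts, category, min_count=int(threshold)) & pool_genes
                )

        stage = "prioritize"
        matrix = build_evidence_matrix(
            candidate_deg_pool=deg_pool,
            candidate_ur_pool=urs.pooled,
            recurrence_sets={2: ge2, 3: ge3},
            placement_union=placement.gene_union,
            lit_top_sets=lit_top_sets,
            deg_provenance=deg_prov,
            ur_provenance=ur_prov,
            multi_trait_flags=multi_trait,
        )
        report = priority_set(
            matrix,
            mode=config.priority_mode,
            min_criteria=config.min_criteria,
            manifest=config.manifest(),
        )
        tables["evidence_matrix"] = matrix.to_frame()
        tables["priority"] = report.to_frame()
        tables["criteria_sets"] = pd.DataFrame(
            [
                {"criterion": c, "n_genes": len(genes),
                 "genes": ";".join(sorted(genes))}
                for c, genes in sorted(report.criteria_sets.items())
            ]
        )

        stage = "write"
        out_paths = write_report(tables, config.out_dir, format="tsv")
        manifest_path = Path(config.out_dir) / "manifest.json"
        manifest_path.write_text(
            json.dumps(report.manifest, indent=1, sort_keys=True) + "\n"
        )
        out_paths["manifest"] = manifest_path
    except (ConfigError, StageError):
        raise
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc
    return PipelineResult(report=report, out_dir=Path(config.out_dir), tables=out_paths)


def run_synthetic_bundle(bundle: SyntheticBundle, ur_q: float = 0.01,
                         min_hits: int = 2) -> PriorityReport:
    """In-memory pipeline over a synthetic bundle (no files written).

    Mirrors :func:`run_pipeline` full mode: curate the generated
    associations, compute recurrence, intersect with trait sets, place in
    pathways, scan the network for URs, take literature tops, and
    prioritize.
    """
    from .gwas import GwasAssociation

    associations = [
        GwasAssociation(
            accession=row["STUDY ACCESSION"],
            trait=row["DISEASE/TRAIT"],
            rsid=row["SNPS"],
            mapped_gene_raw=row["MAPPED_GENE"],
        )
        for _, row in bundle.associations.iterrows()
    ]
    trait_sets, _ = curate_traits(associations, alias_map={})
    studies = list(bundle.studies)
    ge2 = genes_in_at_least(studies, 2)
    ge3 = genes_in_at_least(studies, 3)
    cdeg = candidate_degs(studies, trait_sets)
    placement = placement_table(cdeg.pooled, bundle.collection, min_hits=min_hits)
    universe = bundle.collection.universe or bundle.collection.all_genes()
    ur_lists = {}
    for s in studies:
        scan = ur_overlap_scan(s, bundle.network, frozenset(universe))
        ur_lists[s.study_id] = significant_urs(scan, ur_q)
    gwas_genes = frozenset().union(*[ts.genes for ts in trait_sets.values()])
    urs = candidate_urs(ur_lists, gwas_genes)
    thresholds = bundle.params.lit_thresholds
    lit_top_sets = {
        f"deg_{cat}": top_genes(bundle.lit_counts, cat, min_count=thr) & cdeg.pooled
        for cat, thr in thresholds.items()
    }
    lit_top_sets.update(
        {
            f"ur_{cat}": top_genes(bundle.lit_counts, cat, min_count=thr) & urs.pooled
            for cat, thr in thresholds.items()
        }
    )
    matrix = build_evidence_matrix(
        candidate_deg_pool=cdeg.pooled,
        candidate_ur_pool=urs.pooled,
        recurrence_sets={2: ge2, 3: ge3},
        placement_union=placement.gene_union,
        lit_top_sets=lit_top_sets,
    )
    return priority_set(matrix, manifest={"seed": bundle.truth.seed})
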