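"""Synthetic inputs with planted ground truth for every pipeline stage.

The generator emulates the statistical shape of the real inputs: five
studies with DEG list sizes in the hundreds-to-thousands over a ~20k-gene
universe, a small shared core plus planted priority genes recurring in >=2
studies, trait-tagged GWAS gene sets partially overlapping the DEGs (with
decoy associations matching the default exclusion phrases), pathway sets
and regulator networks with planted enriched members, and heavy-tailed
literature counts with the planted genes above threshold.

Every generator is a pure function of ``(params, seed)``: one documented
pseudo-random stream per stage (derived from the seed by stage index) keeps
the stages decoupled, so regenerating one stage never perturbs another.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core_io import GeneSet, GeneSetCollection, RegulatorNetwork, StudyGeneSet
from .errors import UsageError
from .evidence import LiteratureCounts

#: Fixed stage -> stream index map; append only, never reorder.
_STAGES = {
    "planted": 0,
    "studies": 1,
    "gwas": 2,
    "pathways": 3,
    "network": 4,
    "lit": 5,
}

#: Trait strings for decoy associations; all are removed by the default
#: curation rules (either no include term matches or an exclude phrase does).
DECOY_TRAITS = (
    "Preeclampsia",
    "Pulmonary arterial hypertension",
    "Early-onset hypertension",
    "Treatment-resistant hypertension",
    "Hypertension risk in short sleep duration",
)


@dataclass(frozen=True)
class SyntheticParams:
    """Generator parameters; the defaults mirror the magnitudes of the real
    study conditions (5 studies of 554-2231 DEGs, trait sets of 375/69/58
    genes, a 20,000-gene universe)."""

    universe_size: int = 20_000
    study_sizes: tuple[int, ...] = (1693, 717, 554, 2231, 1401)
    shared_core_size: int = 10
    n_planted_priority: int = 8
    trait_set_sizes: Mapping[str, int] = field(
        default_factory=lambda: {
            "hypertension": 375,
            "atherosclerosis": 69,
            "arterial_stiffness": 58,
        }
    )
    assoc_per_gene: float = 1.2
    n_decoy_associations: int = 15
    planted_trait_overlap: float = 1.0
    n_background_sets: int = 30
    n_planted_pathways: int = 2
    pathway_size_range: tuple[int, int] = (20, 80)
    enrichment_factor: float = 5.0
    n_background_regulators: int = 40
    n_planted_regulators: int = 3
    regulator_targets_range: tuple[int, int] = (100, 400)
    bias_factor: float = 5.0
    n_lit_background: int = 150
    lit_thresholds: Mapping[str, int] = field(
        default_factory=lambda: {"cvd_snp": 30, "nutrition_snp": 5}
    )
    lit_tail_p: float = 0.2


@dataclass(frozen=True)
class SyntheticTruth:
    universe_size: int
    planted_priority_genes: frozenset[str]
    planted_pathways: frozenset[str]
    planted_regulators: frozenset[str]
    study_sizes: tuple[int, ...]
    shared_core_size: int
    trait_set_sizes: Mapping[str, int]
    seed: int


def _rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(_STAGES[stage],))
    )


def gene_universe(universe_size: int) -> np.ndarray:
    return np.array([f"G{i:05d}" for i in range(1, universe_size + 1)])


def planted_priority_genes(params: SyntheticParams, seed: int) -> frozenset[str]:
    if params.n_planted_priority == 0:
        return frozenset()
    rng = _rng(seed, "planted")
    universe = gene_universe(params.universe_size)
    return frozenset(
        str(g) for g in rng.choice(universe, size=params.n_planted_priority, replace=False)
    )


def generate_studies(params: SyntheticParams, seed: int) -> list[StudyGeneSet]:
    """Each study = shared core + its planted genes + an independent uniform fill.

    Planted priority genes are each placed in at least two studies, so they
    recur; the shared core recurs in all studies.
    """
    sizes = params.study_sizes
    k = len(sizes)
    if params.shared_core_size > min(sizes):
        raise UsageError(
            f"shared_core_size {params.shared_core_size} exceeds the smallest "
            f"study size {min(sizes)}"
        )
    if params.n_planted_priority > 0 and k < 2:
        raise UsageError("planting priority genes in >=2 studies needs >=2 studies")
    planted = sorted(planted_priority_genes(params, seed))
    rng = _rng(seed, "studies")
    universe = gene_universe(params.universe_size)
    rest = np.array(sorted(set(universe) - set(planted)))
    core = [str(g) for g in rng.choice(rest, size=params.shared_core_size, replace=False)]
    fill_pool = np.array(sorted(set(rest) - set(core)))

    member_of: list[set[str]] = [set() for _ in range(k)]
    for gene in planted:
        n_studies = int(rng.integers(2, k + 1))
        for idx in rng.choice(k, size=n_studies, replace=False):
            member_of[idx].add(gene)

    studies = []
    for idx, size in enumerate(sizes):
        fixed = set(core) | member_of[idx]
        if size < len(fixed):
            raise UsageError(f"study size {size} smaller than core+planted {len(fixed)}")
        fill = [str(g) for g in rng.choice(fill_pool, size=size - len(fixed), replace=False)]
        studies.append(
            StudyGeneSet(
                study_id=f"S{idx + 1}",
                genes=frozenset(fixed) | frozenset(fill),
                description=f"synthetic study {idx + 1}",
            )
        )
    return studies


def generate_gwas(
    params: SyntheticParams, seed: int
) -> tuple[pd.DataFrame, dict[str, frozenset[str]]]:
    """Association export (catalog dialect) with per-trait truth gene sets.

    ``planted_trait_overlap`` is the fraction of planted priority genes
    inserted into trait sets (0 leaves them absent); decoy rows carry trait
    strings matching the default exclusion rules.
    """
    rng = _rng(seed, "gwas")
    universe = gene_universe(params.universe_size)
    planted = sorted(planted_priority_genes(params, seed))
    n_overlap = int(round(params.planted_trait_overlap * len(planted)))
    chosen = [str(g) for g in rng.choice(planted, size=n_overlap, replace=False)] if n_overlap else []
    traits = list(params.trait_set_sizes)
    trait_genes: dict[str, set[str]] = {t: set() for t in traits}
    for i, gene in enumerate(chosen):
        trait_genes[traits[i % len(traits)]].add(gene)
    for trait, size in params.trait_set_sizes.items():
        need = size - len(trait_genes[trait])
        if need < 0:
            raise UsageError(f"trait set size {size} too small for planted genes")
        pool = np.array(sorted(set(universe) - trait_genes[trait]))
        trait_genes[trait] |= {str(g) for g in rng.choice(pool, size=need, replace=False)}

    trait_strings = {
        "hypertension": "Hypertension",
        "atherosclerosis": "Atherosclerosis",
        "arterial_stiffness": "Arterial stiffness",
    }
    rows = []
    for trait in traits:
        accessions = [
            f"GCST9{int(a):06d}" for a in rng.integers(0, 1_000_000, size=6)
        ]
        members = sorted(trait_genes[trait])
        for gene in members:
            n_assoc = 1 + (1 if rng.random() < params.assoc_per_gene - 1 else 0)
            for _ in range(n_assoc):
                if rng.random() < 0.05 and len(members) > 1:
                    other = members[int(rng.integers(0, len(members)))]
                    mapped = f"{gene} - {other}" if other != gene else gene
                else:
                    mapped = gene
                rows.append(
                    {
                        "DISEASE/TRAIT": trait_strings.get(trait, trait),
                        "MAPPED_GENE": mapped,
                        "SNPS": f"rs{int(rng.integers(10**6, 10**8))}",
                        "STUDY ACCESSION": accessions[int(rng.integers(0, 6))],
                        "P-VALUE": f"{10.0 ** -rng.uniform(8, 30):.2e}",
                    }
                )
    for _ in range(params.n_decoy_associations):
        rows.append(
            {
                "DISEASE/TRAIT": DECOY_TRAITS[int(rng.integers(0, len(DECOY_TRAITS)))],
                "MAPPED_GENE": str(rng.choice(universe)),
                "SNPS": f"rs{int(rng.integers(10**6, 10**8))}",
                "STUDY ACCESSION": f"GCST9{int(rng.integers(0, 1_000_000)):06d}",
                "P-VALUE": f"{10.0 ** -rng.uniform(8, 30):.2e}",
            }
        )
    frame = pd.DataFrame(
        rows, columns=["DISEASE/TRAIT", "MAPPED_GENE", "SNPS", "STUDY ACCESSION", "P-VALUE"]
    )
    return frame, {t: frozenset(g) for t, g in trait_genes.items()}


def _weighted_draw(
    rng: np.random.Generator,
    universe: np.ndarray,
    favored: frozenset[str],
    factor: float,
    size: int,
    forced: Sequence[str] = (),
) -> frozenset[str]:
    """Draw ``size`` genes without replacement, oversampling ``favored`` by
    ``factor``; ``forced`` members are always included."""
    forced = [g for g in forced]
    remaining = size - len(forced)
    pool = np.array(sorted(set(universe) - set(forced)))
    if factor == 1.0:
        picked = rng.choice(pool, size=remaining, replace=False)
    else:
        weights = np.where(np.isin(pool, sorted(favored)), factor, 1.0)
        weights = weights / weights.sum()
        picked = rng.choice(pool, size=remaining, replace=False, p=weights)
    return frozenset(forced) | frozenset(str(g) for g in picked)


def generate_collection_and_network(
    params: SyntheticParams,
    seed: int,
    studies: Optional[Sequence[StudyGeneSet]] = None,
) -> tuple[GeneSetCollection, RegulatorNetwork, frozenset[str], frozenset[str]]:
    """Pathway collection and regulator network with planted enrichment.

    Planted pathways oversample the pooled DEG union by ``enrichment_factor``
    (and, when the factor exceeds 1, contain the planted priority genes so
    that planted signal survives the placement filter); planted regulators'
    targets oversample the DEG union by ``bias_factor``.  A factor of 1
    everywhere yields pure null structure.

    Returns (collection, network, planted_pathway_ids, planted_regulators).
    """
    if params.enrichment_factor < 1 or params.bias_factor < 1:
        raise UsageError("enrichment/bias factors must be >= 1")
    if studies is None:
        studies = generate_studies(params, seed)
    deg_union: set[str] = set()
    for s in studies:
        deg_union |= s.genes
    deg_union = frozenset(deg_union)
    planted = sorted(planted_priority_genes(params, seed))
    universe = gene_universe(params.universe_size)

    rng = _rng(seed, "pathways")
    lo, hi = params.pathway_size_range
    sets = []
    planted_ids = []
    for i in range(params.n_planted_pathways):
        size = int(rng.integers(max(lo, len(planted)), hi + 1))
        forced = planted if params.enrichment_factor > 1 else []
        genes = _weighted_draw(
            rng, universe, deg_union, params.enrichment_factor, size, forced=forced
        )
        set_id = f"PATH_PLANTED_{i + 1:02d}"
        planted_ids.append(set_id)
        sets.append(GeneSet(set_id, set_id, "KEGG", genes))
    for i in range(params.n_background_sets):
        size = int(rng.integers(lo, hi + 1))
        genes = frozenset(str(g) for g in rng.choice(universe, size=size, replace=False))
        tag = "KEGG" if i % 2 == 0 else "WikiPathways"
        sets.append(GeneSet(f"PATH_BG_{i + 1:03d}", f"PATH_BG_{i + 1:03d}", tag, genes))
    collection = GeneSetCollection(sets=sets, universe=frozenset(universe))

    rng = _rng(seed, "network")
    lo_t, hi_t = params.regulator_targets_range
    n_regs = params.n_planted_regulators + params.n_background_regulators
    regulators = rng.choice(universe, size=n_regs, replace=False)
    edges: set[tuple[str, str, Optional[int]]] = set()
    planted_regs = []
    for i, reg in enumerate(regulators):
        size = int(rng.integers(lo_t, hi_t + 1))
        if i < params.n_planted_regulators:
            planted_regs.append(str(reg))
            targets = _weighted_draw(rng, universe, deg_union, params.bias_factor, size)
        else:
            targets = frozenset(str(g) for g in rng.choice(universe, size=size, replace=False))
        for t in targets:
            edges.add((str(reg), str(t), None))
    network = RegulatorNetwork(edges=frozenset(edges))
    return collection, network, frozenset(planted_ids), frozenset(planted_regs)


def generate_lit_counts(params: SyntheticParams, seed: int) -> LiteratureCounts:
    """Heavy-right-tailed counts; planted genes sit at or above the category
    threshold while background counts are truncated just below it, so the
    threshold rule separates them by construction."""
    rng = _rng(seed, "lit")
    universe = gene_universe(params.universe_size)
    planted = sorted(planted_priority_genes(params, seed))
    background = rng.choice(
        np.array(sorted(set(universe) - set(planted))),
        size=params.n_lit_background,
        replace=False,
    )
    counts: dict[tuple[str, str], int] = {}
    for category, threshold in params.lit_thresholds.items():
        for gene in planted:
            counts[(gene, category)] = threshold + int(rng.geometric(params.lit_tail_p)) - 1
        for gene in background:
            tail = int(rng.geometric(params.lit_tail_p)) - 1
            counts[(str(gene), category)] = min(tail, threshold - 1)
    return LiteratureCounts(counts=counts)


@dataclass(frozen=True)
class SyntheticBundle:
    params: SyntheticParams
    studies: tuple[StudyGeneSet, ...]
    associations: pd.DataFrame
    trait_truth: Mapping[str, frozenset[str]]
    collection: GeneSetCollection
    network: RegulatorNetwork
    lit_counts: LiteratureCounts
    truth: SyntheticTruth


def generate_all(params: SyntheticParams, seed: int) -> SyntheticBundle:
    studies = generate_studies(params, seed)
    associations, trait_truth = generate_gwas(params, seed)
    collection, network, planted_paths, planted_regs = generate_collection_and_network(
        params, seed, studies=studies
    )
    lit = generate_lit_counts(params, seed)
    truth = SyntheticTruth(
        universe_size=params.universe_size,
        planted_priority_genes=planted_priority_genes(params, seed),
        planted_pathways=planted_paths,
        planted_regulators=planted_regs,
        study_sizes=tuple(params.study_sizes),
        shared_core_size=params.shared_core_size,
        trait_set_sizes=dict(params.trait_set_sizes),
        seed=seed,
    )
    return SyntheticBundle(
        params=params,
        studies=tuple(studies),
        associations=associations,
        trait_truth=trait_truth,
        collection=collection,
        network=network,
        lit_counts=lit,
        truth=truth,
    )


def write_synthetic(bundle: SyntheticBundle, out_dir) -> dict[str, Path]:
    """Emit the bundle in exactly the formats the ingestion modules read."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for s in bundle.studies:
        p = out / f"study_{s.study_id}.tsv"
        pd.DataFrame({"gene": sorted(s.genes)}).to_csv(p, sep="\t", index=False)
        paths[f"study_{s.study_id}"] = p
    p = out / "gwas_associations.tsv"
    bundle.associations.to_csv(p, sep="\t", index=False)
    paths["gwas"] = p
    p = out / "pathways.gmt"
    lines = [
        "\t".join([s.set_id, s.source_tag, *sorted(s.genes)])
        for s in bundle.collection
    ]
    p.write_text("\n".join(lines) + "\n")
    paths["gmt"] = p
    p = out / "network.tsv"
    edges = sorted((r, t) for r, t, _ in bundle.network.edges)
    pd.DataFrame(edges, columns=["regulator", "target"]).to_csv(p, sep="\t", index=False)
    paths["network"] = p
    p = out / "lit_counts.tsv"
    rows = [
        {"gene": g, "category": c, "count": n}
        for (g, c), n in sorted(bundle.lit_counts.counts.items())
    ]
    pd.DataFrame(rows, columns=["gene", "category", "count"]).to_csv(
        p, sep="\t", index=False
    )
    paths["lit_counts"] = p
    p = out / "universe.txt"
    p.write_text("\n".join(gene_universe(bundle.params.universe_size)) + "\n")
    paths["universe"] = p
    p = out / "truth.json"
    truth = dataclasses.asdict(bundle.truth)
    truth = {
        k: sorted(v) if isinstance(v, frozenset) else v for k, v in truth.items()
    }
    p.write_text(json.dumps(truth, indent=1, sort_keys=True) + "\n")
    paths["truth"] = p
    return paths
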