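"""Generator construction guarantees, determinism, and statistical shape."""

import dataclasses
import json

import numpy as np
import pytest

from flavogwas.core_io import read_gmt, read_network, read_study_table
from flavogwas.errors import UsageError
from flavogwas.evidence import read_lit_counts, top_genes
from flavogwas.gwas import GwasAssociation, curate_traits
from flavogwas.synthetic import (
    SyntheticParams,
    generate_all,
    generate_gwas,
    generate_lit_counts,
    generate_studies,
    planted_priority_genes,
    write_synthetic,
)


def _associations(frame):
    return [
        GwasAssociation(
            accession=row["STUDY ACCESSION"],
            trait=row["DISEASE/TRAIT"],
            rsid=row["SNPS"],
            mapped_gene_raw=row["MAPPED_GENE"],
        )
        for _, row in frame.iterrows()
    ]


class TestStudies:
    def test_sizes_and_core(self, small_params):
        studies = generate_studies(small_params, seed=0)
        assert [s.n_degs for s in studies] == list(small_params.study_sizes)
        core = frozenset.intersection(*[s.genes for s in studies])
        assert len(core) >= small_params.shared_core_size

    def test_planted_in_at_least_two_studies(self, small_params):
        studies = generate_studies(small_params, seed=0)
        for gene in planted_priority_genes(small_params, 0):
            assert sum(gene in s.genes for s in studies) >= 2

    def test_infeasible_core_rejected(self, small_params):
        bad = dataclasses.replace(small_params, shared_core_size=1000)
        with pytest.raises(UsageError):
            generate_studies(bad, seed=0)

    def test_pairwise_overlap_near_expectation_without_core(self):
        params = SyntheticParams(
            universe_size=500,
            study_sizes=(60, 50),
            shared_core_size=0,
            n_planted_priority=0,
        )
        expected = 60 * 50 / 500  # uniform-draw expectation
        per_seed_sd = np.sqrt(expected * (1 - 60 / 500) * (1 - 50 / 500))
        overlaps = []
        for seed in range(100):
            a, b = generate_studies(params, seed)
            overlaps.append(len(a.genes & b.genes))
        tolerance = 3 * per_seed_sd / np.sqrt(len(overlaps))
        assert abs(np.mean(overlaps) - expected) < tolerance


class TestGwas:
    def test_trait_sizes_match_request(self, small_params):
        _, truth = generate_gwas(small_params, seed=1)
        for trait, size in small_params.trait_set_sizes.items():
            assert len(truth[trait]) == size

    def test_decoys_removed_by_default_curation(self, small_params):
        frame, truth = generate_gwas(small_params, seed=1)
        per_trait, _ = curate_traits(_associations(frame), alias_map={})
        for trait, ts in per_trait.items():
            assert ts.genes == truth[trait]

    def test_zero_overlap_excludes_planted(self, small_params):
        params = dataclasses.replace(small_params, planted_trait_overlap=0.0)
        _, truth = generate_gwas(params, seed=1)
        planted = planted_priority_genes(params, 1)
        for genes in truth.values():
            assert not (planted & genes)


class TestLitCounts:
    def test_threshold_separates_planted(self, small_params):
        counts = generate_lit_counts(small_params, seed=2)
        planted = planted_priority_genes(small_params, 2)
        for category, threshold in small_params.lit_thresholds.items():
            tops = top_genes(counts, category, min_count=threshold)
            assert tops == planted

    def test_background_below_threshold(self, small_params):
        counts = generate_lit_counts(small_params, seed=2)
        planted = planted_priority_genes(small_params, 2)
        for (gene, category), count in counts.counts.items():
            if gene not in planted:
                assert count < small_params.lit_thresholds[category]


class TestDeterminismAndRoundTrip:
    def test_same_seed_same_bundle(self, small_params):
        a = generate_all(small_params, seed=9)
        b = generate_all(small_params, seed=9)
        assert [s.genes for s in a.studies] == [s.genes for s in b.studies]
        assert a.associations.equals(b.associations)
        assert a.network.edges == b.network.edges
        assert a.lit_counts.counts == b.lit_counts.counts
        assert a.truth == b.truth

    def test_different_seed_differs(self, small_params):
        a = generate_all(small_params, seed=9)
        b = generate_all(small_params, seed=10)
        assert [s.genes for s in a.studies] != [s.genes for s in b.studies]

    def test_written_bundle_reads_back(self, small_params, tmp_path):
        bundle = generate_all(small_params, seed=3)
        paths = write_synthetic(bundle, tmp_path)
        for s in bundle.studies:
            back = read_study_table(paths[f"study_{s.study_id}"], s.study_id)
            assert back.genes == s.genes
        coll = read_gmt(paths["gmt"])
        assert {c.set_id for c in coll} == {c.set_id for c in bundle.collection}
        net = read_network(paths["network"])
        assert {(r, t) for r, t, _ in net.edges} == {
            (r, t) for r, t, _ in bundle.network.edges
        }
        counts = read_lit_counts(paths["lit_counts"])
        assert counts.counts == bundle.lit_counts.counts
        truth = json.loads(paths["truth"].read_text())
        assert truth["seed"] == 3
        assert set(truth["planted_priority_genes"]) == bundle.truth.planted_priority_genes

    def test_identical_bytes_on_disk(self, small_params, tmp_path):
        p1 = write_synthetic(generate_all(small_params, seed=5), tmp_path / "a")
        p2 = write_synthetic(generate_all(small_params, seed=5), tmp_path / "b")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes()
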