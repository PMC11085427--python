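"""Hypergeometric ORA against exhaustive enumeration, BH step-up, placement."""

import itertools
import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

from flavogwas.core_io import GeneSet, GeneSetCollection
from flavogwas.errors import UsageError
from flavogwas.enrichment import (
    bh_adjust,
    hypergeom_right_tail,
    placement_table,
    run_ora,
)


def enumerate_right_tail(N, K, n, k):
    """Independent oracle: count draws of size n (from N items, first K
    marked) whose marked count is >= k, over all C(N, n) subsets."""
    hits = total = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if sum(1 for i in draw if i < K) >= k:
            hits += 1
    return hits / total


class TestHypergeomRightTail:
    def test_zero_overlap_is_one(self):
        assert hypergeom_right_tail(100, 10, 5, 0) == 1.0

    def test_four_of_five_marked(self):
        # 5 favourable draws out of C(10,4) = 210
        assert hypergeom_right_tail(10, 5, 4, 4) == pytest.approx(5 / 210, rel=1e-12)

    @pytest.mark.parametrize("N", [6, 8])
    def test_matches_enumeration(self, N):
        for K in range(N + 1):
            for n in range(N + 1):
                for k in range(min(K, n) + 1):
                    assert hypergeom_right_tail(N, K, n, k) == pytest.approx(
                        enumerate_right_tail(N, K, n, k), abs=1e-12
                    )

    @given(st.integers(1, 200), st.data())
    def test_monotone_in_k(self, N, data):
        K = data.draw(st.integers(0, N))
        n = data.draw(st.integers(0, N))
        previous = 1.1
        for k in range(min(K, n) + 1):
            p = hypergeom_right_tail(N, K, n, k)
            assert p <= previous + 1e-15
            previous = p

    @pytest.mark.parametrize(
        "args", [(10, 11, 5, 1), (10, 5, 11, 1), (10, 5, 5, 6), (-1, 0, 0, 0)]
    )
    def test_domain_errors(self, args):
        with pytest.raises(UsageError):
            hypergeom_right_tail(*args)


def step_up_oracle(pvals):
    """Hand-rolled BH: sort, p(i)*m/i, cumulative minimum from the top."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        adjusted[i] = min(running, 1.0)
    return adjusted


class TestBHAdjust:
    def test_single_value(self):
        assert bh_adjust([0.04]) == [0.04]

    def test_ramp_collapses(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04]
        )

    def test_all_equal_stay_equal(self):
        assert bh_adjust([0.3, 0.3, 0.3]) == pytest.approx([0.3, 0.3, 0.3])

    @given(st.lists(st.floats(1e-8, 1.0), min_size=1, max_size=40))
    def test_matches_step_up_oracle(self, pvals):
        assert bh_adjust(pvals) == pytest.approx(step_up_oracle(pvals), rel=1e-9)

    @given(st.lists(st.floats(1e-8, 1.0), min_size=2, max_size=20), st.randoms())
    def test_permutation_equivariance(self, pvals, rnd):
        perm = list(range(len(pvals)))
        rnd.shuffle(perm)
        direct = bh_adjust(pvals)
        permuted = bh_adjust([pvals[i] for i in perm])
        assert permuted == pytest.approx([direct[i] for i in perm], rel=1e-9)

    @pytest.mark.parametrize("bad", [[0.0], [-0.1], [1.2], [float("nan")]])
    def test_domain_errors(self, bad):
        with pytest.raises(UsageError):
            bh_adjust(bad)


def _collection(sets, universe=None):
    return GeneSetCollection(
        sets=[GeneSet(sid, sid, "KEGG", frozenset(genes)) for sid, genes in sets],
        universe=frozenset(universe) if universe else None,
    )


class TestRunOra:
    def test_disjoint_query(self):
        coll = _collection([("S1", {"A", "B"}), ("S2", {"C"})])
        results = run_ora(frozenset({"X"}), coll, frozenset("ABCX"))
        assert all(r.k == 0 and r.p_right == 1.0 for r in results)

    def test_full_query_brute_force(self):
        universe = frozenset(f"G{i}" for i in range(8))
        coll = _collection([("S1", {"G0", "G1", "G2"}), ("S2", {"G3"})])
        results = {r.set_id: r for r in run_ora(universe, coll, universe)}
        # query = universe forces k = K and p = 1 (verified by enumeration)
        for r in results.values():
            assert r.k == r.K
            assert r.p_right == pytest.approx(
                enumerate_right_tail(8, r.K, 8, r.k), abs=1e-12
            )

    def test_planted_pathway_ranks_first(self):
        rng = random.Random(5)
        universe = [f"G{i}" for i in range(300)]
        query = set(rng.sample(universe, 40))
        planted = set(rng.sample(sorted(query), 12)) | set(rng.sample(universe, 8))
        background = [
            (f"BG{j}", set(rng.sample(universe, 20))) for j in range(10)
        ]
        coll = _collection([("PLANTED", planted)] + background)
        results = run_ora(frozenset(query), coll, frozenset(universe))
        assert results[0].set_id == "PLANTED"
        assert results[0].q_bh < 0.05

    def test_sorted_by_p_then_set_id(self):
        coll = _collection([("B", {"A"}), ("A", {"A"})])
        results = run_ora(frozenset({"A"}), coll, frozenset({"A", "B", "C"}))
        assert [r.set_id for r in results] == ["A", "B"]

    def test_empty_universe_rejected(self):
        with pytest.raises(UsageError):
            run_ora(frozenset(), _collection([("S", {"A"})]), frozenset())


class TestPlacementTable:
    def test_min_hits_and_sorting(self):
        coll = _collection(
            [("LOW", {"A"}), ("MID", {"A", "B"}), ("TOP", {"A", "B", "C"})]
        )
        placed = placement_table(frozenset("ABC"), coll, min_hits=2)
        assert list(placed.table["set_id"]) == ["TOP", "MID"]
        assert placed.gene_union == {"A", "B", "C"}

    def test_union_subset_of_query(self, curated):
        query = frozenset({"LDLR", "LPL", "TCF7L2", "NOTAGENE1"})
        placed = placement_table(query, curated.pathway_collection, min_hits=2)
        assert placed.gene_union <= query

    def test_no_hits_empty_table(self):
        coll = _collection([("S", {"A", "B"})])
        placed = placement_table(frozenset({"Z"}), coll, min_hits=1)
        assert placed.table.empty
        assert placed.gene_union == frozenset()

    def test_min_hits_validation(self):
        with pytest.raises(UsageError):
            placement_table(frozenset(), _collection([("S", {"A"})]), min_hits=0)
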