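import math
from bisect import bisect_left
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qmnet.enrichment import bh_adjust, enrich, hypergeom_p
from qmnet.model import GeneSetCollection


def enumeration_tails(N, n):
    """Exhaustive oracle: for every K, the distribution of |draw ∩ first-K|
    over all C(N, n) draws, as upper-tail probabilities."""
    counts = np.zeros((N + 1, n + 1), dtype=np.int64)
    for draw in combinations(range(N), n):
        arr = sorted(draw)
        for K in range(N + 1):
            counts[K, bisect_left(arr, K)] += 1
    total = math.comb(N, n)
    tails = np.cumsum(counts[:, ::-1], axis=1)[:, ::-1] / total
    return tails  # tails[K, k] = P(X >= k)


class TestHypergeomP:
    def test_k_zero_is_one(self):
        assert hypergeom_p(100, 10, 10, 0) == 1.0

    def test_saturated_set_is_one(self):
        for k in range(6):
            assert hypergeom_p(20, 20, 5, k) == pytest.approx(1.0)

    def test_example_matches_enumeration(self):
        tails = enumeration_tails(20, 5)
        assert hypergeom_p(20, 5, 5, 4) == pytest.approx(tails[5, 4], rel=1e-12)

    @pytest.mark.parametrize("N", range(1, 13))
    def test_full_enumeration_sweep(self, N):
        """Agreement with exhaustive draw enumeration for every (K, n, k), N <= 12."""
        for n in range(N + 1):
            tails = enumeration_tails(N, n)
            for K in range(N + 1):
                for k in range(min(K, n) + 1):
                    assert hypergeom_p(N, K, n, k) == pytest.approx(
                        tails[K, k], rel=1e-10, abs=1e-14
                    )

    def test_monotone_nonincreasing_in_k(self):
        vals = [hypergeom_p(1000, 60, 80, k) for k in range(0, 40)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_large_universe_stability(self):
        p = hypergeom_p(100_000, 500, 400, 30)
        assert 0.0 < p < 1e-10  # far tail, finite and positive

    @pytest.mark.parametrize(
        "N,K,n,k", [(10, 11, 5, 0), (10, 5, 11, 0), (10, 5, 5, 6), (-1, 0, 0, 0)]
    )
    def test_domain_errors(self, N, K, n, k):
        with pytest.raises(ValueError):
            hypergeom_p(N, K, n, k)


class TestBhAdjust:
    def test_single_p_is_identity(self):
        assert bh_adjust([0.05]) == [0.05]

    def test_hand_computed_step_up(self):
        # p_(i) * m / i: [.04, .04, .04, .04] after monotonicity enforcement
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_hand_computed_mixed(self):
        # m=3: raw [0.03, 0.6, 0.01] -> ranks: 0.01*3/1=0.03, 0.03*3/2=0.045, 0.6
        assert bh_adjust([0.03, 0.6, 0.01]) == pytest.approx([0.045, 0.6, 0.03])

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(1e-9, 1.0), min_size=1, max_size=30))
    def test_bounded_and_order_invariant(self, ps):
        adj = bh_adjust(ps)
        assert all(a >= p for a, p in zip(adj, ps))
        assert all(a <= 1.0 for a in adj)
        # permuting inputs permutes outputs identically
        order = sorted(range(len(ps)), key=lambda i: ps[i])
        adj_sorted = bh_adjust([ps[i] for i in order])
        assert adj_sorted == pytest.approx([adj[i] for i in order])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.0, 0.5])
        with pytest.raises(ValueError):
            bh_adjust([1.5])


class TestEnrich:
    def test_degenerate_universe_gives_p_one(self):
        genes = {"A", "B", "C"}
        ann = GeneSetCollection(sets={"S": ("only", set(genes))})
        rows = enrich(genes, ann, universe_mode="explicit", universe=set(genes))
        assert len(rows) == 1
        r = rows[0]
        assert r.overlap == r.set_size == r.query_size == 3
        assert r.p_value == pytest.approx(1.0)

    def test_top_n_zero_truncates_to_empty(self):
        ann = GeneSetCollection(sets={"S": ("s", {"A"})})
        assert enrich({"A"}, ann, top_n=0) == []

    def test_disjoint_query_warns_and_returns_empty(self):
        ann = GeneSetCollection(sets={"S": ("s", {"A", "B"})})
        with pytest.warns(UserWarning, match="no annotated gene set"):
            assert enrich({"Z"}, ann) == []

    def test_rows_sorted_by_overlap_then_p(self):
        ann = GeneSetCollection(
            sets={
                "big": ("b", {"A", "B", "C", "D", "E", "F"}),
                "small": ("s", {"A", "B"}),
                "other": ("o", {"C", "G", "H"}),
            }
        )
        rows = enrich({"A", "B", "C"}, ann)
        overlaps = [r.overlap for r in rows]
        assert overlaps == sorted(overlaps, reverse=True)
        assert rows[0].p_adjusted >= rows[0].p_value

    def test_planted_enriched_set_ranks_first(self, synthetic_study):
        common = set().union(*synthetic_study.truth.expected_common.values())
        rows = enrich(common, synthetic_study.pathways)
        by_p = sorted(rows, key=lambda r: (r.p_value, r.set_id))
        planted = synthetic_study.truth.planted_enriched_sets
        assert {r.set_id for r in by_p[: len(planted)]} == planted


def test_null_model_type_one_error_calibration():
    """Under uniform null queries the fraction of p < 0.05 sits within 3 SE
    of the nominal level (dense-support configuration: exact tests are
    conservative where the discrete tail has no achievable value near 0.05)."""
    N, K, n, n_queries = 2000, 140, 125, 1000
    rng = np.random.default_rng(20)
    ks = rng.hypergeometric(K, N - K, n, size=n_queries)
    pcache = {k: hypergeom_p(N, K, n, int(k)) for k in np.unique(ks)}
    frac = np.mean([pcache[k] < 0.05 for k in ks])
    se = math.sqrt(0.05 * 0.95 / n_queries)
    assert abs(frac - 0.05) <= 3 * se
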