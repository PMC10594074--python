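"""Pairwise-distance sets, binning, and the G-test."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats
from scipy.stats import chi2_contingency

from cpforage.consistency import (
    BinnedDistribution,
    bin_distances,
    build_between_season_pairs,
    build_reference_pairs,
    build_within_season_pairs,
    g_test,
)
from cpforage.geodesy import GeoPoint, destination_point
from cpforage.trip_builder import COLONY_CENTRE


def metrics_table(layout: list[tuple[str, str, int]], seed: int = 0) -> pd.DataFrame:
    """A toy metrics table: (individual, deployment, season) per trip."""
    rng = np.random.default_rng(seed)
    rows = []
    for i, (ind, dep, season) in enumerate(layout):
        p = destination_point(
            COLONY_CENTRE, float(rng.uniform(0, 360)), float(rng.uniform(20, 400))
        )
        rows.append((f"t{i:03d}", ind, dep, season, p.latitude_deg, p.longitude_deg))
    return pd.DataFrame(
        rows, columns=["trip_id", "individual_id", "deployment_id", "season", "max_lat", "max_lon"]
    )


class TestPairSets:
    def test_reference_counts_choose_two(self):
        layout = [(f"b{i}", f"b{i}_2017", 2017) for i in range(10) for _ in range(3)]
        ref = build_reference_pairs(metrics_table(layout), seed=1)
        assert ref.n_pairs == 45  # C(10, 2)

    def test_reference_two_individuals(self):
        layout = [("a", "a_2017", 2017), ("b", "b_2017", 2017)]
        assert build_reference_pairs(metrics_table(layout)).n_pairs == 1

    def test_reference_all_trips_mode(self):
        layout = [(f"b{i}", f"b{i}_2017", 2017) for i in range(4) for _ in range(2)]
        ref = build_reference_pairs(metrics_table(layout), mode="all_trips")
        assert ref.n_pairs == 28  # C(8, 2)

    def test_reference_needs_two_individuals(self):
        with pytest.raises(ValueError):
            build_reference_pairs(metrics_table([("a", "a_2017", 2017)] * 3))

    def test_within_season_counts(self):
        # deployments with 1, 2 and 4 trips -> 0 + 1 + 6 = 7 pairs
        layout = (
            [("a", "a_2017", 2017)]
            + [("b", "b_2017", 2017)] * 2
            + [("c", "c_2017", 2017)] * 4
        )
        within = build_within_season_pairs(metrics_table(layout))
        assert within.n_pairs == 7

    def test_between_season_counts(self):
        # 2 seasons -> 1 pair; 3 seasons -> 3 pairs
        layout = (
            [("a", "a_2016", 2016), ("a", "a_2017", 2017)]
            + [("b", "b_2016", 2016), ("b", "b_2017", 2017), ("b", "b_2018", 2018)]
            + [("c", "c_2017", 2017)]
        )
        between = build_between_season_pairs(metrics_table(layout), seed=3)
        assert between.n_pairs == 1 + 3

    @given(st.lists(st.integers(min_value=1, max_value=4), min_size=2, max_size=6))
    def test_counts_match_brute_force_enumeration(self, trip_counts):
        layout = [
            (f"b{i}", f"b{i}_2017", 2017) for i, k in enumerate(trip_counts) for _ in range(k)
        ]
        table = metrics_table(layout)
        ref = build_reference_pairs(table, seed=0)
        within = build_within_season_pairs(table)
        n = len(trip_counts)
        assert ref.n_pairs == n * (n - 1) // 2
        brute_within = sum(
            1
            for a, b in combinations(table.itertuples(), 2)
            if a.deployment_id == b.deployment_id
        )
        assert within.n_pairs == brute_within

    def test_pairs_are_unordered_without_self_pairs(self):
        layout = [(f"b{i}", f"b{i}_2017", 2017) for i in range(6)]
        ref = build_reference_pairs(metrics_table(layout), seed=0)
        seen = set()
        for row in ref.pairs.itertuples():
            assert row.trip_id_a != row.trip_id_b
            key = frozenset((row.trip_id_a, row.trip_id_b))
            assert key not in seen
            seen.add(key)
            assert row.distance_km >= 0

    def test_within_pairs_share_deployment(self):
        layout = [("a", "a_2017", 2017)] * 3 + [("b", "b_2017", 2017)] * 2
        table = metrics_table(layout)
        within = build_within_season_pairs(table)
        dep = table.set_index("trip_id")["deployment_id"]
        for row in within.pairs.itertuples():
            assert dep[row.trip_id_a] == dep[row.trip_id_b]


class TestBinDistances:
    def make_set(self, distances):
        from cpforage.consistency import PairComparisonSet

        pairs = pd.DataFrame(
            {
                "trip_id_a": [f"a{i}" for i in range(len(distances))],
                "trip_id_b": [f"b{i}" for i in range(len(distances))],
                "distance_km": distances,
            }
        )
        return PairComparisonSet("reference", pairs)

    def test_basic_binning(self):
        binned = bin_distances(self.make_set([10.0, 60.0, 60.0]), 50.0, 100.0)
        assert list(binned.counts) == [1, 2]

    def test_empty_set_all_zero(self):
        binned = bin_distances(self.make_set([]), 50.0, 1100.0)
        assert binned.counts.sum() == 0 and len(binned.counts) == 22

    def test_overflow_goes_to_final_bin(self):
        binned = bin_distances(self.make_set([10.0, 1500.0, 1099.0]), 50.0, 1100.0)
        assert binned.counts[-1] == 2 and binned.n == 3

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_conservation_under_uniform_draws(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.uniform(0, 500, 1000)
        binned = bin_distances(self.make_set(d), 50.0, 500.0)
        assert binned.n == 1000 and len(binned.counts) == 10


class TestGTest:
    def test_identical_distributions_give_zero(self):
        edges = np.arange(0, 150.0, 50.0)
        a = BinnedDistribution(edges, np.array([30, 20]))
        res = g_test(a, a)
        assert res.G == 0.0 and res.p == 1.0

    def test_two_by_two_hand_value(self):
        # G = 2 sum O ln(O/E) for [[10, 20], [20, 10]]: margins 30/30,
        # E = 15 everywhere -> G = 2*(10 ln(2/3)*2 + 20 ln(4/3)*2) = 6.796
        edges = np.arange(0, 150.0, 50.0)
        res = g_test(
            BinnedDistribution(edges, np.array([10, 20])),
            BinnedDistribution(edges, np.array([20, 10])),
        )
        assert res.G == pytest.approx(6.796, abs=0.01)
        assert res.df == 1

    def test_matches_scipy_log_likelihood_ratio(self):
        edges = np.arange(0, 350.0, 50.0)
        ca = np.array([40, 25, 15, 10, 8, 7])
        cb = np.array([10, 20, 30, 25, 10, 10])
        res = g_test(BinnedDistribution(edges, ca), BinnedDistribution(edges, cb))
        g2, p2, df2, _ = chi2_contingency(np.vstack([ca, cb]), lambda_="log-likelihood")
        assert res.G == pytest.approx(g2, rel=1e-12)
        assert res.df == df2
        assert res.p == pytest.approx(p2, rel=1e-12)

    def test_pooling_merges_sparse_tail(self):
        edges = np.arange(0, 350.0, 50.0)
        ca = np.array([50, 40, 3, 1, 0, 1])
        cb = np.array([45, 42, 2, 2, 1, 0])
        res = g_test(BinnedDistribution(edges, ca), BinnedDistribution(edges, cb))
        assert "pooled" in res.pooled_bins
        assert res.df < 5

    def test_permutation_invariance_without_pooling(self):
        edges = np.arange(0, 250.0, 50.0)
        ca = np.array([30, 40, 25, 35])
        cb = np.array([45, 20, 30, 25])
        perm = [2, 0, 3, 1]
        res = g_test(BinnedDistribution(edges, ca), BinnedDistribution(edges, cb))
        res_p = g_test(BinnedDistribution(edges, ca[perm]), BinnedDistribution(edges, cb[perm]))
        assert res.G == pytest.approx(res_p.G, rel=1e-12)

    def test_mismatched_edges_rejected(self):
        a = BinnedDistribution(np.arange(0, 150.0, 50.0), np.array([10, 10]))
        b = BinnedDistribution(np.arange(0, 300.0, 100.0), np.array([10, 10]))
        with pytest.raises(ValueError, match="bin edges"):
            g_test(a, b)

    def test_empty_table_rejected(self):
        edges = np.arange(0, 150.0, 50.0)
        a = BinnedDistribution(edges, np.array([0, 0]))
        with pytest.raises(ValueError):
            g_test(a, a)

    def test_goodness_of_fit_mode(self):
        edges = np.arange(0, 250.0, 50.0)
        ref = BinnedDistribution(edges, np.array([100, 100, 100, 100]))
        obs = BinnedDistribution(edges, np.array([40, 20, 20, 20]))
        res = g_test(ref, obs, goodness_of_fit=True)
        # hand: E = 25 per bin; G = 2*(40 ln 1.6 + 3*20 ln 0.8)
        hand = 2 * (40 * np.log(1.6) + 3 * 20 * np.log(0.8))
        assert res.G == pytest.approx(hand, rel=1e-9)
        assert res.df == 3

    def test_null_calibration_on_independent_samples(self):
        # two independent multinomial samples from one distribution:
        # rejection rate at alpha = .05 is close to .05
        rng = np.random.default_rng(42)
        probs = np.array([0.35, 0.25, 0.2, 0.12, 0.08])
        edges = np.arange(0, 300.0, 50.0)
        rej = 0
        reps = 500
        for _ in range(reps):
            ca = rng.multinomial(400, probs)
            cb = rng.multinomial(300, probs)
            res = g_test(BinnedDistribution(edges, ca), BinnedDistribution(edges, cb))
            rej += res.p < 0.05
        # binomial 95% band around 0.05 with n = 500
        assert 15 <= rej <= 34
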