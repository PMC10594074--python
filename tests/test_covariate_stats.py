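"""Covariate tests against textbook-formula oracles and simulations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import i0e, i1e

from cpforage.covariate_stats import (
    circular_anova_lrt,
    delta_s_t_test,
    kappa_mle,
    linear_regression,
    mean_direction,
    one_way_anova,
    sequential_sinuosity_deltas,
    welch_t_test,
)


class TestWelchT:
    def test_textbook_fixture(self):
        # means 2 and 5, each variance 1: t = -3 / sqrt(2/3) = -3.674, df = 4
        res = welch_t_test([1, 2, 3], [4, 5, 6])
        assert res.t == pytest.approx(-3.674, abs=0.001)
        assert res.df == pytest.approx(4.0)

    def test_identical_samples(self):
        res = welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0 and res.p == pytest.approx(1.0)

    def test_degenerate_zero_variance(self):
        res = welch_t_test([2.0, 2.0], [2.0, 2.0])
        assert res.t == 0.0 and res.p == 1.0

    def test_manual_welch_formula(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(0, 1, 12), rng.normal(0.5, 2, 9)
        res = welch_t_test(x, y)
        vx, vy = x.var(ddof=1), y.var(ddof=1)
        se = np.sqrt(vx / len(x) + vy / len(y))
        t_hand = (x.mean() - y.mean()) / se
        df_hand = se**4 / ((vx / len(x)) ** 2 / 11 + (vy / len(y)) ** 2 / 8)
        assert res.t == pytest.approx(t_hand, abs=1e-10)
        assert res.df == pytest.approx(df_hand, abs=1e-10)
        assert res.p == pytest.approx(2 * stats.t.sf(abs(t_hand), df_hand), abs=1e-12)


class TestLinearRegression:
    def test_exact_line(self):
        x = np.arange(10.0)
        res = linear_regression(x, 2 * x + 1)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_normal_equations_oracle(self):
        # small printed fixture, n = 10
        x = np.array([7.0, 9.0, 12.0, 15.0, 18.0, 21.0, 24.0, 27.0, 31.0, 36.0])
        y = np.array([210.0, 180.0, 240.0, 195.0, 260.0, 205.0, 230.0, 215.0, 250.0, 225.0])
        res = linear_regression(x, y)
        X = np.vstack([np.ones_like(x), x]).T
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        ss_res = resid @ resid
        ss_tot = ((y - y.mean()) ** 2).sum()
        f_hand = (ss_tot - ss_res) / (ss_res / (len(x) - 2))
        assert res.intercept == pytest.approx(beta[0], abs=1e-8)
        assert res.slope == pytest.approx(beta[1], abs=1e-8)
        assert res.F == pytest.approx(f_hand, abs=1e-8)
        assert res.p == pytest.approx(stats.f.sf(f_hand, 1, 8), abs=1e-12)

    def test_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(1)
        x = rng.uniform(7, 36, 40)
        y = 0.5 * x + rng.normal(0, 5, 40)
        res = linear_regression(x, y)
        fit = sm.OLS(y, sm.add_constant(x)).fit()
        assert res.F == pytest.approx(fit.fvalue, rel=1e-10)
        assert res.p == pytest.approx(fit.f_pvalue, rel=1e-10)
        assert res.r_squared == pytest.approx(fit.rsquared, rel=1e-10)

    def test_confidence_band_formula(self):
        rng = np.random.default_rng(2)
        x = np.linspace(0, 10, 20)
        y = 3 * x + rng.normal(0, 1, 20)
        res = linear_regression(x, y)
        fit, lo, hi = res.confidence_band(np.array([x.mean()]))
        # at x-bar the band half-width is t_crit * s / sqrt(n)
        s2 = ((y - (res.intercept + res.slope * x)) ** 2).sum() / 18
        half = stats.t.ppf(0.975, 18) * np.sqrt(s2 / 20)
        assert (hi[0] - lo[0]) / 2 == pytest.approx(half, rel=1e-10)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            linear_regression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 1, 25)
        ps = [linear_regression(x, rng.normal(0, 1, 25)).p for _ in range(500)]
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestOneWayAnova:
    def test_all_identical_values(self):
        res = one_way_anova([[3.0, 3.0], [3.0, 3.0, 3.0]])
        assert res.F == 0.0 and res.p == 1.0

    def test_df_bookkeeping_seven_groups(self):
        # 7 groups totalling 183 observations -> df (6, 176)
        rng = np.random.default_rng(4)
        sizes = [26, 26, 26, 26, 26, 26, 27]
        groups = [rng.normal(0, 1, n) for n in sizes]
        res = one_way_anova(groups)
        assert (res.df1, res.df2) == (6, 176)

    def test_sum_of_squares_oracle(self):
        groups = [np.array([1.0, 2.0, 3.0]), np.array([2.0, 4.0]), np.array([6.0, 5.0, 7.0, 8.0])]
        res = one_way_anova(groups)
        allv = np.concatenate(groups)
        grand = allv.mean()
        ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
        f_hand = (ss_between / 2) / (ss_within / (len(allv) - 3))
        assert res.F == pytest.approx(f_hand, abs=1e-8)

    def test_two_groups_equal_pooled_t_squared(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(0, 1, 14), rng.normal(0.4, 1, 11)
        res_f = one_way_anova([x, y])
        res_t = welch_t_test(x, y, pooled=True)
        assert res_f.F == pytest.approx(res_t.t**2, rel=1e-10)


class TestCircularStats:
    def test_mean_direction_symmetric_pair(self):
        mu, rbar = mean_direction([0.0, 90.0])
        assert mu == pytest.approx(45.0)
        assert rbar == pytest.approx(np.sqrt(2) / 2, abs=1e-4)

    def test_mean_direction_wraps_north(self):
        mu, _ = mean_direction([350.0, 10.0])
        assert abs((mu + 180.0) % 360.0 - 180.0) < 1e-9  # circular distance to 0

    def test_antipodal_pair_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            mean_direction([0.0, 180.0])

    def test_mean_direction_recovers_von_mises_centre(self):
        rng = np.random.default_rng(6)
        sample = np.degrees(rng.vonmises(np.radians(286) - np.pi, 5.0, 10_000) + np.pi) % 360
        mu, _ = mean_direction(sample)
        assert abs((mu - 286 + 180) % 360 - 180) < 2.0

    def test_kappa_mle_inverts_a1(self):
        # A1(kappa) = I1/I0; the three-piece closed form should invert it
        for rbar in (0.1, 0.3, 0.5, 0.6, 0.8, 0.9, 0.95):
            k = kappa_mle(rbar)
            a1 = i1e(k) / i0e(k)
            assert a1 == pytest.approx(rbar, abs=0.012)

    def test_kappa_mle_monotone(self):
        ks = [kappa_mle(r) for r in np.linspace(0.05, 0.97, 30)]
        assert np.all(np.diff(ks) > 0)


class TestCircularAnova:
    def test_identical_groups_give_zero(self):
        b = [10.0, 350.0, 30.0, 320.0]
        res = circular_anova_lrt(b + b, ["a"] * 4 + ["b"] * 4)
        assert res.chi_sq == pytest.approx(0.0, abs=1e-9)
        assert res.p == pytest.approx(1.0)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(7)
        b = np.degrees(rng.vonmises(0, 2.0, 60) + np.pi) % 360
        labels = np.repeat(["a", "b", "c"], 20)
        res1 = circular_anova_lrt(b, labels)
        res2 = circular_anova_lrt((b + 123.4) % 360, labels)
        assert res1.chi_sq == pytest.approx(res2.chi_sq, abs=1e-9)

    def test_separated_groups_detected(self):
        rng = np.random.default_rng(8)
        a = np.degrees(rng.vonmises(0.0, 2.0, 90)) % 360
        b = np.degrees(rng.vonmises(np.radians(60), 2.0, 90)) % 360
        res = circular_anova_lrt(np.concatenate([a, b]), np.repeat(["f", "m"], 90))
        assert res.df == 1
        assert res.p < 1e-4

    def test_group_needs_two_observations(self):
        with pytest.raises(ValueError, match="at least 2"):
            circular_anova_lrt([0.0, 10.0, 20.0], ["a", "a", "b"])


class TestSinuosityDeltas:
    def frame(self):
        return pd.DataFrame(
            {
                "trip_id": ["t1", "t2", "t3", "t4", "t5"],
                "individual_id": ["a", "a", "a", "a", "b"],
                "deployment_id": ["a_2016", "a_2016", "a_2016", "a_2017", "b_2016"],
                "season": [2016, 2016, 2016, 2017, 2016],
                "start_time": pd.to_datetime(
                    ["2016-10-01", "2016-10-05", "2016-10-09", "2017-10-01", "2016-10-02"],
                    utc=True,
                ),
                "sinuosity_S": [0.5, 0.3, 0.4, 0.45, 0.2],
            }
        )

    def test_within_season_consecutive_deltas(self):
        deltas = sequential_sinuosity_deltas(self.frame(), "within_season")
        assert list(deltas["delta_S"].round(10)) == [-0.2, 0.1]
        assert set(deltas["individual_id"]) == {"a"}

    def test_between_season_first_trip_deltas(self):
        deltas = sequential_sinuosity_deltas(self.frame(), "between_season")
        # individual a: first trip 2016 (S=0.5) vs first trip 2017 (S=0.45)
        assert len(deltas) == 1
        assert deltas.loc[0, "delta_S"] == pytest.approx(-0.05)

    def test_singleton_individuals_contribute_nothing(self):
        frame = self.frame().iloc[[4]]
        assert len(sequential_sinuosity_deltas(frame, "within_season")) == 0
        assert len(sequential_sinuosity_deltas(frame, "between_season")) == 0

    def test_delta_t_test_centred_on_zero(self):
        rng = np.random.default_rng(9)
        deltas = pd.DataFrame({"delta_S": rng.normal(0, 0.05, 200)})
        res = delta_s_t_test(deltas)
        assert res.p > 0.001  # no systematic drift detected
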