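"""Covariate and trend tests for trip metrics.

Linear-scale metrics (distance, duration, sinuosity) are compared
across sexes with Welch's t-test, regressed on age with ordinary least
squares, and compared across years with a one-way ANOVA.  Trip bearing
is circular, so its group comparisons use a von Mises likelihood-ratio
test with a common concentration parameter: the null model fits one
mean direction to all bearings, the alternative fits one per group, and
twice the log-likelihood gain is referred to a chi-squared distribution
with (groups - 1) degrees of freedom.

Sequential sinuosity differences (``delta_S`` between an individual's
consecutive trips) quantify whether trips become more direct with
experience; a mean delta of zero indicates no such trend.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import i0e

__all__ = [
    "TTestResult",
    "RegressionResult",
    "AnovaResult",
    "CircularAnovaResult",
    "welch_t_test",
    "linear_regression",
    "one_way_anova",
    "mean_direction",
    "kappa_mle",
    "circular_anova_lrt",
    "sequential_sinuosity_deltas",
    "delta_s_t_test",
]

#: Concentration cap applied when the resultant length approaches 1 and
#: the maximum-likelihood kappa diverges.
KAPPA_MAX = 1e8


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df1: int
    df2: int
    p: float


@dataclass(frozen=True)
class RegressionResult:
    """Simple linear regression summary with the overall F test.

    For a single predictor the overall F equals the squared t statistic
    of the slope, on (1, n - 2) degrees of freedom.
    """

    slope: float
    intercept: float
    F: float
    df: tuple[int, int]
    p: float
    r_squared: float
    _band_params: tuple = field(repr=False, default=())

    def confidence_band(self, x_new) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """95% confidence band for the regression mean at ``x_new``.

        Returns ``(fitted, lower, upper)``.
        """
        n, x_bar, sxx, s2 = self._band_params
        x_new = np.asarray(x_new, dtype=float)
        fit = self.intercept + self.slope * x_new
        se = np.sqrt(s2 * (1.0 / n + (x_new - x_bar) ** 2 / sxx))
        tcrit = stats.t.ppf(0.975, n - 2)
        return fit, fit - tcrit * se, fit + tcrit * se


@dataclass(frozen=True)
class CircularAnovaResult:
    chi_sq: float
    df: int
    p: float
    group_mean_directions_deg: dict
    kappa_hat: float


def _clean_sample(x, name: str, min_n: int = 2) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if not np.isfinite(x).all():
        raise ValueError(f"{name} contains non-finite values")
    if len(x) < min_n:
        raise ValueError(f"{name} needs at least {min_n} observations, got {len(x)}")
    return x


def welch_t_test(x, y, pooled: bool = False) -> TTestResult:
    """Two-sided two-sample t-test, unequal variances by default.

    The degenerate case of two zero-variance samples with equal means
    returns ``t = 0, p = 1`` rather than NaN.
    """
    x = _clean_sample(x, "x")
    y = _clean_sample(y, "y")
    if np.var(x) == 0 and np.var(y) == 0 and np.mean(x) == np.mean(y):
        df = len(x) + len(y) - 2 if pooled else float(len(x) + len(y) - 2)
        return TTestResult(t=0.0, df=float(df), p=1.0)
    res = stats.ttest_ind(x, y, equal_var=pooled)
    df = len(x) + len(y) - 2 if pooled else _welch_df(x, y)
    return TTestResult(t=float(res.statistic), df=float(df), p=float(res.pvalue))


def _welch_df(x, y) -> float:
    vx, vy = np.var(x, ddof=1), np.var(y, ddof=1)
    nx, ny = len(x), len(y)
    num = (vx / nx + vy / ny) ** 2
    den = (vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1)
    return float(num / den)


def linear_regression(x, y) -> RegressionResult:
    """Ordinary least squares of ``y`` on ``x`` with the overall F test."""
    x = _clean_sample(x, "x", min_n=3)
    y = _clean_sample(y, "y", min_n=3)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; the slope is not identifiable")
    n = len(x)
    fit = stats.linregress(x, y)
    t_slope = fit.slope / fit.stderr if fit.stderr > 0 else np.inf
    F = float(t_slope**2)
    p = float(stats.f.sf(F, 1, n - 2)) if np.isfinite(F) else 0.0
    resid = y - (fit.intercept + fit.slope * x)
    s2 = float(resid @ resid) / (n - 2)
    x_bar = float(np.mean(x))
    sxx = float(((x - x_bar) ** 2).sum())
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        F=F,
        df=(1, n - 2),
        p=p,
        r_squared=float(fit.rvalue**2),
        _band_params=(n, x_bar, sxx, s2),
    )


def one_way_anova(groups) -> AnovaResult:
    """Classical one-way ANOVA across a list of samples."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 1 for g in groups):
        raise ValueError("every group needs at least one observation")
    N = sum(len(g) for g in groups)
    g = len(groups)
    if N <= g:
        raise ValueError("total sample size must exceed the number of groups")
    allv = np.concatenate(groups)
    if np.ptp(allv) == 0:
        return AnovaResult(F=0.0, df1=g - 1, df2=N - g, p=1.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.f_oneway(*groups)
    F = float(res.statistic)
    if not np.isfinite(F):  # zero within-group variance
        F = np.inf
    return AnovaResult(F=F, df1=g - 1, df2=N - g, p=float(res.pvalue))


# ---------------------------------------------------------------------------
# Circular statistics
# ---------------------------------------------------------------------------

def mean_direction(bearings_deg) -> tuple[float, float]:
    """Circular mean direction and mean resultant length.

    Returns ``(mu_deg in [0, 360), R_bar in [0, 1])``.  Raises if the
    resultant length is numerically zero (e.g. two antipodal bearings),
    where no mean direction exists.
    """
    b = _clean_sample(bearings_deg, "bearings", min_n=1)
    theta = np.radians(b)
    c, s = np.cos(theta).mean(), np.sin(theta).mean()
    r_bar = float(np.hypot(c, s))
    if r_bar < 1e-12:
        raise ValueError("mean direction undefined: resultant length is zero")
    mu = float(np.degrees(np.arctan2(s, c)) % 360.0)
    return mu, r_bar


def kappa_mle(r_bar: float) -> float:
    """Maximum-likelihood von Mises concentration from the resultant length.

    Uses the standard three-piece closed-form approximation to the
    inverse of A1(kappa) = I1(kappa)/I0(kappa):
    2R + R^3 + 5R^5/6 for R < 0.53; -0.4 + 1.39R + 0.43/(1-R) for
    0.53 <= R < 0.85; 1/(R^3 - 4R^2 + 3R) above.  Capped (with a
    warning) as R approaches 1, where the MLE diverges.
    """
    r = float(r_bar)
    if not 0.0 <= r <= 1.0:
        raise ValueError(f"resultant length must be in [0, 1], got {r}")
    if r < 0.53:
        k = 2 * r + r**3 + 5 * r**5 / 6
    elif r < 0.85:
        k = -0.4 + 1.39 * r + 0.43 / (1 - r)
    else:
        denom = r**3 - 4 * r**2 + 3 * r
        k = 1.0 / denom if denom > 0 else np.inf
    if k > KAPPA_MAX:
        warnings.warn(
            f"concentration estimate capped at {KAPPA_MAX:g} (R_bar={r}); "
            "the sample is almost perfectly aligned",
            RuntimeWarning,
        )
        k = KAPPA_MAX
    return float(k)


def _ln_i0(kappa: float) -> float:
    # exponentially-scaled Bessel avoids overflow at large kappa
    return float(np.log(i0e(kappa)) + kappa)


def circular_anova_lrt(bearings_deg, group_labels) -> CircularAnovaResult:
    """von Mises likelihood-ratio ANOVA for a difference in mean direction.

    Both models assume a common concentration kappa.  Null: one mean
    direction for all groups.  Alternative: one mean direction per
    group.  Kappa is re-estimated under each model from the relevant
    resultant lengths.  The statistic ``2 * (l_alt - l_null)`` is
    referred to chi-squared with ``n_groups - 1`` degrees of freedom
    (clamped at zero if numerically negative).
    """
    b = _clean_sample(bearings_deg, "bearings", min_n=2)
    labels = np.asarray(group_labels)
    if len(labels) != len(b):
        raise ValueError("bearings and group labels must have equal length")
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    theta = np.radians(b)
    n = len(theta)

    # resultant length of the pooled sample (null model)
    c_all, s_all = np.cos(theta).sum(), np.sin(theta).sum()
    r_all = float(np.hypot(c_all, s_all))

    # summed per-group resultant lengths (alternative model)
    r_group_sum = 0.0
    group_means: dict = {}
    for lab in uniq:
        t = theta[labels == lab]
        if len(t) < 2:
            raise ValueError(f"group {lab!r} needs at least 2 observations")
        r_g = float(np.hypot(np.cos(t).sum(), np.sin(t).sum()))
        if r_g < 1e-12:
            raise ValueError(f"group {lab!r} has zero resultant length; mean undefined")
        group_means[lab] = float(np.degrees(np.arctan2(np.sin(t).sum(), np.cos(t).sum())) % 360.0)
        r_group_sum += r_g

    k0 = kappa_mle(r_all / n)
    k1 = kappa_mle(r_group_sum / n)
    # profile log-likelihood at the MLE mean directions:
    # l(kappa) = kappa * R - n * ln(2 pi I0(kappa)); the 2 pi terms cancel
    l0 = k0 * r_all - n * _ln_i0(k0)
    l1 = k1 * r_group_sum - n * _ln_i0(k1)
    chi = 2.0 * (l1 - l0)
    if chi < 0:
        if chi < -1e-6:
            warnings.warn(f"negative LRT statistic {chi:.3g} clamped to 0", RuntimeWarning)
        chi = 0.0
    df = len(uniq) - 1
    return CircularAnovaResult(
        chi_sq=float(chi),
        df=df,
        p=float(stats.chi2.sf(chi, df)),
        group_mean_directions_deg=group_means,
        kappa_hat=float(k1),
    )


# ---------------------------------------------------------------------------
# Sequential sinuosity differences
# ---------------------------------------------------------------------------

def sequential_sinuosity_deltas(metrics: pd.DataFrame, scope: str = "within_season") -> pd.DataFrame:
    """Differences in sinuosity S between an individual's successive trips.

    ``within_season``: delta between consecutive (time-ordered) trips
    of the same deployment.  ``between_season``: delta between the
    first trips of an individual's consecutive tracked seasons.
    Individuals with fewer than two qualifying trips contribute
    nothing.  Returns columns ``individual_id, pair, delta_S`` where
    ``pair`` is the trip-rank pair, e.g. ``"1-2"``.
    """
    needed = ["trip_id", "individual_id", "deployment_id", "season", "start_time", "sinuosity_S"]
    missing = [c for c in needed if c not in metrics.columns]
    if missing:
        raise ValueError(f"metrics table missing columns {missing}")
    rows = []
    if scope == "within_season":
        for dep, grp in metrics.sort_values("start_time").groupby("deployment_id", sort=True):
            s = grp["sinuosity_S"].to_numpy()
            ind = grp["individual_id"].iloc[0]
            for k in range(len(s) - 1):
                rows.append((ind, f"{k + 1}-{k + 2}", float(s[k + 1] - s[k])))
    elif scope == "between_season":
        firsts = (
            metrics.sort_values("start_time")
            .groupby(["individual_id", "season"], sort=True)
            .first()
            .reset_index()
        )
        for ind, grp in firsts.groupby("individual_id", sort=True):
            grp = grp.sort_values("season")
            seasons = grp["season"].to_numpy()
            s = grp["sinuosity_S"].to_numpy()
            # successive seasons in the individual's tracked-season order
            for k in range(len(s) - 1):
                rows.append((ind, f"{seasons[k]}-{seasons[k + 1]}", float(s[k + 1] - s[k])))
    else:
        raise ValueError(f"unknown scope {scope!r}")
    return pd.DataFrame(rows, columns=["individual_id", "pair", "delta_S"])


def delta_s_t_test(deltas: pd.DataFrame) -> TTestResult:
    """Two-sided one-sample t-test that the mean sinuosity delta is zero."""
    d = _clean_sample(deltas["delta_S"], "delta_S")
    if np.var(d) == 0 and np.mean(d) == 0:
        return TTestResult(t=0.0, df=float(len(d) - 1), p=1.0)
    res = stats.ttest_1samp(d, 0.0)
    return TTestResult(t=float(res.statistic), df=float(len(d) - 1), p=float(res.pvalue))
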