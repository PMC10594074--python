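"""Individual site-fidelity analysis via pairwise max-displacement distances.

Each trip is summarised by the coordinate of its maximum displacement
from the colony.  Three sets of pairwise great-circle distances between
these coordinates are built:

* **reference** — by default one randomly selected trip per individual,
  then all unordered cross-individual pairs (``C(n_individuals, 2)``
  pairs); this is the between-individual "random" background.
* **within_season** — all unordered pairs of trips recorded during the
  same deployment of the same individual.
* **between_season** — for each individual tracked in several seasons,
  one randomly selected trip per season, then all unordered
  cross-season pairs.

If same-individual trips target the same places, the within/between
distances concentrate at short range relative to the reference, and a
G-test on the binned distributions detects the shift.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .geodesy import _hav_arrays

__all__ = [
    "PairComparisonSet",
    "BinnedDistribution",
    "GTestResult",
    "build_reference_pairs",
    "build_within_season_pairs",
    "build_between_season_pairs",
    "bin_distances",
    "g_test",
]

KIND_REFERENCE = "reference"
KIND_WITHIN = "within_season"
KIND_BETWEEN = "between_season"

_REQUIRED = ["trip_id", "individual_id", "deployment_id", "season", "max_lat", "max_lon"]


@dataclass(frozen=True)
class PairComparisonSet:
    """Unordered trip pairs with the distance between their summary coordinates."""

    kind: str
    pairs: pd.DataFrame  # columns: trip_id_a, trip_id_b, distance_km
    seed: int | None = None

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def distances_km(self) -> np.ndarray:
        return self.pairs["distance_km"].to_numpy()


@dataclass(frozen=True)
class BinnedDistribution:
    """Histogram with uniform, left-closed right-open bins.

    The final bin additionally absorbs everything at or beyond its
    right edge, so counts always sum to the number of pairs.
    """

    bin_edges: np.ndarray
    counts: np.ndarray

    @property
    def n(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class GTestResult:
    G: float
    df: int
    p: float
    pooled_bins: str


def _check_metrics(metrics: pd.DataFrame) -> None:
    missing = [c for c in _REQUIRED if c not in metrics.columns]
    if missing:
        raise ValueError(f"metrics table missing columns {missing}")


def _pair_frame(metrics: pd.DataFrame, id_pairs: list[tuple[str, str]]) -> pd.DataFrame:
    coords = metrics.set_index("trip_id")[["max_lat", "max_lon"]]
    a = [p[0] for p in id_pairs]
    b = [p[1] for p in id_pairs]
    la, lo = coords.loc[a, "max_lat"].to_numpy(), coords.loc[a, "max_lon"].to_numpy()
    lb, nb = coords.loc[b, "max_lat"].to_numpy(), coords.loc[b, "max_lon"].to_numpy()
    d = _hav_arrays(la, lo, lb, nb) if id_pairs else np.empty(0)
    return pd.DataFrame({"trip_id_a": a, "trip_id_b": b, "distance_km": d})


def build_reference_pairs(
    metrics: pd.DataFrame,
    mode: str = "one_per_individual",
    seed: int | None = 0,
) -> PairComparisonSet:
    """Build the between-individual reference distance set.

    ``one_per_individual`` (default): one uniformly random trip per
    individual, then all unordered cross-individual pairs.
    ``all_trips``: every unordered pair of trips in the table.
    """
    _check_metrics(metrics)
    if mode == "one_per_individual":
        rng = np.random.default_rng(seed)
        chosen = []
        for _, grp in metrics.sort_values("trip_id").groupby("individual_id", sort=True):
            ids = grp["trip_id"].tolist()
            chosen.append(ids[rng.integers(0, len(ids))])
        if len(chosen) < 2:
            raise ValueError("need at least 2 individuals for the reference set")
        id_pairs = list(combinations(chosen, 2))
    elif mode == "all_trips":
        ids = metrics["trip_id"].tolist()
        if len(ids) < 2:
            raise ValueError("need at least 2 trips for the all_trips reference set")
        id_pairs = list(combinations(ids, 2))
    else:
        raise ValueError(f"unknown reference mode {mode!r}")
    return PairComparisonSet(KIND_REFERENCE, _pair_frame(metrics, id_pairs), seed=seed)


def build_within_season_pairs(metrics: pd.DataFrame) -> PairComparisonSet:
    """All unordered pairs of trips within each deployment."""
    _check_metrics(metrics)
    id_pairs: list[tuple[str, str]] = []
    for _, grp in metrics.sort_values("trip_id").groupby("deployment_id", sort=True):
        id_pairs.extend(combinations(grp["trip_id"].tolist(), 2))
    return PairComparisonSet(KIND_WITHIN, _pair_frame(metrics, id_pairs))


def build_between_season_pairs(metrics: pd.DataFrame, seed: int | None = 0) -> PairComparisonSet:
    """Cross-season pairs for individuals tracked in several seasons.

    One seeded-random trip is selected per individual per season, and
    all unordered cross-season pairs are formed for that individual.
    """
    _check_metrics(metrics)
    rng = np.random.default_rng(seed)
    id_pairs: list[tuple[str, str]] = []
    for _, ind_grp in metrics.sort_values("trip_id").groupby("individual_id", sort=True):
        picks = []
        for _, season_grp in ind_grp.groupby("season", sort=True):
            ids = season_grp["trip_id"].tolist()
            picks.append(ids[rng.integers(0, len(ids))])
        id_pairs.extend(combinations(picks, 2))
    return PairComparisonSet(KIND_BETWEEN, _pair_frame(metrics, id_pairs), seed=seed)


def bin_distances(
    pair_set: PairComparisonSet,
    bin_width_km: float = 50.0,
    max_km: float = 1100.0,
) -> BinnedDistribution:
    """Histogram the pair distances into uniform bins.

    Distances at or beyond ``max_km`` are pooled into the final bin so
    the counts conserve ``n_pairs``.
    """
    if bin_width_km <= 0:
        raise ValueError("bin width must be positive")
    edges = np.arange(0.0, max_km + bin_width_km, bin_width_km)
    d = np.minimum(pair_set.distances_km, edges[-2] + bin_width_km / 2.0)
    counts, _ = np.histogram(d, edges)
    return BinnedDistribution(edges, counts)


def _g_statistic(table: np.ndarray) -> float:
    rows = table.sum(axis=1, keepdims=True)
    cols = table.sum(axis=0, keepdims=True)
    expected = rows @ cols / table.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(table > 0, table * np.log(table / expected), 0.0)
    return float(2.0 * terms.sum())


def g_test(
    dist_a: BinnedDistribution,
    dist_b: BinnedDistribution,
    min_expected: float = 5.0,
    goodness_of_fit: bool = False,
) -> GTestResult:
    """Likelihood-ratio (G) test that two binned distributions differ.

    Default is the 2xk contingency form with expected counts from the
    row/column margins, treating both distributions as samples.  Bins
    are pooled from the right tail inward until every expected cell is
    at least ``min_expected`` (small expected counts make the
    chi-squared reference unreliable); at least two bins are always
    retained so the test keeps one degree of freedom.

    ``goodness_of_fit=True`` instead treats ``dist_a`` as fixed
    reference proportions for ``dist_b`` (df = k - 1).
    """
    if dist_a.bin_edges.shape != dist_b.bin_edges.shape or not np.allclose(
        dist_a.bin_edges, dist_b.bin_edges
    ):
        raise ValueError("distributions must share identical bin edges")
    table = np.vstack([dist_a.counts, dist_b.counts]).astype(float)
    if table.sum() == 0:
        raise ValueError("cannot test two empty distributions")
    if (table.sum(axis=1) == 0).any():
        raise ValueError("each distribution must contain at least one count")

    k0 = table.shape[1]
    # pool right-tail bins inward until expected counts are adequate
    while table.shape[1] > 2:
        if goodness_of_fit:
            props = table[0] / table[0].sum()
            expected = np.vstack([table[0], props * table[1].sum()])
        else:
            rows = table.sum(axis=1, keepdims=True)
            cols = table.sum(axis=0, keepdims=True)
            expected = rows @ cols / table.sum()
        if (expected >= min_expected).all():
            break
        table = np.hstack([table[:, :-2], table[:, -2:].sum(axis=1, keepdims=True)])
    k = table.shape[1]
    pooled = f"none (k={k})" if k == k0 else f"right-tail pooled {k0}->{k} bins (E>={min_expected:g})"

    if goodness_of_fit:
        props = table[0] / table[0].sum()
        observed = table[1]
        expected = props * observed.sum()
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(observed > 0, observed * np.log(observed / expected), 0.0)
        g = float(2.0 * terms.sum())
    else:
        g = _g_statistic(table)
    df = k - 1
    p = float(stats.chi2.sf(g, df))
    return GTestResult(G=g, df=df, p=p, pooled_bins=pooled)
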