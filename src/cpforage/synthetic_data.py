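"""Synthetic GPS-logger records with known individual-fidelity structure.

The generator emulates the statistical structure of a multi-year
central-place foraging telemetry study: a fixed island colony, tags
sampling every 10-20 minutes, deployments that alternate colony
residencies with foraging trips of hours to weeks, individuals
re-tracked across seasons, and a population whose foraging targets
favour westerly bearings toward a shelf break.

Ground truth is explicit.  Each individual has a preferred foraging
site drawn from the population pool; each trip's target is that site
plus isotropic noise with standard deviation ``fidelity_sd_km`` (the
fidelity knob).  Setting the knob to zero disables individual
preference entirely: every trip target is an independent draw from the
population pool.  Tracks are correlated random walks out to the
target, an area-restricted-search dwell, and a return leg, with
per-fix GPS jitter and up-to-350-m wander while at the colony.

Everything is reproducible from a single integer seed; per-individual
substreams are derived from (seed, individual index) so adding an
individual never perturbs the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta, timezone

import numpy as np
import pandas as pd

from .geodesy import GeoPoint, _dest_arrays, _hav_arrays, _bearing_arrays
from .trip_builder import COLONY_CENTRE, FIX_COLUMNS
from .trip_metrics import BathymetryGrid

__all__ = [
    "SyntheticPopulationConfig",
    "GroundTruth",
    "ConfigError",
    "simulate_population",
    "simulate_trip",
    "simulate_trip_summaries",
    "make_bathymetry",
    "analytic_depth",
]


class ConfigError(ValueError):
    """The generator configuration describes infeasible geometry."""


@dataclass(frozen=True)
class SyntheticPopulationConfig:
    """Generative parameters for a synthetic tracking study.

    Defaults mirror the scale of a seven-season incubation-stage study:
    ~100 individuals, 10-min sampling (20-min in the late-winter
    season), trip targets 9-520 km from the colony with a west-dominant
    bearing mixture (87% around 286 deg), and cruise speeds giving trip
    durations from hours to about two weeks.
    """

    seed: int
    n_individuals: int = 96
    seasons: tuple[int, ...] = (2013, 2014, 2015, 2016, 2017, 2018, 2019)
    #: probability of k+1 trips in a deployment, k = 0..len-1
    trips_per_deployment_probs: tuple[float, ...] = (0.35, 0.30, 0.18, 0.10, 0.05, 0.02)
    p_multiseason: float = 0.25
    max_tracked_seasons: int = 3
    colony: GeoPoint = COLONY_CENTRE
    colony_radius_m: float = 400.0
    sampling_interval_min: float = 10.0
    #: per-season overrides, e.g. coarser sampling in a late-winter season
    sampling_interval_overrides: dict = field(default_factory=lambda: {2018: 20.0})
    fidelity_sd_km: float = 20.0
    bearing_mix_weights: tuple[float, ...] = (0.87, 0.13)
    bearing_mix_means_deg: tuple[float, ...] = (286.0, 60.0)
    bearing_mix_kappas: tuple[float, ...] = (2.0, 1.0)
    #: lognormal target distance, clipped to distance_range_km
    distance_log_mean: float = math.log(150.0)
    distance_log_sd: float = 0.6
    distance_range_km: tuple[float, float] = (9.0, 520.0)
    speed_kmh: float = 30.0
    speed_sd_kmh: float = 5.0
    min_speed_kmh: float = 5.0
    #: heading concentration of the correlated random walk; None = straight
    turning_kappa: float | None = 20.0
    ars_duration_h: float = 12.0
    ars_speed_kmh: float = 6.0
    ars_radius_km: float = 5.0
    gps_noise_m: float = 10.0
    colony_jitter_max_m: float = 350.0
    colony_residency_fixes: int = 6
    #: probability that a deployment's first trip is truncated (starts at sea)
    p_truncate_first_trip: float = 0.0
    #: optional planned sinuosity schedule: trip k in a deployment aims for
    #: sinuosity_first + k * sinuosity_drift_per_trip (clipped to [0.05, 0.5])
    sinuosity_first: float | None = None
    sinuosity_drift_per_trip: float = 0.0
    max_trip_duration_h: float = 16.0 * 24.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("a seed is mandatory")
        if self.n_individuals < 1:
            raise ConfigError("need at least one individual")
        if not math.isclose(sum(self.trips_per_deployment_probs), 1.0, abs_tol=1e-9):
            raise ConfigError("trips_per_deployment_probs must sum to 1")
        if not 0.0 <= self.p_multiseason <= 1.0:
            raise ConfigError("p_multiseason must be a probability")
        for name in ("fidelity_sd_km", "gps_noise_m", "colony_jitter_max_m", "ars_duration_h"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        lo, hi = self.distance_range_km
        if not 0 < lo < hi:
            raise ConfigError("distance_range_km must be an increasing positive pair")
        worst_h = 2.0 * hi / max(self.min_speed_kmh, 1e-9) + self.ars_duration_h
        if worst_h > self.max_trip_duration_h:
            raise ConfigError(
                f"infeasible geometry: a {hi:.0f} km target at "
                f"{self.min_speed_kmh:.0f} km/h needs {worst_h:.0f} h, above the "
                f"{self.max_trip_duration_h:.0f} h trip ceiling"
            )

    def interval_min(self, season: int) -> float:
        return float(self.sampling_interval_overrides.get(season, self.sampling_interval_min))


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually did, for recovery tests."""

    preferred_sites: dict  # individual_id -> GeoPoint
    trips: pd.DataFrame  # individual/deployment/season/trip_index/target/n_fixes/...
    roster: pd.DataFrame  # deployment_id, individual_id, season, n_trips
    individuals: pd.DataFrame  # individual_id, sex, age_years


def _ind_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, index]))


def _draw_pool_targets(rng: np.random.Generator, cfg: SyntheticPopulationConfig, n: int):
    """Draw n (bearing, distance) pairs from the population pool."""
    comp = rng.choice(len(cfg.bearing_mix_weights), size=n, p=cfg.bearing_mix_weights)
    means = np.radians(np.asarray(cfg.bearing_mix_means_deg))[comp]
    kappas = np.asarray(cfg.bearing_mix_kappas)[comp]
    bearings = np.degrees(rng.vonmises(means - np.pi, kappas) + np.pi) % 360.0
    lo, hi = cfg.distance_range_km
    dist = np.clip(rng.lognormal(cfg.distance_log_mean, cfg.distance_log_sd, n), lo, hi)
    return bearings, dist


def _pool_point(rng, cfg) -> GeoPoint:
    b, d = _draw_pool_targets(rng, cfg, 1)
    lat, lon = _dest_arrays(cfg.colony.latitude_deg, cfg.colony.longitude_deg, b[0], d[0])
    return GeoPoint(float(lat), float(lon))


def _displace(point: GeoPoint, rng: np.random.Generator, sd_km: float) -> GeoPoint:
    """Isotropic Gaussian displacement in the local tangent plane."""
    if sd_km <= 0:
        return point
    dx, dy = rng.normal(0.0, sd_km, 2)
    r = math.hypot(dx, dy)
    if r == 0:
        return point
    brg = math.degrees(math.atan2(dx, dy)) % 360.0
    lat, lon = _dest_arrays(point.latitude_deg, point.longitude_deg, brg, r)
    return GeoPoint(float(lat), float(lon))


def _jitter_colony_fix(cfg, rng) -> tuple[float, float]:
    """A colony fix jittered uniformly within the nesting-wander disc."""
    r_m = cfg.colony_jitter_max_m * math.sqrt(rng.random())
    brg = rng.random() * 360.0
    lat, lon = _dest_arrays(
        cfg.colony.latitude_deg, cfg.colony.longitude_deg, brg, r_m / 1000.0
    )
    return float(lat), float(lon)


def _heading_noise(rng, kappa: float | None) -> float:
    if kappa is None:
        return 0.0
    return math.degrees(rng.vonmises(0.0, kappa))


def simulate_trip(
    start: GeoPoint,
    target: GeoPoint,
    config: SyntheticPopulationConfig,
    rng: np.random.Generator,
    interval_min: float | None = None,
    truncate_start: bool = False,
    planned_sinuosity: float | None = None,
) -> list[tuple[float, float]]:
    """Simulate the at-sea fixes of one trip as (lat, lon) pairs.

    The walk flies out to ``target`` with heading noise of
    concentration ``turning_kappa``, dwells near the target in slow,
    tortuous area-restricted search, and returns.  With
    ``planned_sinuosity`` the dwell length is instead sized so the
    realised sinuosity ``S = max_disp / total`` comes out near the
    requested value.  ``truncate_start`` drops the first half of the
    outbound leg, producing a trip that starts at sea.
    """
    cfg = config
    dt_h = (interval_min if interval_min is not None else cfg.sampling_interval_min) / 60.0
    speed = max(cfg.min_speed_kmh, rng.normal(cfg.speed_kmh, cfg.speed_sd_kmh))
    step = speed * dt_h
    target_dist = float(
        _hav_arrays(
            cfg.colony.latitude_deg, cfg.colony.longitude_deg,
            target.latitude_deg, target.longitude_deg,
        )
    )

    # Legs approach their goal to a 0.45-km standoff: far enough outside
    # the 400-m colony radius that default GPS jitter cannot flip the last
    # at-sea fix to at-colony, close enough that the path length of an
    # out-and-back trip is within ~1 km of twice the maximum displacement.
    standoff = 0.45

    def leg(pos: tuple[float, float], goal: GeoPoint) -> list[tuple[float, float]]:
        pts = []
        lat, lon = pos
        while True:
            d = float(_hav_arrays(lat, lon, goal.latitude_deg, goal.longitude_deg))
            if d <= standoff + 1e-9:
                break
            brg = float(_bearing_arrays(lat, lon, goal.latitude_deg, goal.longitude_deg))
            if d <= step + standoff:
                # final approach: one straight sub-step to the standoff ring
                lat_a, lon_a = _dest_arrays(lat, lon, brg, d - standoff)
                pts.append((float(lat_a), float(lon_a)))
                break
            brg += _heading_noise(rng, cfg.turning_kappa)
            lat_a, lon_a = _dest_arrays(lat, lon, brg, step)
            lat, lon = float(lat_a), float(lon_a)
            pts.append((lat, lon))
        return pts

    # depart: first at-sea fix on the standoff ring toward the target, so
    # the recorded path starts where the at-sea record starts
    brg0 = float(
        _bearing_arrays(
            start.latitude_deg, start.longitude_deg,
            target.latitude_deg, target.longitude_deg,
        )
    )
    lat0, lon0 = _dest_arrays(start.latitude_deg, start.longitude_deg, brg0, standoff)
    first = (float(lat0), float(lon0))
    outbound = [first] + leg(first, target)

    # dwell (area-restricted search) near the target
    ars_step = max(cfg.ars_speed_kmh * dt_h, 0.2)
    if planned_sinuosity is not None:
        extra_path = max(target_dist * (1.0 / planned_sinuosity - 2.0), 0.0)
        n_dwell = int(round(extra_path / ars_step))
    else:
        n_dwell = int(round(cfg.ars_duration_h / dt_h))
    dwell: list[tuple[float, float]] = []
    lat, lon = outbound[-1]
    heading = rng.random() * 360.0
    for _ in range(n_dwell):
        d_t = float(_hav_arrays(lat, lon, target.latitude_deg, target.longitude_deg))
        if d_t > cfg.ars_radius_km:  # re-centre on the patch
            heading = float(
                _bearing_arrays(lat, lon, target.latitude_deg, target.longitude_deg)
            )
        heading = (heading + rng.normal(0.0, 60.0)) % 360.0
        lat_a, lon_a = _dest_arrays(lat, lon, heading, ars_step)
        lat, lon = float(lat_a), float(lon_a)
        dwell.append((lat, lon))

    inbound = leg((lat, lon) if dwell else outbound[-1], cfg.colony)

    fixes = outbound + dwell + inbound
    if truncate_start:
        fixes = fixes[len(outbound) // 2:]

    if cfg.gps_noise_m > 0:
        noisy = []
        for lat, lon in fixes:
            dx, dy = rng.normal(0.0, cfg.gps_noise_m / 1000.0, 2)
            r = math.hypot(dx, dy)
            if r > 0:
                brg = math.degrees(math.atan2(dx, dy)) % 360.0
                lat_a, lon_a = _dest_arrays(lat, lon, brg, r)
                lat, lon = float(lat_a), float(lon_a)
            noisy.append((lat, lon))
        fixes = noisy
    return fixes


def _planned_s(cfg: SyntheticPopulationConfig, trip_index: int) -> float | None:
    if cfg.sinuosity_first is None:
        return None
    return float(np.clip(cfg.sinuosity_first + trip_index * cfg.sinuosity_drift_per_trip, 0.05, 0.5))


def _build_roster(cfg: SyntheticPopulationConfig, rng: np.random.Generator):
    """Assign tracked seasons, per-deployment trip counts, and life history.

    Sexes follow the typical banding-study mix (about 40% of known sex
    each way, the rest unassigned); ages span the 7-36-year range of a
    long-lived breeder.
    """
    rows = []
    ind_rows = []
    n_trip_choices = np.arange(1, len(cfg.trips_per_deployment_probs) + 1)
    for i in range(cfg.n_individuals):
        ind = f"bird{i + 1:03d}"
        sex = rng.choice(["female", "male", "unknown"], p=[0.4, 0.4, 0.2])
        age = int(rng.integers(7, 37))
        ind_rows.append((ind, sex, age))
        seasons = [cfg.seasons[rng.integers(0, len(cfg.seasons))]]
        while (
            len(seasons) < min(cfg.max_tracked_seasons, len(cfg.seasons))
            and rng.random() < cfg.p_multiseason
        ):
            remaining = [s for s in cfg.seasons if s not in seasons]
            seasons.append(remaining[rng.integers(0, len(remaining))])
        for season in sorted(seasons):
            n_trips = int(rng.choice(n_trip_choices, p=cfg.trips_per_deployment_probs))
            rows.append((f"{ind}_{season}", ind, season, n_trips))
    roster = pd.DataFrame(rows, columns=["deployment_id", "individual_id", "season", "n_trips"])
    individuals = pd.DataFrame(ind_rows, columns=["individual_id", "sex", "age_years"])
    return roster, individuals


def simulate_population(config: SyntheticPopulationConfig):
    """Generate a full synthetic study.

    Returns ``(fixes, truth)`` where ``fixes`` is a DataFrame in the
    long fix-CSV dialect (individual_id, deployment_id, season,
    timestamp, lat, lon) and ``truth`` is the :class:`GroundTruth`.
    Identical config (including seed) gives identical output.
    """
    cfg = config
    master = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xC01097]))
    roster, individuals = _build_roster(cfg, master)

    ind_ids = sorted(roster["individual_id"].unique())
    ind_index = {ind: i for i, ind in enumerate(ind_ids)}
    preferred = {}
    for ind in ind_ids:
        r = _ind_rng(cfg.seed, ind_index[ind])
        preferred[ind] = _pool_point(r, cfg)

    fix_rows = []
    truth_rows = []
    for _, dep in roster.iterrows():
        ind = dep["individual_id"]
        season = int(dep["season"])
        dep_id = dep["deployment_id"]
        rng = np.random.default_rng(
            np.random.SeedSequence([cfg.seed, ind_index[ind], season])
        )
        interval = cfg.interval_min(season)
        t = datetime(season, 10, 1, 6, 0, tzinfo=timezone.utc) + timedelta(
            minutes=float(rng.integers(0, 12 * 60))
        )
        dt = timedelta(minutes=interval)

        def emit(lat: float, lon: float) -> None:
            nonlocal t
            fix_rows.append(
                (ind, dep_id, season, t.isoformat().replace("+00:00", "Z"), lat, lon)
            )
            t += dt

        truncate_first = rng.random() < cfg.p_truncate_first_trip
        for k in range(int(dep["n_trips"])):
            truncate = truncate_first and k == 0
            if not truncate:
                for _ in range(cfg.colony_residency_fixes):
                    emit(*_jitter_colony_fix(cfg, rng))
            if cfg.fidelity_sd_km > 0:
                target = _displace(preferred[ind], rng, cfg.fidelity_sd_km)
            else:
                target = _pool_point(rng, cfg)
            planned = _planned_s(cfg, k)
            pts = simulate_trip(
                cfg.colony, target, cfg, rng,
                interval_min=interval,
                truncate_start=truncate,
                planned_sinuosity=planned,
            )
            for lat, lon in pts:
                emit(lat, lon)
            truth_rows.append(
                (ind, dep_id, season, k, target.latitude_deg, target.longitude_deg,
                 len(pts), truncate, planned)
            )
        for _ in range(cfg.colony_residency_fixes):
            emit(*_jitter_colony_fix(cfg, rng))

    fixes = pd.DataFrame(fix_rows, columns=FIX_COLUMNS)
    trips = pd.DataFrame(
        truth_rows,
        columns=[
            "individual_id", "deployment_id", "season", "trip_index",
            "target_lat", "target_lon", "n_fixes", "truncated", "planned_S",
        ],
    )
    return fixes, GroundTruth(
        preferred_sites=preferred, trips=trips, roster=roster, individuals=individuals
    )


def simulate_trip_summaries(config: SyntheticPopulationConfig) -> pd.DataFrame:
    """Fast path: per-trip summary coordinates without track integration.

    Draws the same deployment roster and per-trip targets as
    :func:`simulate_population` would, and returns a metrics-style
    table whose ``max_lat`` / ``max_lon`` are the trip targets — the
    coordinate of maximum displacement up to track-level wobble.  Used
    for replication-heavy calibration experiments on the consistency
    statistics, where integrating every 10-minute fix adds cost but no
    information about the pairwise-distance structure.
    """
    cfg = config
    master = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xC01097]))
    roster, _ = _build_roster(cfg, master)
    ind_ids = sorted(roster["individual_id"].unique())
    ind_index = {ind: i for i, ind in enumerate(ind_ids)}
    preferred = {ind: _pool_point(_ind_rng(cfg.seed, ind_index[ind]), cfg) for ind in ind_ids}

    rows = []
    for _, dep in roster.iterrows():
        ind = dep["individual_id"]
        season = int(dep["season"])
        rng = np.random.default_rng(
            np.random.SeedSequence([cfg.seed, ind_index[ind], season])
        )
        for k in range(int(dep["n_trips"])):
            if cfg.fidelity_sd_km > 0:
                target = _displace(preferred[ind], rng, cfg.fidelity_sd_km)
            else:
                target = _pool_point(rng, cfg)
            rows.append(
                (
                    f"{dep['deployment_id']}_t{k + 1:03d}", ind, dep["deployment_id"],
                    season, target.latitude_deg, target.longitude_deg,
                )
            )
    return pd.DataFrame(
        rows,
        columns=["trip_id", "individual_id", "deployment_id", "season", "max_lat", "max_lon"],
    )


# ---------------------------------------------------------------------------
# Synthetic bathymetry
# ---------------------------------------------------------------------------

def analytic_depth(
    distance_km,
    shelf_edge_distance_km: float = 150.0,
    band_width_km: float = 60.0,
    slope_m_per_km: float = 8.0,
    max_depth_m: float = 5500.0,
):
    """Seafloor depth (m, positive down) as a function of colony distance.

    Piecewise linear: shallow shelf (< 200 m) inside the shelf edge, a
    200-1000 m shelf-break band of the stated width, then a pelagic
    plain deepening at ``slope_m_per_km`` up to ``max_depth_m``.
    """
    d = np.asarray(distance_km, dtype=float)
    edge, band = shelf_edge_distance_km, band_width_km
    depth = np.where(
        d < edge,
        20.0 + 180.0 * d / edge,
        np.where(
            d < edge + band,
            200.0 + 800.0 * (d - edge) / band,
            np.minimum(1000.0 + slope_m_per_km * (d - edge - band), max_depth_m),
        ),
    )
    return depth


def make_bathymetry(
    colony: GeoPoint = COLONY_CENTRE,
    extent: tuple[float, float, float, float] | None = None,
    shelf_edge_distance_km: float = 150.0,
    band_width_km: float = 60.0,
    cellsize_deg: float = 0.1,
    slope_m_per_km: float = 8.0,
    max_depth_m: float = 5500.0,
) -> BathymetryGrid:
    """Synthetic bathymetry grid around the colony.

    ``extent`` is (lat_min, lat_max, lon_min, lon_max); the default
    covers 520-km trips with margin.  Cell values evaluate
    :func:`analytic_depth` at cell centres.
    """
    if extent is None:
        extent = (
            colony.latitude_deg - 6.5, colony.latitude_deg + 6.5,
            colony.longitude_deg - 8.5, colony.longitude_deg + 8.5,
        )
    lat_min, lat_max, lon_min, lon_max = extent
    if not (lat_min < colony.latitude_deg < lat_max and lon_min < colony.longitude_deg < lon_max):
        raise ValueError("extent must cover the colony")
    nrows = int(np.ceil((lat_max - lat_min) / cellsize_deg))
    ncols = int(np.ceil((lon_max - lon_min) / cellsize_deg))
    # cell centres, row 0 northernmost
    lats = lat_min + (np.arange(nrows)[::-1] + 0.5) * cellsize_deg
    lons = lon_min + (np.arange(ncols) + 0.5) * cellsize_deg
    glat, glon = np.meshgrid(lats, lons, indexing="ij")
    dist = _hav_arrays(glat, glon, colony.latitude_deg, colony.longitude_deg)
    depths = analytic_depth(
        dist, shelf_edge_distance_km, band_width_km, slope_m_per_km, max_depth_m
    )
    return BathymetryGrid(depths, xllcorner=lon_min, yllcorner=lat_min, cellsize=cellsize_deg)
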