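"""Segment raw GPS fixes into central-place foraging trips.

A fix is *at the colony* when its great-circle displacement from the
colony centre is at most the colony radius (default 400 m, chosen to be
safely above the few-hundred-metre jitter GPS tags show on nesting
birds), otherwise it is *at sea*.  A trip is a maximal contiguous run of
at-sea fixes within one deployment.  Runs touching the start or end of
the record are kept and flagged (``starts_at_sea`` / ``ends_at_sea``)
because tags are often attached to a bird that departs immediately.

Cleaning removes trips with too few fixes to describe a path (ten or
fewer) and trips whose sinuosity exceeds the 0.5 ceiling of a true
out-and-back trip, which indicates a truncated record rather than a
real loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from typing import Callable, Iterable, Sequence

import pandas as pd

from .geodesy import GeoPoint, haversine_km

__all__ = [
    "AT_COLONY",
    "AT_SEA",
    "COLONY_CENTRE",
    "ColonySite",
    "GpsFix",
    "Trip",
    "TripRemoval",
    "classify_fix",
    "segment_trips",
    "clean_trips",
    "read_fixes_csv",
    "fixes_from_frame",
    "trips_summary_frame",
    "trip_fixes_frame",
]

AT_COLONY = "at_colony"
AT_SEA = "at_sea"

#: Colony centre used throughout the worked examples: a shy albatross
#: breeding colony on an island in the western Bass Strait.
COLONY_CENTRE = GeoPoint(-40.3780953, 144.6557384)

REASON_TOO_FEW_FIXES = "too_few_fixes"
REASON_SINUOSITY = "sinuosity"

FIX_COLUMNS = ["individual_id", "deployment_id", "season", "timestamp", "lat", "lon"]


@dataclass(frozen=True)
class ColonySite:
    """The central place: a colony centre and the at-colony radius."""

    centre: GeoPoint = COLONY_CENTRE
    radius_m: float = 400.0

    def __post_init__(self) -> None:
        if not self.radius_m > 0:
            raise ValueError(f"colony radius must be positive, got {self.radius_m}")


@dataclass(frozen=True)
class GpsFix:
    """One timestamped logger position.

    ``displacement_m`` is the haversine distance to the colony centre;
    it is filled in lazily by :func:`classify_fix` / :func:`segment_trips`
    when constructed without one.
    """

    individual_id: str
    deployment_id: str
    season: int
    timestamp: datetime
    position: GeoPoint
    displacement_m: float | None = None


@dataclass(frozen=True)
class Trip:
    """An ordered at-sea run of fixes between two colony residencies."""

    trip_id: str
    individual_id: str
    deployment_id: str
    season: int
    fixes: tuple[GpsFix, ...]
    starts_at_sea: bool = False
    ends_at_sea: bool = False

    @property
    def n_fixes(self) -> int:
        return len(self.fixes)

    @property
    def start_time(self) -> datetime:
        return self.fixes[0].timestamp

    @property
    def end_time(self) -> datetime:
        return self.fixes[-1].timestamp


@dataclass(frozen=True)
class TripRemoval:
    trip_id: str
    reason: str
    detail: str = ""


def _with_displacement(fix: GpsFix, colony: ColonySite) -> GpsFix:
    if fix.displacement_m is not None:
        return fix
    d_m = haversine_km(fix.position, colony.centre) * 1000.0
    return replace(fix, displacement_m=d_m)


def classify_fix(fix: GpsFix, colony: ColonySite) -> str:
    """Classify a fix as ``at_colony`` or ``at_sea``.

    Displacement exactly equal to the radius counts as at-colony, so a
    bird sitting on the boundary is not split into spurious trips by
    float noise.
    """
    fix = _with_displacement(fix, colony)
    return AT_COLONY if fix.displacement_m <= colony.radius_m else AT_SEA


def _check_ordered(fixes: Sequence[GpsFix]) -> None:
    for i in range(1, len(fixes)):
        if fixes[i].timestamp <= fixes[i - 1].timestamp:
            raise ValueError(
                f"fixes must be strictly time-ordered within a deployment: "
                f"fix {i} at {fixes[i].timestamp} follows {fixes[i - 1].timestamp}"
            )
        if fixes[i].deployment_id != fixes[0].deployment_id:
            raise ValueError("segment_trips expects fixes from a single deployment")


def segment_trips(fixes: Sequence[GpsFix], colony: ColonySite) -> list[Trip]:
    """Cut one deployment's fix sequence into raw trips.

    Trips are maximal contiguous at-sea runs; colony fixes belong to no
    trip, and every at-sea fix belongs to exactly one trip.  A run that
    begins at the first record of the deployment is flagged
    ``starts_at_sea`` (and symmetrically for the last record), since the
    colony departure/return was not observed.  A single stray at-colony
    fix inside a run splits it: no smoothing is applied.
    """
    fixes = [_with_displacement(f, colony) for f in fixes]
    _check_ordered(fixes)
    trips: list[Trip] = []
    run: list[GpsFix] = []
    n = len(fixes)
    for i, fix in enumerate(fixes):
        if classify_fix(fix, colony) == AT_SEA:
            run.append(fix)
        elif run:
            trips.append(_make_trip(run, len(trips), started_at_record_start=(i - len(run) == 0)))
            run = []
    if run:
        trip = _make_trip(run, len(trips), started_at_record_start=(n == len(run)))
        trips.append(replace(trip, ends_at_sea=True))
    return trips


def _make_trip(run: list[GpsFix], index: int, started_at_record_start: bool) -> Trip:
    first = run[0]
    return Trip(
        trip_id=f"{first.deployment_id}_t{index + 1:03d}",
        individual_id=first.individual_id,
        deployment_id=first.deployment_id,
        season=first.season,
        fixes=tuple(run),
        starts_at_sea=started_at_record_start,
        ends_at_sea=False,
    )


def clean_trips(
    trips: Iterable[Trip],
    sinuosity_fn: Callable[[Trip], float] | None = None,
    min_fixes: int = 11,
    max_sinuosity: float = 0.5,
) -> tuple[list[Trip], list[TripRemoval]]:
    """Apply the fix-count and sinuosity filters.

    The fix-count filter runs first so each removal has a single
    attributable reason.  Trips with sinuosity exactly ``max_sinuosity``
    are kept: an ideal straight out-and-back trip sits exactly on the
    boundary and is a legitimate trip, whereas S above it implies the
    record misses part of the loop.

    Parameters
    ----------
    sinuosity_fn
        Maps a trip to its sinuosity S (max displacement / total path
        length).  Defaults to the standard metric computation.
    """
    if sinuosity_fn is None:
        from .trip_metrics import trip_sinuosity

        sinuosity_fn = trip_sinuosity
    kept: list[Trip] = []
    removed: list[TripRemoval] = []
    for trip in trips:
        if trip.n_fixes < min_fixes:
            removed.append(
                TripRemoval(trip.trip_id, REASON_TOO_FEW_FIXES, f"n_fixes={trip.n_fixes}")
            )
            continue
        s = sinuosity_fn(trip)
        if s > max_sinuosity:
            removed.append(TripRemoval(trip.trip_id, REASON_SINUOSITY, f"S={s:.4f}"))
            continue
        kept.append(trip)
    return kept, removed


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

def fixes_from_frame(frame: pd.DataFrame, source: str = "<frame>") -> list[GpsFix]:
    """Validate a fix table and convert it to :class:`GpsFix` records.

    Expects the long-format fix dialect (one row per fix, columns
    ``individual_id, deployment_id, season, timestamp, lat, lon``).
    Timestamps must be strictly increasing within each deployment;
    violations are reported with the offending row number.
    """
    missing = [c for c in FIX_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{source}: missing columns {missing}")
    ts = pd.to_datetime(frame["timestamp"], utc=True, format="ISO8601")
    fixes: list[GpsFix] = []
    last_seen: dict[str, tuple[datetime, int]] = {}
    for row_no, (idx, row) in enumerate(frame.iterrows(), start=2):
        t = ts.loc[idx].to_pydatetime()
        dep = str(row["deployment_id"])
        if dep in last_seen:
            prev_t, prev_row = last_seen[dep]
            if t == prev_t:
                raise ValueError(
                    f"{source}: line {row_no}: duplicate timestamp {t.isoformat()} "
                    f"in deployment {dep} (previous at line {prev_row})"
                )
            if t < prev_t:
                raise ValueError(
                    f"{source}: line {row_no}: timestamp {t.isoformat()} out of order "
                    f"in deployment {dep} (previous at line {prev_row})"
                )
        last_seen[dep] = (t, row_no)
        fixes.append(
            GpsFix(
                individual_id=str(row["individual_id"]),
                deployment_id=dep,
                season=int(row["season"]),
                timestamp=t,
                position=GeoPoint(float(row["lat"]), float(row["lon"])),
            )
        )
    return fixes


def read_fixes_csv(path) -> list[GpsFix]:
    """Read the fix CSV dialect (see :func:`fixes_from_frame`)."""
    frame = pd.read_csv(path)
    return fixes_from_frame(frame, source=str(path))


def trips_summary_frame(trips: Sequence[Trip]) -> pd.DataFrame:
    """One row per trip: ids, fix count, and the at-sea start/end flags."""
    return pd.DataFrame(
        {
            "trip_id": [t.trip_id for t in trips],
            "individual_id": [t.individual_id for t in trips],
            "deployment_id": [t.deployment_id for t in trips],
            "season": [t.season for t in trips],
            "n_fixes": [t.n_fixes for t in trips],
            "starts_at_sea": [t.starts_at_sea for t in trips],
            "ends_at_sea": [t.ends_at_sea for t in trips],
        }
    )


def trip_fixes_frame(trips: Sequence[Trip]) -> pd.DataFrame:
    """Long-format table of every trip fix, keyed by ``trip_id``."""
    rows = []
    for t in trips:
        for f in t.fixes:
            rows.append(
                (
                    t.trip_id,
                    t.individual_id,
                    t.deployment_id,
                    t.season,
                    f.timestamp.isoformat(),
                    f.position.latitude_deg,
                    f.position.longitude_deg,
                    f.displacement_m,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "trip_id",
            "individual_id",
            "deployment_id",
            "season",
            "timestamp",
            "lat",
            "lon",
            "displacement_m",
        ],
    )


def group_by_deployment(fixes: Sequence[GpsFix]) -> dict[str, list[GpsFix]]:
    """Group a fix list by deployment id, preserving order."""
    groups: dict[str, list[GpsFix]] = {}
    for f in fixes:
        groups.setdefault(f.deployment_id, []).append(f)
    return groups
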