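"""Per-trip geometry metrics, bearing regions, and bathymetric habitat.

The trip summary statistics are: maximum displacement from the colony
(and the coordinate attaining it), the bearing from the colony to that
coordinate, total path length, duration, and sinuosity
``S = max_displacement / total_distance``.  S equals 0.5 for a perfectly
straight out-and-back trip and shrinks as the path becomes more
convoluted.

Bearing regions partition the compass into three sectors used to
describe where trips head: east (355-130 deg), southwest (130-260 deg)
and northwest (260-355 deg).  Habitat classes partition seafloor depth:
shelf (neritic, < 200 m), shelf break (200-1000 m) and pelagic
(> 1000 m); a trip's habitat class is the deepest category any of its
fixes encounters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .geodesy import GeoPoint, haversine_km, initial_bearing_deg, _hav_arrays
from .trip_builder import ColonySite, Trip

__all__ = [
    "TripMetrics",
    "BathymetryGrid",
    "OutOfExtentError",
    "compute_metrics",
    "trip_sinuosity",
    "classify_region",
    "classify_depth",
    "trip_habitat_class",
    "metrics_frame",
    "REGION_EAST",
    "REGION_NORTHWEST",
    "REGION_SOUTHWEST",
]

REGION_EAST = "east"
REGION_NORTHWEST = "northwest"
REGION_SOUTHWEST = "southwest"

DEPTH_LAND = "land"
DEPTH_SHELF = "shelf"
DEPTH_SHELF_BREAK = "shelf_break"
DEPTH_PELAGIC = "pelagic"

HABITAT_NERITIC = "neritic"
HABITAT_SHELF_BREAK = "shelf_break"
HABITAT_PELAGIC = "pelagic"


class OutOfExtentError(ValueError):
    """A queried position falls outside the bathymetry grid."""


@dataclass(frozen=True)
class TripMetrics:
    trip_id: str
    individual_id: str
    deployment_id: str
    season: int
    n_fixes: int
    max_displacement_km: float
    max_disp_coord: GeoPoint
    bearing_deg: float
    total_distance_km: float
    duration_h: float
    sinuosity_S: float
    region: str
    start_time: pd.Timestamp
    habitat_class: str | None = None
    deepest_depth_m: float | None = None


def _fix_arrays(trip: Trip) -> tuple[np.ndarray, np.ndarray]:
    lats = np.array([f.position.latitude_deg for f in trip.fixes])
    lons = np.array([f.position.longitude_deg for f in trip.fixes])
    return lats, lons


def trip_sinuosity(trip: Trip, colony: ColonySite | None = None) -> float:
    """Sinuosity S = max displacement / total path length."""
    colony = colony or ColonySite()
    lats, lons = _fix_arrays(trip)
    disp = _hav_arrays(lats, lons, colony.centre.latitude_deg, colony.centre.longitude_deg)
    total = float(_hav_arrays(lats[:-1], lons[:-1], lats[1:], lons[1:]).sum())
    if total <= 0:
        return np.inf
    return float(disp.max()) / total


def compute_metrics(trip: Trip, colony: ColonySite | None = None) -> TripMetrics:
    """Compute the geometry metrics of one trip.

    Total distance sums consecutive fix-to-fix legs of the at-sea fixes
    only: the colony coordinate is *not* prepended or appended, so a
    truncated record (trip starting or ending at sea) shows up as S
    above 0.5 rather than being silently repaired.  The coordinate of
    maximum displacement is the first fix attaining the maximum, which
    makes the result invariant to downstream reordering.
    """
    colony = colony or ColonySite()
    if trip.n_fixes < 2:
        raise ValueError(
            f"trip {trip.trip_id}: need at least 2 fixes to compute metrics, "
            f"got {trip.n_fixes}"
        )
    lats, lons = _fix_arrays(trip)
    disp = _hav_arrays(lats, lons, colony.centre.latitude_deg, colony.centre.longitude_deg)
    i_max = int(np.argmax(disp))  # argmax returns the first maximum
    max_disp = float(disp[i_max])
    max_coord = trip.fixes[i_max].position
    total = float(_hav_arrays(lats[:-1], lons[:-1], lats[1:], lons[1:]).sum())
    duration_h = (trip.end_time - trip.start_time).total_seconds() / 3600.0
    bearing = initial_bearing_deg(colony.centre, max_coord)
    s = max_disp / total if total > 0 else np.inf
    return TripMetrics(
        trip_id=trip.trip_id,
        individual_id=trip.individual_id,
        deployment_id=trip.deployment_id,
        season=trip.season,
        n_fixes=trip.n_fixes,
        max_displacement_km=max_disp,
        max_disp_coord=max_coord,
        bearing_deg=bearing,
        total_distance_km=total,
        duration_h=duration_h,
        sinuosity_S=s,
        region=classify_region(bearing),
        start_time=pd.Timestamp(trip.start_time),
    )


def classify_region(
    bearing_deg: float,
    boundaries: tuple[float, float, float] = (130.0, 260.0, 355.0),
) -> str:
    """Assign a bearing to one of the three compass sectors.

    ``boundaries = (east/southwest, southwest/northwest,
    northwest/east)`` in degrees.  With the defaults the sectors form a
    half-open partition of [0, 360): east = [355, 360) + [0, 130),
    southwest = [130, 260), northwest = [260, 355).
    """
    b = float(bearing_deg)
    if not (0.0 <= b < 360.0):
        raise ValueError(f"bearing {b} outside [0, 360)")
    e_sw, sw_nw, nw_e = boundaries
    if b >= nw_e or b < e_sw:
        return REGION_EAST
    if b < sw_nw:
        return REGION_SOUTHWEST
    return REGION_NORTHWEST


def classify_depth(
    depth_m: float,
    shelf_break_min_m: float = 200.0,
    pelagic_min_m: float = 1000.0,
) -> str:
    """Classify a seafloor depth (metres, positive down) into habitat bands.

    Negative depth is land.  Boundaries: shelf [0, 200), shelf break
    [200, 1000], pelagic > 1000 — chosen so that "deeper than 1000 m"
    is unambiguously pelagic.
    """
    d = float(depth_m)
    if not np.isfinite(d):
        raise ValueError(f"depth must be finite, got {d}")
    if d < 0:
        return DEPTH_LAND
    if d < shelf_break_min_m:
        return DEPTH_SHELF
    if d <= pelagic_min_m:
        return DEPTH_SHELF_BREAK
    return DEPTH_PELAGIC


class BathymetryGrid:
    """A regular lat/lon grid of seafloor depths (metres, positive down).

    Backed by an ESRI ASCII grid layout: row 0 is the northernmost row,
    cells are square in degrees.  Lookup is nearest-cell with no
    interpolation; habitat class boundaries are far coarser than a cell.
    """

    def __init__(self, depths: np.ndarray, xllcorner: float, yllcorner: float, cellsize: float):
        depths = np.asarray(depths, dtype=float)
        if depths.ndim != 2:
            raise ValueError("depths must be a 2-D array")
        if cellsize <= 0:
            raise ValueError("cellsize must be positive")
        self.depths = depths
        self.xllcorner = float(xllcorner)
        self.yllcorner = float(yllcorner)
        self.cellsize = float(cellsize)

    @property
    def nrows(self) -> int:
        return self.depths.shape[0]

    @property
    def ncols(self) -> int:
        return self.depths.shape[1]

    def _rowcol(self, point: GeoPoint) -> tuple[int, int]:
        col = int(np.floor((point.longitude_deg - self.xllcorner) / self.cellsize))
        row_from_bottom = int(np.floor((point.latitude_deg - self.yllcorner) / self.cellsize))
        row = self.nrows - 1 - row_from_bottom
        if not (0 <= row < self.nrows and 0 <= col < self.ncols):
            raise OutOfExtentError(
                f"point ({point.latitude_deg}, {point.longitude_deg}) outside grid extent "
                f"lat [{self.yllcorner}, {self.yllcorner + self.nrows * self.cellsize}], "
                f"lon [{self.xllcorner}, {self.xllcorner + self.ncols * self.cellsize}]"
            )
        return row, col

    def depth_at(self, point: GeoPoint) -> float:
        """Depth of the grid cell containing ``point``."""
        row, col = self._rowcol(point)
        return float(self.depths[row, col])

    # -- ESRI ASCII grid I/O ------------------------------------------------

    @classmethod
    def from_ascii(cls, path, negate: bool = False) -> "BathymetryGrid":
        """Read an ESRI ASCII grid.

        Set ``negate=True`` for rasters storing elevation (sea negative)
        rather than depth (sea positive).
        """
        header: dict[str, float] = {}
        with open(path) as fh:
            lines = fh.readlines()
        n_header = 0
        for line in lines:
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
            }:
                header[parts[0].lower()] = float(parts[1])
                n_header += 1
            else:
                break
        for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
            if key not in header:
                raise ValueError(f"{path}: missing ESRI ASCII header field {key}")
        data = np.loadtxt(lines[n_header:]).reshape(int(header["nrows"]), int(header["ncols"]))
        if negate:
            data = -data
        return cls(data, header["xllcorner"], header["yllcorner"], header["cellsize"])

    def to_ascii(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"ncols {self.ncols}\n")
            fh.write(f"nrows {self.nrows}\n")
            fh.write(f"xllcorner {self.xllcorner}\n")
            fh.write(f"yllcorner {self.yllcorner}\n")
            fh.write(f"cellsize {self.cellsize}\n")
            np.savetxt(fh, self.depths, fmt="%.1f")


def trip_habitat_class(trip: Trip, grid: BathymetryGrid) -> tuple[str, float]:
    """Deepest habitat category encountered over a trip's fixes.

    Returns ``(habitat_class, deepest_depth_m)``.  Priority is
    pelagic > shelf_break > neritic; a trip is neritic only if no fix
    lies over water of 200 m or more.  Fixes over land cells count as
    neritic water for classification but are excluded from the deepest
    depth when deeper water was seen.
    """
    bad: list[str] = []
    deepest = -np.inf
    for f in trip.fixes:
        try:
            d = grid.depth_at(f.position)
        except OutOfExtentError:
            bad.append(f.timestamp.isoformat())
            continue
        deepest = max(deepest, d)
    if bad:
        raise OutOfExtentError(
            f"trip {trip.trip_id}: {len(bad)} fixes outside bathymetry extent "
            f"(first at {bad[0]})"
        )
    if deepest > 1000.0:
        cls = HABITAT_PELAGIC
    elif deepest >= 200.0:
        cls = HABITAT_SHELF_BREAK
    else:
        cls = HABITAT_NERITIC
    return cls, float(deepest)


def metrics_frame(
    trips: Sequence[Trip],
    colony: ColonySite | None = None,
    grid: BathymetryGrid | None = None,
) -> pd.DataFrame:
    """Metrics table with one row per trip.

    Includes the identifying columns needed by the consistency and
    covariate analyses (individual, deployment, season, start time) and
    the max-displacement coordinate as ``max_lat`` / ``max_lon``.
    """
    colony = colony or ColonySite()
    rows = []
    for t in trips:
        m = compute_metrics(t, colony)
        habitat, deepest = (None, None)
        if grid is not None:
            habitat, deepest = trip_habitat_class(t, grid)
        rows.append(
            {
                "trip_id": m.trip_id,
                "individual_id": m.individual_id,
                "deployment_id": m.deployment_id,
                "season": m.season,
                "n_fixes": m.n_fixes,
                "start_time": m.start_time,
                "max_displacement_km": m.max_displacement_km,
                "max_lat": m.max_disp_coord.latitude_deg,
                "max_lon": m.max_disp_coord.longitude_deg,
                "bearing_deg": m.bearing_deg,
                "total_distance_km": m.total_distance_km,
                "duration_h": m.duration_h,
                "sinuosity_S": m.sinuosity_S,
                "region": m.region,
                "habitat_class": habitat,
                "deepest_depth_m": deepest,
            }
        )
    return pd.DataFrame(rows)
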