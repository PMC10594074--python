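"""Great-circle primitives on a spherical Earth.

All distances are in kilometres on a sphere of radius 6371.0088 km (the
IUGG mean Earth radius).  Bearings are initial great-circle bearings in
degrees clockwise from true north, in ``[0, 360)``.  At the spatial scale
of central-place foraging trips (a few hundred km) the difference between
spherical and ellipsoidal distances is well below GPS accuracy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "EARTH_RADIUS_KM",
    "GeoPoint",
    "UndefinedBearingError",
    "haversine_km",
    "initial_bearing_deg",
    "destination_point",
]

EARTH_RADIUS_KM = 6371.0088


class UndefinedBearingError(ValueError):
    """Raised when a bearing is requested between coincident points."""


def _normalise_lon(lon: float) -> float:
    """Map a longitude to [-180, 180)."""
    lon = (lon + 180.0) % 360.0 - 180.0
    # (x % 360) can return 360.0 - eps edge cases; -180.0 is the canonical form
    return -180.0 if lon == 180.0 else lon


@dataclass(frozen=True)
class GeoPoint:
    """A position on the sphere in decimal degrees.

    Latitude must lie in [-90, 90]; longitude is normalised to
    [-180, 180) at construction so that equality is well defined.
    """

    latitude_deg: float
    longitude_deg: float

    def __post_init__(self) -> None:
        lat = float(self.latitude_deg)
        lon = float(self.longitude_deg)
        if not (math.isfinite(lat) and math.isfinite(lon)):
            raise ValueError(f"non-finite coordinates: ({lat!r}, {lon!r})")
        if not -90.0 <= lat <= 90.0:
            raise ValueError(f"latitude {lat} outside [-90, 90]")
        object.__setattr__(self, "latitude_deg", lat)
        object.__setattr__(self, "longitude_deg", _normalise_lon(lon))


def _hav_arrays(lat1, lon1, lat2, lon2):
    """Vectorised haversine distance (km) on decimal-degree arrays."""
    p1 = np.radians(lat1)
    p2 = np.radians(lat2)
    dp = p2 - p1
    dl = np.radians(np.asarray(lon2, dtype=float) - np.asarray(lon1, dtype=float))
    a = np.sin(dp / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def _bearing_arrays(lat1, lon1, lat2, lon2):
    """Vectorised initial bearing (degrees in [0, 360)) on degree arrays."""
    p1 = np.radians(lat1)
    p2 = np.radians(lat2)
    dl = np.radians(np.asarray(lon2, dtype=float) - np.asarray(lon1, dtype=float))
    y = np.sin(dl) * np.cos(p2)
    x = np.cos(p1) * np.sin(p2) - np.sin(p1) * np.cos(p2) * np.cos(dl)
    return np.degrees(np.arctan2(y, x)) % 360.0


def _dest_arrays(lat, lon, bearing_deg, distance_km):
    """Vectorised destination point; returns (lat, lon) degree arrays."""
    d = np.asarray(distance_km, dtype=float) / EARTH_RADIUS_KM
    b = np.radians(bearing_deg)
    p1 = np.radians(lat)
    l1 = np.radians(lon)
    p2 = np.arcsin(np.sin(p1) * np.cos(d) + np.cos(p1) * np.sin(d) * np.cos(b))
    l2 = l1 + np.arctan2(
        np.sin(b) * np.sin(d) * np.cos(p1),
        np.cos(d) - np.sin(p1) * np.sin(p2),
    )
    lon2 = (np.degrees(l2) + 180.0) % 360.0 - 180.0
    return np.degrees(p2), lon2


def haversine_km(a: GeoPoint, b: GeoPoint) -> float:
    """Great-circle distance between two points, in kilometres.

    Symmetric, non-negative, and zero exactly when the two points
    coincide on the sphere.
    """
    return float(
        _hav_arrays(a.latitude_deg, a.longitude_deg, b.latitude_deg, b.longitude_deg)
    )


def initial_bearing_deg(a: GeoPoint, b: GeoPoint) -> float:
    """Initial great-circle bearing from ``a`` to ``b``.

    Raises
    ------
    UndefinedBearingError
        If the two points coincide: the bearing is then undefined and
        returning 0 would silently bias downstream circular statistics.
    """
    if a == b:
        raise UndefinedBearingError(f"bearing undefined between coincident points {a}")
    return float(
        _bearing_arrays(a.latitude_deg, a.longitude_deg, b.latitude_deg, b.longitude_deg)
    )


def destination_point(a: GeoPoint, bearing_deg: float, distance_km: float) -> GeoPoint:
    """Point reached from ``a`` travelling ``distance_km`` along ``bearing_deg``."""
    if not math.isfinite(bearing_deg) or not math.isfinite(distance_km):
        raise ValueError("bearing and distance must be finite")
    if distance_km < 0:
        raise ValueError(f"distance must be non-negative, got {distance_km}")
    if distance_km == 0:
        return a
    lat, lon = _dest_arrays(a.latitude_deg, a.longitude_deg, bearing_deg, distance_km)
    return GeoPoint(float(lat), float(lon))
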