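from datetime import datetime, timedelta, timezone

import pytest
from hypothesis import settings

from cpforage.geodesy import GeoPoint, destination_point
from cpforage.trip_builder import ColonySite, GpsFix, Trip

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")

T0 = datetime(2017, 10, 1, 6, 0, tzinfo=timezone.utc)


@pytest.fixture(scope="session")
def colony() -> ColonySite:
    return ColonySite()


def fix_at(
    colony: ColonySite,
    dist_km: float,
    bearing_deg: float,
    minute: int,
    individual_id: str = "bird001",
    deployment_id: str = "bird001_2017",
    season: int = 2017,
) -> GpsFix:
    """A fix at the given range/bearing from the colony centre."""
    pos = (
        colony.centre
        if dist_km == 0
        else destination_point(colony.centre, bearing_deg, dist_km)
    )
    return GpsFix(
        individual_id=individual_id,
        deployment_id=deployment_id,
        season=season,
        timestamp=T0 + timedelta(minutes=minute),
        position=pos,
    )


def trip_from_ranges(
    colony: ColonySite,
    ranges_km: list[float],
    bearing_deg: float = 270.0,
    interval_min: int = 10,
    trip_id: str = "bird001_2017_t001",
) -> Trip:
    """A trip whose fixes sit at the given colony ranges along one bearing."""
    fixes = tuple(
        fix_at(colony, r, bearing_deg, i * interval_min) for i, r in enumerate(ranges_km)
    )
    return Trip(
        trip_id=trip_id,
        individual_id="bird001",
        deployment_id="bird001_2017",
        season=2017,
        fixes=fixes,
    )
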