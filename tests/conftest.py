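from datetime import datetime, timedelta, timezone

import numpy as np
import pytest

from hikespeed.gpx import TrackPoint, TrackSegment
from hikespeed.models import published_model
from hikespeed.synthetic import SynthConfig, simulate_dataset

T0 = datetime(2022, 6, 1, 9, 0, tzinfo=timezone.utc)


@pytest.fixture(scope="session")
def published_fit():
    """The published per-terrain coefficient set."""
    return published_model()


@pytest.fixture(scope="session")
def small_world():
    """A small seeded synthetic world shared across tests (read-only)."""
    return simulate_dataset(SynthConfig(seed=11, track_count=6))


def make_segment(xy, dt=20.0, track_id="t0", source="hikr", times=None):
    """Build a projected segment from (x, y) metre coordinates.

    Latitude/longitude are back-filled consistently via the default local
    projection so GPX round-trips stay valid.
    """
    from hikespeed.geometry import LocalProjection

    proj = LocalProjection(54.5, -2.5)
    points = []
    for i, (x, y) in enumerate(xy):
        lat, lon = proj.to_latlon(x, y)
        ts = times[i] if times is not None else T0 + timedelta(seconds=i * dt)
        points.append(TrackPoint(lat=float(lat), lon=float(lon), timestamp=ts,
                                 x=float(x), y=float(y)))
    return TrackSegment(points=points, track_id=track_id, source=source)


@pytest.fixture
def straight_walk_segment():
    """Constant 6 km/h due-east walk: 33.33 m steps every 20 s, no pauses."""
    xy = [(i * 100.0 / 3.0, 0.0) for i in range(60)]
    return make_segment(xy)
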