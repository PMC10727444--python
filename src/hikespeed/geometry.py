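"""Local metric projection and planimetric geometry helpers.

Hike-scale extents (a few tens of km) are projected onto a local
tangent-plane equirectangular grid: metres east/north of a reference
point. Distortion over such extents is far below GPS noise, and all
raster cell sizes and search radii in this package are metric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

#: Mean Earth radius (m), IUGG value.
EARTH_RADIUS_M = 6_371_008.8


@dataclass(frozen=True)
class LocalProjection:
    """Equirectangular projection about a reference latitude/longitude.

    ``x`` is metres east of ``ref_lon``, ``y`` metres north of ``ref_lat``.
    """

    ref_lat: float
    ref_lon: float

    def to_xy(self, lat, lon):
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        coslat = math.cos(math.radians(self.ref_lat))
        x = np.radians(lon - self.ref_lon) * EARTH_RADIUS_M * coslat
        y = np.radians(lat - self.ref_lat) * EARTH_RADIUS_M
        return x, y

    def to_latlon(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        coslat = math.cos(math.radians(self.ref_lat))
        lon = self.ref_lon + np.degrees(x / (EARTH_RADIUS_M * coslat))
        lat = self.ref_lat + np.degrees(y / EARTH_RADIUS_M)
        return lat, lon


def bearing_degrees(dx: float, dy: float) -> float:
    """Compass bearing of the displacement (dx east, dy north), degrees in [0, 360)."""
    return math.degrees(math.atan2(dx, dy)) % 360.0


def bearing_quadrant(bearing: float) -> int:
    """Quadrant 1-4 of a compass bearing: Q1=[0,90), Q2=[90,180), Q3=[180,270), Q4=[270,360)."""
    return int(bearing % 360.0 // 90.0) + 1


def turn_angle_degrees(bearing_prev: float, bearing_next: float) -> float:
    """Absolute change of heading between consecutive steps, in [0, 180]."""
    d = abs(bearing_next - bearing_prev) % 360.0
    return min(d, 360.0 - d)
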