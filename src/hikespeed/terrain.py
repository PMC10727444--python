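"""Terrain and geodata handling: rasters, slopes, roads and obstruction.

The modelling needs four terrain variables per GPS point:

* elevation, sampled from a digital terrain model (DTM, bare earth);
* walking slope θ — the signed gradient along the direction of travel;
* hill slope φ — the unsigned steepest gradient of the terrain surface,
  derived by fitting a quadratic surface to a raster neighbourhood;
* terrain class — paved road, unpaved road, or off-road, with off-road
  travel further split by obstruction height (DSM − DTM, the height of
  vegetation and other features above bare ground).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path

import numpy as np
from shapely.geometry import LineString, Point, shape


class CoverageError(ValueError):
    """A raster query fell outside the grid extent or hit nodata cells."""


class SlopeUndefinedError(ValueError):
    """Walking slope requested over zero planimetric distance."""


class TerrainClass(str, Enum):
    """Five-way terrain classification used by the walking-speed model."""

    PAVED_ROAD = "paved_road"
    UNPAVED_ROAD = "unpaved_road"
    OFFROAD_UNKNOWN = "offroad_unknown"
    OFFROAD_LIGHT = "offroad_light"
    OFFROAD_HEAVY = "offroad_heavy"

    @property
    def is_offroad(self) -> bool:
        return self in (
            TerrainClass.OFFROAD_UNKNOWN,
            TerrainClass.OFFROAD_LIGHT,
            TerrainClass.OFFROAD_HEAVY,
        )


#: Obstruction height (m) separating light from heavy off-road obstruction.
OBSTRUCTION_CUTOFF_M = 0.10

#: Search radius (m) for matching GPS points to the road network.
ROAD_SEARCH_RADIUS_M = 50.0


@dataclass
class RasterGrid:
    """Regular elevation grid in projected metric coordinates.

    ``values[i, j]`` is the elevation of the cell whose centre is at
    ``(origin_x + (j + 0.5) * cell_size, origin_y + (i + 0.5) * cell_size)``;
    row 0 is the southernmost row. ``origin_x/origin_y`` are the coordinates
    of the lower-left corner of the grid.
    """

    origin_x: float
    origin_y: float
    cell_size: float
    values: np.ndarray
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the covered area."""
        return (
            self.origin_x,
            self.origin_y,
            self.origin_x + self.n_cols * self.cell_size,
            self.origin_y + self.n_rows * self.cell_size,
        )

    def contains(self, x: float, y: float) -> bool:
        xmin, ymin, xmax, ymax = self.extent
        return xmin <= x <= xmax and ymin <= y <= ymax

    def is_nodata(self, value: float) -> bool:
        return not np.isfinite(value) or value == self.nodata

    # ---- ESRI ASCII grid I/O -------------------------------------------

    @classmethod
    def from_ascii(cls, path: str | Path) -> "RasterGrid":
        """Read an ESRI ASCII grid (.asc). Rows in the file run north to south."""
        header: dict[str, float] = {}
        rows: list[list[float]] = []
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                key = parts[0].lower()
                if key in ("ncols", "nrows", "xllcorner", "yllcorner",
                           "cellsize", "nodata_value"):
                    header[key] = float(parts[1])
                else:
                    rows.append([float(v) for v in parts])
        values = np.array(rows, dtype=float)
        ncols = int(header["ncols"])
        nrows = int(header["nrows"])
        values = values.reshape(nrows, ncols)[::-1]  # store south-up
        return cls(
            origin_x=header["xllcorner"],
            origin_y=header["yllcorner"],
            cell_size=header["cellsize"],
            values=values,
            nodata=header.get("nodata_value", -9999.0),
        )

    def to_ascii(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"ncols {self.n_cols}\n")
            fh.write(f"nrows {self.n_rows}\n")
            fh.write(f"xllcorner {self.origin_x!r}\n")
            fh.write(f"yllcorner {self.origin_y!r}\n")
            fh.write(f"cellsize {self.cell_size!r}\n")
            fh.write(f"nodata_value {self.nodata!r}\n")
            for row in self.values[::-1]:
                fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def sample_elevation(grid: RasterGrid, x: float, y: float) -> float:
    """Bilinearly interpolated elevation at a projected coordinate.

    Interpolates between the four surrounding cell centres. Points inside
    the extent but beyond the outermost cell centres are clamped to the
    centre hull (edge extension). Returns the grid's nodata value when any
    contributing cell is nodata.

    Raises :class:`CoverageError` when (x, y) is outside the grid extent.
    """
    if not grid.contains(x, y):
        raise CoverageError(f"point ({x}, {y}) outside raster extent {grid.extent}")
    fx = (x - grid.origin_x) / grid.cell_size - 0.5
    fy = (y - grid.origin_y) / grid.cell_size - 0.5
    fx = min(max(fx, 0.0), grid.n_cols - 1.0)
    fy = min(max(fy, 0.0), grid.n_rows - 1.0)
    j0 = min(int(fx), grid.n_cols - 2) if grid.n_cols > 1 else 0
    i0 = min(int(fy), grid.n_rows - 2) if grid.n_rows > 1 else 0
    j1 = min(j0 + 1, grid.n_cols - 1)
    i1 = min(i0 + 1, grid.n_rows - 1)
    tx = fx - j0
    ty = fy - i0
    corners = (
        grid.values[i0, j0], grid.values[i0, j1],
        grid.values[i1, j0], grid.values[i1, j1],
    )
    if any(grid.is_nodata(c) for c in corners):
        return grid.nodata
    z00, z01, z10, z11 = corners
    return (
        z00 * (1 - tx) * (1 - ty)
        + z01 * tx * (1 - ty)
        + z10 * (1 - tx) * ty
        + z11 * tx * ty
    )


def walking_slope(elev_start: float, elev_end: float,
                  planimetric_distance: float) -> float:
    """Signed walking slope θ in degrees; positive uphill in travel direction.

    θ = arctan(Δz / planimetric distance), so 45° corresponds to a 1:1 rise
    over map distance.
    """
    if planimetric_distance <= 0:
        raise SlopeUndefinedError("walking slope undefined over zero distance")
    return math.degrees(math.atan((elev_end - elev_start) / planimetric_distance))


def hill_slope_quadratic(grid: RasterGrid, x: float, y: float,
                         window: int = 1) -> float:
    """Unsigned hill slope φ (degrees) via a quadratic surface fit.

    Fits z = A·u² + B·w² + C·u·w + D·u + E·w + F by least squares over the
    (2·window+1)² cell centres around the containing cell, then returns
    φ = arctan(√(D² + E²)). The default 3×3 window at native cell size is
    the classic formulation; the fit reproduces any plane exactly, so φ on
    a planar surface equals the analytic slope regardless of aspect.

    Raises :class:`CoverageError` if the window touches the grid boundary
    or contains nodata.
    """
    if not grid.contains(x, y):
        raise CoverageError(f"point ({x}, {y}) outside raster extent")
    j = int((x - grid.origin_x) / grid.cell_size)
    i = int((y - grid.origin_y) / grid.cell_size)
    j = min(j, grid.n_cols - 1)
    i = min(i, grid.n_rows - 1)
    if (i - window < 0 or i + window >= grid.n_rows
            or j - window < 0 or j + window >= grid.n_cols):
        raise CoverageError("quadratic-surface window touches the grid boundary")
    sub = grid.values[i - window:i + window + 1, j - window:j + window + 1]
    if any(grid.is_nodata(v) for v in sub.ravel()):
        raise CoverageError("quadratic-surface window contains nodata")
    offsets = np.arange(-window, window + 1, dtype=float) * grid.cell_size
    ww, uu = np.meshgrid(offsets, offsets, indexing="ij")  # w: north, u: east
    u = uu.ravel()
    w = ww.ravel()
    design = np.column_stack([u ** 2, w ** 2, u * w, u, w, np.ones_like(u)])
    coef, *_ = np.linalg.lstsq(design, sub.ravel(), rcond=None)
    d_coef, e_coef = coef[3], coef[4]
    return math.degrees(math.atan(math.hypot(d_coef, e_coef)))


# ---- Road network ------------------------------------------------------


def _default_tag_map() -> dict[str, list[str]]:
    with resources.files("hikespeed.data").joinpath("highway_classes.json").open() as fh:
        return json.load(fh)


@dataclass
class RoadNetwork:
    """Road polylines in projected coordinates, each with an OSM highway tag."""

    ways: list[tuple[LineString, str]] = field(default_factory=list)

    @classmethod
    def from_geojson(cls, path: str | Path, projection=None) -> "RoadNetwork":
        """Load LineString features carrying a "highway" property.

        If ``projection`` (a :class:`~hikespeed.geometry.LocalProjection`)
        is given, feature coordinates are treated as (lon, lat) and
        projected; otherwise they are taken as already-projected metres.
        """
        with open(path) as fh:
            collection = json.load(fh)
        ways = []
        for feature in collection.get("features", []):
            geom = shape(feature["geometry"])
            tag = feature.get("properties", {}).get("highway", "")
            if geom.geom_type != "LineString" or not tag:
                continue
            if projection is not None:
                lons, lats = zip(*geom.coords)
                xs, ys = projection.to_xy(list(lats), list(lons))
                geom = LineString(zip(xs, ys))
            ways.append((geom, tag))
        return cls(ways=ways)

    def to_geojson(self, path: str | Path) -> None:
        features = [
            {
                "type": "Feature",
                "geometry": {"type": "LineString",
                             "coordinates": [list(c) for c in line.coords]},
                "properties": {"highway": tag},
            }
            for line, tag in self.ways
        ]
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": features}, fh)


def classify_road(x: float, y: float, roads: RoadNetwork,
                  radius: float = ROAD_SEARCH_RADIUS_M,
                  tag_map: dict[str, list[str]] | None = None) -> str:
    """Three-way road classification by nearest way within a search radius.

    Returns ``"paved_road"``, ``"unpaved_road"`` or ``"off_road"``. The
    nearest recognised way within ``radius`` decides the class; the
    unpaved tags are {path, bridleway, track} and all other recognised
    highway values count as paved. Ways with unrecognised tags are ignored.
    Deterministic and independent of the order of ways.
    """
    if tag_map is None:
        tag_map = _default_tag_map()
    unpaved = set(tag_map["unpaved"])
    paved = set(tag_map["paved"])
    point = Point(x, y)
    best: tuple[float, str] | None = None
    for line, tag in roads.ways:
        if tag in unpaved:
            cls = "unpaved_road"
        elif tag in paved:
            cls = "paved_road"
        else:
            continue
        dist = line.distance(point)
        if dist <= radius and (best is None or (dist, cls) < best):
            best = (dist, cls)
    return best[1] if best is not None else "off_road"


def obstruction_class(dsm: RasterGrid | None, dtm: RasterGrid, x: float, y: float,
                      cutoff: float = OBSTRUCTION_CUTOFF_M) -> tuple[TerrainClass, float]:
    """Off-road obstruction class and height from the DSM − DTM difference.

    Height is floored at zero (a DSM below the DTM is measurement noise).
    Missing DSM coverage yields ``OFFROAD_UNKNOWN`` with NaN height — a
    valid class, not an error, because surface-model coverage is patchy
    in practice.
    """
    if dsm is None or not dsm.contains(x, y):
        return TerrainClass.OFFROAD_UNKNOWN, float("nan")
    surf = sample_elevation(dsm, x, y)
    ground = sample_elevation(dtm, x, y)
    if dsm.is_nodata(surf) or dtm.is_nodata(ground):
        return TerrainClass.OFFROAD_UNKNOWN, float("nan")
    height = max(0.0, surf - ground)
    if height > cutoff:
        return TerrainClass.OFFROAD_HEAVY, height
    return TerrainClass.OFFROAD_LIGHT, height


def classify_terrain(x: float, y: float, roads: RoadNetwork,
                     dtm: RasterGrid, dsm: RasterGrid | None,
                     radius: float = ROAD_SEARCH_RADIUS_M,
                     cutoff: float = OBSTRUCTION_CUTOFF_M,
                     tag_map: dict[str, list[str]] | None = None,
                     ) -> tuple[TerrainClass, float]:
    """Full five-way terrain classification: roads first, then obstruction.

    Returns (terrain class, obstruction height); height is NaN on roads
    and where the DSM is missing.
    """
    road = classify_road(x, y, roads, radius=radius, tag_map=tag_map)
    if road == "paved_road":
        return TerrainClass.PAVED_ROAD, float("nan")
    if road == "unpaved_road":
        return TerrainClass.UNPAVED_ROAD, float("nan")
    return obstruction_class(dsm, dtm, x, y, cutoff=cutoff)
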