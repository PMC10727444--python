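"""Synthetic terrain, roads and GPS hiking tracks with known ground truth.

Every stage of the pipeline is testable without downloads: smooth
correlated terrain surfaces with controllable relief, a surface model
equal to the terrain plus non-negative vegetation patches, sparse road
polylines with paved/unpaved tags, and GPX tracks walked over that
terrain at speeds drawn from the log-linear walking-speed model with
log-normal noise. Tracks embed the artefacts the cleaning pipeline must
remove — stationary jittered break clusters and high-speed drive
prefixes/suffixes — and carry per-point ground-truth labels.

All randomness flows from a single seeded generator, so every fixture
is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone

import numpy as np
from scipy.ndimage import gaussian_filter

from .geometry import LocalProjection
from .gpx import TrackPoint, TrackSegment
from .models import GLMSpeedModel, published_model
from .terrain import (
    CoverageError,
    RasterGrid,
    RoadNetwork,
    TerrainClass,
    classify_terrain,
    hill_slope_quadratic,
    sample_elevation,
    walking_slope,
)


@dataclass
class SynthConfig:
    """Study conditions for the synthetic world.

    Defaults emulate UK hill-walking country at the native 5 m terrain
    resolution: tens of metres of smooth relief over a few km, sparse
    vegetation patches, a handful of roads and paths, walkers moving at
    0–10 km/h with occasional multi-minute breaks and the odd drive to
    the trailhead recorded in the same track.
    """

    seed: int = 0
    extent: float = 4000.0          # m, square side
    cell_size: float = 5.0          # m
    roughness_amplitude: float = 40.0   # m, SD of terrain relief
    roughness_length: float = 400.0     # m, correlation length
    vegetation_density: float = 30.0    # patches per km²
    vegetation_height_range: tuple[float, float] = (0.3, 2.0)  # m
    vegetation_radius_range: tuple[float, float] = (10.0, 40.0)  # m
    road_count: int = 5
    dsm_coverage: float = 0.7  # fraction of the extent (west side) with DSM tiles
    track_count: int = 20
    hikr_fraction: float = 0.5
    walker_model: GLMSpeedModel | None = None  # defaults to the published fit
    speed_noise_sigma: float = 0.25     # log-scale SD of per-point speed
    gps_noise_m: float = 3.0            # isotropic position noise
    # During a break the walker is stationary; observed scatter comes from
    # GPS noise. break_jitter_m adds wander on top (useful for isolating
    # cluster morphology in tests with GPS noise disabled).
    break_jitter_m: float = 0.0
    point_interval_range: tuple[float, float] = (10.0, 30.0)   # s
    track_duration_range: tuple[float, float] = (1200.0, 3600.0)  # s
    break_rate_per_hour: float = 1.0    # roughly one rest stop per hour
    break_duration_range: tuple[float, float] = (180.0, 900.0)  # s
    drive_probability: float = 0.2
    drive_speed_range: tuple[float, float] = (30.0, 80.0)  # km/h
    heading_sigma_deg: float = 15.0
    follow_road_probability: float = 0.35  # fraction of walkers following a way
    ref_lat: float = 54.5
    ref_lon: float = -2.5

    def model(self) -> GLMSpeedModel:
        return self.walker_model if self.walker_model is not None else published_model()

    def projection(self) -> LocalProjection:
        return LocalProjection(ref_lat=self.ref_lat, ref_lon=self.ref_lon)


@dataclass
class TrackTruth:
    """Per-point ground truth for one simulated segment."""

    labels: list[str]                   # walk | break | drive, per point
    walking_slope: np.ndarray           # per point, degrees (NaN for non-walk)
    hill_slope: np.ndarray
    terrain: list[TerrainClass | None]
    model_speed: np.ndarray             # km/h incl. noise (NaN for non-walk)


@dataclass
class SyntheticDataset:
    dtm: RasterGrid
    dsm: RasterGrid
    roads: RoadNetwork
    segments: list[TrackSegment]
    truths: list[TrackTruth]
    projection: LocalProjection


def make_terrain(config: SynthConfig,
                 rng: np.random.Generator | None = None
                 ) -> tuple[RasterGrid, RasterGrid]:
    """Generate a (DTM, DSM) pair; DSM = DTM + vegetation, DSM ≥ DTM."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = int(round(config.extent / config.cell_size))
    if config.roughness_amplitude > 0:
        noise = rng.standard_normal((n, n))
        smooth = gaussian_filter(noise, sigma=config.roughness_length / config.cell_size,
                                 mode="reflect")
        sd = smooth.std()
        z = smooth / sd * config.roughness_amplitude if sd > 0 else smooth * 0.0
        z = z + 200.0  # base elevation
    else:
        rng.standard_normal((n, n))  # keep the draw sequence stable
        z = np.full((n, n), 200.0)
    dtm = RasterGrid(origin_x=0.0, origin_y=0.0, cell_size=config.cell_size,
                     values=z)

    veg = np.zeros((n, n))
    area_km2 = (config.extent / 1000.0) ** 2
    n_patches = int(rng.poisson(config.vegetation_density * area_km2))
    centres = config.cell_size * (np.arange(n) + 0.5)
    xx, yy = np.meshgrid(centres, centres)  # xx: east, yy: north
    for _ in range(n_patches):
        cx, cy = rng.uniform(0, config.extent, size=2)
        radius = rng.uniform(*config.vegetation_radius_range)
        height = rng.uniform(*config.vegetation_height_range)
        mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius ** 2
        veg[mask] = np.maximum(veg[mask], height)
    # Surface-model coverage is patchy in practice; only the western part
    # of the extent gets DSM tiles, so the obstruction-unknown class occurs.
    n_dsm = max(1, int(round(n * config.dsm_coverage)))
    dsm = RasterGrid(origin_x=0.0, origin_y=0.0, cell_size=config.cell_size,
                     values=(z + veg)[:, :n_dsm])
    return dtm, dsm


_ROAD_TAGS = ["residential", "track", "path", "footway", "bridleway"]


def make_roads(config: SynthConfig,
               rng: np.random.Generator | None = None) -> RoadNetwork:
    """Sparse polylines crossing the extent, cycling paved and unpaved tags."""
    from shapely.geometry import LineString

    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    ways = []
    for i in range(config.road_count):
        tag = _ROAD_TAGS[i % len(_ROAD_TAGS)]
        if rng.random() < 0.5:  # west-east
            y0, y1 = rng.uniform(0, config.extent, size=2)
            coords = [(0.0, y0)]
            for frac in (0.33, 0.66):
                coords.append((config.extent * frac,
                               np.clip(y0 + (y1 - y0) * frac
                                       + rng.normal(0, config.extent * 0.05),
                                       0, config.extent)))
            coords.append((config.extent, y1))
        else:  # south-north
            x0, x1 = rng.uniform(0, config.extent, size=2)
            coords = [(x0, 0.0)]
            for frac in (0.33, 0.66):
                coords.append((np.clip(x0 + (x1 - x0) * frac
                                       + rng.normal(0, config.extent * 0.05),
                                       0, config.extent),
                               config.extent * frac))
            coords.append((x1, config.extent))
        ways.append((LineString(coords), tag))
    return RoadNetwork(ways=ways)


def _safe_hill_slope(dtm: RasterGrid, x: float, y: float) -> float:
    try:
        return hill_slope_quadratic(dtm, x, y)
    except CoverageError:
        return 0.0


def _safe_elevation(dtm: RasterGrid, x: float, y: float) -> float:
    try:
        z = sample_elevation(dtm, x, y)
        return 0.0 if dtm.is_nodata(z) else z
    except CoverageError:
        return 0.0


def simulate_track(config: SynthConfig, dtm: RasterGrid, dsm: RasterGrid,
                   roads: RoadNetwork, rng: np.random.Generator,
                   track_id: str = "synth-0", source: str = "hikr",
                   start_time: datetime | None = None,
                   start_xy: tuple[float, float] | None = None,
                   heading_deg: float | None = None,
                   ) -> tuple[TrackSegment, TrackTruth]:
    """Walk one synthetic track over the terrain.

    Most walkers follow a random smoothly-turning heading, reflecting off
    the extent margins; a configurable fraction start on a road or path
    and are steered back towards it when they stray, emulating hikers
    following waymarked routes. At each emission interval the walking
    slope is found by a short fixed-point iteration (step length depends
    on speed, speed depends on the slope over the step), the terrain
    class is read at the step midpoint, and the speed is drawn as
    ``exp(log v_model + ε)`` with ε ~ Normal(0, σ). Stationary break
    clusters and drive prefixes/suffixes are inserted per configuration;
    every emitted point carries a walk/break/drive label.
    """
    from shapely.geometry import Point

    model = config.model()
    projection = config.projection()
    margin = 12 * config.cell_size
    lo, hi = margin, config.extent - margin
    dt = float(rng.uniform(*config.point_interval_range))
    duration = float(rng.uniform(*config.track_duration_range))
    n_steps = max(2, int(duration / dt))

    follow_line = None
    heading_sigma = config.heading_sigma_deg
    if (start_xy is None and heading_deg is None and roads.ways
            and rng.random() < config.follow_road_probability):
        follow_line = roads.ways[int(rng.integers(len(roads.ways)))][0]
        s = float(rng.uniform(0.1, 0.9)) * follow_line.length
        p0 = follow_line.interpolate(s)
        p1 = follow_line.interpolate(min(follow_line.length, s + 10.0))
        pos = np.clip(np.array([p0.x, p0.y]), lo, hi)
        heading = math.degrees(math.atan2(p1.x - p0.x, p1.y - p0.y))
        if rng.random() < 0.5:
            heading += 180.0
        heading_sigma = config.heading_sigma_deg * 0.25
    elif start_xy is None:
        pos = np.array([rng.uniform(lo + margin, hi - margin),
                        rng.uniform(lo + margin, hi - margin)])
        heading = float(rng.uniform(0, 360)) if heading_deg is None else float(heading_deg)
    else:
        pos = np.array(start_xy, dtype=float)
        heading = float(rng.uniform(0, 360)) if heading_deg is None else float(heading_deg)

    # (true position, label, truth values) per emitted point
    positions: list[np.ndarray] = [pos.copy()]
    labels: list[str] = ["walk"]
    theta_true: list[float] = [float("nan")]
    phi_true: list[float] = [float("nan")]
    terrain_true: list[TerrainClass | None] = [None]
    speed_true: list[float] = [float("nan")]

    hours = duration / 3600.0
    n_breaks = int(rng.poisson(config.break_rate_per_hour * hours))
    break_steps = sorted(rng.choice(n_steps, size=min(n_breaks, n_steps),
                                    replace=False)) if n_breaks else []
    break_iter = iter(break_steps)
    next_break = next(break_iter, None)

    for step_i in range(n_steps):
        if next_break is not None and step_i == next_break:
            b_dur = float(rng.uniform(*config.break_duration_range))
            for _ in range(max(1, int(b_dur / dt))):
                jitter = rng.normal(0, config.break_jitter_m, size=2) \
                    if config.break_jitter_m > 0 else np.zeros(2)
                positions.append(pos + jitter)
                labels.append("break")
                theta_true.append(float("nan"))
                phi_true.append(float("nan"))
                terrain_true.append(None)
                speed_true.append(float("nan"))
            next_break = next(break_iter, None)
        heading += float(rng.normal(0, heading_sigma))
        if follow_line is not None:
            nearest = follow_line.interpolate(follow_line.project(Point(pos)))
            off = math.hypot(nearest.x - pos[0], nearest.y - pos[1])
            if off > 20.0:  # strayed off the way: steer back towards it
                heading = math.degrees(math.atan2(nearest.x - pos[0],
                                                  nearest.y - pos[1]))
        direction = np.array([math.sin(math.radians(heading)),
                              math.cos(math.radians(heading))])
        phi = _safe_hill_slope(dtm, pos[0], pos[1])
        theta = 0.0
        v = model.predict(phi, theta, TerrainClass.PAVED_ROAD)
        terrain: TerrainClass = TerrainClass.PAVED_ROAD
        for _ in range(2):  # fixed point: step length <-> slope over step
            d = v * dt / 3.6
            nxt = pos + d * direction
            if not (lo <= nxt[0] <= hi and lo <= nxt[1] <= hi):
                heading += 180.0 + float(rng.normal(0, 30))
                direction = np.array([math.sin(math.radians(heading)),
                                      math.cos(math.radians(heading))])
                nxt = pos + d * direction
                nxt = np.clip(nxt, lo, hi)
            z0 = _safe_elevation(dtm, pos[0], pos[1])
            z1 = _safe_elevation(dtm, nxt[0], nxt[1])
            dist = float(np.hypot(*(nxt - pos)))
            theta = walking_slope(z0, z1, dist) if dist > 0 else 0.0
            mid = (pos + nxt) / 2.0
            terrain, _ = classify_terrain(mid[0], mid[1], roads, dtm, dsm)
            v = model.predict(phi, theta, terrain)
        eps = float(rng.normal(0, config.speed_noise_sigma)) \
            if config.speed_noise_sigma > 0 else 0.0
        v_noisy = v * math.exp(eps)
        d = v_noisy * dt / 3.6
        pos = pos + d * direction
        pos = np.clip(pos, lo, hi)
        positions.append(pos.copy())
        labels.append("walk")
        theta_true.append(theta)
        phi_true.append(phi)
        terrain_true.append(terrain)
        speed_true.append(v_noisy)

    def make_drive(attach_start: bool) -> list[np.ndarray]:
        v_drive = float(rng.uniform(*config.drive_speed_range))
        step = v_drive * dt / 3.6
        n_drive = int(rng.uniform(120, 300) / dt)
        anchor = positions[0] if attach_start else positions[-1]
        ang = float(rng.uniform(0, 360))
        u = np.array([math.sin(math.radians(ang)), math.cos(math.radians(ang))])
        pts = []
        for k in range(1, n_drive + 1):
            p = anchor + u * step * k
            if not (0 <= p[0] <= config.extent and 0 <= p[1] <= config.extent):
                break
            pts.append(p)
        return pts

    if rng.random() < config.drive_probability:
        prefix = make_drive(attach_start=True)[::-1]
        positions = prefix + positions
        labels = ["drive"] * len(prefix) + labels
        theta_true = [float("nan")] * len(prefix) + theta_true
        phi_true = [float("nan")] * len(prefix) + phi_true
        terrain_true = [None] * len(prefix) + terrain_true
        speed_true = [float("nan")] * len(prefix) + speed_true
    if rng.random() < config.drive_probability:
        suffix = make_drive(attach_start=False)
        positions = positions + suffix
        labels = labels + ["drive"] * len(suffix)
        theta_true = theta_true + [float("nan")] * len(suffix)
        phi_true = phi_true + [float("nan")] * len(suffix)
        terrain_true = terrain_true + [None] * len(suffix)
        speed_true = speed_true + [float("nan")] * len(suffix)

    if start_time is None:
        start_time = datetime(2022, 6, 1, 9, 0, tzinfo=timezone.utc)
    points: list[TrackPoint] = []
    for i, p in enumerate(positions):
        if config.gps_noise_m > 0:
            obs = p + rng.normal(0, config.gps_noise_m, size=2)
        else:
            obs = p
        lat, lon = projection.to_latlon(obs[0], obs[1])
        points.append(TrackPoint(lat=float(lat), lon=float(lon),
                                 timestamp=start_time + timedelta(seconds=i * dt),
                                 x=float(obs[0]), y=float(obs[1])))
    segment = TrackSegment(points=points, source=source, track_id=track_id)
    truth = TrackTruth(labels=labels,
                       walking_slope=np.array(theta_true),
                       hill_slope=np.array(phi_true),
                       terrain=terrain_true,
                       model_speed=np.array(speed_true))
    return segment, truth


def simulate_dataset(config: SynthConfig) -> SyntheticDataset:
    """Full seeded world: terrain, roads and a set of labelled tracks."""
    rng = np.random.default_rng(config.seed)
    dtm, dsm = make_terrain(config, rng)
    roads = make_roads(config, rng)
    segments: list[TrackSegment] = []
    truths: list[TrackTruth] = []
    base_time = datetime(2022, 6, 1, 8, 0, tzinfo=timezone.utc)
    n_hikr = int(round(config.track_count * config.hikr_fraction))
    for i in range(config.track_count):
        source = "hikr" if i < n_hikr else "osm"
        seg, truth = simulate_track(
            config, dtm, dsm, roads, rng,
            track_id=f"synth-{i:03d}", source=source,
            start_time=base_time + timedelta(hours=2 * i))
        segments.append(seg)
        truths.append(truth)
    return SyntheticDataset(dtm=dtm, dsm=dsm, roads=roads,
                            segments=segments, truths=truths,
                            projection=config.projection())


#: Terrain-class shares of a UK hiking corpus by distance (paved roads
#: dominate; off-road travel is rare). Used when emulating the observed
#: composition rather than the balanced default.
UK_TERRAIN_MIX = (0.820, 0.147, 0.010, 0.017, 0.006)


def simulate_sections(model: GLMSpeedModel | None = None,
                      n_tracks: int = 200, sections_per_track: int = 50,
                      sigma: float = 0.25, track_sigma: float = 0.0,
                      class_probs: tuple[float, ...] | None = None,
                      seed: int = 0):
    """Draw modelling-ready sections directly from the speed model.

    Bypasses the GPS layer: slopes, terrain classes and section lengths
    are sampled from hike-like distributions (hill slopes mostly under
    20°, walking slope magnitude bounded by the hill slope, ~60 m
    sections) and observed speeds are the model prediction times
    log-normal noise ``exp(ε)``, ε ~ Normal(0, σ), plus an optional
    shared per-track effect for studying within-track correlation.

    Returns a DataFrame in the cleaned-sections schema.
    """
    import pandas as pd

    model = model if model is not None else published_model()
    rng = np.random.default_rng(seed)
    classes = list(TerrainClass)
    if class_probs is None:
        probs = np.array([0.35, 0.20, 0.15, 0.15, 0.15])
    else:
        probs = np.asarray(class_probs, dtype=float)
        probs = probs / probs.sum()
    n = n_tracks * sections_per_track
    track_idx = np.repeat(np.arange(n_tracks), sections_per_track)
    u_track = (rng.normal(0, track_sigma, size=n_tracks)
               if track_sigma > 0 else np.zeros(n_tracks))
    phi = np.minimum(np.abs(rng.normal(0, 12.0, size=n)), 44.0)
    theta = rng.uniform(-1.0, 1.0, size=n) * phi
    cls_idx = rng.choice(len(classes), size=n, p=probs)
    distance = np.maximum(50.0, rng.normal(60.0, 10.0, size=n))
    eps = rng.normal(0, sigma, size=n) if sigma > 0 else np.zeros(n)
    mean_speed = np.empty(n)
    for ci, terrain in enumerate(classes):
        mask = cls_idx == ci
        if mask.any():
            mean_speed[mask] = model.predict(phi[mask], theta[mask], terrain)
    speed = mean_speed * np.exp(u_track[track_idx] + eps)
    terrain_values = np.array([c.value for c in classes])[cls_idx]
    offroad = np.array([c.is_offroad for c in classes])[cls_idx]
    return pd.DataFrame({
        "track_id": np.array([f"sim-{t:04d}" for t in range(n_tracks)])[track_idx],
        "source": "hikr",
        "start_x": 0.0, "start_y": 0.0, "end_x": distance, "end_y": 0.0,
        "start_time": datetime(2022, 6, 1, tzinfo=timezone.utc),
        "duration_s": 3.6 * distance / speed,
        "distance_m": distance,
        "speed_kmh": speed, "elevation_m": 200.0,
        "walking_slope_deg": theta, "hill_slope_deg": phi,
        "obstruction_height_m": float("nan"),
        "terrain": terrain_values,
        "on_road": ~offroad,
        "paved": terrain_values == TerrainClass.PAVED_ROAD.value,
        "obstruction_known": np.isin(terrain_values,
                                     [TerrainClass.OFFROAD_LIGHT.value,
                                      TerrainClass.OFFROAD_HEAVY.value]),
        "heavy_obstruction": terrain_values == TerrainClass.OFFROAD_HEAVY.value,
    })
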