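"""GPS track cleaning: break detection, non-walking filtering, section merging.

Raw crowdsourced GPS tracks mix genuine walking with stationary breaks,
drives to and from the trailhead, and recording glitches. Cleaning runs
in three stages:

1. **Break finding** — flag points by pointwise rules (zero speed,
   implausibly long steps or gaps, a fast step straight after a long
   pause) and by spatial clustering: a stationary walker produces a
   tight cluster of jittered points with headings scattered across
   opposite compass quadrants.
2. **Filtering** — drop duplicate uploads and whole segments whose
   speeds are implausible for walking; excise long breaks; for the
   uncurated corpus ("osm"), apply speed bounds estimated from the
   known-walking corpus ("hikr") until the segment is stable.
3. **Merging** — combine consecutive steps into sections of at least
   50 m so that GPS positional error does not dominate the speed signal;
   slope and obstruction values are duration-weighted means of the
   constituent steps.

The output is a list of :class:`SectionRecord`, the modelling unit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from datetime import datetime
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.spatial.distance import pdist

from .geometry import bearing_quadrant, turn_angle_degrees
from .gpx import PointStep, TrackSegment, compute_steps, deduplicate_segments
from .terrain import (
    OBSTRUCTION_CUTOFF_M,
    CoverageError,
    RasterGrid,
    RoadNetwork,
    TerrainClass,
    classify_road,
    hill_slope_quadratic,
    obstruction_class,
    sample_elevation,
    walking_slope,
)

logger = logging.getLogger(__name__)


class InsufficientDataError(ValueError):
    """Too few known-walking segments to estimate filtering bounds."""


@dataclass
class CleaningConfig:
    """Thresholds for break finding and filtering.

    Defaults follow the published cleaning procedure: 10 km/h speed cap,
    1 km / 3 min step limits, breaks over 30 s excised, 50 m minimum
    section length, 2.5 min minimum segment duration and a 0.5% speed
    trim of the pooled data.
    """

    speed_cap: float = 10.0             # km/h; faster is not walking
    break_max_duration: float = 180.0   # s; a longer gap is a break
    break_max_distance: float = 1000.0  # m; a longer step is a glitch/drive
    short_break_keep: float = 30.0      # s; breaks up to this stay in the data
    min_section_length: float = 50.0    # m
    min_segment_duration: float = 150.0  # s (2.5 minutes)
    trim_fraction: float = 0.005        # fastest/slowest share trimmed
    cluster_window: int = 5             # points each side in a neighbourhood
    cluster_radius_factor: float = 2.0  # × median step distance
    low_likelihood_threshold: float = 0.5
    likelihood_speed_weight: float = 0.5
    likelihood_angle_weight: float = 0.5
    # Percentiles of the known-walking per-segment summaries used as bounds.
    bound_median_percentile: float = 99.0
    bound_min_percentile: float = 99.0
    bound_quartile_percentile: float = 99.0
    bound_whisker_percentile: float = 1.0
    max_filter_passes: int = 100

    def __post_init__(self) -> None:
        if not 0 < self.trim_fraction < 0.5:
            raise ValueError("trim_fraction must be in (0, 0.5)")


@dataclass
class BreakRegion:
    """A contiguous run of point indices identified as a break."""

    segment_id: str
    start_index: int
    end_index: int  # inclusive
    reason: str     # zero_speed | long_distance | long_duration | fast_after_pause | cluster

    def indices(self) -> range:
        return range(self.start_index, self.end_index + 1)


@dataclass
class FilterBounds:
    """Plausible-walking speed bounds estimated from known-walking segments."""

    max_median_speed: float
    max_min_speed: float
    max_upper_quartile_speed: float
    min_upper_whisker_speed: float
    # Pooled-speed trim thresholds; populated after a first filtering pass
    # so a re-run with the same bounds is idempotent.
    trim_speed_low: float | None = None
    trim_speed_high: float | None = None

    def __post_init__(self) -> None:
        if not (0 < self.max_min_speed <= self.max_median_speed
                <= self.max_upper_quartile_speed):
            raise ValueError("bounds must satisfy max_min <= max_median <= max_quartile")
        if self.min_upper_whisker_speed <= 0:
            raise ValueError("bounds must be positive")


@dataclass
class SectionRecord:
    """A merged run of consecutive GPS steps of at least 50 m — the modelling unit."""

    track_id: str
    source: str
    start_x: float
    start_y: float
    end_x: float
    end_y: float
    start_time: datetime
    duration: float          # s
    distance: float          # m, sum of constituent step distances
    speed: float             # km/h
    elevation: float = float("nan")          # m, duration-weighted
    walking_slope: float = float("nan")      # θ, degrees, signed
    hill_slope: float = float("nan")         # φ, degrees, unsigned
    obstruction_height: float = float("nan")  # m
    terrain: TerrainClass | None = None


@dataclass
class StepAnnotations:
    """Per-step terrain variables aligned with a segment's steps."""

    elevation: np.ndarray
    walking_slope: np.ndarray
    hill_slope: np.ndarray
    obstruction_height: np.ndarray
    road_class: list[str]  # per-step: paved_road | unpaved_road | off_road


Annotator = Callable[[TrackSegment, list[PointStep]], StepAnnotations]


# ---- Break likelihood and break finding --------------------------------


def break_likelihood(speed: float, s_median: float, turn_angle: float,
                     config: CleaningConfig = CleaningConfig()) -> float:
    """Score in [0, 1] for how break-like a point's kinematics are.

    Increases with the heading change at the point and decreases with
    speed relative to the segment median; a zero-speed point is a break
    by definition (likelihood 1). The score depends on speed only through
    the ratio to the segment median, so it is invariant to uniformly
    rescaling all speeds.
    """
    if speed == 0:
        return 1.0
    if s_median > 0:
        speed_term = max(0.0, 1.0 - speed / s_median)
    else:
        speed_term = 0.0
    angle_term = min(abs(turn_angle), 180.0) / 180.0
    score = (config.likelihood_speed_weight * speed_term
             + config.likelihood_angle_weight * angle_term)
    return min(1.0, max(0.0, score))


def _point_kinematics(steps: list[PointStep]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-point speed/distance/duration, attributing step i to point i+1."""
    n = len(steps) + 1
    speed = np.full(n, np.nan)
    dist = np.full(n, np.nan)
    dur = np.full(n, np.nan)
    for i, s in enumerate(steps):
        speed[i + 1] = s.speed
        dist[i + 1] = s.distance
        dur[i + 1] = s.duration
    return speed, dist, dur


def _point_likelihoods(steps: list[PointStep], s_median: float,
                       config: CleaningConfig) -> np.ndarray:
    n = len(steps) + 1
    lik = np.zeros(n)
    for i in range(1, n):
        if i >= 2:
            angle = turn_angle_degrees(steps[i - 2].bearing, steps[i - 1].bearing)
        else:
            angle = 0.0
        lik[i] = break_likelihood(steps[i - 1].speed, s_median, angle, config)
    return lik


def find_breaks(segment: TrackSegment,
                config: CleaningConfig = CleaningConfig()) -> list[BreakRegion]:
    """Identify break regions in a projected segment.

    Pointwise rules flag zero speed, steps over 1 km, gaps over 3 min and
    a >10 km/h step immediately after a >3 min pause. Cluster detection
    finds neighbourhoods whose maximum pairwise extent is within a factor
    of the median step distance, grows them by absorbing overlapping
    cluster neighbourhoods, trims low-likelihood ends, gap-fills to a
    contiguous run, and accepts the run as a break only if at least half
    its points look break-like and its steps include travel in opposite
    compass quadrants (Q1 & Q3 or Q2 & Q4) — the signature of stationary
    jitter rather than through-travel.
    """
    steps = compute_steps(segment)
    n = len(segment.points)
    pt_speed, pt_dist, pt_dur = _point_kinematics(steps)
    speeds = np.array([s.speed for s in steps])
    dists = np.array([s.distance for s in steps])
    s_median = float(np.median(speeds)) if len(speeds) else 0.0
    r_median = float(np.median(dists)) if len(dists) else 0.0
    lik = _point_likelihoods(steps, s_median, config)

    flagged: dict[int, str] = {}

    def flag(idx: int, reason: str) -> None:
        flagged.setdefault(idx, reason)

    for i in range(1, n):
        if pt_speed[i] == 0:
            flag(i, "zero_speed")
        elif pt_dist[i] > config.break_max_distance:
            flag(i, "long_distance")
        elif pt_dur[i] > config.break_max_duration:
            flag(i, "long_duration")
        if (i >= 2 and pt_speed[i] > config.speed_cap
                and pt_dur[i - 1] > config.break_max_duration):
            flag(i, "fast_after_pause")

    # Cluster rule: needs enough points for a neighbourhood.
    if n > config.cluster_window and r_median > 0:
        xy = np.array([(p.x, p.y) for p in segment.points])
        radius = config.cluster_radius_factor * r_median

        def neighbourhood(i: int) -> range:
            return range(max(0, i - config.cluster_window),
                         min(n, i + config.cluster_window + 1))

        def is_cluster(idxs: Iterable[int]) -> bool:
            pts = xy[list(idxs)]
            span_x = pts[:, 0].max() - pts[:, 0].min()
            span_y = pts[:, 1].max() - pts[:, 1].min()
            if math.hypot(span_x, span_y) <= radius:
                return True  # bounding-box diagonal bounds all pairwise distances
            if max(span_x, span_y) > radius:
                return False  # either span alone already exceeds the radius
            return float(pdist(pts).max()) <= radius

        visited: set[int] = set()
        for p in range(n):
            if p in visited:
                continue
            nbhd = neighbourhood(p)
            if not is_cluster(nbhd):
                continue
            cluster = set(nbhd)
            queue = list(nbhd)
            while queue:
                pc = queue.pop()
                if pc == p:
                    continue
                nb = neighbourhood(pc)
                if not set(nb) <= cluster and is_cluster(nb):
                    new = set(nb) - cluster
                    cluster |= new
                    queue.extend(new)
            visited |= cluster
            ordered = sorted(cluster)
            low = lik < config.low_likelihood_threshold
            while ordered and low[ordered[0]]:
                ordered.pop(0)
            while ordered and low[ordered[-1]]:
                ordered.pop()
            if not ordered:
                continue
            run = list(range(ordered[0], ordered[-1] + 1))  # gap-fill
            n_low = int(np.sum(low[run]))
            if n_low >= len(run) / 2:
                continue
            quadrants = {bearing_quadrant(steps[i].bearing)
                         for i in range(run[0], run[-1]) if 0 <= i < len(steps)}
            if not ({1, 3} <= quadrants or {2, 4} <= quadrants):
                continue
            for idx in run:
                flag(idx, "cluster")

    # Collapse flagged indices into maximal contiguous regions.
    regions: list[BreakRegion] = []
    for idx in sorted(flagged):
        if regions and idx == regions[-1].end_index + 1:
            regions[-1].end_index = idx
        else:
            regions.append(BreakRegion(segment.track_id, idx, idx, flagged[idx]))
    return regions


# ---- Annotation --------------------------------------------------------


def make_annotator(dtm: RasterGrid, dsm: RasterGrid | None,
                   roads: RoadNetwork,
                   cutoff: float = OBSTRUCTION_CUTOFF_M) -> Annotator:
    """Build a per-step terrain annotator from rasters and a road network.

    Each step is annotated at its endpoints (elevation, walking slope)
    and midpoint (hill slope, road class, obstruction). Points without
    raster coverage get NaN values rather than failing the pipeline.
    """

    def annotate(segment: TrackSegment, steps: list[PointStep]) -> StepAnnotations:
        m = len(steps)
        elev = np.full(m, np.nan)
        theta = np.full(m, np.nan)
        phi = np.full(m, np.nan)
        obstr = np.full(m, np.nan)
        road: list[str] = []
        for i, step in enumerate(steps):
            p0, p1 = segment.points[i], segment.points[i + 1]
            mx, my = (p0.x + p1.x) / 2.0, (p0.y + p1.y) / 2.0
            try:
                e0 = sample_elevation(dtm, p0.x, p0.y)
                e1 = sample_elevation(dtm, p1.x, p1.y)
                if not (dtm.is_nodata(e0) or dtm.is_nodata(e1)):
                    elev[i] = (e0 + e1) / 2.0
                    if step.distance > 0:
                        theta[i] = walking_slope(e0, e1, step.distance)
                    else:
                        theta[i] = 0.0
            except CoverageError:
                pass
            try:
                phi[i] = hill_slope_quadratic(dtm, mx, my)
            except CoverageError:
                pass
            cls = classify_road(mx, my, roads)
            road.append(cls)
            if cls == "off_road":
                _, height = obstruction_class(dsm, dtm, mx, my, cutoff=cutoff)
                obstr[i] = height
        return StepAnnotations(elevation=elev, walking_slope=theta,
                               hill_slope=phi, obstruction_height=obstr,
                               road_class=road)

    return annotate


# ---- Section merging ---------------------------------------------------


def _weighted_mean(values: np.ndarray, weights: np.ndarray) -> float:
    mask = np.isfinite(values) & (weights > 0)
    if not mask.any():
        return float("nan")
    return float(np.average(values[mask], weights=weights[mask]))


def _section_terrain(road_classes: Sequence[str], durations: np.ndarray,
                     obstruction: float,
                     cutoff: float = OBSTRUCTION_CUTOFF_M) -> TerrainClass | None:
    if not road_classes:
        return None
    weight: dict[str, float] = {}
    for cls, dur in zip(road_classes, durations):
        weight[cls] = weight.get(cls, 0.0) + float(dur)
    majority = max(weight.items(), key=lambda kv: (kv[1], kv[0]))[0]
    if majority == "paved_road":
        return TerrainClass.PAVED_ROAD
    if majority == "unpaved_road":
        return TerrainClass.UNPAVED_ROAD
    if math.isnan(obstruction):
        return TerrainClass.OFFROAD_UNKNOWN
    if obstruction > cutoff:
        return TerrainClass.OFFROAD_HEAVY
    return TerrainClass.OFFROAD_LIGHT


def _merge_run(segment: TrackSegment, steps: list[PointStep],
               step_indices: list[int], min_length: float,
               annotations: StepAnnotations | None) -> list[SectionRecord]:
    """Greedy forward merge of one contiguous run of steps into sections."""
    groups: list[list[int]] = []
    chunk: list[int] = []
    chunk_dist = 0.0
    for idx in step_indices:
        chunk.append(idx)
        chunk_dist += steps[idx].distance
        if chunk_dist >= min_length:
            groups.append(chunk)
            chunk, chunk_dist = [], 0.0
    if chunk:
        if groups:
            groups[-1] = groups[-1] + chunk  # fold short remainder backwards
        else:
            logger.info("run in %s shorter than %.0f m; no section emitted",
                        segment.track_id, min_length)

    sections: list[SectionRecord] = []
    for indices in groups:
        i0, i1 = indices[0], indices[-1] + 1
        dur = np.array([steps[i].duration for i in indices])
        dist = np.array([steps[i].distance for i in indices])
        total_dist = float(dist.sum())
        total_dur = float(dur.sum())
        speed = 3.6 * total_dist / total_dur if total_dur > 0 else 0.0
        rec = SectionRecord(
            track_id=segment.track_id,
            source=segment.source,
            start_x=segment.points[i0].x, start_y=segment.points[i0].y,
            end_x=segment.points[i1].x, end_y=segment.points[i1].y,
            start_time=segment.points[i0].timestamp,
            duration=total_dur, distance=total_dist, speed=speed,
        )
        if annotations is not None:
            rec.elevation = _weighted_mean(annotations.elevation[indices], dur)
            rec.walking_slope = _weighted_mean(annotations.walking_slope[indices], dur)
            rec.hill_slope = _weighted_mean(annotations.hill_slope[indices], dur)
            rec.obstruction_height = _weighted_mean(
                annotations.obstruction_height[indices], dur)
            rec.terrain = _section_terrain(
                [annotations.road_class[i] for i in indices], dur,
                rec.obstruction_height)
        sections.append(rec)
    return sections


def merge_points(segment: TrackSegment, breaks: list[BreakRegion],
                 min_length: float = 50.0,
                 annotations: StepAnnotations | None = None,
                 removed_points: set[int] | None = None,
                 ) -> list[list[SectionRecord]]:
    """Merge non-break steps into sections of at least ``min_length`` metres.

    Returns one list of sections per contiguous run of surviving steps
    (runs are separated by excised break points, which matters for edge
    trimming downstream). Distance and duration are sums over constituent
    steps; slope, elevation and obstruction values are duration-weighted
    means; a trailing remainder shorter than ``min_length`` is folded
    into the preceding section.
    """
    steps = compute_steps(segment)
    if removed_points is None:
        removed_points = set()
        for region in breaks:
            removed_points |= set(region.indices())
    runs: list[list[int]] = []
    current: list[int] = []
    for i in range(len(steps)):
        # step i connects points i and i+1; it dies with either endpoint
        if i in removed_points or (i + 1) in removed_points:
            if current:
                runs.append(current)
                current = []
        else:
            current.append(i)
    if current:
        runs.append(current)
    return [secs for run in runs
            if (secs := _merge_run(segment, steps, run, min_length, annotations))]


# ---- Filtering bounds --------------------------------------------------


def segment_speed_summary(speeds: np.ndarray) -> dict[str, float]:
    """Box-plot style summary of a segment's point speeds."""
    speeds = np.asarray(speeds, dtype=float)
    q1, q2, q3 = np.percentile(speeds, [25, 50, 75])
    return {
        "median": float(q2),
        "minimum": float(speeds.min()),
        "upper_quartile": float(q3),
        "upper_whisker": float(q3 + 1.5 * (q3 - q1)),
    }


def estimate_filter_bounds(hikr_speed_arrays: Sequence[np.ndarray],
                           config: CleaningConfig = CleaningConfig(),
                           min_segments: int = 30) -> FilterBounds:
    """Estimate plausible-walking bounds from known-walking segments.

    Each bound is an empirical percentile of the per-segment summary
    distribution: the 99th percentile of medians, minima and upper
    quartiles (upper bounds) and the 1st percentile of upper whiskers
    (a lower bound — a walking segment should show *some* spread of
    speeds up to its whisker).
    """
    if len(hikr_speed_arrays) < min_segments:
        raise InsufficientDataError(
            f"need at least {min_segments} known-walking segments, "
            f"got {len(hikr_speed_arrays)}")
    summaries = [segment_speed_summary(s) for s in hikr_speed_arrays]
    medians = [s["median"] for s in summaries]
    minima = [s["minimum"] for s in summaries]
    quartiles = [s["upper_quartile"] for s in summaries]
    whiskers = [s["upper_whisker"] for s in summaries]
    return FilterBounds(
        max_median_speed=float(np.percentile(medians, config.bound_median_percentile)),
        max_min_speed=float(np.percentile(minima, config.bound_min_percentile)),
        max_upper_quartile_speed=float(
            np.percentile(quartiles, config.bound_quartile_percentile)),
        min_upper_whisker_speed=float(
            np.percentile(whiskers, config.bound_whisker_percentile)),
    )


# ---- Full filtering pipeline -------------------------------------------


@dataclass
class FilterOutcome:
    sections: list[SectionRecord]
    audit: list[dict]
    bounds_used: FilterBounds


def _edge_trim(runs: list[list[SectionRecord]], cap: float,
               audit: list[dict], track_id: str) -> bool:
    """Recursively drop >cap sections at run edges. Returns True if changed."""
    changed = False
    for run in runs:
        while run and run[0].speed > cap:
            audit.append({"rule": "edge_speed", "track": track_id,
                          "speed": run[0].speed})
            run.pop(0)
            changed = True
        while run and run[-1].speed > cap:
            audit.append({"rule": "edge_speed", "track": track_id,
                          "speed": run[-1].speed})
            run.pop()
            changed = True
    runs[:] = [r for r in runs if r]
    return changed


def _segment_bound_check(sections: list[SectionRecord], bounds: FilterBounds,
                         config: CleaningConfig) -> str | None:
    speeds = np.array([s.speed for s in sections])
    if len(speeds) == 0:
        return None
    q3 = float(np.percentile(speeds, 75))
    q1 = float(np.percentile(speeds, 25))
    if float(np.median(speeds)) > bounds.max_median_speed:
        return "median_speed_bound"
    if float(speeds.min()) > bounds.max_min_speed:
        return "min_speed_bound"
    if q3 > bounds.max_upper_quartile_speed:
        return "upper_quartile_bound"
    if q3 + 1.5 * (q3 - q1) < bounds.min_upper_whisker_speed:
        return "upper_whisker_bound"
    total_duration = sum(s.duration for s in sections)
    if total_duration < config.min_segment_duration:
        return "short_duration"
    return None


def filter_tracks(segments: list[TrackSegment],
                  bounds: FilterBounds | None = None,
                  config: CleaningConfig = CleaningConfig(),
                  annotator: Annotator | None = None) -> FilterOutcome:
    """Run the full cleaning pipeline over projected segments.

    Stages, in order: deduplicate; drop segments with median point speed
    over the cap; find breaks and excise those longer than 30 s or
    containing over-cap speeds / over-limit steps; merge surviving steps
    into ≥50 m sections; recursively trim over-cap sections at run edges;
    then the source-specific branch — known-walking segments are dropped
    if their mean speed exceeds the cap, uncurated segments are screened
    against the estimated bounds (key-point rules plus an iterated
    bound/edge-trim loop); finally all sections are pooled and the
    fastest and slowest ``trim_fraction`` are removed.

    When ``bounds`` already carries trim thresholds the pooled trim uses
    them directly, which makes re-filtering a previous output a no-op.
    Every removal is recorded in the audit log.
    """
    audit: list[dict] = []
    deduped = deduplicate_segments(segments)
    if len(deduped) < len(segments):
        audit.append({"rule": "duplicate_segment",
                      "removed": len(segments) - len(deduped)})

    all_sections: list[SectionRecord] = []
    for segment in deduped:
        steps = compute_steps(segment)
        if not steps:
            continue
        speeds = np.array([s.speed for s in steps])
        if float(np.median(speeds)) > config.speed_cap:
            audit.append({"rule": "segment_median_speed", "track": segment.track_id,
                          "median": float(np.median(speeds))})
            continue
        breaks = find_breaks(segment, config)
        pt_speed, pt_dist, pt_dur = _point_kinematics(steps)
        removed_points: set[int] = set()
        for region in breaks:
            idx = list(region.indices())
            duration = float(np.nansum(pt_dur[idx]))
            over_speed = bool(np.any(pt_speed[idx] > config.speed_cap))
            over_dist = bool(np.any(pt_dist[idx] > config.break_max_distance))
            if duration > config.short_break_keep or over_speed or over_dist:
                removed_points |= set(idx)
                audit.append({"rule": "break_excised", "track": segment.track_id,
                              "reason": region.reason,
                              "start": region.start_index,
                              "end": region.end_index,
                              "duration": duration})
        annotations = annotator(segment, steps) if annotator else None
        runs = merge_points(segment, breaks, config.min_section_length,
                            annotations=annotations,
                            removed_points=removed_points)
        _edge_trim(runs, config.speed_cap, audit, segment.track_id)
        if not runs:
            continue

        if segment.source == "hikr":
            total_dist = sum(s.distance for run in runs for s in run)
            total_dur = sum(s.duration for run in runs for s in run)
            mean_speed = 3.6 * total_dist / total_dur if total_dur > 0 else 0.0
            if mean_speed > config.speed_cap:
                audit.append({"rule": "segment_mean_speed",
                              "track": segment.track_id, "mean": mean_speed})
                continue
            for run in runs:
                all_sections.extend(run)
            continue

        # Uncurated (osm) branch: requires bounds from the walking corpus.
        if bounds is None:
            raise ValueError("filtering uncurated segments requires FilterBounds")
        new_runs: list[list[SectionRecord]] = []
        for run in runs:
            is_key = [s.speed <= bounds.max_median_speed for s in run]
            keep = np.ones(len(run), dtype=bool)
            # Drop single non-key sections sandwiched between key sections.
            for i in range(1, len(run) - 1):
                if not is_key[i] and is_key[i - 1] and is_key[i + 1]:
                    keep[i] = False
                    audit.append({"rule": "single_between_key_points",
                                  "track": segment.track_id, "speed": run[i].speed})
            # Drop non-key runs between consecutive key points whose median
            # speed exceeds the bound.
            i = 0
            while i < len(run):
                if is_key[i] or not keep[i]:
                    i += 1
                    continue
                j = i
                while j < len(run) and not is_key[j]:
                    j += 1
                chunk = [run[k].speed for k in range(i, j) if keep[k]]
                if chunk and float(np.median(chunk)) > bounds.max_median_speed:
                    keep[i:j] = False
                    audit.append({"rule": "fast_run_between_key_points",
                                  "track": segment.track_id, "n": j - i})
                i = j
            # Splitting at removals creates new runs.
            piece: list[SectionRecord] = []
            for k, s in enumerate(run):
                if keep[k]:
                    piece.append(s)
                elif piece:
                    new_runs.append(piece)
                    piece = []
            if piece:
                new_runs.append(piece)
        runs = new_runs
        dropped = False
        for _ in range(config.max_filter_passes):
            changed = _edge_trim(runs, config.speed_cap, audit, segment.track_id)
            flat = [s for run in runs for s in run]
            if not flat:
                dropped = True
                break
            verdict = _segment_bound_check(flat, bounds, config)
            if verdict is not None:
                audit.append({"rule": verdict, "track": segment.track_id})
                dropped = True
                break
            if not changed:
                break
        else:
            logger.warning("filter loop hit pass limit for %s", segment.track_id)
        if not dropped:
            for run in runs:
                all_sections.extend(run)

    # Pooled trim of the fastest and slowest tails.
    if bounds is not None and bounds.trim_speed_low is not None:
        lo, hi = bounds.trim_speed_low, bounds.trim_speed_high
        kept = [s for s in all_sections if lo <= s.speed <= hi]
        audit.append({"rule": "speed_trim", "removed": len(all_sections) - len(kept),
                      "low": lo, "high": hi})
        bounds_used = bounds
    else:
        kept, lo, hi, n_trimmed = trim_sections(all_sections, config.trim_fraction)
        audit.append({"rule": "speed_trim", "removed": n_trimmed,
                      "low": lo, "high": hi})
        if bounds is not None:
            bounds_used = replace(bounds, trim_speed_low=lo, trim_speed_high=hi)
        else:
            bounds_used = FilterBounds(
                max_median_speed=config.speed_cap,
                max_min_speed=config.speed_cap,
                max_upper_quartile_speed=config.speed_cap,
                min_upper_whisker_speed=1e-9,
                trim_speed_low=lo, trim_speed_high=hi)
    return FilterOutcome(sections=kept, audit=audit, bounds_used=bounds_used)


def trim_sections(sections: list[SectionRecord], trim_fraction: float,
                  ) -> tuple[list[SectionRecord], float, float, int]:
    """Remove the fastest and slowest ``trim_fraction`` of sections by speed.

    Ties at the thresholds are broken by stable sort order. Returns the
    kept sections, the realised (low, high) speed thresholds and the
    number removed.
    """
    n = len(sections)
    k = int(trim_fraction * n)
    if n == 0 or k == 0:
        return list(sections), 0.0, math.inf, 0
    order = sorted(range(n), key=lambda i: sections[i].speed)
    drop = set(order[:k]) | set(order[n - k:])
    kept = [s for i, s in enumerate(sections) if i not in drop]
    lo = sections[order[k]].speed
    hi = sections[order[n - k - 1]].speed
    return kept, lo, hi, len(drop)


def sections_to_dataframe(sections: Sequence[SectionRecord]):
    """Sections as a tidy DataFrame (one row per section).

    Columns mirror the cleaned-datapoint schema: start/end coordinates,
    start time, duration, distance, speed, elevation, walking slope,
    hill slope, and the terrain classification expanded into on-road /
    paved / obstruction-known / heavy-obstruction flags.
    """
    import pandas as pd

    columns = ["track_id", "source", "start_x", "start_y", "end_x", "end_y",
               "start_time", "duration_s", "distance_m", "speed_kmh",
               "elevation_m", "walking_slope_deg", "hill_slope_deg",
               "obstruction_height_m", "terrain", "on_road", "paved",
               "obstruction_known", "heavy_obstruction"]
    if not sections:
        return pd.DataFrame(columns=columns)
    rows = []
    for s in sections:
        t = s.terrain
        rows.append({
            "track_id": s.track_id,
            "source": s.source,
            "start_x": s.start_x, "start_y": s.start_y,
            "end_x": s.end_x, "end_y": s.end_y,
            "start_time": s.start_time,
            "duration_s": s.duration,
            "distance_m": s.distance,
            "speed_kmh": s.speed,
            "elevation_m": s.elevation,
            "walking_slope_deg": s.walking_slope,
            "hill_slope_deg": s.hill_slope,
            "obstruction_height_m": s.obstruction_height,
            "terrain": t.value if t is not None else "",
            "on_road": (t is not None and not t.is_offroad) if t else False,
            "paved": t == TerrainClass.PAVED_ROAD if t else False,
            "obstruction_known": t in (TerrainClass.OFFROAD_LIGHT,
                                       TerrainClass.OFFROAD_HEAVY) if t else False,
            "heavy_obstruction": t == TerrainClass.OFFROAD_HEAVY if t else False,
        })
    return pd.DataFrame(rows)


def dataframe_to_sections(df) -> list[SectionRecord]:
    """Inverse of :func:`sections_to_dataframe` (terrain from the `terrain` column)."""
    out = []
    for row in df.itertuples(index=False):
        out.append(SectionRecord(
            track_id=row.track_id, source=row.source,
            start_x=row.start_x, start_y=row.start_y,
            end_x=row.end_x, end_y=row.end_y,
            start_time=row.start_time,
            duration=row.duration_s, distance=row.distance_m,
            speed=row.speed_kmh, elevation=row.elevation_m,
            walking_slope=row.walking_slope_deg,
            hill_slope=row.hill_slope_deg,
            obstruction_height=row.obstruction_height_m,
            terrain=TerrainClass(row.terrain) if row.terrain else None,
        ))
    return out


def refilter_sections(sections: list[SectionRecord], bounds: FilterBounds,
                      config: CleaningConfig = CleaningConfig()) -> list[SectionRecord]:
    """Re-apply the section-level filtering rules to an existing output.

    Used to verify idempotence: on the output of :func:`filter_tracks`
    with the same bounds (including the realised trim thresholds) this
    removes nothing.
    """
    kept: list[SectionRecord] = []
    by_track: dict[str, list[SectionRecord]] = {}
    for s in sections:
        by_track.setdefault(s.track_id, []).append(s)
    for track_sections in by_track.values():
        # note: the over-cap rule applies only at run edges during the full
        # pipeline, so surviving interior sections are not re-screened here
        if track_sections[0].source == "osm":
            if _segment_bound_check(track_sections, bounds, config) is not None:
                continue
        kept.extend(track_sections)
    if bounds.trim_speed_low is not None:
        kept = [s for s in kept
                if bounds.trim_speed_low <= s.speed <= bounds.trim_speed_high]
    return kept
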