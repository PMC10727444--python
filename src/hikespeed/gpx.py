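"""GPX 1.1 ingestion, per-point kinematics and segment deduplication."""

from __future__ import annotations

import logging
import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np

from .geometry import LocalProjection, bearing_degrees

logger = logging.getLogger(__name__)

GPX_NS = "http://www.topografix.com/GPX/1/1"


@dataclass
class TrackPoint:
    """A single GPS observation; projected coordinates are filled at ingest."""

    lat: float
    lon: float
    timestamp: datetime
    x: float = float("nan")
    y: float = float("nan")


@dataclass
class PointStep:
    """Kinematics of the step between two consecutive track points."""

    distance: float  # m, planimetric
    duration: float  # s
    speed: float     # km/h
    bearing: float   # degrees clockwise from north, [0, 360)


@dataclass
class TrackSegment:
    """Ordered GPS points from one <trkseg>, tagged with their source corpus.

    ``source`` distinguishes tracks known to be hikes ("hikr") from
    uncurated tracks ("osm"); the cleaning filter branches on it.
    """

    points: list[TrackPoint]
    source: str = "hikr"
    track_id: str = ""

    def __len__(self) -> int:
        return len(self.points)

    def project(self, projection: LocalProjection) -> None:
        lats = [p.lat for p in self.points]
        lons = [p.lon for p in self.points]
        xs, ys = projection.to_xy(lats, lons)
        for p, x, y in zip(self.points, xs, ys):
            p.x, p.y = float(x), float(y)


def _parse_time(text: str) -> datetime:
    ts = datetime.fromisoformat(text.replace("Z", "+00:00"))
    if ts.tzinfo is None:
        ts = ts.replace(tzinfo=timezone.utc)
    return ts.astimezone(timezone.utc)


def read_gpx(path: str | Path, source: str = "hikr") -> list[TrackSegment]:
    """Read a GPX 1.1 file into track segments, one per ``<trkseg>``.

    Segments containing any point without a timestamp are rejected (the
    cleaning pipeline is speed-based and cannot use them); the rejection
    is logged with the file and segment index.
    """
    tree = ET.parse(path)  # malformed XML raises ParseError
    root = tree.getroot()
    ns = {"gpx": GPX_NS}
    segments: list[TrackSegment] = []
    track_base = Path(path).stem
    seg_counter = 0
    for trk in root.findall("gpx:trk", ns):
        for trkseg in trk.findall("gpx:trkseg", ns):
            seg_counter += 1
            points: list[TrackPoint] = []
            rejected = False
            for trkpt in trkseg.findall("gpx:trkpt", ns):
                time_el = trkpt.find("gpx:time", ns)
                if time_el is None or not (time_el.text or "").strip():
                    rejected = True
                    break
                points.append(TrackPoint(
                    lat=float(trkpt.get("lat")),
                    lon=float(trkpt.get("lon")),
                    timestamp=_parse_time(time_el.text.strip()),
                ))
            if rejected:
                logger.warning("rejected segment %d of %s: points without timestamps",
                               seg_counter, path)
                continue
            if len(points) < 2:
                logger.warning("rejected segment %d of %s: fewer than 2 points",
                               seg_counter, path)
                continue
            segments.append(TrackSegment(
                points=points, source=source,
                track_id=f"{track_base}#{seg_counter}",
            ))
    return segments


def write_gpx(segments: list[TrackSegment], path: str | Path) -> None:
    """Write segments to a GPX 1.1 file (one <trk> per segment)."""
    ET.register_namespace("", GPX_NS)
    root = ET.Element(f"{{{GPX_NS}}}gpx", version="1.1", creator="hikespeed")
    for seg in segments:
        trk = ET.SubElement(root, f"{{{GPX_NS}}}trk")
        name = ET.SubElement(trk, f"{{{GPX_NS}}}name")
        name.text = seg.track_id or "track"
        trkseg = ET.SubElement(trk, f"{{{GPX_NS}}}trkseg")
        for p in seg.points:
            trkpt = ET.SubElement(trkseg, f"{{{GPX_NS}}}trkpt",
                                  lat=f"{p.lat:.7f}", lon=f"{p.lon:.7f}")
            t = ET.SubElement(trkpt, f"{{{GPX_NS}}}time")
            t.text = p.timestamp.strftime("%Y-%m-%dT%H:%M:%SZ")
    ET.ElementTree(root).write(path, encoding="unicode", xml_declaration=True)


def compute_steps(segment: TrackSegment) -> list[PointStep]:
    """Planimetric step kinematics between consecutive points (length n−1).

    Distance is the 2-D Euclidean distance between projected coordinates;
    speed is km/h (zero when the duration is zero). A negative duration
    means out-of-order timestamps and raises ``ValueError``.
    """
    steps: list[PointStep] = []
    for prev, curr in zip(segment.points, segment.points[1:]):
        if math.isnan(prev.x) or math.isnan(curr.x):
            raise ValueError("segment must be projected before computing steps")
        duration = (curr.timestamp - prev.timestamp).total_seconds()
        if duration < 0:
            raise ValueError("non-monotonic timestamps in segment")
        dx = curr.x - prev.x
        dy = curr.y - prev.y
        distance = math.hypot(dx, dy)
        speed = 3.6 * distance / duration if duration > 0 else 0.0
        steps.append(PointStep(distance=distance, duration=duration,
                               speed=speed, bearing=bearing_degrees(dx, dy)))
    return steps


def _dedupe_key(seg: TrackSegment) -> tuple:
    first, last = seg.points[0], seg.points[-1]
    duration = (last.timestamp - first.timestamp).total_seconds()
    return (
        round(first.lat, 6), round(first.lon, 6),
        round(last.lat, 6), round(last.lon, 6),
        first.timestamp.replace(microsecond=0),
        round(duration),
    )


def deduplicate_segments(segments: list[TrackSegment]) -> list[TrackSegment]:
    """Keep one representative per (start location, end location, start time, duration).

    Coordinates are compared at 1e-6 degrees and times at 1 s, so re-uploads
    of the same recording collapse while genuinely distinct segments survive.
    """
    seen: set[tuple] = set()
    kept: list[TrackSegment] = []
    for seg in segments:
        key = _dedupe_key(seg)
        if key not in seen:
            seen.add(key)
            kept.append(seg)
    return kept
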