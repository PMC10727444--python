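import math
from datetime import timedelta

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hikespeed.cleaning import (
    InsufficientDataError,
    SectionRecord,
    StepAnnotations,
    break_likelihood,
    estimate_filter_bounds,
    filter_tracks,
    find_breaks,
    merge_points,
    refilter_sections,
    sections_to_dataframe,
    trim_sections,
)
from hikespeed.gpx import compute_steps

from conftest import T0, make_segment


class TestBreakLikelihood:
    def test_zero_speed_is_certain_break(self):
        assert break_likelihood(0.0, 4.0, 0.0) == 1.0

    def test_median_speed_straight_ahead_is_low(self):
        assert break_likelihood(4.0, 4.0, 0.0) <= 0.5

    def test_monotone_in_angle_and_speed(self):
        base = break_likelihood(2.0, 4.0, 30.0)
        assert break_likelihood(2.0, 4.0, 90.0) > base       # sharper turn
        assert break_likelihood(1.0, 4.0, 30.0) > base       # slower
        assert break_likelihood(8.0, 4.0, 30.0) < base       # faster

    def test_invariant_to_uniform_speed_rescaling(self):
        a = break_likelihood(2.0, 4.0, 45.0)
        b = break_likelihood(20.0, 40.0, 45.0)
        assert a == pytest.approx(b)


class TestFindBreaks:
    def test_clean_walk_has_no_breaks(self, straight_walk_segment):
        assert find_breaks(straight_walk_segment) == []

    def test_planted_stationary_cluster_recovered(self):
        rng = np.random.default_rng(3)
        xy = [(i * 30.0, 0.0) for i in range(20)]
        centre = np.array([xy[-1][0] + 5.0, 0.0])
        planted = list(range(20, 40))  # 20 jittered points, 20 s apart
        for _ in planted:
            xy.append(tuple(centre + rng.normal(0, 4.0, size=2)))
        xy += [(centre[0] + 30.0 * (i + 1), 0.0) for i in range(20)]
        seg = make_segment(xy)
        regions = find_breaks(seg)
        assert len(regions) == 1
        flagged = set(regions[0].indices())
        recovered = len(flagged & set(planted)) / len(planted)
        assert recovered >= 0.8

    def test_single_long_step_flagged(self, straight_walk_segment):
        seg = straight_walk_segment
        # teleport one point 1.2 km east of its predecessor
        seg.points[30].x = seg.points[29].x + 1200.0
        regions = find_breaks(seg)
        assert any(r.reason == "long_distance" and 30 in r.indices()
                   for r in regions)

    def test_fast_step_after_long_pause_flagged(self):
        times = [T0, T0 + timedelta(seconds=20), T0 + timedelta(seconds=220),
                 T0 + timedelta(seconds=240)]
        xy = [(0.0, 0.0), (30.0, 0.0), (60.0, 0.0), (130.0, 0.0)]  # last: 12.6 km/h
        seg = make_segment(xy, times=times)
        regions = find_breaks(seg)
        flagged = set().union(*(set(r.indices()) for r in regions))
        assert {2, 3} <= flagged


class TestMergePoints:
    def test_short_steps_merge_to_one_section(self):
        seg = make_segment([(0.0, 0.0), (20.0, 0.0), (35.0, 0.0), (55.0, 0.0)])
        (run,) = merge_points(seg, breaks=[])
        (section,) = run
        assert section.distance == pytest.approx(55.0)
        assert section.duration == pytest.approx(60.0)
        assert section.speed == pytest.approx(3.6 * 55.0 / 60.0)

    def test_duration_weighted_slope_average(self):
        times = [T0 + timedelta(seconds=s) for s in (0, 18, 32, 52)]
        seg = make_segment([(0.0, 0.0), (20.0, 0.0), (35.0, 0.0), (55.0, 0.0)],
                           times=times)
        ann = StepAnnotations(
            elevation=np.full(3, np.nan),
            walking_slope=np.array([2.0, 4.0, 6.0]),
            hill_slope=np.full(3, np.nan),
            obstruction_height=np.full(3, np.nan),
            road_class=["off_road"] * 3,
        )
        (run,) = merge_points(seg, breaks=[], annotations=ann)
        (section,) = run
        assert section.walking_slope == pytest.approx(212.0 / 52.0, abs=1e-9)
        assert section.walking_slope == pytest.approx(4.077, abs=1e-3)

    def test_single_long_step_unchanged(self):
        seg = make_segment([(0.0, 0.0), (80.0, 0.0)])
        (run,) = merge_points(seg, breaks=[])
        (section,) = run
        assert section.distance == pytest.approx(80.0)
        assert section.duration == pytest.approx(20.0)

    def test_run_below_minimum_yields_nothing(self):
        seg = make_segment([(0.0, 0.0), (10.0, 0.0), (20.0, 0.0)])
        assert merge_points(seg, breaks=[]) == []

    @settings(max_examples=30, deadline=None)
    @given(dists=st.lists(st.floats(1.0, 100.0), min_size=2, max_size=40))
    def test_conservation_of_distance_and_duration(self, dists):
        xs = np.concatenate([[0.0], np.cumsum(dists)])
        seg = make_segment([(x, 0.0) for x in xs])
        runs = merge_points(seg, breaks=[], min_length=1.0)
        sections = [s for run in runs for s in run]
        assert sum(s.distance for s in sections) == pytest.approx(sum(dists), abs=1e-6)
        assert sum(s.duration for s in sections) == pytest.approx(20.0 * len(dists), abs=1e-6)


class TestFilterBounds:
    def test_degenerate_distribution(self):
        arrays = [np.full(50, 4.5) for _ in range(40)]
        bounds = estimate_filter_bounds(arrays)
        assert bounds.max_median_speed == pytest.approx(4.5)
        assert bounds.max_min_speed == pytest.approx(4.5)

    def test_too_few_segments(self):
        with pytest.raises(InsufficientDataError):
            estimate_filter_bounds([np.full(50, 4.5)] * 10)

    def test_monotone_under_adding_slower_segment(self):
        rng = np.random.default_rng(0)
        arrays = [rng.uniform(2, 7, size=60) for _ in range(40)]
        before = estimate_filter_bounds(arrays)
        after = estimate_filter_bounds(arrays + [np.full(60, 0.5)])
        assert after.max_median_speed <= before.max_median_speed
        assert after.max_min_speed <= before.max_min_speed
        assert after.max_upper_quartile_speed <= before.max_upper_quartile_speed
        assert after.min_upper_whisker_speed <= before.min_upper_whisker_speed

    def test_invariants_hold_on_simulated_input(self):
        rng = np.random.default_rng(7)
        arrays = [rng.lognormal(1.4, 0.3, size=80) for _ in range(60)]
        bounds = estimate_filter_bounds(arrays)  # constructor enforces ordering
        assert bounds.max_min_speed <= bounds.max_median_speed \
            <= bounds.max_upper_quartile_speed


def _walk_segment(n=80, speed_kmh=6.0, dt=20.0, track_id="walk", source="hikr"):
    step = speed_kmh * dt / 3.6
    return make_segment([(i * step, 0.0) for i in range(n)], dt=dt,
                        track_id=track_id, source=source)


class TestFilterTracks:
    def test_drive_segment_removed(self):
        walk = _walk_segment(track_id="walk")
        drive = _walk_segment(n=30, speed_kmh=60.0, track_id="drive")
        out = filter_tracks([walk, drive])
        assert out.sections
        assert {s.track_id for s in out.sections} == {"walk"}
        assert any(e["rule"] == "segment_median_speed" for e in out.audit)

    def test_short_planted_break_excised_walk_retained(self):
        # 45 s stationary pause: longer than the 30 s keep threshold
        dt = 15.0
        step = 6.0 * dt / 3.6  # 25 m
        xy = [(i * step, 0.0) for i in range(40)]
        pause_at = xy[-1]
        xy += [pause_at] * 3   # 45 s of zero movement
        xy += [(pause_at[0] + step * (i + 1), 0.0) for i in range(40)]
        seg = make_segment(xy, dt=dt, track_id="pausewalk")
        out = filter_tracks([seg])
        assert out.sections
        pause_start = T0 + timedelta(seconds=40 * dt)
        pause_end = T0 + timedelta(seconds=43 * dt)
        for s in out.sections:
            s_end = s.start_time + timedelta(seconds=s.duration)
            assert not (s.start_time < pause_end and pause_start < s_end), \
                "section overlaps the excised break"

    def test_pooled_trim_size(self):
        sections = [
            SectionRecord(track_id="t", source="hikr", start_x=0, start_y=0,
                          end_x=60, end_y=0, start_time=T0, duration=40.0,
                          distance=60.0, speed=2.0 + 6.0 * i / 999.0)
            for i in range(1000)
        ]
        kept, lo, hi, removed = trim_sections(sections, 0.005)
        assert removed == 10
        assert abs(len(kept) - math.ceil(0.99 * 1000)) <= 1
        speeds = [s.speed for s in kept]
        assert min(speeds) >= lo and max(speeds) <= hi

    def test_surviving_speeds_inside_trimmed_range(self, small_world):
        hikr = [s for s in small_world.segments if s.source == "hikr"]
        arrays = [np.array([step.speed for step in compute_steps(s)]) for s in hikr]
        bounds = estimate_filter_bounds(arrays, min_segments=len(arrays))
        out = filter_tracks(small_world.segments, bounds)
        used = out.bounds_used
        for s in out.sections:
            assert used.trim_speed_low <= s.speed <= used.trim_speed_high

    def test_idempotent_given_fixed_bounds(self, small_world):
        hikr = [s for s in small_world.segments if s.source == "hikr"]
        arrays = [np.array([step.speed for step in compute_steps(s)]) for s in hikr]
        bounds = estimate_filter_bounds(arrays, min_segments=len(arrays))
        out = filter_tracks(small_world.segments, bounds)
        again = refilter_sections(out.sections, out.bounds_used)
        assert len(again) == len(out.sections)

    def test_empty_input_is_valid(self):
        out = filter_tracks([])
        assert out.sections == []


def test_sections_dataframe_schema(small_world):
    hikr = [s for s in small_world.segments if s.source == "hikr"]
    arrays = [np.array([step.speed for step in compute_steps(s)]) for s in hikr]
    bounds = estimate_filter_bounds(arrays, min_segments=len(arrays))
    out = filter_tracks(small_world.segments, bounds)
    df = sections_to_dataframe(out.sections)
    assert len(df) == len(out.sections)
    assert {"speed_kmh", "walking_slope_deg", "hill_slope_deg", "terrain",
            "distance_m", "duration_s"} <= set(df.columns)
    # speed identity holds row-wise
    np.testing.assert_allclose(df["speed_kmh"],
                               3.6 * df["distance_m"] / df["duration_s"])
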