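"""Gaze pipeline: velocity, I-VT detection, merging, AOIs, aggregation.

The detector and merger are checked exhaustively against independent
brute-force oracles (a per-sample run-length scanner and a pairwise merge
fixed-point iterator).
"""

import math
import warnings

import numpy as np
import pandas as pd
import pytest

from efrp.gaze import (AOITrack, Fixation, Segment, angular_velocity,
                       aggregate_durations, assign_aoi, assign_segments,
                       cyclopean_gaze, detect_fixations, GazeError,
                       interpolate_aoi, merge_fixations, run_gaze_pipeline,
                       segment_session)


def _gaze_frame(ts, x, y, valid=None):
    n = len(ts)
    valid = np.ones(n, int) if valid is None else np.asarray(valid, int)
    return pd.DataFrame({
        "timestamp": ts, "left_x": x, "left_y": y,
        "right_x": x, "right_y": y,
        "left_valid": valid, "right_valid": valid,
    })


# ---------------------------------------------------------------------------
# Brute-force oracles (kept deliberately naive)

def brute_force_fixations(ts, xs, ys, velocity, threshold, min_duration):
    """Per-sample scanner: grow runs one sample at a time."""
    out = []
    run = []
    for i in range(len(ts)):
        sub = (np.isfinite(velocity[i]) and velocity[i] < threshold
               and np.isfinite(xs[i]))
        if sub:
            run.append(i)
        if not sub or i == len(ts) - 1:
            if run:
                dur = ts[run[-1]] - ts[run[0]]
                if dur >= min_duration:
                    out.append((ts[run[0]], dur,
                                float(np.mean([xs[j] for j in run])),
                                float(np.mean([ys[j] for j in run]))))
                run = []
    return out


def brute_force_merge(fixs, geometry, max_angle, max_gap, min_duration):
    """Repeatedly merge the first qualifying pair until none qualifies."""
    fixs = [Fixation(f.onset, f.duration, f.x, f.y) for f in fixs]
    changed = True
    while changed:
        changed = False
        for i in range(len(fixs) - 1):
            a, b = fixs[i], fixs[i + 1]
            gap = b.onset - (a.onset + a.duration)
            sep = geometry.pixels_to_degrees(b.x - a.x, b.y - a.y)
            if gap < max_gap and sep < max_angle:
                w = a.duration + b.duration or 1.0
                fixs[i] = Fixation(a.onset,
                                   b.onset + b.duration - a.onset,
                                   (a.x * a.duration + b.x * b.duration) / w,
                                   (a.y * a.duration + b.y * b.duration) / w)
                del fixs[i + 1]
                changed = True
                break
    return [f for f in fixs if f.duration >= min_duration]


# ---------------------------------------------------------------------------

class TestAngularVelocity:
    def test_constant_gaze_has_zero_velocity(self, geometry):
        ts = np.arange(120) / 120.0
        g = _gaze_frame(ts, np.full(120, 500.0), np.full(120, 400.0))
        v = angular_velocity(g, geometry)
        assert np.allclose(v, 0.0)

    def test_one_degree_step_at_120hz_is_120_deg_per_s(self, geometry):
        # construct the pixel offset that subtends exactly 1 degree
        dx_cm = geometry.viewing_distance * math.tan(math.radians(1.0))
        dx_px = dx_cm * geometry.px_per_cm_x
        g = _gaze_frame([0.0, 1 / 120.0], [500.0, 500.0 + dx_px],
                        [400.0, 400.0])
        v = angular_velocity(g, geometry)
        assert v[1] == pytest.approx(120.0, rel=1e-6)
        assert v[0] == v[1]  # first sample copies the second

    def test_single_valid_sample_raises(self, geometry):
        g = _gaze_frame([0.0, 1 / 120.0], [500.0, 500.0], [400.0, 400.0],
                        valid=[1, 0])
        with pytest.raises(GazeError):
            angular_velocity(g, geometry)

    def test_one_eye_fallback_matches_that_eye(self, geometry):
        ts = np.arange(10) / 120.0
        g = _gaze_frame(ts, np.full(10, 500.0), np.full(10, 400.0))
        g.loc[4, "left_valid"] = 0
        pos = cyclopean_gaze(g)
        assert pos[4, 0] == g.loc[4, "right_x"]


class TestDetector:
    def test_one_second_of_stillness_is_one_fixation(self, geometry):
        ts = np.arange(121) / 120.0
        g = _gaze_frame(ts, np.full(121, 500.0), np.full(121, 400.0))
        v = angular_velocity(g, geometry)
        fixs = detect_fixations(g, v)
        assert len(fixs) == 1
        assert fixs[0].duration == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("n_sub,kept", [(6, False), (13, True)])
    def test_minimum_duration_filter(self, geometry, n_sub, kept):
        # a ~40 ms sub-threshold run is discarded, a ~100 ms run is kept
        v = np.array([500.0] * 3 + [0.0] * n_sub + [500.0] * 3)
        n = len(v)
        ts = np.arange(n) / 120.0
        g = _gaze_frame(ts, np.full(n, 500.0), np.full(n, 400.0))
        fixs = detect_fixations(g, v)
        assert bool(fixs) is kept

    def test_matches_brute_force_on_random_inputs(self, geometry):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n = int(rng.integers(2, 40))
            ts = np.cumsum(rng.uniform(0.006, 0.012, n))
            xs = rng.uniform(0, 1024, n)
            ys = rng.uniform(0, 768, n)
            v = rng.choice([5.0, 20.0, 40.0, 200.0, np.nan], n)
            g = _gaze_frame(ts, xs, ys)
            got = detect_fixations(g, v)
            want = brute_force_fixations(ts, xs, ys, v, 30.0, 0.06)
            assert len(got) == len(want)
            for f, (o, d, x, y) in zip(got, want):
                assert f.onset == pytest.approx(o)
                assert f.duration == pytest.approx(d)
                assert f.x == pytest.approx(x)
                assert f.y == pytest.approx(y)


class TestMerge:
    def test_close_pair_merges(self, geometry):
        sep = geometry.degrees_to_pixels(0.3)
        fixs = [Fixation(0.0, 0.2, 500.0, 400.0),
                Fixation(0.25, 0.2, 500.0 + sep, 400.0)]
        out = merge_fixations(fixs, geometry)
        assert len(out) == 1
        assert out[0].onset == 0.0
        assert out[0].duration == pytest.approx(0.45)

    def test_single_fixation_unchanged(self, geometry):
        fixs = [Fixation(0.0, 0.3, 500.0, 400.0)]
        assert merge_fixations(fixs, geometry) == fixs

    def test_far_pair_not_merged(self, geometry):
        sep = geometry.degrees_to_pixels(2.0)
        fixs = [Fixation(0.0, 0.2, 500.0, 400.0),
                Fixation(0.25, 0.2, 500.0 + sep, 400.0)]
        assert len(merge_fixations(fixs, geometry)) == 2

    def test_chain_of_three_collapses_to_one(self, geometry):
        sep = geometry.degrees_to_pixels(0.2)
        fixs = [Fixation(0.2 * i, 0.15, 500.0 + sep * i, 400.0)
                for i in range(3)]
        out = merge_fixations(fixs, geometry)
        assert len(out) == 1

    def test_matches_brute_force_fixpoint_on_random_inputs(self, geometry):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            n = int(rng.integers(1, 8))
            onset = 0.0
            fixs = []
            for _ in range(n):
                onset += rng.uniform(0.0, 0.15)
                dur = rng.uniform(0.02, 0.4)
                fixs.append(Fixation(onset, dur,
                                     rng.uniform(480, 530),
                                     rng.uniform(380, 430)))
                onset += dur
            got = merge_fixations(list(fixs), geometry)
            want = brute_force_merge(fixs, geometry, 0.5, 0.075, 0.06)
            assert len(got) == len(want)
            for a, b in zip(got, want):
                assert a.onset == pytest.approx(b.onset)
                assert a.duration == pytest.approx(b.duration)
                assert a.x == pytest.approx(b.x)

    def test_merge_is_idempotent(self, geometry):
        rng = np.random.default_rng(9)
        onset, fixs = 0.0, []
        for _ in range(20):
            onset += rng.uniform(0.0, 0.1)
            dur = rng.uniform(0.06, 0.3)
            fixs.append(Fixation(onset, dur, rng.uniform(480, 540),
                                 rng.uniform(380, 440)))
            onset += dur
        once = merge_fixations(fixs, geometry)
        twice = merge_fixations(once, geometry)
        assert [(f.onset, f.duration) for f in once] == \
               [(f.onset, f.duration) for f in twice]


class TestAOI:
    def _track(self, **kw):
        return AOITrack("billboard", np.array([0.0, 1.0]),
                        np.array([[0.0, 0.0, 10.0, 10.0],
                                  [10.0, 10.0, 20.0, 20.0]]),
                        padding_cm=kw.get("padding_cm", 0.0))

    def test_keyframe_query_is_exact(self, geometry):
        box = interpolate_aoi(self._track(), 1.0, geometry)
        assert np.allclose(box, [10.0, 10.0, 20.0, 20.0])

    def test_linear_interpolation_midpoint(self, geometry):
        box = interpolate_aoi(self._track(), 0.5, geometry)
        assert np.allclose(box, [5.0, 5.0, 15.0, 15.0])

    def test_clamps_to_first_box_before_span(self, geometry):
        box = interpolate_aoi(self._track(), -5.0, geometry)
        assert np.allclose(box, [0.0, 0.0, 10.0, 10.0])

    def test_padding_converts_cm_to_pixels(self, geometry):
        tr = self._track(padding_cm=3.0)
        box = interpolate_aoi(tr, 1.0, geometry)
        assert box[2] == pytest.approx(20.0 + 3.0 * geometry.px_per_cm_x)

    def test_centroid_inside_padding_hits_speedometer(self, geometry):
        # 2 cm outside the unpadded box, padding 3 cm -> still a hit
        tr = AOITrack("speedometer", np.array([0.0, 10.0]),
                      np.tile([472.0, 685.0, 552.0, 735.0], (2, 1)))
        x_out = 552.0 + 2.0 * geometry.px_per_cm_x
        fix = Fixation(1.0, 0.3, x_out, 710.0)
        assert assign_aoi(fix, [tr], geometry) == "speedometer"

    def test_no_hit_yields_other(self, geometry):
        tr = self._track()
        fix = Fixation(0.5, 0.3, 900.0, 700.0)
        assert assign_aoi(fix, [tr], geometry) == "other"

    def test_precedence_sign_over_billboard(self, geometry):
        boxes = np.tile([100.0, 100.0, 200.0, 200.0], (2, 1))
        sign = AOITrack("speed_sign", np.array([0.0, 1.0]), boxes.copy(),
                        padding_cm=0.0)
        bb = AOITrack("billboard", np.array([0.0, 1.0]), boxes.copy(),
                      padding_cm=0.0)
        fix = Fixation(0.5, 0.3, 150.0, 150.0)
        assert assign_aoi(fix, [bb, sign], geometry) == "speed_sign"

    def test_inactive_track_does_not_capture(self, geometry):
        tr = self._track()
        fix = Fixation(5.0, 0.3, 5.0, 5.0)  # track span ends at t=1
        assert assign_aoi(fix, [tr], geometry) == "other"


class TestSegments:
    def _events(self, pass_times):
        return pd.DataFrame({
            "timestamp": pass_times,
            "kind": ["region_enter"] * len(pass_times),
            "region_index": np.arange(1, len(pass_times) + 1),
            "billboard_type": ["static"] * len(pass_times),
            "car_x": 0.0, "speed": 60.0, "accelerator": 0.5,
        })

    def test_full_synthetic_session_gives_one_window_per_region(
            self, small_session_gaze_only, small_layout):
        bundle, _, _ = small_session_gaze_only
        segs = segment_session(bundle.events, expected=small_layout.n_regions)
        assert len(segs) == small_layout.n_regions
        for a, b in zip(segs, segs[1:]):
            assert a.end <= b.start or b.start == a.end

    def test_windows_truncate_to_inter_pass_interval(self):
        segs = segment_session(self._events([10.0, 20.0]), expected=2)
        assert segs[1].start == 10.0
        assert segs[1].end - segs[1].start == pytest.approx(10.0)

    def test_no_events_warns_and_returns_empty(self):
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            segs = segment_session(pd.DataFrame(columns=["timestamp", "kind",
                                                         "region_index"]))
        assert segs == [] and caught

    def test_fewer_passes_than_expected_warns_with_count(self):
        with pytest.warns(UserWarning, match="found 2"):
            segment_session(self._events([20.0, 40.0]), expected=50)


class _TwoTypeLayout:
    def billboard_type_of(self, idx):
        return "dynamic" if idx % 2 == 0 else "static"


class TestAggregation:
    def test_no_fixations_gives_zero_totals(self):
        segs = [Segment(1, 0.0, 15.0), Segment(2, 15.0, 30.0)]
        _, totals = aggregate_durations([], segs, _TwoTypeLayout())
        assert (totals["seconds"] == 0).all()

    def test_additivity_within_segment(self):
        segs = [Segment(2, 0.0, 15.0)]
        fixs = [Fixation(1.0, 1.0, 0, 0, "billboard", 2),
                Fixation(5.0, 1.0, 0, 0, "billboard", 2)]
        _, totals = aggregate_durations(fixs, segs, _TwoTypeLayout())
        assert totals.loc[("dynamic", "billboard"), "seconds"] == \
            pytest.approx(2.0)

    def test_totals_invariant_to_splitting_a_fixation(self):
        segs = [Segment(1, 0.0, 15.0)]
        whole = [Fixation(2.0, 1.0, 0, 0, "speed_sign", 1)]
        split = [Fixation(2.0, 0.4, 0, 0, "speed_sign", 1),
                 Fixation(2.4, 0.6, 0, 0, "speed_sign", 1)]
        _, t1 = aggregate_durations(whole, segs, _TwoTypeLayout())
        _, t2 = aggregate_durations(split, segs, _TwoTypeLayout())
        assert np.allclose(t1["seconds"], t2["seconds"])

    def test_fixations_outside_segments_excluded(self):
        segs = [Segment(1, 10.0, 15.0)]
        fixs = [Fixation(2.0, 1.0, 0, 0, "billboard", None)]
        assign_segments(fixs, segs)
        _, totals = aggregate_durations(fixs, segs, _TwoTypeLayout())
        assert (totals["seconds"] == 0).all()


class TestGroundTruthRecovery:
    def test_detector_recovers_true_fixations_to_one_sample(
            self, small_session_gaze_only, geometry):
        bundle, truth, tracks = small_session_gaze_only
        fixs, _ = run_gaze_pipeline(bundle.gaze, tracks, bundle.events,
                                    geometry)
        det_onsets = np.array([f.onset for f in fixs])
        tol = 1.0 / 120.0 + 1e-9
        hits = 0
        for t0 in truth.fixations["onset"]:
            err = np.min(np.abs(det_onsets - t0)) if len(det_onsets) else np.inf
            hits += err <= tol
        assert hits / len(truth.fixations) >= 0.95

    def test_aggregate_matches_ground_truth_dwell(
            self, small_session_gaze_only, small_layout, geometry):
        bundle, truth, tracks = small_session_gaze_only
        fixs, segs = run_gaze_pipeline(bundle.gaze, tracks, bundle.events,
                                       geometry)
        _, totals = aggregate_durations(fixs, segs, small_layout)
        # ground-truth billboard dwell per type, within one sample period
        # per contributing fixation
        tf = truth.fixations
        segs_by_idx = {s.index: s for s in segs}
        for btype in ("static", "dynamic"):
            want, n_fix = 0.0, 0
            for row in tf[tf["aoi"] == "billboard"].itertuples(index=False):
                seg = segs_by_idx.get(row.region)
                if seg is not None and seg.start <= row.onset < seg.end \
                        and small_layout.billboard_type_of(row.region) == btype:
                    want += row.duration
                    n_fix += 1
            got = totals.loc[(btype, "billboard"), "seconds"]
            assert abs(got - want) <= (n_fix + 1) * (1 / 120.0) + 0.05
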