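"""Gaze pipeline: I-VT fixation detection, AOI assignment, aggregation.

The velocity-threshold (I-VT) detector classifies a gaze sample as part of
a fixation when the angular velocity of the cyclopean gaze point falls
below 30 deg/s.  Maximal sub-threshold runs become fixations; fixations
shorter than 60 ms are discarded; fixations closer than 0.5 degrees with an
inter-fixation gap under 75 ms are merged.  Areas of interest (speed sign,
billboard, speedometer) are keyframed bounding-box trajectories with
physical-unit padding; fixations are hit-tested at their onset time.  The
session is divided into 50 segments, each ending when the car passes a
billboard and spanning at most 15 s; dwell time per AOI is totalled per
segment and split by billboard type.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .session_io import ScreenGeometry

#: AOI padding in physical centimetres, applied on all four sides.
PADDING_CM = {"speedometer": 3.0, "billboard": 10.0, "speed_sign": 2.0}

AOI_PRECEDENCE = ("speed_sign", "speedometer", "billboard")
AOI_LABELS = ("speed_sign", "billboard", "speedometer", "other")

VELOCITY_THRESHOLD = 30.0   # deg/s
MIN_FIXATION_DURATION = 0.06  # s
MERGE_MAX_ANGLE = 0.5       # deg
MERGE_MAX_GAP = 0.075       # s
SEGMENT_LENGTH = 15.0       # s


class GazeError(ValueError):
    """Raised when gaze input cannot support the requested computation."""


@dataclass
class Fixation:
    """A detected fixation with centroid in screen pixels."""

    onset: float
    duration: float
    x: float
    y: float
    aoi: str | None = None
    segment_index: int | None = None

    @property
    def end(self) -> float:
        return self.onset + self.duration


def fixations_to_frame(fixations: list[Fixation]) -> pd.DataFrame:
    return pd.DataFrame(
        [(f.onset, f.duration, f.x, f.y,
          f.aoi if f.aoi is not None else "",
          f.segment_index if f.segment_index is not None else -1)
         for f in fixations],
        columns=["onset", "duration", "x", "y", "aoi", "segment"],
    )


def frame_to_fixations(df: pd.DataFrame) -> list[Fixation]:
    out = []
    for row in df.itertuples(index=False):
        aoi = row.aoi if isinstance(row.aoi, str) and row.aoi else None
        seg = int(row.segment) if row.segment != -1 else None
        out.append(Fixation(row.onset, row.duration, row.x, row.y, aoi, seg))
    return out


# ---------------------------------------------------------------------------
# Velocity and detection

def cyclopean_gaze(gaze: pd.DataFrame) -> np.ndarray:
    """Cyclopean gaze: mean of valid eyes, single eye if one is invalid,
    NaN if both are invalid (NaN samples break fixation runs)."""
    lx = gaze["left_x"].to_numpy(float)
    ly = gaze["left_y"].to_numpy(float)
    rx = gaze["right_x"].to_numpy(float)
    ry = gaze["right_y"].to_numpy(float)
    lv = gaze["left_valid"].to_numpy().astype(bool)
    rv = gaze["right_valid"].to_numpy().astype(bool)
    n = len(gaze)
    out = np.full((n, 2), np.nan)
    both = lv & rv
    out[both, 0] = 0.5 * (lx[both] + rx[both])
    out[both, 1] = 0.5 * (ly[both] + ry[both])
    lonly = lv & ~rv
    out[lonly, 0] = lx[lonly]
    out[lonly, 1] = ly[lonly]
    ronly = rv & ~lv
    out[ronly, 0] = rx[ronly]
    out[ronly, 1] = ry[ronly]
    return out


def angular_velocity(gaze: pd.DataFrame, geometry: ScreenGeometry,
                     smooth_window: int | None = None) -> np.ndarray:
    """Per-sample angular velocity of the cyclopean gaze in deg/s.

    Two-point backward difference: ``v[i]`` is the visual angle between
    samples ``i-1`` and ``i`` divided by their time difference; ``v[0]``
    copies ``v[1]``.  Samples with both eyes invalid yield NaN velocities
    on the steps they touch.  ``smooth_window`` applies an optional
    centred moving average (odd number of samples).
    """
    pos = cyclopean_gaze(gaze)
    if np.isfinite(pos[:, 0]).sum() < 2:
        raise GazeError("angular velocity requires at least 2 valid samples")
    ts = gaze["timestamp"].to_numpy(float)
    dx_cm = np.diff(pos[:, 0]) / geometry.px_per_cm_x
    dy_cm = np.diff(pos[:, 1]) / geometry.px_per_cm_y
    ang = np.degrees(np.arctan2(np.hypot(dx_cm, dy_cm),
                                geometry.viewing_distance))
    v = np.empty(len(ts))
    v[1:] = ang / np.diff(ts)
    v[0] = v[1]
    if smooth_window and smooth_window > 1:
        k = int(smooth_window) | 1
        kernel = np.ones(k) / k
        finite = np.isfinite(v)
        vv = np.where(finite, v, 0.0)
        sm = np.convolve(vv, kernel, "same")
        norm = np.convolve(finite.astype(float), kernel, "same")
        with np.errstate(invalid="ignore"):
            v = np.where(norm > 0, sm / np.maximum(norm, 1e-12), np.nan)
        v[~finite] = np.nan
    return v


def detect_fixations(gaze: pd.DataFrame, velocity: np.ndarray,
                     threshold: float = VELOCITY_THRESHOLD,
                     min_duration: float = MIN_FIXATION_DURATION,
                     ) -> list[Fixation]:
    """Maximal runs of sub-threshold velocity samples become fixations.

    A run's onset is its first sample's timestamp and its duration the
    first-to-last timestamp span; runs shorter than ``min_duration`` are
    discarded.  The centroid is the mean cyclopean position of the member
    samples.  NaN velocities (invalid samples) break runs.
    """
    ts = gaze["timestamp"].to_numpy(float)
    pos = cyclopean_gaze(gaze)
    with np.errstate(invalid="ignore"):
        mask = np.isfinite(velocity) & (velocity < threshold)
    mask &= np.isfinite(pos[:, 0])
    out: list[Fixation] = []
    if not mask.any():
        return out
    padded = np.concatenate(([False], mask, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0]  # exclusive
    for a, b in zip(starts, ends):
        dur = ts[b - 1] - ts[a]
        if dur >= min_duration:
            cx, cy = pos[a:b].mean(axis=0)
            out.append(Fixation(float(ts[a]), float(dur), float(cx), float(cy)))
    return out


def merge_fixations(fixations: list[Fixation], geometry: ScreenGeometry,
                    max_angle: float = MERGE_MAX_ANGLE,
                    max_gap: float = MERGE_MAX_GAP,
                    min_duration: float = MIN_FIXATION_DURATION,
                    ) -> list[Fixation]:
    """Merge nearby fixations, iterating to a fixed point.

    Adjacent fixations whose centroids are less than ``max_angle`` apart
    and whose inter-fixation gap is less than ``max_gap`` are merged: the
    merged onset is the earlier onset, the duration spans both fixations
    plus the gap, and the centroid is the duration-weighted mean.  Pairs
    are merged leftmost-first and iteration continues until no pair
    qualifies (the fixed point of repeated pairwise merging); the
    minimum-duration filter is re-applied afterwards.
    """
    fixs = sorted(fixations, key=lambda f: f.onset)
    i = 0
    while i < len(fixs) - 1:
        cur, nxt = fixs[i], fixs[i + 1]
        gap = nxt.onset - cur.end
        sep = geometry.pixels_to_degrees(nxt.x - cur.x, nxt.y - cur.y)
        if gap < max_gap and sep < max_angle:
            w1, w2 = cur.duration, nxt.duration
            tot = w1 + w2 if (w1 + w2) > 0 else 1.0
            fixs[i] = Fixation(
                onset=cur.onset,
                duration=nxt.end - cur.onset,
                x=(cur.x * w1 + nxt.x * w2) / tot,
                y=(cur.y * w1 + nxt.y * w2) / tot,
            )
            del fixs[i + 1]
            i = max(i - 1, 0)  # a merge can enable the preceding pair
        else:
            i += 1
    return [f for f in fixs if f.duration >= min_duration]


# ---------------------------------------------------------------------------
# AOI tracks

@dataclass
class AOITrack:
    """Keyframed, linearly interpolated bounding-box trajectory.

    ``times`` is strictly increasing; ``boxes`` holds one (left, top,
    right, bottom) pixel box per keyframe (unpadded).  ``padding_cm`` is
    converted to pixels through the screen geometry and added on all four
    sides at query time; the padded box is clamped to the screen.
    ``region_index`` ties a track to one road region (the speedometer
    track spans the whole session and has ``region_index=None``).
    """

    target: str
    times: np.ndarray
    boxes: np.ndarray
    padding_cm: float | None = None
    region_index: int | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.boxes = np.asarray(self.boxes, dtype=float)
        if self.boxes.ndim != 2 or self.boxes.shape[1] != 4:
            raise ValueError("boxes must be (n, 4)")
        if len(self.times) != len(self.boxes) or len(self.times) == 0:
            raise ValueError("need matching, non-empty keyframe arrays")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("keyframe timestamps must be strictly increasing")
        if self.padding_cm is None:
            self.padding_cm = PADDING_CM.get(self.target, 0.0)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.times[0]), float(self.times[-1])

    def active_at(self, t: float) -> bool:
        return self.times[0] <= t <= self.times[-1]


def interpolate_aoi(track: AOITrack, t: float, geometry: ScreenGeometry,
                    padded: bool = True) -> np.ndarray:
    """Padded, interpolated (left, top, right, bottom) box at time ``t``.

    Each edge is linearly interpolated between bracketing keyframes and
    clamped to the first/last keyframe box outside the span.  Padding is
    ``padding_cm`` converted to pixels per axis; the result is clamped to
    the screen.
    """
    box = np.array([np.interp(t, track.times, track.boxes[:, k])
                    for k in range(4)])
    if padded and track.padding_cm:
        px = track.padding_cm * geometry.px_per_cm_x
        py = track.padding_cm * geometry.px_per_cm_y
        box = box + np.array([-px, -py, px, py])
    box[0] = np.clip(box[0], 0, geometry.pixel_width)
    box[2] = np.clip(box[2], 0, geometry.pixel_width)
    box[1] = np.clip(box[1], 0, geometry.pixel_height)
    box[3] = np.clip(box[3], 0, geometry.pixel_height)
    return box


def assign_aoi(fixation: Fixation, tracks: list[AOITrack],
               geometry: ScreenGeometry, t: float | None = None) -> str:
    """AOI label of a fixation, hit-tested at its onset time.

    Tracks are tested in fixed precedence order (speed sign, speedometer,
    billboard); only tracks whose keyframe span covers ``t`` participate.
    The label of the first track whose padded interpolated box contains the
    centroid is returned, else ``"other"``.
    """
    if t is None:
        t = fixation.onset
    for target in AOI_PRECEDENCE:
        for track in tracks:
            if track.target != target or not track.active_at(t):
                continue
            left, top, right, bottom = interpolate_aoi(track, t, geometry)
            if left <= fixation.x <= right and top <= fixation.y <= bottom:
                return target
    return "other"


def assign_aois(fixations: list[Fixation], tracks: list[AOITrack],
                geometry: ScreenGeometry) -> list[Fixation]:
    """Label every fixation in place (returns the same list)."""
    by_target: dict[str, list[AOITrack]] = {}
    for tr in tracks:
        by_target.setdefault(tr.target, []).append(tr)
    ordered = [tr for tgt in AOI_PRECEDENCE for tr in by_target.get(tgt, [])]
    for f in fixations:
        f.aoi = assign_aoi(f, ordered, geometry)
    return fixations


def save_aoi_tracks(tracks: list[AOITrack], path) -> None:
    """Write tracks as aoi_tracks.csv (unpadded boxes; padding at load)."""
    rows = []
    for tr in tracks:
        for t, box in zip(tr.times, tr.boxes):
            rows.append((tr.target,
                         tr.region_index if tr.region_index is not None else -1,
                         t, *box))
    pd.DataFrame(rows, columns=["target", "region_index", "timestamp",
                                "left", "top", "right", "bottom"]
                 ).to_csv(path, index=False)


def load_aoi_tracks(path) -> list[AOITrack]:
    df = pd.read_csv(path)
    tracks = []
    for (target, region), sub in df.groupby(["target", "region_index"],
                                            sort=False):
        sub = sub.sort_values("timestamp")
        tracks.append(AOITrack(
            target=str(target),
            times=sub["timestamp"].to_numpy(float),
            boxes=sub[["left", "top", "right", "bottom"]].to_numpy(float),
            region_index=None if region == -1 else int(region),
        ))
    return tracks


# ---------------------------------------------------------------------------
# Segmentation and aggregation

@dataclass
class Segment:
    """One analysis window, ending when the car passes billboard ``index``."""

    index: int
    start: float
    end: float


@dataclass
class SegmentSummary:
    segment_index: int
    billboard_type: str
    totals: dict = field(default_factory=dict)  # aoi label -> seconds


def segment_session(events: pd.DataFrame,
                    segment_length: float = SEGMENT_LENGTH,
                    expected: int | None = None) -> list[Segment]:
    """Non-overlapping windows ending at each billboard-pass time.

    Billboard passes are the ``region_enter`` events (the boundary at
    which the car drives past billboard ``region_index``).  Each window
    spans ``min(segment_length, time since the previous pass)``.  When
    ``expected`` is given (e.g. the 50 regions of the standard course), a
    shortfall triggers a warning with the observed count.
    """
    if len(events) == 0:
        warnings.warn("no events: produced 0 segments", stacklevel=2)
        return []
    passes = events[events["kind"] == "region_enter"].sort_values("timestamp")
    if expected is not None and len(passes) < expected:
        warnings.warn(f"expected {expected} billboard passes, found "
                      f"{len(passes)}", stacklevel=2)
    out: list[Segment] = []
    prev = -np.inf
    for row in passes.itertuples(index=False):
        t = float(row.timestamp)
        out.append(Segment(int(row.region_index),
                           max(t - segment_length, prev), t))
        prev = t
    return out


def assign_segments(fixations: list[Fixation],
                    segments: list[Segment]) -> list[Fixation]:
    """Attach segment indices by fixation onset (half-open windows)."""
    starts = np.array([s.start for s in segments])
    ends = np.array([s.end for s in segments])
    for f in fixations:
        hit = np.nonzero((starts <= f.onset) & (f.onset < ends))[0]
        f.segment_index = segments[hit[0]].index if hit.size else None
    return fixations


def aggregate_durations(fixations: list[Fixation], segments: list[Segment],
                        layout) -> tuple[list[SegmentSummary], pd.DataFrame]:
    """Total fixation seconds per AOI, per segment and by billboard type.

    ``layout`` is a :class:`efrp.synthetic.RoadLayout` (or anything with a
    ``billboard_type_of(region_index)`` method).  Fixations outside all
    segments are excluded.  Returns per-segment summaries and a totals
    table indexed by (billboard_type, aoi).
    """
    summaries = []
    totals = {(bt, aoi): 0.0 for bt in ("static", "dynamic")
              for aoi in AOI_LABELS}
    for seg in segments:
        btype = layout.billboard_type_of(seg.index)
        sums = dict.fromkeys(AOI_LABELS, 0.0)
        for f in fixations:
            if f.segment_index == seg.index:
                label = f.aoi if f.aoi in AOI_LABELS else "other"
                sums[label] += f.duration
        summaries.append(SegmentSummary(seg.index, btype, sums))
        for aoi in AOI_LABELS:
            totals[(btype, aoi)] += sums[aoi]
    tot = pd.DataFrame(
        [(bt, aoi, totals[(bt, aoi)]) for bt in ("static", "dynamic")
         for aoi in AOI_LABELS],
        columns=["billboard_type", "aoi", "seconds"],
    ).set_index(["billboard_type", "aoi"])
    return summaries, tot


def run_gaze_pipeline(gaze: pd.DataFrame, tracks: list[AOITrack],
                      events: pd.DataFrame, geometry: ScreenGeometry,
                      *, threshold: float = VELOCITY_THRESHOLD,
                      min_duration: float = MIN_FIXATION_DURATION,
                      merge_angle: float = MERGE_MAX_ANGLE,
                      merge_gap: float = MERGE_MAX_GAP,
                      segment_length: float = SEGMENT_LENGTH,
                      smooth_window: int | None = None,
                      ) -> tuple[list[Fixation], list[Segment]]:
    """Velocity -> detect -> merge -> AOI labels -> segment assignment."""
    v = angular_velocity(gaze, geometry, smooth_window=smooth_window)
    fixs = detect_fixations(gaze, v, threshold, min_duration)
    fixs = merge_fixations(fixs, geometry, merge_angle, merge_gap, min_duration)
    assign_aois(fixs, tracks, geometry)
    segments = segment_session(events, segment_length)
    assign_segments(fixs, segments)
    return fixs, segments
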