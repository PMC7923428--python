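"""Synthetic session generator with known ground truth.

Generates complete simulator sessions — road layout, car kinematics,
billboard events, a stochastic scanpath over the areas of interest, and
EEG assembled from fixation-locked ERP templates plus structured noise —
so that every downstream stage of the pipeline can be tested against
ground truth without access to participant recordings.

Layout and timing follow the simulated two-lane highway: 50 regions, each
with a speed sign / digital billboard pair, sign spacing tied to the
posted limit (300 m at 40 km/h, 400 m at 60, 500 m at 80), limits never
repeating consecutively, half the billboards static and half dynamic, and
dynamic billboards changing content when the car comes within 80 m.

The scanpath emulates the behaviour summarised by the study's dwell
statistics: on approaching each sign the driver fixates the sign, then the
speedometer (sometimes followed by a speed adjustment), then the
billboard; white-space fixations fill the remaining time.  Gaze is a
120 Hz binocular stream alternating sub-threshold fixation plateaus and
supra-threshold saccade ramps.  EEG is the sum of per-condition Gaussian
component templates locked to the condition-labelled fixation onsets, plus
pink noise, mains interference and blink artifacts.  Condition labels in
the ground truth are derived by applying the package's own event rules to
the true (noise-free) fixation list.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import events as ev_mod
from . import gaze as gaze_mod
from .session_io import (EEGRecording, MONTAGE, ScreenGeometry,
                         SessionBundle)

GAZE_RATE = 120.0
EEG_RATE = 512.0

SPACING_BY_LIMIT = {40: 300.0, 60: 400.0, 80: 500.0}
DEFAULT_SIGN_COUNTS = {40: 18, 60: 13, 80: 19}


class LayoutError(RuntimeError):
    """The requested sign counts cannot satisfy the layout constraints."""


@dataclass(frozen=True)
class Region:
    speed_limit: int          # km/h
    spacing_m: float          # distance from this sign/billboard pair to the next
    billboard_type: str       # "static" | "dynamic"


@dataclass
class RoadLayout:
    """Ordered road regions plus the billboard-change threshold distance."""

    regions: list[Region]
    change_distance: float = 80.0

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    def billboard_type_of(self, region_index: int) -> str:
        """Billboard type for a 1-based region index."""
        return self.regions[region_index - 1].billboard_type

    def billboard_positions(self) -> np.ndarray:
        """x-coordinate of each sign/billboard pair (metres from start)."""
        return np.cumsum([r.spacing_m for r in self.regions])

    def validate(self) -> None:
        limits = [r.speed_limit for r in self.regions]
        for i in range(1, len(limits)):
            if limits[i] == limits[i - 1]:
                raise LayoutError(f"equal consecutive limits at region {i + 1}")
        for r in self.regions:
            if SPACING_BY_LIMIT.get(r.speed_limit) != r.spacing_m:
                raise LayoutError(
                    f"spacing {r.spacing_m} inconsistent with limit "
                    f"{r.speed_limit}")


def generate_layout(seed: int, counts: dict[int, int] | None = None,
                    change_distance: float = 80.0,
                    max_tries: int = 500) -> RoadLayout:
    """Random layout satisfying all constraints; deterministic per seed.

    ``counts`` maps speed limit to number of signs (default 18/13/19 for
    40/60/80 km/h).  Raises :class:`LayoutError` when the counts force two
    equal consecutive limits (e.g. one limit holding more than half the
    regions).
    """
    rng = np.random.default_rng(seed)
    counts = dict(counts if counts is not None else DEFAULT_SIGN_COUNTS)
    total = sum(counts.values())
    if total <= 0:
        raise LayoutError("counts must sum to a positive number of regions")
    if max(counts.values()) > (total + 1) // 2:
        raise LayoutError("counts force two equal consecutive speed limits")

    limits: list[int] | None = None
    for _ in range(max_tries):
        remaining = dict(counts)
        seq: list[int] = []
        ok = True
        for _ in range(total):
            choices = [k for k, v in remaining.items()
                       if v > 0 and (not seq or k != seq[-1])]
            if not choices:
                ok = False
                break
            weights = np.array([remaining[k] for k in choices], dtype=float)
            pick = rng.choice(len(choices), p=weights / weights.sum())
            k = choices[pick]
            seq.append(k)
            remaining[k] -= 1
        if ok:
            limits = seq
            break
    if limits is None:
        raise LayoutError("could not place signs without equal consecutive "
                          f"limits in {max_tries} tries")

    n_dyn = total // 2
    types = ["static"] * (total - n_dyn) + ["dynamic"] * n_dyn
    rng.shuffle(types)
    regions = [Region(limit, SPACING_BY_LIMIT[limit], btype)
               for limit, btype in zip(limits, types)]
    layout = RoadLayout(regions, change_distance)
    layout.validate()
    return layout


# ---------------------------------------------------------------------------
# ERP templates and noise model

@dataclass(frozen=True)
class ComponentTemplate:
    """One Gaussian ERP bump: ``amplitude * exp(-(t-latency)^2/2w^2)``
    scaled per electrode by ``weights``."""

    name: str
    latency_ms: float
    amplitude_uv: float
    width_ms: float
    weights: dict[str, float]


_P1N1_WEIGHTS = {"PO1": 1.0, "PO2": 1.0, "P7": 0.5, "P8": 0.5, "Pz": 0.3}
_P2_WEIGHTS = {"Cz": 1.0, "Pz": 0.85, "P2": 0.7, "CP5": 0.25, "CP6": 0.25}
_N2_WEIGHTS = {"Cz": 1.0, "Pz": 0.3}


@dataclass
class ERPTemplateSet:
    """Per-condition lists of component templates."""

    by_condition: dict[str, list[ComponentTemplate]]

    @classmethod
    def default(cls) -> "ERPTemplateSet":
        def c(name, lat, amp, width, weights):
            return ComponentTemplate(name, lat, amp, width, dict(weights))
        return cls({
            "A": [c("P1", 75.0, 5.0, 10.0, _P1N1_WEIGHTS),
                  c("N1", 108.0, -4.0, 12.0, _P1N1_WEIGHTS),
                  c("P2", 185.0, 4.0, 14.0, _P2_WEIGHTS),
                  c("N2", 247.0, -4.5, 12.0, _N2_WEIGHTS)],
            "B": [c("P1", 78.0, 5.0, 10.0, _P1N1_WEIGHTS),
                  c("N1", 110.0, -4.2, 12.0, _P1N1_WEIGHTS),
                  c("P2", 188.0, 3.8, 14.0, _P2_WEIGHTS)],
            "C": [c("P1", 70.0, 5.2, 10.0, _P1N1_WEIGHTS),
                  c("N1", 104.0, -5.5, 12.0, _P1N1_WEIGHTS),
                  c("P2", 195.0, 5.0, 14.0, _P2_WEIGHTS)],
            "D": [c("P1", 72.0, 5.1, 10.0, _P1N1_WEIGHTS),
                  c("N1", 106.0, -5.0, 12.0, _P1N1_WEIGHTS),
                  c("P2", 192.0, 4.6, 14.0, _P2_WEIGHTS)],
        })

    def waveform(self, condition: str, electrode: str,
                 t_ms: np.ndarray) -> np.ndarray:
        """Noise-free composite template at one electrode (microvolts)."""
        out = np.zeros_like(np.asarray(t_ms, dtype=float))
        for c in self.by_condition.get(condition, []):
            w = c.weights.get(electrode, 0.0)
            if w:
                out = out + w * c.amplitude_uv * np.exp(
                    -0.5 * ((t_ms - c.latency_ms) / c.width_ms) ** 2)
        return out


#: Blink artifact spatial profile (frontal dominance).
BLINK_WEIGHTS = {
    "AF3": 1.0, "AF4": 1.0, "F7": 0.55, "F8": 0.55, "T7": 0.2, "T8": 0.2,
    "CP5": 0.1, "CP6": 0.1, "P7": 0.05, "P8": 0.05, "P1": 0.05, "PO1": 0.05,
    "PO2": 0.05, "P2": 0.05, "Cz": 0.15, "Pz": 0.1,
}


@dataclass(frozen=True)
class NoiseModel:
    """Additive EEG noise: pink background, mains hum, blink artifacts.

    ``pink_noise_scale`` is the per-sample standard deviation (microvolts)
    of the 1/f background before filtering; the 3 uV default represents
    the residual broadband background of a low-artifact recording in the
    0.16--30 Hz analysis band.  Blink lobes (default 200 uV, 300 ms) are
    frontally dominant and large enough for threshold rejection to catch
    any epoch they touch.
    """

    pink_noise_scale: float = 3.0
    line_noise_hz: float = 50.0
    line_noise_amplitude: float = 1.0
    blink_rate_per_min: float = 6.0
    blink_amplitude: float = 200.0
    blink_duration: float = 0.3

    def __post_init__(self) -> None:
        for name in ("pink_noise_scale", "line_noise_hz",
                     "line_noise_amplitude", "blink_rate_per_min",
                     "blink_amplitude", "blink_duration"):
            if getattr(self, name) < 0:
                raise ValueError(f"NoiseModel.{name} must be non-negative")

    @classmethod
    def silent(cls) -> "NoiseModel":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, 0.3)


# ---------------------------------------------------------------------------
# Scanpath parameters

@dataclass(frozen=True)
class DurationDist:
    """Clipped-normal dwell duration distribution (seconds)."""

    mean: float
    sd: float
    lo: float
    hi: float

    def draw(self, rng: np.random.Generator, hi_cap: float | None = None,
             ) -> float:
        hi = self.hi if hi_cap is None else min(self.hi, hi_cap)
        if hi < self.lo:
            return -1.0  # caller skips the fixation
        return float(np.clip(rng.normal(self.mean, self.sd), self.lo, hi))


@dataclass(frozen=True)
class ScanpathParams:
    """Tunables of the stochastic driver scanpath.

    Dwell distributions are free parameters of the generator, calibrated
    only in aggregate so that per-segment AOI dwell proportions resemble
    the study's summary table (long sign and speedometer dwell, shorter
    billboard engagement, longer on dynamic than static billboards).
    """

    p_adjust: float = 0.65            # probability of a speed adjustment
    p_second_sign: float = 0.8
    p_early_glance: float = 0.45      # billboard glance before the sign chain
    p_post_glance: float = 0.7        # second look after the C fixation
    p_extra_speedometer: float = 0.35  # speedometer glance with no sign context

    sign_dur: DurationDist = DurationDist(1.5, 0.4, 0.8, 2.4)
    sign2_dur: DurationDist = DurationDist(1.1, 0.3, 0.7, 1.8)
    speedo_dur: DurationDist = DurationDist(1.5, 0.3, 1.0, 1.9)
    c_dur: DurationDist = DurationDist(0.95, 0.2, 0.5, 1.3)
    post_dur: DurationDist = DurationDist(0.45, 0.1, 0.3, 0.7)
    d_dur: DurationDist = DurationDist(0.85, 0.18, 0.55, 1.3)
    glance_dur: DurationDist = DurationDist(0.32, 0.07, 0.22, 0.5)
    white_dur: DurationDist = DurationDist(0.42, 0.18, 0.12, 1.0)
    dynamic_dwell_factor: float = 1.0  # extra multiplier on dynamic-billboard dwell

    speedo_distance: float = 105.0    # m before billboard: speedometer onset
    adjust_distance: float = 95.0     # m before billboard: speed ramp start
    ramp_duration: float = 2.0        # s

    jitter_px: float = 1.5
    min_target_sep_deg: float = 1.0
    blink_guard_pre: float = 0.45     # s before a labelled onset kept blink-free
    blink_guard_post: float = 1.0     # s after a labelled onset kept blink-free
    stationary: bool = False          # degenerate mode: no saccades at all


# ---------------------------------------------------------------------------
# World model / projection

@dataclass(frozen=True)
class WorldModel:
    """Pinhole projection of roadside objects onto the centre monitor.

    Distances in metres; the focal length in pixels is
    ``viewing_distance * pixels_per_cm`` (rendering assumed matched to the
    physical viewing geometry).
    """

    horizon_y: float = 340.0
    eye_height: float = 1.2
    sign_lateral: float = -3.5
    sign_height: float = 2.2
    sign_half: float = 0.6
    bb_lateral: float = 6.0
    bb_height: float = 4.0
    bb_half_w: float = 2.0
    bb_half_h: float = 1.5
    speedo_box: tuple[float, float, float, float] = (472.0, 685.0, 552.0, 735.0)

    def focal_px(self, geometry: ScreenGeometry) -> float:
        return geometry.viewing_distance * 0.5 * (
            geometry.px_per_cm_x + geometry.px_per_cm_y)

    def project(self, d: np.ndarray, lateral: float, height: float,
                half_w: float, half_h: float,
                geometry: ScreenGeometry) -> np.ndarray:
        """(n, 4) screen boxes for an object at distances ``d``."""
        d = np.maximum(np.asarray(d, dtype=float), 1.0)
        f = self.focal_px(geometry)
        cx = geometry.pixel_width / 2 + f * lateral / d
        cy = self.horizon_y + f * (self.eye_height - height) / d
        hw = f * half_w / d
        hh = f * half_h / d
        box = np.stack([cx - hw, cy - hh, cx + hw, cy + hh], axis=-1)
        box[..., [0, 2]] = np.clip(box[..., [0, 2]], 0, geometry.pixel_width)
        box[..., [1, 3]] = np.clip(box[..., [1, 3]], 0, geometry.pixel_height)
        return box


# ---------------------------------------------------------------------------
# Car kinematics

@dataclass
class DrivePlan:
    """10 Hz kinematics of one run plus per-region event times."""

    t: np.ndarray        # s
    x: np.ndarray        # m
    v: np.ndarray        # km/h
    t_pass: np.ndarray       # per region (1-based index - 1)
    t_threshold: np.ndarray  # change-threshold crossing per region
    adjusted: np.ndarray     # bool per region: effective speed ramp

    def t_of_x(self, xq) -> np.ndarray:
        return np.interp(xq, self.x, self.t)


def simulate_drive(layout: RoadLayout, params: ScanpathParams,
                   rng: np.random.Generator, tail_s: float = 8.0) -> DrivePlan:
    """Piecewise-constant speed per region with 2 s linear adjustment ramps.

    The driver enters at the first region's limit.  In each region a speed
    adjustment towards the posted limit is made with probability
    ``p_adjust`` (and only when the difference is at least 2 km/h),
    starting ``adjust_distance`` metres before the billboard.
    """
    dt = 0.1
    xs = layout.billboard_positions()
    t_list = [0.0]
    x_list = [0.0]
    v_list = [float(layout.regions[0].speed_limit)]
    c = float(layout.regions[0].speed_limit)
    t_pass = np.empty(layout.n_regions)
    t_thresh = np.empty(layout.n_regions)
    adjusted = np.zeros(layout.n_regions, dtype=bool)

    t, x = 0.0, 0.0
    for r, region in enumerate(layout.regions):
        target = float(region.speed_limit)
        adjust = (rng.random() < params.p_adjust
                  and abs(target - c) >= 2.0)
        adjusted[r] = adjust
        ramp_x = xs[r] - params.adjust_distance
        t_ramp = None
        while x < xs[r]:
            if adjust and t_ramp is None and x >= ramp_x:
                t_ramp = t
            if t_ramp is not None:
                frac = min((t - t_ramp) / params.ramp_duration, 1.0)
                v = c + (target - c) * frac
            else:
                v = c
            x += v / 3.6 * dt
            t += dt
            t_list.append(t)
            x_list.append(x)
            v_list.append(v)
        if adjust:
            c = target
    for _ in range(int(tail_s / dt)):
        t += dt
        x += c / 3.6 * dt
        t_list.append(t)
        x_list.append(x)
        v_list.append(c)

    ta = np.array(t_list)
    xa = np.array(x_list)
    va = np.array(v_list)
    t_pass[:] = np.interp(xs, xa, ta)
    t_thresh[:] = np.interp(xs - layout.change_distance, xa, ta)
    return DrivePlan(ta, xa, va, t_pass, t_thresh, adjusted)


def build_events(layout: RoadLayout, plan: DrivePlan) -> pd.DataFrame:
    """Simulator event stream: threshold crossings, content changes and
    region boundaries (``region_enter`` marks driving past billboard
    ``region_index``)."""
    rows = []
    for r, region in enumerate(layout.regions):
        idx = r + 1
        for kind, tt in (("billboard_threshold", plan.t_threshold[r]),
                         ("region_enter", plan.t_pass[r])):
            v = float(np.interp(tt, plan.t, plan.v))
            xq = float(np.interp(tt, plan.t, plan.x))
            rows.append((tt, kind, idx, region.billboard_type, xq, v,
                         round(min(v / 90.0, 1.0), 3)))
        if region.billboard_type == "dynamic":
            tt = plan.t_threshold[r]
            v = float(np.interp(tt, plan.t, plan.v))
            xq = float(np.interp(tt, plan.t, plan.x))
            rows.append((tt, "billboard_change", idx, "dynamic", xq, v,
                         round(min(v / 90.0, 1.0), 3)))
    df = pd.DataFrame(rows, columns=["timestamp", "kind", "region_index",
                                     "billboard_type", "car_x", "speed",
                                     "accelerator"])
    return df.sort_values("timestamp", kind="stable").reset_index(drop=True)


def build_aoi_tracks(layout: RoadLayout, plan: DrivePlan,
                     geometry: ScreenGeometry, world: WorldModel,
                     keyframe_dt: float = 1.0 / 3.0,
                     far_distance: float = 230.0,
                     near_distance: float = 5.0) -> list[gaze_mod.AOITrack]:
    """Keyframed AOI tracks: one speedometer track spanning the session and
    one sign plus one billboard track per region (keyframes roughly every
    10 video frames while the target is in useful view)."""
    tracks: list[gaze_mod.AOITrack] = []
    t_end = plan.t[-1]
    tracks.append(gaze_mod.AOITrack(
        "speedometer", np.array([0.0, t_end]),
        np.tile(np.asarray(world.speedo_box, dtype=float), (2, 1))))
    xs = layout.billboard_positions()
    for r in range(layout.n_regions):
        t0 = float(plan.t_of_x(max(xs[r] - far_distance, 0.0)))
        t1 = float(plan.t_of_x(xs[r] - near_distance))
        times = np.arange(t0, t1, keyframe_dt)
        if len(times) < 2:
            times = np.array([t0, t1])
        d = xs[r] - np.interp(times, plan.t, plan.x)
        sign_boxes = world.project(d, world.sign_lateral, world.sign_height,
                                   world.sign_half, world.sign_half, geometry)
        bb_boxes = world.project(d, world.bb_lateral, world.bb_height,
                                 world.bb_half_w, world.bb_half_h, geometry)
        tracks.append(gaze_mod.AOITrack("speed_sign", times, sign_boxes,
                                        region_index=r + 1))
        tracks.append(gaze_mod.AOITrack("billboard", times, bb_boxes,
                                        region_index=r + 1))
    return tracks


# ---------------------------------------------------------------------------
# Scanpath generation

@dataclass
class _Anchor:
    onset: float
    duration: float
    aoi: str
    region: int
    track: gaze_mod.AOITrack | None  # None -> speedometer handled via track too
    labelled: bool                   # candidate condition event (blink guard)


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    fixations: pd.DataFrame          # onset,duration,x,y,aoi,region,condition
    condition_events: pd.DataFrame   # onset,label,segment,duration
    blink_times: list[float]
    layout: RoadLayout
    templates: ERPTemplateSet
    noise: NoiseModel
    params: ScanpathParams


def _schedule_anchors(layout: RoadLayout, plan: DrivePlan,
                      params: ScanpathParams, tracks: list[gaze_mod.AOITrack],
                      rng: np.random.Generator) -> list[_Anchor]:
    xs = layout.billboard_positions()
    sign_tracks = {tr.region_index: tr for tr in tracks
                   if tr.target == "speed_sign"}
    bb_tracks = {tr.region_index: tr for tr in tracks
                 if tr.target == "billboard"}
    speedo = next(tr for tr in tracks if tr.target == "speedometer")
    sacc = 4.0 / GAZE_RATE
    anchors: list[_Anchor] = []
    dyn_factor = params.dynamic_dwell_factor

    for r, region in enumerate(layout.regions):
        idx = r + 1
        dynamic = region.billboard_type == "dynamic"
        t_speedo = float(plan.t_of_x(xs[r] - params.speedo_distance)) \
            + rng.uniform(0.0, 0.1)
        speedo_dur = params.speedo_dur.draw(rng)
        anchors.append(_Anchor(t_speedo, speedo_dur, "speedometer", idx,
                               speedo, labelled=True))
        # sign chain, scheduled backwards from the speedometer onset
        t_cursor = t_speedo
        if rng.random() < params.p_second_sign:
            dur2 = params.sign2_dur.draw(rng)
            end2 = t_cursor - rng.uniform(0.25, 0.45) - 2 * sacc
            anchors.append(_Anchor(end2 - dur2, dur2, "speed_sign", idx,
                                   sign_tracks[idx], labelled=False))
            t_cursor = end2 - dur2
        dur1 = params.sign_dur.draw(rng)
        end1 = t_cursor - rng.uniform(0.3, 0.5) - 2 * sacc
        sign1_onset = end1 - dur1
        anchors.append(_Anchor(sign1_onset, dur1, "speed_sign", idx,
                               sign_tracks[idx], labelled=False))
        # early billboard glance before the sign chain (before any change)
        if rng.random() < params.p_early_glance:
            dur = params.glance_dur.draw(rng)
            if dynamic:
                dur *= dyn_factor
            end = sign1_onset - rng.uniform(0.3, 0.5) - 2 * sacc
            anchors.append(_Anchor(end - dur, dur, "billboard", idx,
                                   bb_tracks[idx], labelled=False))
        speedo_end = t_speedo + speedo_dur
        t_near = float(plan.t_of_x(xs[r] - 30.0))
        if dynamic:
            t_change = plan.t_threshold[r]
            c_onset = max(t_change + rng.uniform(0.5, 0.9),
                          speedo_end + 0.35)
            c_d = params.c_dur.draw(rng, hi_cap=t_near - c_onset) * dyn_factor
            if c_d > 0:
                anchors.append(_Anchor(c_onset, c_d, "billboard", idx,
                                       bb_tracks[idx], labelled=True))
                if rng.random() < params.p_post_glance:
                    p_onset = c_onset + c_d + rng.uniform(0.3, 0.45)
                    p_d = params.post_dur.draw(
                        rng, hi_cap=t_near + 0.4 - p_onset) * dyn_factor
                    if p_d > 0:
                        anchors.append(_Anchor(p_onset, p_d, "billboard",
                                               idx, bb_tracks[idx],
                                               labelled=False))
        else:
            d_onset = max(float(plan.t_of_x(xs[r] - 52.0)),
                          speedo_end + 0.35)
            d_d = params.d_dur.draw(rng, hi_cap=t_near - d_onset)
            if d_d > 0:
                anchors.append(_Anchor(d_onset, d_d, "billboard", idx,
                                       bb_tracks[idx], labelled=True))
        # occasional speedometer glance with no sign context, after the pass
        if rng.random() < params.p_extra_speedometer:
            g_onset = plan.t_pass[r] + rng.uniform(1.0, 2.2)
            if r + 1 < layout.n_regions:
                next_first = float(plan.t_of_x(xs[r + 1] - 230.0))
                cap = next_first - 0.6 - g_onset
            else:
                cap = plan.t[-1] - 1.0 - g_onset
            dur = min(rng.uniform(0.45, 0.8), cap)
            if dur > 0.3:
                anchors.append(_Anchor(g_onset, dur, "speedometer", idx,
                                       speedo, labelled=False))
    anchors.sort(key=lambda a: a.onset)
    return anchors


def _saccade_block(p: np.ndarray, q: np.ndarray, n: int,
                   geometry: ScreenGeometry,
                   rng: np.random.Generator) -> np.ndarray:
    """``n`` samples moving from ``p`` to ``q`` with every inter-sample
    step supra-threshold (>= ~45 deg/s at 120 Hz)."""
    if n <= 0:
        return np.empty((0, 2))
    step_px = geometry.degrees_to_pixels(45.0 / GAZE_RATE)  # min step length
    need = step_px * (n + 1)
    d = float(np.hypot(*(q - p)))
    if d >= need:
        fr = np.arange(1, n + 1) / (n + 1)
        return p + fr[:, None] * (q - p)
    # bow the path through a waypoint so each leg is long enough
    mid = 0.5 * (p + q)
    if d > 1e-9:
        perp = np.array([-(q - p)[1], (q - p)[0]]) / d
    else:
        perp = np.array([0.0, 1.0])
    h = math.sqrt(max((0.55 * need) ** 2 - (0.5 * d) ** 2, 1.0))
    w = mid + perp * h * (1 if rng.random() < 0.5 else -1)
    # clamp waypoint into the screen; legs remain >= h >= required length
    w[0] = np.clip(w[0], 5, geometry.pixel_width - 5)
    w[1] = np.clip(w[1], 5, geometry.pixel_height - 5)
    pts = []
    n1 = (n + 1) // 2
    n2 = n + 1 - n1
    for i in range(1, n1 + 1):
        pts.append(p + (w - p) * i / n1)
    for i in range(1, n2):
        pts.append(w + (q - w) * i / n2)
    return np.array(pts)


def _white_point(t: float, tracks: list[gaze_mod.AOITrack],
                 geometry: ScreenGeometry, rng: np.random.Generator,
                 prev: np.ndarray | None, min_sep_px: float) -> np.ndarray:
    """A white-space target: outside every active padded AOI box (over the
    whole prospective fixation span -- boxes sweep quickly near a pass)
    and at least ``min_sep_px`` from the previous target."""
    probe_times = (t, t + 0.45, t + 0.9)
    active = [tr for tr in tracks
              if any(tr.active_at(tq) for tq in probe_times)]
    for _ in range(60):
        pt = np.array([rng.uniform(170.0, 470.0), rng.uniform(410.0, 660.0)])
        if prev is not None and np.hypot(*(pt - prev)) < min_sep_px:
            continue
        inside = False
        for tr in active:
            for tq in probe_times:
                left, top, right, bottom = gaze_mod.interpolate_aoi(
                    tr, tq, geometry)
                if left <= pt[0] <= right and top <= pt[1] <= bottom:
                    inside = True
                    break
            if inside:
                break
        if not inside:
            return pt
    return np.array([200.0, 640.0])  # safe corner fallback


def generate_scanpath(layout: RoadLayout, params: ScanpathParams,
                      seed: int, geometry: ScreenGeometry | None = None,
                      world: WorldModel | None = None,
                      noise: NoiseModel | None = None,
                      ) -> tuple[pd.DataFrame, pd.DataFrame, list[float],
                                 list[gaze_mod.AOITrack], DrivePlan]:
    """Generate the 120 Hz binocular gaze stream and true fixation list.

    Returns ``(gaze, true_fixations, blink_times, aoi_tracks, drive_plan)``.
    ``true_fixations`` has columns onset/duration/x/y/aoi/region (condition
    labels are attached by :func:`generate_session` after applying the
    event rules).
    """
    geometry = geometry or ScreenGeometry()
    world = world or WorldModel()
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed)

    plan = simulate_drive(layout, params, rng)
    tracks = build_aoi_tracks(layout, plan, geometry, world)
    t_end = float(plan.t[-1])
    n_total = int(round(t_end * GAZE_RATE))
    ts = np.arange(n_total) / GAZE_RATE

    if params.stationary:
        centre = np.array([geometry.pixel_width / 2.0, 620.0])
        pos = np.tile(centre, (n_total, 1)) \
            + rng.normal(0.0, params.jitter_px, (n_total, 2))
        truth = pd.DataFrame([{
            "onset": ts[0], "duration": ts[-1] - ts[0],
            "x": centre[0], "y": centre[1], "aoi": "other", "region": -1,
        }])
        gaze = _binocular_frame(ts, pos, np.ones(n_total, bool), rng, geometry)
        return gaze, truth, [], tracks, plan

    anchors = _schedule_anchors(layout, plan, params, tracks, rng)

    # blink schedule (Poisson), kept clear of labelled onsets
    blink_len = int(round(noise.blink_duration * GAZE_RATE))
    guards = [(a.onset - params.blink_guard_pre - noise.blink_duration,
               a.onset + params.blink_guard_post) for a in anchors
              if a.labelled]
    blink_candidates = []
    if noise.blink_rate_per_min > 0:
        n_blinks = rng.poisson(noise.blink_rate_per_min * t_end / 60.0)
        for tb in np.sort(rng.uniform(2.0, t_end - 2.0, n_blinks)):
            if all(not (lo <= tb <= hi) for lo, hi in guards):
                blink_candidates.append(float(tb))

    min_sep_px = geometry.degrees_to_pixels(params.min_target_sep_deg)
    jit = params.jitter_px

    blocks: list[np.ndarray] = []
    valid_blocks: list[np.ndarray] = []
    truth_rows: list[dict] = []
    blink_times: list[float] = []
    blink_iter = iter(blink_candidates)
    next_blink = next(blink_iter, None)

    cursor = 0
    prev_pos = np.array([320.0, 560.0])

    def emit(samples: np.ndarray, valid: bool) -> None:
        nonlocal cursor, prev_pos
        blocks.append(samples)
        valid_blocks.append(np.full(len(samples), valid))
        cursor += len(samples)
        if valid and len(samples):
            prev_pos = samples[-1]

    def anchored_positions(anchor: _Anchor, a_idx: int, k: int) -> np.ndarray:
        tt = ts[a_idx:a_idx + k]
        tr = anchor.track
        box = np.stack([np.interp(tt, tr.times, tr.boxes[:, e])
                        for e in range(4)], axis=-1)
        cx = 0.5 * (box[:, 0] + box[:, 2])
        cy = 0.5 * (box[:, 1] + box[:, 3])
        hw = np.maximum(0.5 * (box[:, 2] - box[:, 0]), 1.0)
        hh = np.maximum(0.5 * (box[:, 3] - box[:, 1]), 1.0)
        fx = rng.uniform(-0.3, 0.3)
        fy = rng.uniform(-0.3, 0.3)
        out = np.stack([cx + fx * hw, cy + fy * hh], axis=-1)
        return out + rng.normal(0.0, jit, out.shape)

    def fill_white(hi_idx: int, t_ctx: float) -> None:
        """Fill [cursor, hi_idx) with white fixations / blinks / saccades."""
        nonlocal next_blink
        while cursor < hi_idx:
            avail = hi_idx - cursor
            if avail < 14:
                target = _white_point(ts[min(hi_idx, n_total - 1)], tracks,
                                      geometry, rng, prev_pos, min_sep_px)
                emit(_saccade_block(prev_pos, target, avail, geometry, rng),
                     True)
                continue
            if (next_blink is not None
                    and ts[cursor] >= next_blink - 0.2
                    and avail >= blink_len + 14):
                blink_times.append(ts[cursor])
                emit(np.full((blink_len, 2), np.nan), False)
                next_blink = next(blink_iter, None)
                continue
            n_s = int(rng.integers(3, 6))
            target = _white_point(ts[cursor], tracks, geometry, rng,
                                  prev_pos, min_sep_px)
            k = int(np.clip(round(params.white_dur.draw(rng) * GAZE_RATE),
                            10, avail - n_s))
            if avail - n_s - k < 14:
                k = avail - n_s
            emit(_saccade_block(prev_pos, target, n_s, geometry, rng), True)
            onset_i = cursor
            plateau = np.tile(target, (k, 1)) + rng.normal(0.0, jit, (k, 2))
            emit(plateau, True)
            truth_rows.append({"onset": ts[onset_i],
                               "duration": (k - 1) / GAZE_RATE,
                               "x": target[0], "y": target[1],
                               "aoi": "other", "region": -1})
        # skip any blink that this fill has passed over
        while next_blink is not None and next_blink < ts[min(cursor,
                                                             n_total - 1)]:
            next_blink = next(blink_iter, None)

    for anchor in anchors:
        n_s = int(rng.integers(3, 6))
        onset_idx = int(round(anchor.onset * GAZE_RATE))
        onset_idx = max(onset_idx, cursor + n_s + 1)
        k = int(round(anchor.duration * GAZE_RATE))
        if onset_idx + k >= n_total:
            break
        fill_white(onset_idx - n_s, anchor.onset)
        pos = anchored_positions(anchor, onset_idx, k)
        emit(_saccade_block(prev_pos, pos[0], n_s, geometry, rng), True)
        emit(pos, True)
        truth_rows.append({"onset": ts[onset_idx],
                           "duration": (k - 1) / GAZE_RATE,
                           "x": float(pos[:, 0].mean()),
                           "y": float(pos[:, 1].mean()),
                           "aoi": anchor.aoi, "region": anchor.region})
    fill_white(n_total, t_end)

    pos = np.concatenate(blocks)
    valid = np.concatenate(valid_blocks)
    assert len(pos) == n_total
    truth = pd.DataFrame(truth_rows).sort_values("onset").reset_index(drop=True)
    gaze = _binocular_frame(ts, pos, valid, rng, geometry)
    return gaze, truth, blink_times, tracks, plan


def _binocular_frame(ts: np.ndarray, pos: np.ndarray, valid: np.ndarray,
                     rng: np.random.Generator,
                     geometry: ScreenGeometry) -> pd.DataFrame:
    """Split a cyclopean trace into left/right eyes with vergence offset,
    per-eye sensor noise and sporadic single-eye dropouts."""
    n = len(ts)
    verg = np.array([1.0, 0.0])
    eye_noise = 0.5
    left = pos - verg + rng.normal(0.0, eye_noise, (n, 2))
    right = pos + verg + rng.normal(0.0, eye_noise, (n, 2))
    lv = valid & (rng.random(n) > 0.004)
    rv = valid & (rng.random(n) > 0.004)
    for arr in (left, right):
        np.clip(arr[:, 0], 0.0, geometry.pixel_width - 1e-3, out=arr[:, 0])
        np.clip(arr[:, 1], 0.0, geometry.pixel_height - 1e-3, out=arr[:, 1])
    left[~lv] = np.nan
    right[~rv] = np.nan
    return pd.DataFrame({
        "timestamp": ts,
        "left_x": left[:, 0], "left_y": left[:, 1],
        "right_x": right[:, 0], "right_y": right[:, 1],
        "left_valid": lv.astype(int), "right_valid": rv.astype(int),
    })


# ---------------------------------------------------------------------------
# EEG generation

def _pink_noise(n: int, fs: float, rng: np.random.Generator,
                f_floor: float = 0.5) -> np.ndarray:
    """Unit-variance noise with a 1/f power spectrum (flat below
    ``f_floor`` to keep the variance finite)."""
    from scipy import fft as sfft

    m = sfft.next_fast_len(n)
    white = rng.standard_normal(m)
    spec = sfft.rfft(white)
    f = sfft.rfftfreq(m, 1.0 / fs)
    shape = np.empty_like(f)
    shape[0] = 0.0
    shape[1:] = 1.0 / np.sqrt(np.maximum(f[1:], f_floor))
    x = sfft.irfft(spec * shape, m)[:n]
    sd = x.std()
    return x / sd if sd > 0 else x


def generate_eeg(condition_events: pd.DataFrame, duration: float,
                 templates: ERPTemplateSet, noise: NoiseModel, seed: int,
                 blink_times: list[float] | None = None,
                 sample_rate: float = EEG_RATE,
                 channel_names: tuple[str, ...] = MONTAGE,
                 epoch_tmax_ms: float = 800.0) -> EEGRecording:
    """EEG = condition templates locked to labelled fixation onsets + noise.

    ``condition_events`` needs ``onset`` and ``label`` columns.  A
    configuration warning is issued for template latencies beyond the
    epoch window.
    """
    rng = np.random.default_rng(seed)
    n = int(math.ceil(duration * sample_rate))
    data = np.zeros((len(channel_names), n))

    for comps in templates.by_condition.values():
        for c in comps:
            if c.latency_ms > epoch_tmax_ms:
                warnings.warn(
                    f"template {c.name} latency {c.latency_ms} ms beyond "
                    f"the {epoch_tmax_ms} ms epoch window", stacklevel=2)

    ch_index = {ch: i for i, ch in enumerate(channel_names)}
    for row in condition_events.itertuples(index=False):
        comps = templates.by_condition.get(row.label, [])
        for c in comps:
            half = 5.0 * c.width_ms / 1000.0
            centre = row.onset + c.latency_ms / 1000.0
            a = max(int(math.floor((centre - half) * sample_rate)), 0)
            b = min(int(math.ceil((centre + half) * sample_rate)), n)
            if b <= a:
                continue
            tt = np.arange(a, b) / sample_rate
            bump = c.amplitude_uv * np.exp(
                -0.5 * ((tt - centre) * 1000.0 / c.width_ms) ** 2)
            for ch, w in c.weights.items():
                if ch in ch_index:
                    data[ch_index[ch], a:b] += w * bump

    if noise.pink_noise_scale > 0:
        for i in range(len(channel_names)):
            data[i] += noise.pink_noise_scale * _pink_noise(n, sample_rate, rng)
    if noise.line_noise_amplitude > 0 and noise.line_noise_hz > 0:
        tt = np.arange(n) / sample_rate
        for i in range(len(channel_names)):
            phase = rng.uniform(0, 2 * np.pi)
            data[i] += noise.line_noise_amplitude * np.sin(
                2 * np.pi * noise.line_noise_hz * tt + phase)
    if blink_times and noise.blink_amplitude > 0:
        m = int(round(noise.blink_duration * sample_rate))
        lobe = np.sin(np.pi * np.arange(m) / m)
        for tb in blink_times:
            a = int(round(tb * sample_rate))
            b = min(a + m, n)
            if a >= n:
                continue
            for ch, w in BLINK_WEIGHTS.items():
                if ch in ch_index:
                    data[ch_index[ch], a:b] += \
                        noise.blink_amplitude * w * lobe[:b - a]
    return EEGRecording(sample_rate, list(channel_names), data, 0.0)


# ---------------------------------------------------------------------------
# Full session

def generate_session(seed: int, *, layout: RoadLayout | None = None,
                     params: ScanpathParams | None = None,
                     templates: ERPTemplateSet | None = None,
                     noise: NoiseModel | None = None,
                     geometry: ScreenGeometry | None = None,
                     world: WorldModel | None = None,
                     participant: str = "S01", primed: bool = False,
                     with_eeg: bool = True,
                     ) -> tuple[SessionBundle, GroundTruth,
                                list[gaze_mod.AOITrack]]:
    """Generate one full synchronized session with ground truth.

    Deterministic for a fixed seed.  The ground-truth condition labels are
    obtained by applying the package's own event rules to the true
    fixation list, the true speed trace and the true event stream, so they
    are consistent with the emitted streams by construction.
    """
    layout = layout or generate_layout(seed)
    params = params or ScanpathParams()
    templates = templates or ERPTemplateSet.default()
    noise = noise or NoiseModel()
    geometry = geometry or ScreenGeometry()
    world = world or WorldModel()

    gaze, truth, blink_times, tracks, plan = generate_scanpath(
        layout, params, seed, geometry, world, noise)
    events = build_events(layout, plan)
    speed = pd.DataFrame({"timestamp": plan.t, "speed_kmh": plan.v})

    # derive condition labels with the package's own rules
    true_fixs = [gaze_mod.Fixation(r.onset, r.duration, r.x, r.y, r.aoi)
                 for r in truth.itertuples(index=False)]
    segments = gaze_mod.segment_session(events, expected=layout.n_regions)
    gaze_mod.assign_segments(true_fixs, segments)
    cond_events = ev_mod.classify_events(true_fixs, speed, events, layout)
    cond_df = ev_mod.events_to_frame(cond_events)

    truth = truth.copy()
    truth["condition"] = ""
    onset_to_label = {round(e.onset, 6): e.label for e in cond_events}
    truth["condition"] = [onset_to_label.get(round(o, 6), "")
                          for o in truth["onset"]]

    duration = float(plan.t[-1])
    if with_eeg:
        eeg = generate_eeg(cond_df, duration, templates, noise, seed + 1,
                           blink_times)
    else:
        eeg = EEGRecording(EEG_RATE, list(MONTAGE),
                           np.zeros((len(MONTAGE),
                                     int(math.ceil(duration * EEG_RATE)))),
                           0.0)

    bundle = SessionBundle(
        gaze=gaze, eeg=eeg, events=events, speed=speed, geometry=geometry,
        metadata={"participant": participant, "primed": primed, "seed": seed},
    )
    ground_truth = GroundTruth(truth, cond_df, blink_times, layout,
                               templates, noise, params)
    return bundle, ground_truth, tracks
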