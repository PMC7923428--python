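"""Classification of fixation onsets into the four analysis conditions.

Only fixations longer than 200 ms are retained as potential epoch-locking
events (shorter fixations risk contamination by the subsequent gaze
shift).  The conditions are:

* **A** -- fixation on the speedometer whose most recent preceding
  non-white-space fixation in the segment is on the speed sign, followed
  by a speed change;
* **B** -- the same sequence without a speed change;
* **C** -- the first valid fixation on a dynamic billboard after that
  billboard's content-change event;
* **D** -- the last valid fixation on a static billboard before the car
  drives past it.

"Followed by" tolerates intervening white-space ("other") fixations but
not intervening sign or billboard fixations: drivers saccade through empty
scene between targets.  The speed-change criterion (at least 2 km/h within
3 s of the fixation onset) is a configurable default; each fixation yields
at most one label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gaze import Fixation

MIN_EVENT_DURATION = 0.2  # s


@dataclass(frozen=True)
class SpeedChange:
    """Speed-change detection parameters: a change of at least
    ``delta_kmh`` anywhere within ``window`` seconds after the onset."""

    window: float = 3.0
    delta_kmh: float = 2.0

    def __post_init__(self) -> None:
        if self.window <= 0 or self.delta_kmh <= 0:
            raise ValueError("SpeedChange parameters must be positive")


@dataclass
class ConditionEvent:
    """A retained fixation-onset event labelled A/B/C/D."""

    onset: float
    label: str
    segment_index: int | None
    fixation: Fixation


class TraceGapError(ValueError):
    """The speed trace does not cover the queried window."""


def detect_speed_change(speed: pd.DataFrame, t0: float,
                        params: SpeedChange = SpeedChange()) -> bool:
    """True iff max |speed(t) - speed(t0)| >= delta within the window.

    The boundary is inclusive (a step of exactly ``delta_kmh`` counts).
    Raises :class:`TraceGapError` when the trace does not cover
    ``[t0, t0 + window]`` or has a gap spanning the window.
    """
    ts = speed["timestamp"].to_numpy(float)
    v = speed["speed_kmh"].to_numpy(float)
    if len(ts) < 2 or ts[0] > t0 or ts[-1] < t0 + params.window:
        raise TraceGapError(f"speed trace does not cover "
                            f"[{t0}, {t0 + params.window}]")
    sel = (ts >= t0) & (ts <= t0 + params.window)
    if not sel.any():
        raise TraceGapError("speed trace has a gap covering the window")
    v0 = float(np.interp(t0, ts, v))
    return bool(np.max(np.abs(v[sel] - v0)) >= params.delta_kmh)


def classify_events(fixations: list[Fixation], speed: pd.DataFrame,
                    events: pd.DataFrame, layout, *,
                    min_duration: float = MIN_EVENT_DURATION,
                    speed_params: SpeedChange = SpeedChange(),
                    ) -> list[ConditionEvent]:
    """Label retained fixation onsets as condition A/B/C/D events.

    ``fixations`` must carry AOI labels and segment indices.  ``layout``
    provides billboard types per region; ``events`` provides the
    billboard-change and pass times.
    """
    fixs = sorted(fixations, key=lambda f: f.onset)
    ev = events
    change_times = {int(r.region_index): float(r.timestamp)
                    for r in ev[ev["kind"] == "billboard_change"]
                    .itertuples(index=False)}
    pass_times = {int(r.region_index): float(r.timestamp)
                  for r in ev[ev["kind"] == "region_enter"]
                  .itertuples(index=False)}

    out: list[ConditionEvent] = []

    # A / B: speedometer fixations preceded (modulo white space) by a
    # speed-sign fixation within the same segment.
    for i, f in enumerate(fixs):
        if f.aoi != "speedometer" or f.duration <= min_duration:
            continue
        if f.segment_index is None:
            continue
        prev_target = None
        for g in reversed(fixs[:i]):
            if g.segment_index != f.segment_index:
                break
            if g.aoi in ("speed_sign", "billboard", "speedometer"):
                prev_target = g.aoi
                break
        if prev_target != "speed_sign":
            continue
        try:
            changed = detect_speed_change(speed, f.onset, speed_params)
        except TraceGapError:
            warnings.warn(f"speed trace gap at t={f.onset:.2f}; "
                          "event dropped", stacklevel=2)
            continue
        out.append(ConditionEvent(f.onset, "A" if changed else "B",
                                  f.segment_index, f))

    # C / D: billboard fixations, one event per region at most.
    by_region: dict[int, list[Fixation]] = {}
    for f in fixs:
        if (f.aoi == "billboard" and f.duration > min_duration
                and f.segment_index is not None):
            by_region.setdefault(f.segment_index, []).append(f)
    for region, group in sorted(by_region.items()):
        btype = layout.billboard_type_of(region)
        if btype == "dynamic":
            t_change = change_times.get(region)
            if t_change is None:
                continue
            # strictly after the change; boundary ties go to not-C
            after = [f for f in group if f.onset > t_change]
            if after:
                f = after[0]
                out.append(ConditionEvent(f.onset, "C", region, f))
        else:
            t_pass = pass_times.get(region)
            if t_pass is None:
                continue
            before = [f for f in group if f.onset < t_pass]
            if before:
                f = before[-1]
                out.append(ConditionEvent(f.onset, "D", region, f))

    out.sort(key=lambda e: e.onset)
    return out


def events_to_frame(cond_events: list[ConditionEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.onset, e.label,
          e.segment_index if e.segment_index is not None else -1,
          e.fixation.duration)
         for e in cond_events],
        columns=["onset", "label", "segment", "duration"],
    )
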