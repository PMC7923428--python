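"""Session data model and I/O.

A recording session bundles three time-stamped streams on one shared clock
(float seconds, mirroring an LSL-synchronized acquisition):

* binocular gaze samples at a nominal 120 Hz per eye, in screen pixels;
* continuous EEG at 512 Hz over a 16-channel 10-20 montage subset;
* simulator events (billboard threshold crossings, dynamic billboard
  content changes, region boundaries) plus a car speed trace.

On disk a session is a directory of plain CSV files with one-line headers
and a JSON metadata file::

    session-dir/
        gaze.csv     timestamp,left_x,left_y,right_x,right_y,left_valid,right_valid
        eeg.csv      timestamp,<one column per montage channel, microvolts>
        events.csv   timestamp,kind,region_index,billboard_type,car_x,speed,accelerator
        speed.csv    timestamp,speed_kmh
        meta.json    participant, primed flag, seed, geometry, sample rate ...
        aoi_tracks.csv   (optional; read and written by :mod:`efrp.gaze`)

Invalid gaze samples are kept in the file with validity flags rather than
dropped, so that velocity computation controls gap handling downstream.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: The recorded electrode subset (10-20 system plus intermediate sites).
MONTAGE: tuple[str, ...] = (
    "AF3", "F7", "T7", "CP5", "P7", "P1", "PO1", "Cz",
    "Pz", "PO2", "P2", "P8", "CP6", "T8", "F8", "AF4",
)

GAZE_COLUMNS = [
    "timestamp", "left_x", "left_y", "right_x", "right_y",
    "left_valid", "right_valid",
]
EVENT_COLUMNS = [
    "timestamp", "kind", "region_index", "billboard_type",
    "car_x", "speed", "accelerator",
]
EVENT_KINDS = ("billboard_threshold", "billboard_change", "region_enter")
SPEED_COLUMNS = ["timestamp", "speed_kmh"]


class SessionIOError(IOError):
    """A session directory is missing a required file or is unreadable."""


class SessionValidationError(ValueError):
    """A stream violates a hard invariant (e.g. non-monotone timestamps)."""


class OutOfRangeError(ValueError):
    """A queried time falls outside the span of a recording."""


@dataclass(frozen=True)
class ScreenGeometry:
    """Centre-monitor geometry used to convert pixels to visual angle.

    Defaults model the centre monitor of the simulator: 1024 x 768 pixels
    viewed from 100 cm.  The physical panel size is not part of the study
    description; the default (38.4 x 28.8 cm, a 4:3 panel with square
    pixels at 26.67 px/cm) is a documented, configurable choice.
    """

    pixel_width: int = 1024
    pixel_height: int = 768
    physical_width: float = 38.4   # cm
    physical_height: float = 28.8  # cm
    viewing_distance: float = 100.0  # cm

    def __post_init__(self) -> None:
        for name in ("pixel_width", "pixel_height", "physical_width",
                     "physical_height", "viewing_distance"):
            if getattr(self, name) <= 0:
                raise ValueError(f"ScreenGeometry.{name} must be positive")

    @property
    def px_per_cm_x(self) -> float:
        return self.pixel_width / self.physical_width

    @property
    def px_per_cm_y(self) -> float:
        return self.pixel_height / self.physical_height

    def pixels_to_degrees(self, dx_px: float, dy_px: float) -> float:
        """Visual angle (degrees) subtended by a pixel displacement."""
        dx_cm = dx_px / self.px_per_cm_x
        dy_cm = dy_px / self.px_per_cm_y
        d_cm = math.hypot(dx_cm, dy_cm)
        return math.degrees(math.atan2(d_cm, self.viewing_distance))

    def degrees_to_pixels(self, angle_deg: float) -> float:
        """Approximate on-screen pixel extent of a small visual angle."""
        d_cm = self.viewing_distance * math.tan(math.radians(angle_deg))
        return d_cm * 0.5 * (self.px_per_cm_x + self.px_per_cm_y)

    def to_dict(self) -> dict:
        return {
            "pixel_width": self.pixel_width,
            "pixel_height": self.pixel_height,
            "physical_width": self.physical_width,
            "physical_height": self.physical_height,
            "viewing_distance": self.viewing_distance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScreenGeometry":
        return cls(**d)


@dataclass
class EEGRecording:
    """Continuous multichannel EEG in microvolts.

    ``data`` is channels x samples; ``start_time`` places sample 0 on the
    shared session clock.
    """

    sample_rate: float
    channel_names: list[str]
    data: np.ndarray
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("EEG data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError(
                f"{self.data.shape[0]} data rows for "
                f"{len(self.channel_names)} channel names"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.sample_rate

    def time_to_sample(self, t: float) -> int:
        return time_to_sample(t, self)

    def copy(self) -> "EEGRecording":
        return EEGRecording(self.sample_rate, list(self.channel_names),
                            self.data.copy(), self.start_time)

    def pick(self, names: list[str]) -> "EEGRecording":
        idx = [self.channel_names.index(n) for n in names]
        return EEGRecording(self.sample_rate, list(names),
                            self.data[idx], self.start_time)


def time_to_sample(t: float, rec: EEGRecording) -> int:
    """Map a session-clock time to a 0-based sample index (floor rounding).

    Raises :class:`OutOfRangeError` if ``t`` lies outside the recording
    span ``[start_time, start_time + n_samples / sample_rate)``.
    """
    if t < rec.start_time or t >= rec.start_time + rec.n_samples / rec.sample_rate:
        raise OutOfRangeError(
            f"t={t} outside recording span "
            f"[{rec.start_time}, {rec.start_time + rec.duration})"
        )
    return int(math.floor((t - rec.start_time) * rec.sample_rate))


@dataclass
class SessionBundle:
    """All streams of one recorded (or generated) session."""

    gaze: pd.DataFrame
    eeg: EEGRecording
    events: pd.DataFrame
    speed: pd.DataFrame
    geometry: ScreenGeometry = field(default_factory=ScreenGeometry)
    metadata: dict = field(default_factory=dict)

    def equals(self, other: "SessionBundle") -> bool:
        """Field-by-field equality (used by round-trip tests)."""
        if not isinstance(other, SessionBundle):
            return False
        if self.geometry != other.geometry:
            return False
        if self.metadata != other.metadata:
            return False
        if self.eeg.sample_rate != other.eeg.sample_rate:
            return False
        if self.eeg.channel_names != other.eeg.channel_names:
            return False
        if self.eeg.start_time != other.eeg.start_time:
            return False
        if not np.array_equal(self.eeg.data, other.eeg.data):
            return False
        for a, b in ((self.gaze, other.gaze), (self.events, other.events),
                     (self.speed, other.speed)):
            if list(a.columns) != list(b.columns) or len(a) != len(b):
                return False
            for col in a.columns:
                av, bv = a[col].to_numpy(), b[col].to_numpy()
                if av.dtype.kind == "f" or bv.dtype.kind == "f":
                    if not np.array_equal(av.astype(float), bv.astype(float),
                                          equal_nan=True):
                        return False
                elif not (av == bv).all():
                    return False
        return True


# ---------------------------------------------------------------------------
# Validation

NOMINAL_GAZE_RATE = 120.0
RATE_JITTER_TOL = 0.20
MIN_STREAM_OVERLAP = 0.95


def _check_monotone(ts: np.ndarray, stream: str) -> None:
    bad = np.nonzero(np.diff(ts) <= 0)[0]
    if bad.size:
        raise SessionValidationError(
            f"{stream}: timestamps not strictly increasing at index {bad[0] + 1}"
        )


def validate_bundle(bundle: SessionBundle) -> list[str]:
    """Check all bundle invariants.

    Hard violations (non-monotone timestamps, non-finite EEG, malformed
    events) raise :class:`SessionValidationError`; soft deviations (rate
    jitter, short stream overlap, out-of-screen valid samples) are returned
    as a list of warning strings.
    """
    warn: list[str] = []
    g = bundle.gaze
    ts = g["timestamp"].to_numpy(float)
    if len(ts) < 2:
        raise SessionValidationError("gaze: need at least 2 samples")
    _check_monotone(ts, "gaze")

    rate = 1.0 / np.median(np.diff(ts))
    if abs(rate - NOMINAL_GAZE_RATE) > RATE_JITTER_TOL * NOMINAL_GAZE_RATE:
        warn.append(f"gaze: median rate {rate:.1f} Hz deviates more than "
                    f"{RATE_JITTER_TOL:.0%} from {NOMINAL_GAZE_RATE:.0f} Hz")

    geo = bundle.geometry
    for eye in ("left", "right"):
        valid = g[f"{eye}_valid"].to_numpy().astype(bool)
        x = g[f"{eye}_x"].to_numpy(float)[valid]
        y = g[f"{eye}_y"].to_numpy(float)[valid]
        off = ((x < 0) | (x >= geo.pixel_width) |
               (y < 0) | (y >= geo.pixel_height) |
               ~np.isfinite(x) | ~np.isfinite(y))
        if off.any():
            warn.append(f"gaze: {int(off.sum())} valid {eye}-eye samples "
                        "outside the screen")

    if not np.isfinite(bundle.eeg.data).all():
        raise SessionValidationError("eeg: data contains non-finite values")

    ev = bundle.events
    if len(ev):
        unknown = set(ev["kind"]) - set(EVENT_KINDS)
        if unknown:
            raise SessionValidationError(f"events: unknown kinds {sorted(unknown)}")
        enters = ev[ev["kind"] == "region_enter"]
        if enters["region_index"].duplicated().any():
            raise SessionValidationError(
                "events: duplicate region_index for kind=region_enter")
        changes = ev[ev["kind"] == "billboard_change"]
        if (changes["billboard_type"] != "dynamic").any():
            raise SessionValidationError(
                "events: billboard_change on a non-dynamic billboard")

    sp = bundle.speed
    if len(sp) >= 2:
        _check_monotone(sp["timestamp"].to_numpy(float), "speed")

    # stream overlap on the shared clock
    spans = []
    spans.append((ts[0], ts[-1]))
    spans.append((bundle.eeg.start_time,
                  bundle.eeg.start_time + bundle.eeg.duration))
    if len(sp) >= 2:
        spans.append((sp["timestamp"].iloc[0], sp["timestamp"].iloc[-1]))
    lo = max(s[0] for s in spans)
    hi = min(s[1] for s in spans)
    longest = max(s[1] - s[0] for s in spans)
    if longest > 0 and (hi - lo) / longest < MIN_STREAM_OVERLAP:
        warn.append(f"streams overlap only {(hi - lo) / longest:.0%} "
                    f"of the longest stream (< {MIN_STREAM_OVERLAP:.0%})")
    return warn


# ---------------------------------------------------------------------------
# Readers / writers

_FILES = ("gaze.csv", "events.csv", "speed.csv", "meta.json")


def write_session(bundle: SessionBundle, path: str | Path,
                  eeg_format: str = "csv") -> Path:
    """Write a session bundle to ``path`` in the documented layout.

    ``eeg_format`` selects ``eeg.csv`` (default, inspectable) or
    ``eeg.h5`` (single HDF5 dataset with identical content, for large
    recordings).
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    bundle.gaze.to_csv(path / "gaze.csv", index=False,
                        float_format="%.17g")

    eeg = bundle.eeg
    if eeg_format == "h5":
        import h5py

        with h5py.File(path / "eeg.h5", "w") as fh:
            fh.create_dataset("data", data=eeg.data)
    elif eeg_format == "csv":
        eeg_df = pd.DataFrame(eeg.data.T, columns=eeg.channel_names)
        eeg_df.insert(0, "timestamp", eeg.times())
        eeg_df.to_csv(path / "eeg.csv", index=False, float_format="%.17g")
    else:
        raise ValueError(f"unknown eeg_format {eeg_format!r}")

    bundle.events.to_csv(path / "events.csv", index=False,
                          float_format="%.17g")
    bundle.speed.to_csv(path / "speed.csv", index=False,
                         float_format="%.17g")

    meta = {
        "geometry": bundle.geometry.to_dict(),
        "eeg_sample_rate": eeg.sample_rate,
        "eeg_start_time": eeg.start_time,
        "eeg_channels": list(eeg.channel_names),
        **bundle.metadata,
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1))
    return path


def read_session(path: str | Path) -> SessionBundle:
    """Read and validate a session bundle from a directory.

    Raises :class:`SessionIOError` naming the first missing file, and
    :class:`SessionValidationError` on hard invariant violations.  Soft
    validation warnings are emitted via :mod:`warnings`.
    """
    path = Path(path)
    for fname in _FILES:
        if not (path / fname).is_file():
            raise SessionIOError(f"session at {path} is missing {fname}")
    if not (path / "eeg.csv").is_file() and not (path / "eeg.h5").is_file():
        raise SessionIOError(f"session at {path} is missing eeg.csv")

    meta = json.loads((path / "meta.json").read_text())
    geometry = ScreenGeometry.from_dict(meta.pop("geometry"))
    sample_rate = meta.pop("eeg_sample_rate")
    start_time = meta.pop("eeg_start_time")
    channels = meta.pop("eeg_channels")

    gaze = pd.read_csv(path / "gaze.csv", float_precision="round_trip")
    if (path / "eeg.csv").is_file():
        eeg_df = pd.read_csv(path / "eeg.csv",
                             float_precision="round_trip")
        eeg_data = eeg_df[channels].to_numpy(float).T
    else:
        import h5py

        with h5py.File(path / "eeg.h5", "r") as fh:
            eeg_data = fh["data"][()]
    eeg = EEGRecording(sample_rate, list(channels), eeg_data, start_time)
    events = pd.read_csv(
        path / "events.csv",
        dtype={"kind": str, "billboard_type": str},
        keep_default_na=False, na_values=[""],
        float_precision="round_trip",
    )
    if len(events) == 0:
        events = pd.DataFrame(columns=EVENT_COLUMNS)
    speed = pd.read_csv(path / "speed.csv", float_precision="round_trip")

    bundle = SessionBundle(gaze=gaze, eeg=eeg, events=events, speed=speed,
                           geometry=geometry, metadata=meta)
    for msg in validate_bundle(bundle):
        warnings.warn(msg, stacklevel=2)
    return bundle
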