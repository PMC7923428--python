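"""EEG preprocessing, fixation-locked epoching, and component measurement.

The continuous recording is band-pass filtered at 0.16--30 Hz with a
Hamming-windowed sinc FIR filter of order 424, applied in a single forward
pass with group-delay compensation so the output stays time-aligned.
Channels with outlying log-variance are removed (no interpolation: the
montage is too sparse to reconstruct a site from neighbours).  Epochs span
-200..800 ms around each fixation onset (512 samples at 512 Hz, onset at
sample 102), are baseline corrected over the pre-onset interval, and are
rejected whenever any retained channel exceeds +/-75 microvolts.
Artifact-free epochs are grand averaged per condition and component peaks
are measured in fixed windows:

==========  ============  ===========  ========
component   electrodes    window (ms)  polarity
==========  ============  ===========  ========
P1          PO1, PO2      50--100      positive
N1          PO1, PO2      75--125      negative
P2          Pz, P2, Cz    150--225     positive
N2          Cz            225--275     negative
==========  ============  ===========  ========
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .session_io import EEGRecording

FILTER_LOW = 0.16    # Hz
FILTER_HIGH = 30.0   # Hz
FILTER_ORDER = 424
EPOCH_TMIN = -0.2    # s
EPOCH_TMAX = 0.8     # s
REJECT_LIMIT_UV = 75.0
CHANNEL_ZMAX = 5.0


class FilterDesignError(ValueError):
    """Invalid band-pass parameters."""


def design_bandpass(fs: float, low: float = FILTER_LOW,
                    high: float = FILTER_HIGH,
                    order: int = FILTER_ORDER) -> np.ndarray:
    """Linear-phase band-pass FIR taps (difference of windowed sincs).

    ``order`` must be even; the filter has ``order + 1`` symmetric taps.
    """
    if order % 2 != 0:
        raise FilterDesignError("filter order must be even")
    if not (0 < low < high < fs / 2):
        raise FilterDesignError(
            f"need 0 < low < high < fs/2, got low={low}, high={high}, fs={fs}")
    return signal.firwin(order + 1, [low, high], pass_zero=False,
                         window="hamming", fs=fs)


def apply_filter(rec: EEGRecording, taps: np.ndarray | None = None,
                 zero_phase: bool = False) -> EEGRecording:
    """Filter a recording, compensating the FIR group delay.

    The default single forward pass shifts the output left by half the
    filter order so that features stay time-aligned with the input;
    ``zero_phase=True`` uses a forward-backward pass instead.
    """
    if taps is None:
        taps = design_bandpass(rec.sample_rate)
    n = rec.n_samples
    if zero_phase:
        out = signal.filtfilt(taps, [1.0], rec.data, axis=1,
                              padlen=min(3 * len(taps), n - 1))
    else:
        delay = (len(taps) - 1) // 2
        full = signal.oaconvolve(rec.data, taps[np.newaxis, :], axes=1)
        out = full[:, delay:delay + n]
    return EEGRecording(rec.sample_rate, list(rec.channel_names),
                        out, rec.start_time)


class ChannelRejectionError(ValueError):
    """More than half of the channels were flagged as bad."""


def reject_channels(rec: EEGRecording, zmax: float = CHANNEL_ZMAX,
                    extreme_var_ratio: float = 1000.0,
                    ) -> tuple[EEGRecording, list[str]]:
    """Drop channels whose variance marks them as artifact-dominated.

    A channel is removed when the robust z-score (median/MAD) of its log
    variance exceeds ``zmax``, or when its variance exceeds the montage's
    lower-quartile variance by ``extreme_var_ratio`` (a channel more than
    ~30x the quiet-channel amplitude is bad even if outliers dominate the
    median).  Only high-variance channels are removed: the rejection
    targets artifact-dominated sites, and a removed channel is excluded
    from all downstream averages rather than interpolated (the montage is
    too sparse to reconstruct a site from neighbours).  Degenerate spread
    (all-identical variances) removes nothing; rejecting more than half
    the montage is a hard error.
    """
    if rec.n_channels < 4:
        raise ValueError("channel rejection requires at least 4 channels")
    var = rec.data.var(axis=1)
    logv = np.log10(np.maximum(var, 1e-30))
    med = np.median(logv)
    mad = np.median(np.abs(logv - med))
    bad = np.zeros(rec.n_channels, dtype=bool)
    if mad > 0:
        z = (logv - med) / (1.4826 * mad)
        bad |= z > zmax
    floor = np.percentile(var, 25, method="lower")
    if floor > 1e-12:
        bad |= var > extreme_var_ratio * floor
    bad = np.nonzero(bad)[0]
    if len(bad) > rec.n_channels / 2:
        raise ChannelRejectionError(
            f"{len(bad)}/{rec.n_channels} channels rejected; data unusable")
    removed = [rec.channel_names[i] for i in bad]
    keep = [n for n in rec.channel_names if n not in removed]
    return rec.pick(keep), removed


@dataclass
class Epoch:
    """A fixation-locked slice of the recording (channels x samples)."""

    data: np.ndarray
    sample_rate: float
    channel_names: list[str]
    t0_sample: int
    label: str
    onset: float

    def times_ms(self) -> np.ndarray:
        return (np.arange(self.data.shape[1]) - self.t0_sample) \
            / self.sample_rate * 1000.0


def extract_epochs(rec: EEGRecording, cond_events, tmin: float = EPOCH_TMIN,
                   tmax: float = EPOCH_TMAX) -> tuple[list[Epoch], int]:
    """Cut one epoch per event; events whose window exceeds the recording
    are dropped (the count of dropped events is returned).

    At 512 Hz the default window is 512 samples with the onset at sample
    102 (``floor(0.2 * 512)`` pre-onset samples; half-open end).
    """
    fs = rec.sample_rate
    n_pre = int(math.floor(-tmin * fs))
    n_tot = int(math.floor((tmax - tmin) * fs))
    epochs: list[Epoch] = []
    dropped = 0
    for e in cond_events:
        onset_idx = int(math.floor((e.onset - rec.start_time) * fs))
        a = onset_idx - n_pre
        b = a + n_tot
        if a < 0 or b > rec.n_samples or not (
                rec.start_time <= e.onset
                < rec.start_time + rec.n_samples / fs):
            dropped += 1
            continue
        epochs.append(Epoch(rec.data[:, a:b].copy(), fs,
                            list(rec.channel_names), n_pre, e.label, e.onset))
    return epochs, dropped


def baseline_correct(epoch: Epoch) -> Epoch:
    """Subtract the per-channel mean over samples strictly before onset."""
    base = epoch.data[:, :epoch.t0_sample].mean(axis=1, keepdims=True)
    return Epoch(epoch.data - base, epoch.sample_rate,
                 list(epoch.channel_names), epoch.t0_sample,
                 epoch.label, epoch.onset)


def reject_epochs(epochs: list[Epoch], limit: float = REJECT_LIMIT_UV,
                  ) -> tuple[list[Epoch], int]:
    """Drop epochs in which any channel sample exceeds ``limit`` in
    absolute value (both polarities)."""
    kept = [e for e in epochs if np.max(np.abs(e.data)) <= limit]
    return kept, len(epochs) - len(kept)


@dataclass
class EvokedResponse:
    """Per-condition grand average (channels x samples)."""

    data: np.ndarray
    sample_rate: float
    channel_names: list[str]
    t0_sample: int
    label: str
    n_epochs: int

    def times_ms(self) -> np.ndarray:
        return (np.arange(self.data.shape[1]) - self.t0_sample) \
            / self.sample_rate * 1000.0


def grand_average(epochs: list[Epoch],
                  labels: tuple[str, ...] = ("A", "B", "C", "D"),
                  ) -> dict[str, EvokedResponse]:
    """Pointwise mean across epochs per condition.

    The channel set of each average is the intersection of the channels
    retained in its member epochs (epochs from different participants may
    have had different channels rejected).  Conditions with no epochs are
    omitted with a warning.
    """
    out: dict[str, EvokedResponse] = {}
    for label in labels:
        group = [e for e in epochs if e.label == label]
        if not group:
            warnings.warn(f"no epochs for condition {label}; omitted",
                          stacklevel=2)
            continue
        common = [ch for ch in group[0].channel_names
                  if all(ch in e.channel_names for e in group)]
        stack = np.stack([
            e.data[[e.channel_names.index(ch) for ch in common]]
            for e in group
        ])
        out[label] = EvokedResponse(stack.mean(axis=0), group[0].sample_rate,
                                    common, group[0].t0_sample, label,
                                    len(group))
    return out


@dataclass(frozen=True)
class ComponentSpec:
    name: str
    electrodes: tuple[str, ...]
    window_ms: tuple[float, float]
    polarity: int  # +1 positive, -1 negative


#: Default component definitions (electrode sites, peak-latency windows).
COMPONENT_SPECS: tuple[ComponentSpec, ...] = (
    ComponentSpec("P1", ("PO1", "PO2"), (50.0, 100.0), +1),
    ComponentSpec("N1", ("PO1", "PO2"), (75.0, 125.0), -1),
    ComponentSpec("P2", ("Pz", "P2", "Cz"), (150.0, 225.0), +1),
    ComponentSpec("N2", ("Cz",), (225.0, 275.0), -1),
)


@dataclass
class ComponentMeasure:
    """Peak amplitude (microvolts) and latency (ms post-onset) of one
    component at one electrode, for one condition."""

    component: str
    electrode: str
    amplitude: float
    latency_ms: float
    condition: str
    available: bool = True


def measure_component(erp: EvokedResponse, spec: ComponentSpec,
                      ) -> list[ComponentMeasure]:
    """Peak measurement in the component window, per electrode.

    Positive components take the window maximum, negative the minimum;
    latency is the peak sample's time post-onset; ties break to the
    earliest sample.  Electrodes removed upstream yield a measure marked
    unavailable.
    """
    t = erp.times_ms()
    mask = (t >= spec.window_ms[0]) & (t <= spec.window_ms[1])
    idx = np.nonzero(mask)[0]
    out = []
    for ch in spec.electrodes:
        if ch not in erp.channel_names:
            out.append(ComponentMeasure(spec.name, ch, math.nan, math.nan,
                                        erp.label, available=False))
            continue
        row = erp.data[erp.channel_names.index(ch), idx]
        k = int(np.argmax(spec.polarity * row))  # argmax takes first tie
        out.append(ComponentMeasure(spec.name, ch, float(row[k]),
                                    float(t[idx[k]]), erp.label))
    return out


def measure_all(erps: dict[str, EvokedResponse],
                specs: tuple[ComponentSpec, ...] = COMPONENT_SPECS,
                ) -> list[ComponentMeasure]:
    return [m for erp in erps.values() for spec in specs
            for m in measure_component(erp, spec)]
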