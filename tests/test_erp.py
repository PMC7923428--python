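"""ERP core: filter design, channel/epoch rejection, epoching, measurement.

The FIR frequency response is verified against an independently coded
discrete-Fourier oracle on the taps.
"""

import numpy as np
import pytest

from efrp.erp import (COMPONENT_SPECS, ChannelRejectionError, ComponentSpec,
                      Epoch, FilterDesignError, apply_filter,
                      baseline_correct, design_bandpass, extract_epochs,
                      grand_average, measure_component, reject_channels,
                      reject_epochs)
from efrp.session_io import EEGRecording, MONTAGE


def dft_gain(taps, f, fs):
    """|H(f)| computed directly from the definition of the DTFT."""
    k = np.arange(len(taps))
    return abs(np.sum(taps * np.exp(-2j * np.pi * f * k / fs)))


class _Ev:
    def __init__(self, onset, label="A"):
        self.onset = onset
        self.label = label


def _rec(data, fs=512.0, channels=None):
    channels = channels or list(MONTAGE)[:data.shape[0]]
    return EEGRecording(fs, channels, data, 0.0)


class TestFilterDesign:
    def test_taps_are_symmetric_linear_phase(self):
        taps = design_bandpass(512.0)
        assert len(taps) == 425
        assert np.allclose(taps, taps[::-1])

    def test_frequency_response_against_dft_oracle(self):
        taps = design_bandpass(512.0)
        assert dft_gain(taps, 10.0, 512.0) == pytest.approx(1.0, abs=0.01)
        assert dft_gain(taps, 45.0, 512.0) < 0.01
        # high-pass edge: DC gain far below the passband gain
        assert dft_gain(taps, 0.0, 512.0) < dft_gain(taps, 10.0, 512.0)

    def test_constant_signal_is_attenuated(self):
        taps = design_bandpass(512.0)
        rec = _rec(np.full((4, 4096), 10.0))
        out = apply_filter(rec, taps)
        mid = out.data[:, 1000:3000]
        assert np.max(np.abs(mid)) < 10.0 * dft_gain(taps, 10.0, 512.0)

    def test_group_delay_compensation_keeps_alignment(self):
        fs = 512.0
        t = np.arange(4096) / fs
        sig = np.sin(2 * np.pi * 10.0 * t)
        rec = _rec(np.tile(sig, (4, 1)))
        out = apply_filter(rec, design_bandpass(fs))
        mid = slice(1000, 3000)
        assert np.corrcoef(sig[mid], out.data[0, mid])[0, 1] > 0.9999

    @pytest.mark.parametrize("low,high,order", [(30.0, 0.16, 424),
                                                (0.16, 300.0, 424),
                                                (0.16, 30.0, 423)])
    def test_invalid_parameters_rejected(self, low, high, order):
        with pytest.raises(FilterDesignError):
            design_bandpass(512.0, low, high, order)


class TestChannelRejection:
    def test_clean_recording_keeps_all_channels(self):
        rng = np.random.default_rng(0)
        rec = _rec(rng.normal(0, 3.0, (16, 4096)), channels=list(MONTAGE))
        out, removed = reject_channels(rec)
        assert removed == []
        assert out.n_channels == 16

    def test_single_noisy_channel_removed(self):
        rng = np.random.default_rng(1)
        data = rng.normal(0, 3.0, (16, 4096))
        data[5] = rng.normal(0, 300.0, 4096)  # 100x amplitude noise
        out, removed = reject_channels(_rec(data, channels=list(MONTAGE)))
        assert removed == [MONTAGE[5]]
        assert MONTAGE[5] not in out.channel_names

    def test_identical_channels_none_removed(self):
        rec = _rec(np.ones((8, 1024)))
        out, removed = reject_channels(rec)
        assert removed == []

    def test_majority_bad_is_hard_error(self):
        rng = np.random.default_rng(2)
        data = rng.normal(0, 1.0, (8, 4096))
        data[:6] *= 1e4
        with pytest.raises(ChannelRejectionError):
            reject_channels(_rec(data), zmax=1.0)


class TestEpoching:
    def test_epoch_shape_and_onset_sample(self):
        rec = _rec(np.zeros((4, 5120)))
        epochs, dropped = extract_epochs(rec, [_Ev(5.0)])
        assert dropped == 0
        e = epochs[0]
        assert e.data.shape == (4, 512)
        assert e.t0_sample == 102

    def test_event_at_recording_start_dropped(self):
        rec = _rec(np.zeros((4, 5120)))
        epochs, dropped = extract_epochs(rec, [_Ev(0.05)])
        assert epochs == [] and dropped == 1

    def test_event_at_recording_end_dropped(self):
        rec = _rec(np.zeros((4, 5120)))
        epochs, dropped = extract_epochs(rec, [_Ev(9.5)])
        assert epochs == [] and dropped == 1

    def test_identical_events_give_identical_epochs(self):
        rng = np.random.default_rng(3)
        rec = _rec(rng.normal(0, 1, (4, 5120)))
        epochs, _ = extract_epochs(rec, [_Ev(5.0), _Ev(5.0)])
        assert np.array_equal(epochs[0].data, epochs[1].data)


class TestBaseline:
    def _epoch(self, data):
        return Epoch(np.asarray(data, float), 512.0,
                     list(MONTAGE)[:np.asarray(data).shape[0]], 102, "A", 5.0)

    def test_constant_channel_becomes_zero(self):
        e = baseline_correct(self._epoch(np.full((3, 512), 7.0)))
        assert np.allclose(e.data, 0.0)

    def test_pre_onset_mean_is_exactly_zero(self):
        rng = np.random.default_rng(4)
        e = baseline_correct(self._epoch(rng.normal(0, 5, (3, 512))))
        assert np.allclose(e.data[:, :102].mean(axis=1), 0.0, atol=1e-12)

    def test_linear_ramp_keeps_slope(self):
        # 4-sample toy epoch, onset at sample 2: ramp 0,1,2,3 with
        # pre-onset mean (0+1)/2 = 0.5 removed, slope untouched
        e = Epoch(np.array([[0.0, 1.0, 2.0, 3.0]]), 512.0, ["Cz"], 2, "A", 0.1)
        out = baseline_correct(e)
        assert np.allclose(out.data[0], [-0.5, 0.5, 1.5, 2.5])
        assert np.allclose(np.diff(out.data[0]), 1.0)


class TestEpochRejection:
    def _epoch(self, data):
        return Epoch(np.asarray(data, float), 512.0, ["Cz"], 102, "A", 5.0)

    def test_quiet_epoch_kept(self):
        kept, n = reject_epochs([self._epoch(np.zeros((1, 512)))])
        assert len(kept) == 1 and n == 0

    @pytest.mark.parametrize("peak", [80.0, -76.0])
    def test_either_polarity_beyond_limit_rejected(self, peak):
        data = np.zeros((1, 512))
        data[0, 300] = peak
        kept, n = reject_epochs([self._epoch(data)])
        assert kept == [] and n == 1

    def test_exactly_at_limit_kept(self):
        data = np.zeros((1, 512))
        data[0, 300] = 75.0
        kept, _ = reject_epochs([self._epoch(data)])
        assert len(kept) == 1

    def test_rejection_monotone_in_limit(self):
        rng = np.random.default_rng(5)
        epochs = [self._epoch(rng.normal(0, 40, (1, 512)))
                  for _ in range(40)]
        kept_counts = [len(reject_epochs(epochs, lim)[0])
                       for lim in (150.0, 100.0, 75.0, 50.0, 25.0)]
        assert all(b <= a for a, b in zip(kept_counts, kept_counts[1:]))


class TestGrandAverage:
    def _epoch(self, data, label="A", channels=("Cz", "Pz")):
        return Epoch(np.asarray(data, float), 512.0, list(channels), 102,
                     label, 5.0)

    def test_identical_epochs_average_to_themselves(self):
        rng = np.random.default_rng(6)
        base = rng.normal(0, 1, (2, 512))
        out = grand_average([self._epoch(base.copy()) for _ in range(5)],
                            labels=("A",))
        assert np.allclose(out["A"].data, base)
        assert out["A"].n_epochs == 5

    def test_opposite_epochs_cancel(self):
        ones = np.ones((2, 512))
        out = grand_average([self._epoch(ones), self._epoch(-ones)],
                            labels=("A",))
        assert np.allclose(out["A"].data, 0.0)

    def test_channel_set_is_intersection(self):
        e1 = self._epoch(np.ones((2, 512)), channels=("Cz", "Pz"))
        e2 = self._epoch(np.ones((2, 512)), channels=("Pz", "PO1"))
        out = grand_average([e1, e2], labels=("A",))
        assert out["A"].channel_names == ["Pz"]

    def test_empty_condition_warns_and_is_omitted(self):
        with pytest.warns(UserWarning, match="condition B"):
            out = grand_average([self._epoch(np.ones((2, 512)))],
                                labels=("A", "B"))
        assert set(out) == {"A"}

    def test_noise_suppression_scales_as_inverse_sqrt_n(self):
        rng = np.random.default_rng(7)
        rms = []
        for n in (25, 400):
            acc = []
            for _ in range(12):
                epochs = [self._epoch(rng.normal(0, 5, (2, 512)))
                          for _ in range(n)]
                acc.append(np.sqrt(np.mean(
                    grand_average(epochs, labels=("A",))["A"].data ** 2)))
            rms.append(np.mean(acc))
        assert rms[0] / rms[1] == pytest.approx(4.0, rel=0.25)


class TestComponentMeasurement:
    def _erp(self, data, channels):
        from efrp.erp import EvokedResponse
        return EvokedResponse(np.asarray(data, float), 512.0, list(channels),
                              102, "A", 10)

    def test_default_specs_cover_the_four_components(self):
        table = {(s.name, s.electrodes, s.window_ms) for s in COMPONENT_SPECS}
        assert ("P1", ("PO1", "PO2"), (50.0, 100.0)) in table
        assert ("N1", ("PO1", "PO2"), (75.0, 125.0)) in table
        assert ("P2", ("Pz", "P2", "Cz"), (150.0, 225.0)) in table
        assert ("N2", ("Cz",), (225.0, 275.0)) in table

    def test_flat_erp_measures_zero_at_window_start(self):
        spec = ComponentSpec("P1", ("PO1",), (50.0, 100.0), +1)
        m = measure_component(self._erp(np.zeros((1, 512)), ["PO1"]), spec)[0]
        assert m.amplitude == 0.0
        # earliest sample inside [50, 100] ms
        assert m.latency_ms == pytest.approx(50.78125)

    def test_gaussian_bump_peak_recovered(self):
        t = (np.arange(512) - 102) / 512.0 * 1000.0
        bump = 5.0 * np.exp(-0.5 * ((t - 75.0) / 10.0) ** 2)
        spec = ComponentSpec("P1", ("PO1",), (50.0, 100.0), +1)
        m = measure_component(self._erp(bump[None, :], ["PO1"]), spec)[0]
        assert abs(m.latency_ms - 75.0) <= 1000.0 / 512.0
        assert m.amplitude == pytest.approx(5.0, rel=0.01)

    def test_negative_polarity_takes_minimum(self):
        t = (np.arange(512) - 102) / 512.0 * 1000.0
        dip = -3.0 * np.exp(-0.5 * ((t - 250.0) / 10.0) ** 2)
        spec = ComponentSpec("N2", ("Cz",), (225.0, 275.0), -1)
        m = measure_component(self._erp(dip[None, :], ["Cz"]), spec)[0]
        assert m.amplitude == pytest.approx(-3.0, rel=0.01)
        assert abs(m.latency_ms - 250.0) <= 1000.0 / 512.0

    def test_removed_electrode_marked_unavailable(self):
        spec = ComponentSpec("P1", ("PO1", "PO2"), (50.0, 100.0), +1)
        ms = measure_component(self._erp(np.zeros((1, 512)), ["PO1"]), spec)
        avail = {m.electrode: m.available for m in ms}
        assert avail == {"PO1": True, "PO2": False}


class TestPipelineLinearity:
    def test_scaling_recording_scales_measures(self):
        rng = np.random.default_rng(8)
        base = rng.normal(0, 3.0, (16, 5120))
        events = [_Ev(4.0), _Ev(6.0)]
        amps = []
        for k in (1.0, 2.5):
            rec = _rec(base * k, channels=list(MONTAGE))
            filt = apply_filter(rec)
            epochs, _ = extract_epochs(filt, events)
            epochs = [baseline_correct(e) for e in epochs]
            erp = grand_average(epochs, labels=("A",))["A"]
            m = measure_component(erp, COMPONENT_SPECS[0])[0]
            amps.append(m.amplitude)
        assert amps[1] == pytest.approx(2.5 * amps[0], rel=1e-9)
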