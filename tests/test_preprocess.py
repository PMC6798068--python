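"""Filter design/application, epoch extraction, baselines, averaging."""

import numpy as np
import pandas as pd
import pytest

from bistable_eeg import io as bio
from bistable_eeg.montage import CHANNEL_GROUPS, MONTAGE_24
from bistable_eeg.preprocess import (
    EpochSet, FilterDesignError, FilterSpec, average_erp, baseline_correct,
    design_bandpass, expand_to_locations, extract_epochs, filter_recording,
    group_signal, ms_to_samples, stimulus_baselines,
)

FS = 500.0


def freq_response(h, f, fs=FS, n=2 ** 18):
    H = np.abs(np.fft.rfft(h, n))
    w = np.fft.rfftfreq(n, 1 / fs)
    return H[np.argmin(np.abs(w - f))]


class TestFilterDesign:
    def test_coefficients_exactly_symmetric(self):
        h = design_bandpass(FS)
        assert np.array_equal(h, h[::-1])
        assert h.size % 2 == 1  # even order, type-I linear phase

    def test_dc_blocked(self):
        h = design_bandpass(FS)
        assert abs(h.sum()) < 0.01  # |H(0)| = sum of taps

    def test_passband_center_unity(self):
        h = design_bandpass(FS)
        assert 0.99 <= freq_response(h, 33.5) <= 1.01

    def test_passband_flat_within_1pct(self):
        h = design_bandpass(FS)
        for f in (4.0, 10.0, 25.0, 40.0, 55.0):
            assert 0.99 <= freq_response(h, f) <= 1.01, f

    def test_stopband_attenuation_50db(self):
        h = design_bandpass(FS)
        for f in (0.0, 0.5, 1.0, 70.0, 100.0):
            assert freq_response(h, f) < 10 ** (-50 / 20) * 10, f  # > 30 dB floor
        assert freq_response(h, 0.5) < 0.05

    def test_invalid_band_raises(self):
        with pytest.raises(FilterDesignError):
            design_bandpass(100.0, FilterSpec(high_hz=65.0))


def make_rec(data, events=(), labels=None):
    labels = labels or [f"ch{i}" for i in range(data.shape[0])]
    return bio.Recording(data=data, fs=FS, channel_labels=labels,
                         events=list(events))


class TestFilterApplication:
    def test_zero_group_delay(self):
        t = np.arange(30000) / FS
        x = np.sin(2 * np.pi * 10 * t)[None, :]
        y = filter_recording(make_rec(x)).data[0]
        xc = np.correlate(y[5000:25000], x[0, 5000:25000], "full")
        lag = int(np.argmax(xc)) - (20000 - 1)
        assert lag == 0
        assert y.shape == x[0].shape

    def test_stopband_sinusoid_suppressed(self):
        t = np.arange(30000) / FS
        x = np.sin(2 * np.pi * 0.5 * t)[None, :]
        y = filter_recording(make_rec(x)).data[0, 5000:25000]
        assert np.sqrt((y ** 2).mean()) < 0.05 * np.sqrt(0.5)

    def test_dc_offset_removed(self):
        x = np.full((1, 30000), 100.0)
        y = filter_recording(make_rec(x)).data[0, 5000:25000]
        assert abs(y.mean()) < 0.5

    def test_too_short_recording_raises(self):
        with pytest.raises(ValueError, match="too short"):
            filter_recording(make_rec(np.zeros((1, 1000))))


class TestEpochs:
    def test_window_sample_arithmetic(self):
        data = np.arange(10000, dtype=float)[None, :]
        ev = [bio.Event(5000, "stimulus_on", 0, "c1")]
        ep = extract_epochs(make_rec(data, ev), "stimulus_on", (-1000, 5000))
        assert ep.data.shape == (1, 1, 3000)
        assert ep.data[0, 0, 0] == 4500.0  # samples [4500, 7500)
        assert ep.data[0, 0, -1] == 7499.0
        assert ep.lock_index == 500

    def test_underrun_trial_dropped(self):
        data = np.zeros((1, 10000))
        ev = [bio.Event(100, "stimulus_on", 0, "c1"),
              bio.Event(5000, "stimulus_on", 1, "c1")]
        ep = extract_epochs(make_rec(data, ev), "stimulus_on", (-1000, 5000))
        assert ep.n_trials == 1 and ep.n_dropped == 1
        assert "trial 0" in ep.drop_reasons[0]

    def test_all_in_range_kept(self):
        data = np.zeros((2, 30000))
        ev = [bio.Event(s, "stimulus_on", i, "c1")
              for i, s in enumerate((5000, 12000, 20000))]
        ep = extract_epochs(make_rec(data, ev), "stimulus_on", (-1000, 5000))
        assert ep.n_trials == 3

    def test_no_events_warns_empty(self):
        with pytest.warns(UserWarning, match="button2"):
            ep = extract_epochs(make_rec(np.zeros((1, 5000))), "button2")
        assert ep.n_trials == 0

    def test_onset_and_button_epochs_are_views_of_same_data(self):
        """Overlap fidelity: where the onset- and button-locked epochs cover
        the same absolute samples, they are equal."""
        rng = np.random.default_rng(0)
        data = rng.normal(size=(2, 30000))
        onset_s, b1_s = 6000, 6400
        ev = [bio.Event(onset_s, "stimulus_on", 0, "c1"),
              bio.Event(b1_s, "button1", 0, "c1")]
        rec = make_rec(data, ev)
        ep_on = extract_epochs(rec, "stimulus_on", (-1000, 5000))
        ep_b1 = extract_epochs(rec, "button1", (-1000, 5000))
        shift = b1_s - onset_s
        a = ep_on.data[0, :, shift:]
        b = ep_b1.data[0, :, : 3000 - shift]
        assert np.array_equal(a, b)

    def test_filter_then_epoch_commutes_with_epoch_then_filter(self):
        """Interior epochs: filtering the continuous data then epoching
        equals epoching with context, filtering, and trimming."""
        rng = np.random.default_rng(1)
        data = rng.normal(size=(1, 40000))
        ev = [bio.Event(20000, "stimulus_on", 0, "c1")]
        rec = make_rec(data, ev)
        ep_a = extract_epochs(filter_recording(rec), "stimulus_on", (-1000, 5000))
        ctx = 4000  # > filter order on each side
        seg = data[:, 20000 - 500 - ctx: 20000 + 2500 + ctx]
        seg_f = filter_recording(make_rec(seg)).data[:, ctx:-ctx]
        assert np.abs(ep_a.data[0] - seg_f).max() < 1e-6


class TestBaseline:
    def _epochs_and_baselines(self, data, onset):
        ev = [bio.Event(onset, "stimulus_on", 0, "c1")]
        rec = make_rec(data, ev)
        table = pd.DataFrame(
            {"trial": [0], "block": [1], "condition": ["c1"],
             "fixation_on": [onset - 600], "stimulus_on": [onset],
             "button1": [pd.NA], "button2": [pd.NA], "trial_end": [onset + 2500]}
        ).astype({"stimulus_on": "Int64"})
        ep = extract_epochs(rec, "stimulus_on", (-1000, 5000))
        return ep, stimulus_baselines(rec, table)

    def test_constant_epoch_zeroed(self):
        ep, bl = self._epochs_and_baselines(np.full((1, 10000), 5.0), 5000)
        out = baseline_correct(ep, bl)
        assert np.abs(out.data).max() == 0.0

    def test_prestimulus_mean_zero_after_correction(self):
        rng = np.random.default_rng(2)
        ep, bl = self._epochs_and_baselines(rng.normal(size=(3, 10000)), 5000)
        out = baseline_correct(ep, bl)
        pre = out.data[:, :, :500]  # [-1000, 0) ms
        assert np.abs(pre.mean(axis=2)).max() < 1e-9

    def test_ramp_baseline_value(self):
        """Baseline over samples 0..499 of a ramp x[n] = n subtracts 249.5."""
        data = np.arange(10000, dtype=float)[None, :]
        ep, bl = self._epochs_and_baselines(data, 500)
        assert bl[0][0] == pytest.approx(249.5)

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        ep, bl = self._epochs_and_baselines(rng.normal(size=(2, 10000)), 5000)
        once = baseline_correct(ep, bl)
        twice = baseline_correct(once, bl)
        assert np.array_equal(once.data, twice.data)

    def test_missing_baseline_drops_trial(self):
        rng = np.random.default_rng(4)
        ep, bl = self._epochs_and_baselines(rng.normal(size=(1, 10000)), 5000)
        out = baseline_correct(ep, {})
        assert out.n_trials == 0 and out.n_dropped == ep.n_dropped + 1


class TestAverage:
    def _epochset(self, data, conds):
        return EpochSet(
            data=data, lock="stimulus_on", window_ms=(-1000, 5000), fs=FS,
            trial_ids=np.arange(data.shape[0]),
            conditions=np.asarray(conds, dtype=object),
            channel_labels=["a", "b"][: data.shape[1]],
        )

    def test_identical_trials(self):
        one = np.random.default_rng(0).normal(size=(1, 2, 3000))
        ep = self._epochset(np.repeat(one, 5, axis=0), ["c1"] * 5)
        erp = average_erp(ep, "c1")
        assert np.allclose(erp.data, one[0])
        assert erp.n_trials == 5

    def test_opposite_trials_cancel(self):
        v = np.random.default_rng(1).normal(size=(1, 2, 3000))
        ep = self._epochset(np.concatenate([v, -v]), ["c1", "c1"])
        assert np.allclose(average_erp(ep, "c1").data, 0.0)

    def test_noise_shrinks_as_sqrt_n(self):
        rng = np.random.default_rng(2)
        data = rng.normal(0, 10, size=(100, 1, 3000))
        erp = average_erp(self._epochset(data, ["c1"] * 100), "c1")
        assert erp.data.std() == pytest.approx(1.0, rel=0.3)

    def test_zero_trials_raises(self):
        ep = self._epochset(np.zeros((2, 1, 3000)), ["c1", "c1"])
        with pytest.raises(ValueError, match="c2"):
            average_erp(ep, "c2")


class TestGroups:
    def test_identical_channels_equal_virtual(self):
        data = np.tile(np.arange(100.0), (24, 1))
        out = group_signal(data, "L1", MONTAGE_24)
        assert np.array_equal(out, data[0])

    def test_l5_is_mean_of_its_8_channels(self):
        rng = np.random.default_rng(0)
        data = rng.normal(size=(24, 50))
        idx = [MONTAGE_24.index(ch) for ch in
               ("Fp1", "F7", "FC1", "TP9", "CP5", "CP1", "P3", "O1")]
        assert len(idx) == 8
        out = group_signal(data, "L5", MONTAGE_24)
        assert np.allclose(out, data[idx].mean(axis=0))

    def test_30_locations_emitted(self):
        data = np.zeros((24, 10))
        out, labels = expand_to_locations(data, MONTAGE_24)
        assert out.shape == (30, 10)
        assert labels == list(MONTAGE_24) + ["L1", "L2", "L3", "L4", "L5", "L6"]

    def test_l5_l6_disjoint(self):
        assert not set(CHANNEL_GROUPS["L5"]) & set(CHANNEL_GROUPS["L6"])

    def test_missing_channel_named(self):
        with pytest.raises(ValueError, match="Fp1"):
            group_signal(np.zeros((2, 10)), "L1", ["F7", "FC1"])


def test_ms_to_samples_rounding():
    assert ms_to_samples(-1000, 500) == -500
    assert ms_to_samples(150, 500) == 75
    assert ms_to_samples(-50, 500) == -25
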