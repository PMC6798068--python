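"""Simulator contracts: trial grammar, determinism, effect injection."""

import numpy as np
import pandas as pd
import pytest

from bistable_eeg.io import Event
from bistable_eeg.preprocess import extract_epochs, filter_recording
from bistable_eeg.erp_features import find_peak
from bistable_eeg.spectral_features import band_power, welch_psd
from bistable_eeg.synth import (
    BandModulation, ConfigError, ErpComponent, SimConfig, cohort_plan,
    erp_component_waveform, generate_cohort, generate_hft_responses,
    generate_participant, noise_band_fraction, participant_seed,
)


def tiny_config(**kw):
    base = dict(n_training_trials=2, n_blocks=1, trials_per_block=10,
                p_press1=1.0, p_reversal_fd=0.8, p_reversal_fn=0.8,
                p_reversal_fi=0.8, seed=1)
    base.update(kw)
    return SimConfig(**base)


class TestSchedule:
    def test_default_session_has_310_stimuli(self, default_participant):
        rec, table, _ = default_participant
        assert sum(e.type == "stimulus_on" for e in rec.events) == 310
        assert len(table) == 310

    def test_blocks_are_exact_50_50_splits(self, default_participant):
        _, table, _ = default_participant
        test = table[table.block > 0]
        counts = test.groupby(["block", "condition"]).size()
        assert set(counts) == {50}
        assert len(counts) == 6  # 3 blocks x 2 conditions

    def test_event_grammar(self, default_participant):
        rec, table, _ = default_participant
        for row in table.itertuples(index=False):
            assert row.fixation_on < row.stimulus_on <= row.trial_end
            if pd.notna(row.button2):
                assert pd.notna(row.button1)
                assert row.button1 < row.button2
                assert row.condition == "c1"
            if pd.notna(row.button1):
                assert row.stimulus_on < row.button1 <= row.trial_end

    def test_epochs_never_reach_next_stimulus(self, default_participant):
        """Any lock event + 5000 ms stays before the next stimulus onset."""
        _, table, _ = default_participant
        fs = 500.0
        horizon = int(5.0 * fs)
        next_stim = table["stimulus_on"].shift(-1)
        for col in ("stimulus_on", "button1", "button2"):
            locks = table[col].astype("Float64")
            ok = (locks + horizon <= next_stim.astype("Float64")) | next_stim.isna() | locks.isna()
            assert ok.all(), f"{col} epoch crosses the next trial's stimulus"

    def test_determinism_bit_identical(self):
        cfg = tiny_config()
        a = generate_participant(cfg, "P01", "FD", 42)
        b = generate_participant(cfg, "P01", "FD", 42)
        assert np.array_equal(a[0].data, b[0].data)
        assert a[0].events == b[0].events
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_invalid_config_names_field(self):
        with pytest.raises(ConfigError, match="p_c1"):
            SimConfig(p_c1=1.5)
        with pytest.raises(ConfigError, match="fixation"):
            SimConfig(fixation_ms_range=(800.0, 6000.0))
        with pytest.raises(ConfigError, match="noise_model"):
            SimConfig(noise_model="brown")


class TestCohort:
    def test_group_counts(self):
        cfg = tiny_config(n_fd=14, n_fi=7, n_fn=10)
        plan = cohort_plan(cfg)
        assert len(plan) == 31
        groups = [g for _, g in plan]
        assert (groups.count("FD"), groups.count("FI"), groups.count("FN")) == (14, 7, 10)

    def test_single_participant_cohort(self):
        cfg = tiny_config(n_fd=1, n_fi=0, n_fn=0, noise_sigma_uv=1.0)
        bundles = generate_cohort(cfg)
        assert len(bundles) == 1 and bundles[0].group == "FD"

    def test_cohort_seeds_reproducible(self):
        a = participant_seed(7, 3).generate_state(4)
        b = participant_seed(7, 3).generate_state(4)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, participant_seed(7, 4).generate_state(4))


class TestInjection:
    def test_noiseless_component_is_analytic(self):
        comp = ErpComponent("stimulus_on", 150.0, 20.0, 4.0, ["Pz"])
        cfg = tiny_config(noise_sigma_uv=0.0, erp_components=(comp,),
                          trials_per_block=4, n_training_trials=0)
        rec, table, _ = generate_participant(cfg, "P01", "FD", 0)
        wave, offset = erp_component_waveform(comp, cfg.fs)
        pz = cfg.montage.index("Pz")
        onset = int(table.stimulus_on.iloc[0])
        seg = rec.data[pz, onset + offset: onset + offset + wave.size]
        assert np.abs(seg - wave).max() < 1e-9
        others = np.delete(rec.data, pz, axis=0)
        assert np.abs(others).max() == 0.0

    def test_noiseless_latency_recovered_after_filtering(self):
        """Preprocess + peak search recover a planted 150 ms bump at Pz
        within +-4 ms on a noiseless recording."""
        comp = ErpComponent("stimulus_on", 150.0, 20.0, 4.0, ["Pz"])
        cfg = tiny_config(noise_sigma_uv=0.0, erp_components=(comp,),
                          trials_per_block=4, n_training_trials=0)
        rec, table, _ = generate_participant(cfg, "P01", "FD", 0)
        epochs = extract_epochs(filter_recording(rec), "stimulus_on")
        pz = cfg.montage.index("Pz")
        peak = find_peak(epochs.data[0, pz], cfg.fs, (100, 200), "positive")
        assert abs(peak.latency_ms - 150.0) <= 4.0
        # the 2 Hz high-pass attenuates the slow bump deterministically; the
        # attainable amplitude reference is the filtered analytic component
        from bistable_eeg.preprocess import design_bandpass
        from scipy.signal import fftconvolve

        wave, _ = erp_component_waveform(comp, cfg.fs)
        filtered_truth = fftconvolve(wave, design_bandpass(cfg.fs), mode="same").max()
        assert peak.amplitude_uv == pytest.approx(filtered_truth, abs=0.05)

    def test_c2_trials_never_get_button2_locked_effects(self):
        comp = ErpComponent("button2", -250.0, 20.0, 4.0, ["Pz"], "c1")
        cfg = tiny_config(noise_sigma_uv=0.0, erp_components=(comp,))
        rec, table, _ = generate_participant(cfg, "P01", "FD", 0)
        assert table.loc[table.condition == "c2", "button2"].isna().all()

    def test_spectral_control_converges_to_gain(self):
        """Welch band power under a planted x2 modulation converges to
        twice the background's band power (within 10% over 200 trials)."""
        gain = 2.0
        mod = BandModulation((26.0, 60.0), "stimulus_on", (1000.0, 2000.0), gain,
                             channels=("Pz",))
        cfg = tiny_config(
            montage=("Pz", "Cz"), n_training_trials=0, trials_per_block=200,
            p_press1=0.0, band_modulations=(mod,), noise_sigma_uv=10.0, seed=5,
        )
        rec, table, _ = generate_participant(cfg, "P01", "FD", 9)
        on = table.stimulus_on.astype(int).values
        pz = 0  # first montage channel
        # modulated window [1000, 2000] ms after onset = samples [s+500, s+1500)
        mod_segs = np.stack([rec.data[pz, s + 500: s + 1000] for s in on])
        ref_segs = np.stack([rec.data[pz, s - 500: s] for s in on])
        mod_p = band_power(welch_psd(mod_segs, cfg.fs), (26, 60)).mean()
        ref_p = band_power(welch_psd(ref_segs, cfg.fs), (26, 60)).mean()
        assert mod_p / ref_p == pytest.approx(gain, rel=0.10)

    def test_noise_band_fraction_white(self):
        cfg = tiny_config(noise_model="white")
        frac = noise_band_fraction(cfg, (26.0, 60.0))
        assert frac == pytest.approx((60 - 26) / 250.0, rel=0.02)


class TestHftGenerator:
    def test_perfect_ability_all_correct(self):
        r = generate_hft_responses(None, [1.0, 1.0], 32, seed=0)
        assert (r == 1).all()

    def test_zero_ability_all_incorrect(self):
        r = generate_hft_responses(None, [0.0, 0.0], 32, seed=0)
        assert (r == -1).all()

    def test_odd_item_count_rejected(self):
        with pytest.raises(ConfigError, match="even"):
            generate_hft_responses(None, [0.5], 31, seed=0)

    def test_parallel_mode_realizes_target_item_correlation(self, rng):
        r = generate_hft_responses(None, np.full(4000, 0.5), 32, seed=4,
                                   parallel_inter_item_r=0.17)
        items = (r == 1).astype(float)
        c = np.corrcoef(items.T)
        mean_r = c[np.triu_indices(32, 1)].mean()
        assert mean_r == pytest.approx(0.17, abs=0.02)


@pytest.fixture(scope="module")
def default_participant():
    from bistable_eeg.synth import standard_components

    cfg = SimConfig(erp_components=standard_components(), seed=3)
    return generate_participant(cfg, "P01", "FD", participant_seed(3, 0))
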