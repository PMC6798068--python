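"""Monte-Carlo validation studies of the full analysis chain.

Three studies exercise simulator -> preprocessing -> features -> statistics
end to end:

* **ERP parameter recovery** -- a known Gaussian component is planted on a
  noisy background; the study measures how precisely the trial-averaged,
  band-passed peak search recovers its amplitude and latency.  The
  amplitude reference is the analytic component *as seen through the
  analysis band-pass* (the filter's deterministic attenuation of a slow
  bump is part of the forward model, not estimation error; see the methods
  note), while latency is compared to the injected latency directly.
* **Null familywise error rate** -- cohorts in which conditions, button
  epochs and groups are generatively identical (pure noise background);
  the fraction of per-feature Holm families with at least one rejection
  estimates the realized FWER, which Holm bounds at alpha.
* **Planted-effect power** -- an FD-only pre-reversal gamma power doubling
  at chosen channels; the study measures how often the group comparison
  flags exactly those channels after Holm correction.

All studies derive every replicate's seed from a single integer.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .erp_features import find_peak
from .pipeline import simulate_and_extract
from .preprocess import (
    average_erp, baseline_correct, design_bandpass, extract_epochs,
    filter_recording, stimulus_baselines,
)
from .stats import run_comparisons
from .synth import (
    ErpComponent, SimConfig, generate_participant, planted_gamma_modulation,
)

PLANTED_CHANNELS = ("T8", "CP6", "TP10")


def _sub_seed(seed: int, tag: int, index: int) -> int:
    """A stable 31-bit seed derived from (seed, tag, index)."""
    return int(np.random.SeedSequence((seed, tag, index)).generate_state(1)[0] % (2 ** 31))


# ---------------------------------------------------------------------------
# ERP parameter recovery
# ---------------------------------------------------------------------------

RECOVERY_COMPONENT = ErpComponent(
    lock="stimulus_on", latency_ms=150.0, width_ms=18.0, amplitude_uv=4.0,
    channels=("Pz",),
)


def filtered_component_peak(component: ErpComponent = RECOVERY_COMPONENT,
                            fs: float = 500.0) -> float:
    """Peak of the analytic component after the analysis band-pass."""
    from .synth import erp_component_waveform

    wave, _ = erp_component_waveform(component, fs)
    h = design_bandpass(fs)
    pad = np.zeros(h.size)
    padded = np.concatenate([pad, wave, pad])
    y = fftconvolve(padded, h, mode="same")
    peak = float(np.max(y)) if component.amplitude_uv > 0 else float(np.min(y))
    return peak


def erp_recovery_study(
    n_runs: int = 100,
    noise_sigma_uv: float = 1.0,
    n_trials: int = 150,
    seed: int = 0,
) -> pd.DataFrame:
    """Recover the planted component from ``n_trials``-trial averages.

    Returns one row per run with the measured peak amplitude/latency and
    the errors against the filter-aware amplitude reference and the
    injected latency.
    """
    assert n_trials % 3 == 0
    ref_amp = filtered_component_peak()
    rows = []
    for r in range(n_runs):
        cfg = SimConfig(
            n_fd=1, n_fi=0, n_fn=0, montage=("Pz",),
            n_training_trials=0, n_blocks=3, trials_per_block=n_trials // 3,
            p_press1=0.0, noise_sigma_uv=noise_sigma_uv,
            erp_components=(RECOVERY_COMPONENT,),
            seed=_sub_seed(seed, 7001, r),
        )
        rec, table, _ = generate_participant(cfg, f"R{r:03d}", "FD", cfg.seed)
        filtered = filter_recording(rec)
        epochs = baseline_correct(
            extract_epochs(filtered, "stimulus_on"),
            stimulus_baselines(filtered, table),
        )
        erp = average_erp(epochs)
        peak = find_peak(erp.data[0], cfg.fs, (100, 200), "positive")
        rows.append({
            "run": r,
            "amplitude_uv": peak.amplitude_uv,
            "latency_ms": peak.latency_ms,
            "amp_err_uv": peak.amplitude_uv - ref_amp,
            "lat_err_ms": peak.latency_ms - RECOVERY_COMPONENT.latency_ms,
            "n_trials": epochs.n_trials,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Null FWER
# ---------------------------------------------------------------------------

def _null_cohort_config(seed: int) -> SimConfig:
    """Pure-noise cohort: conditions, button epochs and groups all share one
    generative law, so every comparison family is null."""
    return SimConfig(
        n_fd=5, n_fi=5, n_fn=0, n_training_trials=0, n_blocks=1,
        trials_per_block=24, p_press1=1.0,
        p_reversal_fd=0.8, p_reversal_fn=0.8, p_reversal_fi=0.8,
        erp_components=(), band_modulations=(), seed=seed,
    )


def null_fwer_study(
    n_replicates: int = 30, alpha: float = 0.05, seed: int = 0
) -> dict:
    """Fraction of per-feature Holm families with >= 1 rejection under the
    generative null.  Holm guarantees this is <= alpha per family.
    """
    hits = 0
    total = 0
    for r in range(n_replicates):
        cfg = _null_cohort_config(_sub_seed(seed, 7103, r))
        table = simulate_and_extract(cfg, min_trials=3)
        res = run_comparisons(table, alpha=alpha, family_scope="feature")
        fam = res.groupby(["family", "feature"])["reject"].any()
        hits += int(fam.sum())
        total += len(fam)
    return {
        "fwer": hits / total,
        "families_with_rejection": hits,
        "n_families": total,
        "n_replicates": n_replicates,
        "alpha": alpha,
    }


# ---------------------------------------------------------------------------
# Planted-effect power
# ---------------------------------------------------------------------------

def _planted_config(seed: int, power_gain: float = 2.0) -> SimConfig:
    return SimConfig(
        n_fd=7, n_fi=5, n_fn=0, n_training_trials=0, n_blocks=1,
        trials_per_block=30, p_press1=1.0,
        p_reversal_fd=0.8, p_reversal_fn=0.8, p_reversal_fi=0.8,
        band_modulations=(planted_gamma_modulation(PLANTED_CHANNELS, power_gain),),
        seed=seed,
    )


def planted_gamma_power_study(
    n_replicates: int = 10, power_gain: float = 2.0, alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Detection rates for an FD-only pre-reversal gamma doubling.

    Returns the per-channel Holm-corrected detection rate for the group
    comparison of the single-trial gamma feature, plus the realized
    FD-minus-FI difference (dB) at the planted channels.
    """
    detected = {ch: 0 for ch in PLANTED_CHANNELS}
    diffs = []
    for r in range(n_replicates):
        cfg = _planted_config(_sub_seed(seed, 7207, r), power_gain)
        table = simulate_and_extract(cfg, min_trials=3)
        res = run_comparisons(table, alpha=alpha, family_scope="feature")
        sub = res[(res.family == "c_group") & (res.feature == 12)]
        for ch in PLANTED_CHANNELS:
            row = sub[sub.location == ch]
            if not row.empty and bool(row["reject"].iloc[0]):
                detected[ch] += 1
            if not row.empty:
                diffs.append(float(row["mean_a"].iloc[0] - row["mean_b"].iloc[0]))
    return {
        "power_per_channel": {ch: detected[ch] / n_replicates for ch in PLANTED_CHANNELS},
        "min_power": min(detected[ch] / n_replicates for ch in PLANTED_CHANNELS),
        "mean_fd_minus_fi_db": float(np.mean(diffs)),
        "expected_db": float(10 * np.log10(power_gain)),
        "n_replicates": n_replicates,
    }
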