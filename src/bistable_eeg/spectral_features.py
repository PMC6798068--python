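"""Welch band-power estimation for the spectral features.

The estimator splits a segment into non-overlapping Hamming-windowed
pieces, averages their modified periodograms, and normalizes so that the
integral of the PSD over frequency equals the (detrended, window-power-
corrected) signal variance.  With the canonical settings -- 500-point
window, 500-point FFT, no overlap, on 1000 ms epochs at 500 Hz -- this
degenerates to a single modified periodogram on a 1 Hz frequency grid.

The prestimulus low-gamma feature lives on a 150 ms ([-200, -50) ms)
segment of only 75 samples: there the window shrinks to the segment length
and the FFT is zero-padded to 500 points so the reporting grid stays at
1 Hz (see the methods note).

Estimation modes: alpha power is computed on the trial-averaged waveform
(``on_average``); the gamma features are computed per single trial and the
linear band powers averaged before the dB transform (``single_trial_mean``).
Band powers are reported as 10*log10(microvolt^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .features_spec import FeatureSpec
from .preprocess import EpochSet, ms_to_samples

NFFT_DEFAULT = 500
WIN_DEFAULT = 500


@dataclass(frozen=True)
class PSD:
    """One-sided power spectral density in microvolt^2 per Hz."""

    freqs_hz: np.ndarray
    power: np.ndarray
    nfft: int
    window_kind: str
    n_segments: int

    @property
    def df(self) -> float:
        return float(self.freqs_hz[1] - self.freqs_hz[0])


def welch_psd(
    segment: np.ndarray,
    fs: float,
    nfft: int = NFFT_DEFAULT,
    win_len: int = WIN_DEFAULT,
    overlap: int = 0,
) -> PSD:
    """Welch PSD with Hamming windows and per-segment mean removal.

    ``segment`` may be any array whose last axis is time.  Raises if the
    segment is shorter than ``win_len`` (data are never zero-padded; only
    the FFT may be, via ``nfft > win_len``).
    """
    segment = np.asarray(segment, dtype=float)
    n = segment.shape[-1]
    if n < win_len:
        raise ValueError(
            f"segment of {n} samples shorter than window ({win_len}); "
            "reduce win_len instead of zero-padding data"
        )
    if nfft < win_len:
        raise ValueError("nfft must be >= win_len")
    freqs, power = sps.welch(
        segment, fs=fs, window=sps.get_window("hamming", win_len),
        nperseg=win_len, noverlap=overlap, nfft=nfft,
        detrend="constant", scaling="density", axis=-1,
    )
    n_segments = (n - overlap) // (win_len - overlap) if win_len > overlap else 1
    return PSD(freqs_hz=freqs, power=power, nfft=nfft,
               window_kind="hamming", n_segments=n_segments)


def band_power(psd: PSD, band_hz: tuple[float, float]) -> np.ndarray:
    """Rectangle-rule band integral over bins with centers in [low, high].

    Returns linear power (microvolt^2) with the shape of the PSD minus the
    frequency axis.
    """
    lo, hi = band_hz
    mask = (psd.freqs_hz >= lo) & (psd.freqs_hz <= hi)
    if not mask.any():
        raise ValueError(f"band {band_hz} Hz owns no frequency bins")
    return np.asarray(psd.power)[..., mask].sum(axis=-1) * psd.df


def to_db(power_uv2: np.ndarray | float) -> np.ndarray | float:
    return 10.0 * np.log10(power_uv2)


def _segment_slice(epochs: EpochSet, window_ms: tuple[float, float]) -> slice:
    a = epochs.lock_index + ms_to_samples(window_ms[0], epochs.fs)
    b = epochs.lock_index + ms_to_samples(window_ms[1], epochs.fs)
    if a < 0 or b > epochs.data.shape[-1] or b <= a:
        raise ValueError(f"window {window_ms} ms outside the epoch")
    return slice(a, b)


def spectral_feature(
    epochs: EpochSet,
    spec: FeatureSpec,
    nfft: int = NFFT_DEFAULT,
) -> tuple[np.ndarray, np.ndarray]:
    """Compute one band-power feature at every location of an EpochSet.

    Returns ``(value_db, value_uv2)`` arrays over the channel axis.  The
    estimation mode follows the spec: ``on_average`` first averages the
    trials, ``single_trial_mean`` averages per-trial linear band powers.
    """
    if spec.kind != "band_power":
        raise ValueError(f"feature {spec.id} is not spectral")
    if epochs.n_trials == 0:
        raise ValueError("no trials")
    seg = epochs.data[..., _segment_slice(epochs, spec.window_ms)]
    win_len = min(seg.shape[-1], WIN_DEFAULT)
    if spec.estimation == "on_average":
        psd = welch_psd(seg.mean(axis=0), epochs.fs, nfft=max(nfft, win_len),
                        win_len=win_len)
        linear = band_power(psd, spec.band_hz)
    else:
        psd = welch_psd(seg, epochs.fs, nfft=max(nfft, win_len), win_len=win_len)
        linear = band_power(psd, spec.band_hz).mean(axis=0)
    return to_db(linear), linear
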