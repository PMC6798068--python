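"""Local-peak amplitude and latency features on event-locked ERPs.

A "local peak" at sample i is a strict extremum of the requested polarity
relative to every sample within +-neighborhood_ms; if the search window
contains no local extremum, the windowed absolute extremum is returned with
``is_local=False`` (the convention of ERP peak-measurement tools).  Ties
break toward the earliest latency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features_spec import FeatureSpec
from .preprocess import ERP, ms_to_samples

DEFAULT_NEIGHBORHOOD_MS = 20.0


@dataclass(frozen=True)
class PeakResult:
    amplitude_uv: float
    latency_ms: float
    is_local: bool


def find_peak(
    waveform: np.ndarray,
    fs: float,
    window_ms: tuple[float, float],
    polarity: str,
    neighborhood_ms: float = DEFAULT_NEIGHBORHOOD_MS,
    epoch_start_ms: float = -1000.0,
) -> PeakResult:
    """Windowed local-peak search on a single waveform.

    ``window_ms`` bounds are inclusive and relative to the lock event;
    ``epoch_start_ms`` states which epoch time sample 0 corresponds to.
    Neighborhoods are clipped at the epoch edges.
    """
    x = np.asarray(waveform, dtype=float)
    if x.ndim != 1:
        raise ValueError("find_peak expects a single waveform")
    if polarity == "negative":
        res = find_peak(-x, fs, window_ms, "positive", neighborhood_ms, epoch_start_ms)
        return PeakResult(-res.amplitude_uv, res.latency_ms, res.is_local)
    if polarity != "positive":
        raise ValueError(f"polarity must be positive or negative, got {polarity!r}")

    lock = -ms_to_samples(epoch_start_ms, fs)
    lo = lock + ms_to_samples(window_ms[0], fs)
    hi = lock + ms_to_samples(window_ms[1], fs)  # inclusive
    if lo < 0 or hi >= x.size or hi < lo:
        raise ValueError(
            f"window {window_ms} ms maps to samples [{lo}, {hi}] outside the epoch"
        )
    k = ms_to_samples(neighborhood_ms, fs)

    best_idx = -1
    best_val = -np.inf
    for i in range(lo, hi + 1):
        a, b = max(0, i - k), min(x.size, i + k + 1)
        neigh = x[a:b]
        v = x[i]
        # strict local max: larger than every other sample in the neighborhood
        if v > best_val and np.count_nonzero(neigh >= v) == 1:
            best_idx, best_val = i, v
    is_local = best_idx >= 0
    if not is_local:
        seg = x[lo:hi + 1]
        best_idx = lo + int(np.argmax(seg))
        best_val = float(x[best_idx])
    return PeakResult(float(best_val), (best_idx - lock) * 1000.0 / fs, is_local)


def erp_peak_features(
    erp: ERP,
    spec: FeatureSpec,
    neighborhood_ms: float = DEFAULT_NEIGHBORHOOD_MS,
) -> list[PeakResult]:
    """Apply the windowed peak search to every row (location) of an ERP."""
    if spec.kind not in ("peak_amplitude", "peak_latency"):
        raise ValueError(f"feature {spec.id} is not a peak feature")
    return [
        find_peak(
            erp.data[i], erp.fs, spec.window_ms, spec.polarity,
            neighborhood_ms, epoch_start_ms=erp.window_ms[0],
        )
        for i in range(erp.data.shape[0])
    ]
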