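"""Filtering, event-locked epoching, baseline correction and averaging.

The continuous EEG is band-passed 2-65 Hz with a Hamming-windowed linear-
phase FIR filter applied with full group-delay compensation.  Per trial,
three overlapping [-1000, +5000] ms epochs are cut, time-locked to stimulus
onset, first button press and second button press.  Baseline correction
always subtracts the mean over the *trial's* prestimulus window
([-1000, 0) ms before stimulus onset), including for button-locked epochs,
so reversal-related activity is never part of the baseline.

Conventions: 0-based samples, half-open sample windows, ms -> samples via
round(ms * fs / 1000); the lock event sits at epoch time 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import signal

from .io import Recording
from .montage import CHANNEL_GROUPS, LOCATIONS_30
import pandas as pd


class FilterDesignError(ValueError):
    pass


@dataclass(frozen=True)
class FilterSpec:
    """Band edges and transition bandwidths of the analysis band-pass.

    The transition band is wider at the high edge (10 Hz) than at the low
    edge (2 Hz): low-frequency selectivity drives the filter order, while a
    relaxed upper transition keeps the kernel short.
    """

    low_hz: float = 2.0
    high_hz: float = 65.0
    tbw_low_hz: float = 2.0
    tbw_high_hz: float = 10.0


def _hamming_order(fs: float, tbw_hz: float) -> int:
    """Hamming design rule: order ~ 3.3 / (tbw / fs), rounded up to even."""
    order = int(np.ceil(3.3 * fs / tbw_hz))
    return order + (order % 2)


def design_bandpass(fs: float, spec: FilterSpec = FilterSpec()) -> np.ndarray:
    """Symmetric (type-I linear phase) band-pass FIR coefficients.

    Built as the cascade of a Hamming windowed-sinc high-pass (cutoff at
    low + tbw/2) and low-pass (cutoff at high - tbw/2); the cascade of two
    symmetric kernels is symmetric, and its magnitude is the product of the
    two responses (passband within [0.99, 1.01], stopbands > 50 dB down).
    """
    if not 0 < spec.low_hz < spec.high_hz:
        raise FilterDesignError("need 0 < low_hz < high_hz")
    if spec.high_hz >= fs / 2:
        raise FilterDesignError(f"high_hz={spec.high_hz} must be below fs/2={fs / 2}")
    hp_taps = _hamming_order(fs, spec.tbw_low_hz) + 1
    lp_taps = _hamming_order(fs, spec.tbw_high_hz) + 1
    h_hp = signal.firwin(hp_taps, spec.low_hz + spec.tbw_low_hz / 2.0,
                         fs=fs, pass_zero=False, window="hamming")
    h_lp = signal.firwin(lp_taps, spec.high_hz - spec.tbw_high_hz / 2.0,
                         fs=fs, pass_zero=True, window="hamming")
    h = np.convolve(h_hp, h_lp)
    # re-symmetrize: fp summation order breaks bit-exact symmetry of the
    # cascade, and exact c[k] == c[N-1-k] is what guarantees linear phase
    return 0.5 * (h + h[::-1])


def filter_recording(recording: Recording, spec: FilterSpec = FilterSpec(),
                     coeffs: np.ndarray | None = None) -> Recording:
    """Apply the band-pass with zero net group delay and unchanged length.

    Edges are padded by signal reflection before convolution and trimmed
    after, so the kernel never runs off the data.
    """
    h = design_bandpass(recording.fs, spec) if coeffs is None else coeffs
    order = h.size - 1
    n = recording.n_samples
    if n <= 3 * order:
        raise ValueError(
            f"recording of {n} samples too short for filter order {order} "
            f"(need > {3 * order})"
        )
    pad = order // 2
    xp = np.pad(recording.data, ((0, 0), (pad, pad)), mode="reflect")
    # 'same' centering of a symmetric kernel == group-delay compensation
    y = signal.fftconvolve(xp, h[None, :], mode="same", axes=1)[:, pad:pad + n]
    return Recording(
        data=y, fs=recording.fs, channel_labels=list(recording.channel_labels),
        events=list(recording.events), participant_id=recording.participant_id,
        metadata={**recording.metadata, "filtered": f"{spec.low_hz}-{spec.high_hz} Hz"},
    )


# ---------------------------------------------------------------------------
# Epochs
# ---------------------------------------------------------------------------

def ms_to_samples(ms: float, fs: float) -> int:
    return int(round(ms * fs / 1000.0))


@dataclass
class EpochSet:
    """Event-locked trials x channels x samples tensor (microvolts).

    ``window_ms`` is the half-open epoch extent relative to the lock event;
    the lock sits at sample index ``-ms_to_samples(window_ms[0], fs)``.
    """

    data: np.ndarray
    lock: str
    window_ms: tuple[float, float]
    fs: float
    trial_ids: np.ndarray
    conditions: np.ndarray
    channel_labels: Sequence[str]
    baseline_applied: bool = False
    baseline_window_ms: tuple[float, float] = (-1000.0, 0.0)
    n_dropped: int = 0
    drop_reasons: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        expected = ms_to_samples(self.window_ms[1], self.fs) - ms_to_samples(
            self.window_ms[0], self.fs
        )
        if self.data.shape[-1] != expected:
            raise ValueError(
                f"epoch length {self.data.shape[-1]} != window span {expected}"
            )

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def lock_index(self) -> int:
        return -ms_to_samples(self.window_ms[0], self.fs)

    def times_ms(self) -> np.ndarray:
        n = self.data.shape[-1]
        return (np.arange(n) - self.lock_index) * 1000.0 / self.fs

    def select(self, condition: str) -> "EpochSet":
        mask = self.conditions == condition
        return replace(
            self, data=self.data[mask], trial_ids=self.trial_ids[mask],
            conditions=self.conditions[mask], drop_reasons=list(self.drop_reasons),
        )


@dataclass
class ERP:
    """Trial-averaged waveform (channels x samples)."""

    data: np.ndarray
    n_trials: int
    lock: str
    condition: str | None
    window_ms: tuple[float, float]
    fs: float
    channel_labels: Sequence[str]

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("an ERP needs at least one trial")

    @property
    def lock_index(self) -> int:
        return -ms_to_samples(self.window_ms[0], self.fs)


LOCK_ALIASES = {"stimulus_onset": "stimulus_on"}


def extract_epochs(
    recording: Recording,
    lock: str,
    window_ms: tuple[float, float] = (-1000.0, 5000.0),
) -> EpochSet:
    """One epoch per event of the lock type; out-of-range trials dropped.

    The sample window is half-open: [event + round(w0*fs/1000),
    event + round(w1*fs/1000)).
    """
    lock = LOCK_ALIASES.get(lock, lock)
    events = recording.events_of_type(lock)
    off0 = ms_to_samples(window_ms[0], recording.fs)
    off1 = ms_to_samples(window_ms[1], recording.fs)
    n = recording.n_samples
    keep, trials, conds, reasons = [], [], [], []
    for e in events:
        start, stop = e.sample + off0, e.sample + off1
        if start < 0 or stop > n:
            reasons.append(
                f"trial {e.trial}: window [{start}, {stop}) outside recording"
            )
            continue
        keep.append((start, stop))
        trials.append(e.trial)
        conds.append(e.condition or "")
    if not events:
        warnings.warn(f"no events of type {lock!r}", stacklevel=2)
    data = (
        np.stack([recording.data[:, a:b] for a, b in keep])
        if keep else np.zeros((0, recording.n_channels, off1 - off0))
    )
    return EpochSet(
        data=data, lock=lock, window_ms=window_ms, fs=recording.fs,
        trial_ids=np.asarray(trials, dtype=int),
        conditions=np.asarray(conds, dtype=object),
        channel_labels=list(recording.channel_labels),
        n_dropped=len(reasons), drop_reasons=reasons,
    )


def stimulus_baselines(
    recording: Recording, trial_table: pd.DataFrame,
    baseline_window_ms: tuple[float, float] = (-1000.0, 0.0),
) -> dict[int, np.ndarray]:
    """Per-trial channel means over the prestimulus baseline window.

    The anchor is always the trial's stimulus onset, also for button-locked
    epochs.  Trials whose baseline window under-runs the recording are
    omitted (and will be dropped at correction time).
    """
    off0 = ms_to_samples(baseline_window_ms[0], recording.fs)
    off1 = ms_to_samples(baseline_window_ms[1], recording.fs)
    out: dict[int, np.ndarray] = {}
    for row in trial_table.itertuples(index=False):
        if pd.isna(row.stimulus_on):
            continue
        a, b = int(row.stimulus_on) + off0, int(row.stimulus_on) + off1
        if a < 0 or b > recording.n_samples or b <= a:
            continue
        out[int(row.trial)] = recording.data[:, a:b].mean(axis=1)
    return out


def baseline_correct(
    epochs: EpochSet, baselines: Mapping[int, np.ndarray]
) -> EpochSet:
    """Subtract each trial's prestimulus-anchored baseline mean per channel.

    Idempotent: an already-corrected EpochSet is returned unchanged.  Trials
    without an available baseline are dropped with a recorded reason.
    """
    if epochs.baseline_applied:
        return epochs
    have = np.array([int(t) in baselines for t in epochs.trial_ids])
    reasons = list(epochs.drop_reasons)
    for t in epochs.trial_ids[~have]:
        reasons.append(f"trial {int(t)}: no prestimulus baseline window")
    data = epochs.data[have].copy()
    if data.size:
        b = np.stack([baselines[int(t)] for t in epochs.trial_ids[have]])
        data -= b[:, :, None]
    return replace(
        epochs, data=data, trial_ids=epochs.trial_ids[have],
        conditions=epochs.conditions[have], baseline_applied=True,
        n_dropped=epochs.n_dropped + int((~have).sum()), drop_reasons=reasons,
    )


def average_erp(epochs: EpochSet, condition: str | None = None) -> ERP:
    """Pointwise mean over trials (optionally restricted to one condition)."""
    sel = epochs if condition is None else epochs.select(condition)
    if sel.n_trials == 0:
        raise ValueError(
            f"no trials to average (lock={epochs.lock}, condition={condition})"
        )
    return ERP(
        data=sel.data.mean(axis=0), n_trials=sel.n_trials, lock=epochs.lock,
        condition=condition, window_ms=epochs.window_ms, fs=epochs.fs,
        channel_labels=list(epochs.channel_labels),
    )


# ---------------------------------------------------------------------------
# Channel groups / analysis locations
# ---------------------------------------------------------------------------

def group_signal(
    data: np.ndarray, group_name: str, channel_labels: Sequence[str],
    groups: Mapping[str, Sequence[str]] = CHANNEL_GROUPS,
) -> np.ndarray:
    """Unweighted mean across the group's channels (virtual location).

    ``data`` may be channels x samples or trials x channels x samples; the
    channel axis is the second-to-last.
    """
    members = groups[group_name]
    index = {ch: i for i, ch in enumerate(channel_labels)}
    missing = [ch for ch in members if ch not in index]
    if missing:
        raise ValueError(f"group {group_name}: missing channels {missing}")
    rows = [index[ch] for ch in members]
    return np.take(data, rows, axis=-2).mean(axis=-2)


def expand_to_locations(
    data: np.ndarray, channel_labels: Sequence[str],
    groups: Mapping[str, Sequence[str]] = CHANNEL_GROUPS,
) -> tuple[np.ndarray, list[str]]:
    """Append the virtual group locations to the channel axis.

    With the full 24-channel montage this yields the 30 analysis locations.
    """
    virtual = np.stack(
        [group_signal(data, g, channel_labels, groups) for g in groups], axis=-2
    )
    out = np.concatenate([data, virtual], axis=-2)
    return out, list(channel_labels) + list(groups)
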