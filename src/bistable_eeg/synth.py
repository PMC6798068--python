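"""Synthetic bistable-perception EEG experiments with known ground truth.

A simulated session reproduces the trial grammar of the intermittent-
presentation paradigm: a fixation cross for a random 800-1300 ms, stimulus
onset (bistable condition c1 or unambiguous c2, exactly half of each test
block), an optional first button press (initial interpretation) and, in c1
trials only, an optional second press marking the perceptual reversal which
ends the trial; otherwise the trial times out at 5000 ms.  A session is 10
training trials followed by three 100-trial blocks (310 stimuli in total).

On top of a pink (1/f) or white noise background, the generator injects
Gaussian-windowed ERP components time-locked to chosen events and
band-limited oscillatory power modulations, each restricted to chosen
channels, conditions and participant groups, so downstream feature
extraction and statistics can be validated against known effects.

All randomness flows from a single integer seed; identical configurations
produce bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import fft as sp_fft
from scipy import signal

from .io import Event, Recording, trial_table_from_events, validate_trial_table
from .montage import MONTAGE_24

GROUPS = ("FD", "FN", "FI")
LOCKS = ("stimulus_on", "button1", "button2")

#: Fixed inter-trial structure (ms): blank gap, then the blink-reminder
#: screen.  Together with the >= 800 ms fixation this guarantees at least
#: 5000 ms between a trial's end and the next stimulus onset, so no
#: [-1000, +5000] ms epoch can reach the next trial's stimulus window.
GAP_MS = 1500.0
BLINK_MS = 2700.0
LEAD_IN_MS = 2000.0
TAIL_MS = 5200.0


class ConfigError(ValueError):
    """Invalid simulation configuration; the message names the field."""


@dataclass(frozen=True)
class ErpComponent:
    """A Gaussian-windowed ERP bump injected at every matching lock event.

    ``latency_ms`` is the bump center relative to the lock, ``width_ms`` the
    Gaussian SD, ``amplitude_uv`` the signed peak value.  ``channels`` maps
    channel label -> gain (a plain sequence means gain 1 everywhere); None
    targets the whole montage.
    """

    lock: str
    latency_ms: float
    width_ms: float
    amplitude_uv: float
    channels: Mapping[str, float] | Sequence[str] | None = None
    condition_scope: str = "both"  # c1 | c2 | both
    group_scope: str = "both"      # FD | FI | FN | both

    def channel_gains(self, montage: Sequence[str]) -> dict[str, float]:
        if self.channels is None:
            return {ch: 1.0 for ch in montage}
        if isinstance(self.channels, Mapping):
            gains = dict(self.channels)
        else:
            gains = {ch: 1.0 for ch in self.channels}
        unknown = set(gains) - set(montage)
        if unknown:
            raise ConfigError(f"erp_components: channels not in montage: {sorted(unknown)}")
        return gains


@dataclass(frozen=True)
class BandModulation:
    """A multiplicative band-power change over a window around a lock event.

    Implemented by adding a band-limited noise burst (100 ms cosine ramps)
    scaled so the band power over the window becomes ``power_gain`` times
    the background's expected power in ``band_hz``.  ``power_gain`` must be
    >= 1 (power can only be added to the background).
    """

    band_hz: tuple[float, float]
    lock: str
    window_ms: tuple[float, float]
    power_gain: float
    channels: Sequence[str] | None = None
    condition_scope: str = "both"
    group_scope: str = "both"


def _scope_matches(scope: str, value: str) -> bool:
    return scope == "both" or scope == value


@dataclass(frozen=True)
class SimConfig:
    """Full description of a simulated experiment cohort."""

    n_fd: int = 14
    n_fi: int = 7
    n_fn: int = 10
    fs: float = 500.0
    montage: tuple[str, ...] = MONTAGE_24
    n_training_trials: int = 10
    n_blocks: int = 3
    trials_per_block: int = 100
    p_c1: float = 0.5
    fixation_ms_range: tuple[float, float] = (800.0, 1300.0)
    timeout_ms: float = 5000.0
    #: (mean, sd) of the first-press latency; samples truncated to [300, 2000] ms
    rt1_ms: tuple[float, float] = (900.0, 250.0)
    #: (mean, sd) of the button1 -> button2 delay; truncated to [400, 2300] ms
    rt2_delta_ms: tuple[float, float] = (800.0, 300.0)
    p_press1: float = 0.95
    p_reversal_fd: float = 0.55
    p_reversal_fn: float = 0.65
    p_reversal_fi: float = 0.75
    noise_sigma_uv: float = 10.0
    noise_model: str = "pink"  # pink | white
    erp_components: tuple[ErpComponent, ...] = ()
    band_modulations: tuple[BandModulation, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_fd", "n_fi", "n_fn", "n_training_trials", "n_blocks",
                     "trials_per_block"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not 0.0 <= self.p_c1 <= 1.0:
            raise ConfigError("p_c1 must be in [0, 1]")
        lo, hi = self.fixation_ms_range
        if not (0 < lo <= hi < self.timeout_ms):
            raise ConfigError("fixation_ms_range must lie within (0, timeout_ms)")
        if self.fs <= 0:
            raise ConfigError("fs must be positive")
        if self.noise_model not in ("pink", "white"):
            raise ConfigError("noise_model must be 'pink' or 'white'")
        if self.noise_sigma_uv < 0:
            raise ConfigError("noise_sigma_uv must be >= 0")
        for p in ("p_press1", "p_reversal_fd", "p_reversal_fn", "p_reversal_fi"):
            if not 0.0 <= getattr(self, p) <= 1.0:
                raise ConfigError(f"{p} must be in [0, 1]")
        if len(set(self.montage)) != len(self.montage):
            raise ConfigError("montage contains duplicate labels")
        epoch_lo, epoch_hi = -1000.0, 5000.0
        for c in self.erp_components:
            if c.lock not in LOCKS:
                raise ConfigError(f"erp_components: unknown lock {c.lock!r}")
            if c.width_ms <= 0:
                raise ConfigError("erp_components: width_ms must be > 0")
            if not epoch_lo <= c.latency_ms <= epoch_hi:
                raise ConfigError(
                    "erp_components: latency_ms outside the epoch window"
                )
            c.channel_gains(self.montage)
        for m in self.band_modulations:
            if m.lock not in LOCKS:
                raise ConfigError(f"band_modulations: unknown lock {m.lock!r}")
            lo_f, hi_f = m.band_hz
            if not 0 < lo_f < hi_f < self.fs / 2:
                raise ConfigError("band_modulations: band must satisfy 0 < low < high < fs/2")
            if m.power_gain < 1.0:
                raise ConfigError("band_modulations: power_gain must be >= 1")
            if m.channels is not None and set(m.channels) - set(self.montage):
                raise ConfigError("band_modulations: channels not in montage")

    @property
    def reversal_probs(self) -> dict[str, float]:
        return {"FD": self.p_reversal_fd, "FN": self.p_reversal_fn,
                "FI": self.p_reversal_fi}

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=1, default=list)


@dataclass
class GroundTruth:
    """What was actually planted in a simulated participant."""

    participant_id: str
    group: str
    seed_key: tuple[int, int]
    trials: pd.DataFrame
    components: list[dict]
    modulations: list[dict]


@dataclass
class ParticipantBundle:
    participant_id: str
    group: str
    recording: Recording
    trial_table: pd.DataFrame
    ground_truth: GroundTruth


# ---------------------------------------------------------------------------
# Noise background
# ---------------------------------------------------------------------------

_PINK_FLOOR_HZ = 1.0


def _noise_shaping(n: int, fs: float, model: str) -> np.ndarray:
    """Amplitude shaping over the rfft grid for the background noise."""
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    if model == "white":
        amp = np.ones_like(freqs)
    else:  # pink: 1/sqrt(f) with a flat floor below 1 Hz
        amp = 1.0 / np.sqrt(np.maximum(freqs, _PINK_FLOOR_HZ))
    amp[0] = 0.0  # no DC
    return amp


def _background_noise(
    rng: np.random.Generator, n_channels: int, n: int, fs: float,
    sigma: float, model: str,
) -> np.ndarray:
    if sigma == 0.0 or n == 0:
        return np.zeros((n_channels, n))
    # synthesize at an FFT-friendly length and truncate (stationary noise,
    # so truncation does not bias the spectrum)
    nfast = sp_fft.next_fast_len(n, real=True)
    amp = _noise_shaping(nfast, fs, model)
    spec = amp * (
        rng.standard_normal((n_channels, amp.size))
        + 1j * rng.standard_normal((n_channels, amp.size))
    )
    x = sp_fft.irfft(spec, n=nfast, axis=1)[:, :n]
    std = x.std(axis=1, keepdims=True)
    std[std == 0] = 1.0
    return x * (sigma / std)


def noise_band_fraction(config: SimConfig, band_hz: tuple[float, float],
                        n: int = 2 ** 16) -> float:
    """Fraction of the background noise variance inside ``band_hz``.

    Exact for the spectral shaping used by the generator (the per-channel
    empirical normalization preserves the spectral shape in expectation).
    """
    amp = _noise_shaping(n, config.fs, config.noise_model)
    freqs = np.fft.rfftfreq(n, 1.0 / config.fs)
    power = amp ** 2
    total = power.sum()
    in_band = power[(freqs >= band_hz[0]) & (freqs <= band_hz[1])].sum()
    return float(in_band / total)


# ---------------------------------------------------------------------------
# Trial schedule
# ---------------------------------------------------------------------------

def _block_conditions(rng: np.random.Generator, n: int, p_c1: float) -> list[str]:
    """Exact stratified c1/c2 assignment: round(p_c1 * n) c1 trials, shuffled."""
    n_c1 = int(round(p_c1 * n))
    conds = ["c1"] * n_c1 + ["c2"] * (n - n_c1)
    perm = rng.permutation(n)
    return [conds[i] for i in perm]


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               lo: float, hi: float) -> float:
    for _ in range(64):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return float(v)
    return float(min(max(mean, lo), hi))


def _simulate_schedule(
    config: SimConfig, group: str, rng: np.random.Generator
) -> pd.DataFrame:
    """Sample the event schedule (in samples) for one participant."""
    fs = config.fs
    ms = fs / 1000.0
    p_rev = config.reversal_probs[group]
    rows = []
    cursor = LEAD_IN_MS * ms
    trial = 0
    blocks: list[tuple[int, list[str]]] = []
    if config.n_training_trials:
        # training alternates the two pre-selected images (c1, c2, c1, ...)
        train = ["c1" if i % 2 == 0 else "c2" for i in range(config.n_training_trials)]
        blocks.append((0, train))
    for b in range(config.n_blocks):
        blocks.append((b + 1, _block_conditions(rng, config.trials_per_block, config.p_c1)))
    for block, conds in blocks:
        for cond in conds:
            fix_on = int(round(cursor))
            fix_dur = rng.uniform(*config.fixation_ms_range) * ms
            stim_on = int(round(cursor + fix_dur))
            b1 = b2 = None
            if rng.random() < config.p_press1:
                rt1 = _truncnorm(rng, *config.rt1_ms, 300.0, 2000.0)
                b1 = stim_on + int(round(rt1 * ms))
                if cond == "c1" and rng.random() < p_rev:
                    delta = _truncnorm(rng, *config.rt2_delta_ms, 400.0, 2300.0)
                    b2 = b1 + int(round(delta * ms))
            end = b2 if b2 is not None else stim_on + int(round(config.timeout_ms * ms))
            rows.append({
                "trial": trial, "block": block, "condition": cond,
                "fixation_on": fix_on, "stimulus_on": stim_on,
                "button1": b1 if b1 is not None else pd.NA,
                "button2": b2 if b2 is not None else pd.NA,
                "trial_end": end,
            })
            cursor = end + (GAP_MS + BLINK_MS) * ms
            trial += 1
    table = pd.DataFrame(rows)
    for col in ("fixation_on", "stimulus_on", "button1", "button2", "trial_end"):
        table[col] = table[col].astype("Int64")
    validate_trial_table(table)
    return table


def _events_from_table(table: pd.DataFrame) -> list[Event]:
    events: list[Event] = []
    for row in table.itertuples(index=False):
        cond = row.condition
        events.append(Event(int(row.fixation_on), "fixation_on", int(row.trial), cond))
        events.append(Event(int(row.stimulus_on), "stimulus_on", int(row.trial), cond))
        if pd.notna(row.button1):
            events.append(Event(int(row.button1), "button1", int(row.trial), cond))
        if pd.notna(row.button2):
            events.append(Event(int(row.button2), "button2", int(row.trial), cond))
        events.append(Event(int(row.trial_end), "trial_end", int(row.trial), cond))
    events.sort(key=lambda e: (e.sample, e.type))
    return events


# ---------------------------------------------------------------------------
# Effect injection
# ---------------------------------------------------------------------------

def erp_component_waveform(comp: ErpComponent, fs: float) -> tuple[np.ndarray, int]:
    """The analytic bump on a +-4 SD support grid.

    Returns (waveform, offset) where ``offset`` is the sample index of the
    waveform start relative to the lock event.
    """
    ms = fs / 1000.0
    half = int(np.ceil(4.0 * comp.width_ms * ms))
    center = int(round(comp.latency_ms * ms))
    idx = np.arange(-half, half + 1)
    t_ms = (center + idx) / ms
    wave = comp.amplitude_uv * np.exp(
        -0.5 * ((t_ms - comp.latency_ms) / comp.width_ms) ** 2
    )
    return wave, center - half


def _inject_components(
    data: np.ndarray, config: SimConfig, group: str, table: pd.DataFrame,
) -> list[dict]:
    realized = []
    ch_index = {ch: i for i, ch in enumerate(config.montage)}
    for comp in config.erp_components:
        if not _scope_matches(comp.group_scope, group):
            continue
        wave, offset = erp_component_waveform(comp, config.fs)
        gains = comp.channel_gains(config.montage)
        locks = []
        for row in table.itertuples(index=False):
            if not _scope_matches(comp.condition_scope, row.condition):
                continue
            lock_sample = getattr(row, comp.lock)
            if pd.isna(lock_sample):
                continue
            start = int(lock_sample) + offset
            stop = start + wave.size
            w0 = max(0, -start)
            w1 = wave.size - max(0, stop - data.shape[1])
            if w1 <= w0:
                continue
            seg = slice(start + w0, start + w1)
            for ch, g in gains.items():
                data[ch_index[ch], seg] += g * wave[w0:w1]
            locks.append(int(lock_sample))
        realized.append({**asdict(comp), "n_events": len(locks)})
    return realized


_RAMP_MS = 100.0


def _burst(
    rng: np.random.Generator, n: int, fs: float, band_hz: tuple[float, float],
    target_var: float,
) -> np.ndarray:
    """Band-limited noise burst with cosine ramps and exact window power."""
    lo, hi = band_hz
    # generation band inset by 1 Hz so transition-band leakage stays inside
    # the measured band
    g_lo, g_hi = lo + 1.0, hi - 1.0
    if g_hi <= g_lo:
        g_lo, g_hi = lo, hi
    taps = min(2 * (n // 4) + 1, 301)
    taps = max(taps, 31)
    h = signal.firwin(taps, [g_lo, g_hi], fs=fs, pass_zero=False, window="hamming")
    x = signal.fftconvolve(rng.standard_normal(n + taps), h, mode="same")[
        taps // 2: taps // 2 + n
    ]
    ramp = int(round(_RAMP_MS * fs / 1000.0))
    if 2 * ramp < n and ramp > 0:
        env = np.ones(n)
        r = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
        env[:ramp] = r
        env[-ramp:] = r[::-1]
        x = x * env
    p = float(np.mean(x ** 2))
    if p > 0:
        x *= np.sqrt(target_var / p)
    return x


def _inject_modulations(
    data: np.ndarray, config: SimConfig, group: str, table: pd.DataFrame,
    rng: np.random.Generator,
) -> list[dict]:
    realized = []
    ch_index = {ch: i for i, ch in enumerate(config.montage)}
    ms = config.fs / 1000.0
    for mod in config.band_modulations:
        if not _scope_matches(mod.group_scope, group):
            continue
        base_power = config.noise_sigma_uv ** 2 * noise_band_fraction(config, mod.band_hz)
        target_var = (mod.power_gain - 1.0) * base_power
        channels = mod.channels if mod.channels is not None else config.montage
        n_events = 0
        for row in table.itertuples(index=False):
            if not _scope_matches(mod.condition_scope, row.condition):
                continue
            lock_sample = getattr(row, mod.lock)
            if pd.isna(lock_sample):
                continue
            start = int(lock_sample) + int(round(mod.window_ms[0] * ms))
            stop = int(lock_sample) + int(round(mod.window_ms[1] * ms))
            start, stop = max(0, start), min(data.shape[1], stop)
            if stop - start < 8:
                continue
            n_events += 1
            for ch in channels:
                data[ch_index[ch], start:stop] += _burst(
                    rng, stop - start, config.fs, mod.band_hz, target_var
                )
        realized.append({
            "band_hz": list(mod.band_hz), "lock": mod.lock,
            "window_ms": list(mod.window_ms), "power_gain": mod.power_gain,
            "channels": list(channels), "condition_scope": mod.condition_scope,
            "group_scope": mod.group_scope, "n_events": n_events,
        })
    return realized


# ---------------------------------------------------------------------------
# Public generators
# ---------------------------------------------------------------------------

def participant_seed(config_seed: int, index: int) -> np.random.SeedSequence:
    """Deterministic per-participant seed, independent of cohort makeup."""
    return np.random.SeedSequence((int(config_seed), int(index)))


def generate_participant(
    config: SimConfig,
    participant_id: str,
    group: str,
    seed: int | np.random.SeedSequence,
) -> tuple[Recording, pd.DataFrame, GroundTruth]:
    """Simulate one participant's full session.

    Returns the continuous recording (with its event stream), the trial
    table, and the realized ground truth.
    """
    if group not in GROUPS:
        raise ConfigError(f"group must be one of {GROUPS}, got {group!r}")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(int(seed))
    rng_sched, rng_noise, rng_mod = (
        np.random.default_rng(s) for s in ss.spawn(3)
    )
    table = _simulate_schedule(config, group, rng_sched)
    n_samples = int(table["trial_end"].max()) + int(round(TAIL_MS * config.fs / 1000.0))
    data = _background_noise(
        rng_noise, len(config.montage), n_samples, config.fs,
        config.noise_sigma_uv, config.noise_model,
    )
    comps = _inject_components(data, config, group, table)
    mods = _inject_modulations(data, config, group, table, rng_mod)
    events = _events_from_table(table)
    recording = Recording(
        data=data,
        fs=config.fs,
        channel_labels=list(config.montage),
        events=events,
        participant_id=participant_id,
        metadata={"reference": "FCz", "ground": "Fpz", "group": group},
    )
    gt = GroundTruth(
        participant_id=participant_id,
        group=group,
        seed_key=(config.seed, -1),
        trials=table,
        components=comps,
        modulations=mods,
    )
    return recording, table, gt


def cohort_plan(config: SimConfig) -> list[tuple[str, str]]:
    """(participant_id, group) pairs: FD first, then FI, then FN."""
    plan = []
    i = 1
    for group, n in (("FD", config.n_fd), ("FI", config.n_fi), ("FN", config.n_fn)):
        for _ in range(n):
            plan.append((f"P{i:02d}", group))
            i += 1
    return plan


def iter_cohort(config: SimConfig) -> Iterator[ParticipantBundle]:
    """Lazily generate the cohort (one participant in memory at a time)."""
    plan = cohort_plan(config)
    if not plan:
        raise ConfigError("n_fd + n_fi + n_fn must be >= 1")
    for index, (pid, group) in enumerate(plan):
        ss = participant_seed(config.seed, index)
        rec, table, gt = generate_participant(config, pid, group, ss)
        gt.seed_key = (config.seed, index)
        yield ParticipantBundle(pid, group, rec, table, gt)


def generate_cohort(config: SimConfig) -> list[ParticipantBundle]:
    """Generate the whole cohort as a list (small configurations only)."""
    return list(iter_cohort(config))


# ---------------------------------------------------------------------------
# HFT item responses
# ---------------------------------------------------------------------------

def generate_hft_responses(
    config: SimConfig | None,
    group_abilities: Sequence[float],
    n_items: int = 32,
    seed: int | np.random.SeedSequence = 0,
    item_difficulty: Sequence[float] | None = None,
    parallel_inter_item_r: float | None = None,
    p_blank: float = 0.0,
) -> np.ndarray:
    """Generate a participants x items response matrix.

    Entries are ``1`` (correct), ``-1`` (incorrect) or ``0`` (blank).  Two
    regimes:

    * default 2-parameter model: P(correct) = ability ** difficulty with
      per-item difficulty exponents (1 = neutral), independent draws given
      ability;
    * ``parallel_inter_item_r=r``: exchangeable items whose realized 0/1
      scores have inter-item correlation ~ r, via a Gaussian one-factor
      model thresholded at 0 with loading ``sin(pi r / 2)`` (the arcsine
      law inverted at p = 1/2).  Abilities shift the factor mean so group
      differences survive.
    """
    if n_items % 2:
        raise ConfigError("n_items must be even (two equal test parts)")
    abilities = np.asarray(group_abilities, dtype=float)
    if abilities.size and (abilities.min() < 0 or abilities.max() > 1):
        raise ConfigError("abilities must lie in [0, 1]")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(int(seed))
    rng = np.random.default_rng(ss)
    n = abilities.size
    if parallel_inter_item_r is not None:
        r = parallel_inter_item_r
        if not 0.0 <= r < 1.0:
            raise ConfigError("parallel_inter_item_r must be in [0, 1)")
        rho = np.sin(np.pi * r / 2.0)
        shift = 2.0 * (abilities - 0.5)  # ability 0.5 -> P(correct) = 0.5
        factor = rng.standard_normal((n, 1))
        eps = rng.standard_normal((n, n_items))
        z = np.sqrt(rho) * factor + np.sqrt(1 - rho) * eps + shift[:, None]
        correct = z > 0.0
    else:
        diff = (np.ones(n_items) if item_difficulty is None
                else np.asarray(item_difficulty, dtype=float))
        if diff.size != n_items:
            raise ConfigError("item_difficulty length must equal n_items")
        if (diff <= 0).any():
            raise ConfigError("item_difficulty exponents must be > 0")
        p = abilities[:, None] ** diff[None, :]
        correct = rng.random((n, n_items)) < p
    out = np.where(correct, 1, -1).astype(np.int8)
    if p_blank > 0:
        out[rng.random((n, n_items)) < p_blank] = 0
    return out


# ---------------------------------------------------------------------------
# Ready-made effect sets
# ---------------------------------------------------------------------------

#: Default per-group HFT ability centers (FD lowest, FI highest).  The
#: separation is sized so that a tertile split on the 32-item penalized
#: score recovers planted FD/FI labels with >= 90% agreement (the
#: generator's documented recovery property) despite the ~5-point binomial
#: score noise of a 32-item instrument.
GROUP_ABILITY = {"FD": 0.25, "FN": 0.55, "FI": 0.85}
GROUP_ABILITY_SD = 0.05


def sample_group_abilities(
    groups: Sequence[str], seed: int | np.random.SeedSequence = 0
) -> np.ndarray:
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(int(seed))
    rng = np.random.default_rng(ss)
    means = np.array([GROUP_ABILITY[g] for g in groups])
    return np.clip(rng.normal(means, GROUP_ABILITY_SD), 0.0, 1.0)


def standard_components(montage: Sequence[str] = MONTAGE_24,
                        c1_boost: float = 1.25) -> tuple[ErpComponent, ...]:
    """The study-like component set: the four post-onset deflections plus a
    reversal positivity before the second press.

    Components are placed mid-window; c1 amplitudes are ``c1_boost`` times
    the c2 amplitudes (set ``c1_boost=1`` for a condition-null session).
    """
    posterior = [ch for ch in ("P3", "P4", "Pz", "O1", "O2", "CPz") if ch in montage]
    frontal = [ch for ch in ("Fp1", "Fp2", "Fz", "FC1", "FC2") if ch in montage]
    broad = list(montage)
    out: list[ErpComponent] = []
    for cond, scale in (("c1", c1_boost), ("c2", 1.0)):
        out += [
            ErpComponent("stimulus_on", 150.0, 18.0, 4.0 * scale,
                         posterior or broad, cond),
            ErpComponent("stimulus_on", 240.0, 22.0, -3.0 * scale, broad, cond),
            ErpComponent("stimulus_on", 340.0, 35.0, 2.0 * scale,
                         (frontal + posterior) or broad, cond),
            ErpComponent("stimulus_on", 500.0, 55.0, 1.5 * scale,
                         posterior or broad, cond),
        ]
    out.append(ErpComponent("button2", -250.0, 28.0, 2.0 * c1_boost,
                            posterior or broad, "c1"))
    return tuple(out)


def planted_gamma_modulation(
    channels: Sequence[str] = ("T8", "CP6", "TP10"), power_gain: float = 2.0
) -> BandModulation:
    """The FD-only pre-reversal gamma effect used in power studies."""
    return BandModulation(
        band_hz=(26.0, 60.0), lock="button2", window_ms=(-1000.0, 0.0),
        power_gain=power_gain, channels=tuple(channels),
        condition_scope="c1", group_scope="FD",
    )


def null_config(**overrides) -> SimConfig:
    """A cohort in which c1 and c2 are generated identically (all effect
    scopes 'both'); used for false-positive-rate studies."""
    base = dict(
        erp_components=tuple(
            replace(c, condition_scope="both")
            for c in standard_components(overrides.get("montage", MONTAGE_24), 1.0)
            if c.lock == "stimulus_on"
        ),
    )
    base.update(overrides)
    return SimConfig(**base)
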