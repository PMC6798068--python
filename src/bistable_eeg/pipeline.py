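"""End-to-end orchestration: recording -> feature table -> comparisons.

`participant_features` turns one continuous recording plus its trial table
into long-format feature rows (12 features x 30 locations x contexts);
`cohort_feature_table` maps it over a simulated cohort one participant at a
time.  The stimulus-locked features are computed per condition (contexts
``c1``/``c2``); the pre-button features are computed for the first- and
second-press epochs of bistable trials (contexts ``b1``/``b2``).
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .erp_features import DEFAULT_NEIGHBORHOOD_MS, erp_peak_features
from .features_spec import BUTTON_FEATURES, ONSET_FEATURES
from .io import Recording
from .preprocess import (
    EpochSet,
    FilterSpec,
    average_erp,
    baseline_correct,
    expand_to_locations,
    extract_epochs,
    filter_recording,
    stimulus_baselines,
)
from .spectral_features import spectral_feature
from .synth import ParticipantBundle, SimConfig, iter_cohort

#: A participant contributes a feature only if at least this many trials
#: underlie the relevant average (configurable; the source protocols state
#: no minimum).
MIN_TRIALS_DEFAULT = 5

EPOCH_WINDOW_MS = (-1000.0, 5000.0)


def _expand(epochs: EpochSet) -> EpochSet:
    data, labels = expand_to_locations(epochs.data, epochs.channel_labels)
    out = EpochSet(
        data=data, lock=epochs.lock, window_ms=epochs.window_ms, fs=epochs.fs,
        trial_ids=epochs.trial_ids, conditions=epochs.conditions,
        channel_labels=labels, baseline_applied=epochs.baseline_applied,
        n_dropped=epochs.n_dropped, drop_reasons=list(epochs.drop_reasons),
    )
    return out


def participant_features(
    recording: Recording,
    trial_table: pd.DataFrame,
    participant_id: str,
    group: str,
    filter_spec: FilterSpec = FilterSpec(),
    min_trials: int = MIN_TRIALS_DEFAULT,
    neighborhood_ms: float = DEFAULT_NEIGHBORHOOD_MS,
    exclude_training: bool = True,
) -> pd.DataFrame:
    """All 12 features at all analysis locations for one participant.

    Returns long-format rows (participant, group, context, location,
    feature, value, n_trials, aux_linear); combinations whose underlying
    trial count falls below ``min_trials`` are emitted with NaN value, not
    silently skipped.
    """
    filtered = filter_recording(recording, filter_spec)
    if exclude_training and "block" in trial_table.columns:
        test_trials = set(trial_table.loc[trial_table["block"] > 0, "trial"])
        filtered.events = [e for e in filtered.events if e.trial in test_trials]
        trial_table = trial_table[trial_table["block"] > 0]
    baselines = stimulus_baselines(filtered, trial_table)

    # baseline-correct on the 24 electrodes, then append the virtual group
    # locations (the two operations are linear, so the order is immaterial)
    onset_raw = _expand(extract_epochs(filtered, "stimulus_on", EPOCH_WINDOW_MS))
    onset = _expand(
        baseline_correct(extract_epochs(filtered, "stimulus_on", EPOCH_WINDOW_MS),
                         baselines)
    )
    b1 = _expand(
        baseline_correct(extract_epochs(filtered, "button1", EPOCH_WINDOW_MS),
                         baselines)
    )
    b2 = _expand(
        baseline_correct(extract_epochs(filtered, "button2", EPOCH_WINDOW_MS),
                         baselines)
    )
    locations = onset.channel_labels

    rows: list[dict] = []

    def emit(context: str, feature_id: int, values, n_trials: int, aux=None):
        vals = values if values is not None else [np.nan] * len(locations)
        auxs = aux if aux is not None else [np.nan] * len(locations)
        for loc, v, a in zip(locations, vals, auxs):
            rows.append({
                "participant": participant_id, "group": group,
                "context": context, "location": loc, "feature": feature_id,
                "value": float(v), "n_trials": n_trials,
                "aux_linear": float(a),
            })

    # stimulus-locked features, per condition
    for cond in ("c1", "c2"):
        sel = onset.select(cond)
        n = sel.n_trials
        erp = average_erp(sel) if n >= max(min_trials, 1) else None
        for spec in ONSET_FEATURES:
            if spec.kind == "band_power":
                raw_sel = onset_raw.select(cond)  # no baseline branch
                if raw_sel.n_trials >= min_trials:
                    db, lin = spectral_feature(raw_sel, spec)
                    emit(cond, spec.id, db, raw_sel.n_trials, lin)
                else:
                    emit(cond, spec.id, None, raw_sel.n_trials)
            else:
                if erp is None:
                    emit(cond, spec.id, None, n)
                    continue
                peaks = erp_peak_features(erp, spec, neighborhood_ms)
                vals = [
                    p.amplitude_uv if spec.kind == "peak_amplitude" else p.latency_ms
                    for p in peaks
                ]
                emit(cond, spec.id, vals, n)

    # pre-button features, bistable condition only
    for context, epochs in (("b1", b1), ("b2", b2)):
        sel = epochs.select("c1")
        n = sel.n_trials
        for spec in BUTTON_FEATURES:
            if n < min_trials:
                emit(context, spec.id, None, n)
                continue
            if spec.kind == "band_power":
                db, lin = spectral_feature(sel, spec)
                emit(context, spec.id, db, n, lin)
            else:
                erp = average_erp(sel)
                peaks = erp_peak_features(erp, spec, neighborhood_ms)
                vals = [
                    p.amplitude_uv if spec.kind == "peak_amplitude" else p.latency_ms
                    for p in peaks
                ]
                emit(context, spec.id, vals, n)

    return pd.DataFrame(rows)


def cohort_feature_table(
    bundles: Iterable[ParticipantBundle],
    filter_spec: FilterSpec = FilterSpec(),
    min_trials: int = MIN_TRIALS_DEFAULT,
) -> pd.DataFrame:
    """Feature table for a whole cohort (participants processed lazily)."""
    parts = [
        participant_features(
            b.recording, b.trial_table, b.participant_id, b.group,
            filter_spec=filter_spec, min_trials=min_trials,
        )
        for b in bundles
    ]
    return pd.concat(parts, ignore_index=True)


def simulate_and_extract(
    config: SimConfig,
    filter_spec: FilterSpec = FilterSpec(),
    min_trials: int = MIN_TRIALS_DEFAULT,
) -> pd.DataFrame:
    """Convenience: simulate the cohort of ``config`` and extract features."""
    return cohort_feature_table(
        iter_cohort(config), filter_spec=filter_spec, min_trials=min_trials
    )
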