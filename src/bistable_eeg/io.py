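"""Reading and writing the formats the pipeline touches.

Continuous recordings travel either as EDF+C files (16-bit, physical units
microvolt, events stored as EDF+ annotations) or as the package's internal
triplet ``<stem>.data.npy`` + ``<stem>.meta.json`` + ``<stem>.events.tsv``.
Event tables are TSV, feature and result tables are CSV.

Sample indexing is 0-based everywhere; an event's time in seconds is
``sample / fs``.
"""

from __future__ import annotations

import csv
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

EVENT_TYPES = ("fixation_on", "stimulus_on", "button1", "button2", "trial_end")
CONDITIONS = ("c1", "c2")


class FormatError(ValueError):
    """Raised when an on-disk file cannot be interpreted."""


@dataclass(frozen=True)
class Event:
    """A single marker in the continuous recording.

    Parameters
    ----------
    sample : int
        0-based sample index into the recording.
    type : str
        One of ``fixation_on, stimulus_on, button1, button2, trial_end``.
    trial : int
        Trial number the event belongs to (0-based, training included).
    condition : str or None
        ``"c1"`` (bistable) or ``"c2"`` (unambiguous); None if not applicable.
    """

    sample: int
    type: str
    trial: int
    condition: str | None = None

    def __post_init__(self) -> None:
        if self.type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.type!r}")
        if self.trial < 0:
            raise ValueError("trial must be >= 0")
        if self.condition is not None and self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")


@dataclass
class Recording:
    """Continuous multichannel EEG in microvolts.

    ``data`` is channels x samples; ``channel_labels`` names the rows.
    """

    data: np.ndarray
    fs: float
    channel_labels: Sequence[str]
    events: list[Event] = field(default_factory=list)
    participant_id: str | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"data has {self.data.shape[0]} rows but "
                f"{len(self.channel_labels)} channel labels"
            )
        n = self.data.shape[1]
        for ev in self.events:
            if not 0 <= ev.sample < n:
                raise ValueError(
                    f"event sample {ev.sample} outside recording [0, {n})"
                )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def events_of_type(self, type: str) -> list[Event]:
        return [e for e in self.events if e.type == type]


# ---------------------------------------------------------------------------
# Event TSV
# ---------------------------------------------------------------------------

_TSV_HEADER = ["trial", "sample", "type", "condition"]


def write_events_tsv(events: Iterable[Event], path: str | Path) -> None:
    """Write events as a 4-column TSV sorted by sample index."""
    rows = sorted(events, key=lambda e: (e.sample, e.type))
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_TSV_HEADER)
        for e in rows:
            w.writerow([e.trial, e.sample, e.type, e.condition or ""])


def read_events_tsv(path: str | Path) -> list[Event]:
    """Read an event TSV; rows are returned sorted by sample.

    Raises :class:`FormatError` naming the offending line number on a
    malformed row.
    """
    events: list[Event] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration as exc:  # completely empty file
            raise FormatError(f"{path}: empty file, expected header") from exc
        if [h.strip() for h in header] != _TSV_HEADER:
            raise FormatError(
                f"{path}:1: expected header {_TSV_HEADER}, got {header}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 fields, got {len(row)}")
            try:
                events.append(
                    Event(
                        trial=int(row[0]),
                        sample=int(row[1]),
                        type=row[2],
                        condition=row[3] or None,
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    events.sort(key=lambda e: (e.sample, e.type))
    return events


# ---------------------------------------------------------------------------
# Trial tables
# ---------------------------------------------------------------------------

TRIAL_COLUMNS = [
    "trial", "block", "condition", "fixation_on", "stimulus_on",
    "button1", "button2", "trial_end",
]


def trial_table_from_events(events: Iterable[Event]) -> pd.DataFrame:
    """Assemble a per-trial table from an event stream.

    One row per trial with the sample index of each event type; missing
    button presses are <NA>.  ``block`` is left at -1 (unknown) here; the
    simulator fills it in.
    """
    per_trial: dict[int, dict] = {}
    for e in sorted(events, key=lambda ev: ev.sample):
        row = per_trial.setdefault(
            e.trial,
            {"trial": e.trial, "block": -1, "condition": None,
             "fixation_on": pd.NA, "stimulus_on": pd.NA,
             "button1": pd.NA, "button2": pd.NA, "trial_end": pd.NA},
        )
        row[e.type] = e.sample
        if e.condition is not None:
            row["condition"] = e.condition
    table = pd.DataFrame(
        [per_trial[t] for t in sorted(per_trial)], columns=TRIAL_COLUMNS
    )
    for col in ("fixation_on", "stimulus_on", "button1", "button2", "trial_end"):
        table[col] = table[col].astype("Int64")
    validate_trial_table(table)
    return table


def validate_trial_table(table: pd.DataFrame) -> None:
    """Check the trial-table invariants.

    button2 present implies button1 present and earlier; c2 trials never
    carry a button2.
    """
    has_b2 = table["button2"].notna()
    if (has_b2 & table["button1"].isna()).any():
        raise ValueError("trial with button2 but no button1")
    both = has_b2 & table["button1"].notna()
    if (table.loc[both, "button1"] >= table.loc[both, "button2"]).any():
        raise ValueError("button1 must precede button2")
    if (has_b2 & (table["condition"] == "c2")).any():
        raise ValueError("c2 trial carries a button2 event")


# ---------------------------------------------------------------------------
# EDF+ writing (16-bit EDF+C with an annotations channel)
# ---------------------------------------------------------------------------

_EDF_DIG_MAX = 32767  # symmetric digital range +-32767 keeps zero exact


def _edf_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} chars")
    return s.ljust(width).encode("ascii")


def _format_phys(v: float) -> str:
    s = f"{v:.8g}"
    if len(s) > 8:
        s = f"{v:.3g}"
    return s[:8]


def _event_annotation(e: Event, fs: float) -> str:
    cond = e.condition or ""
    return f"+{e.sample / fs:.4f}\x14{e.type}|{e.trial}|{cond}\x14\x00"


def write_edf(recording: Recording, path: str | Path) -> None:
    """Write an EDF+C file with one annotations channel.

    The physical range is chosen symmetric to cover the observed amplitude,
    giving a quantization step of at most ``range / 2**16`` microvolts
    (<= 0.1 uV whenever amplitudes stay below ~3.2 mV).  Data are never
    clipped; non-finite samples are an error.
    """
    data = np.asarray(recording.data, dtype=np.float64)
    if not np.isfinite(data).all():
        raise ValueError("recording contains non-finite samples; not representable")
    fs = recording.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs_i = int(round(fs))

    maxabs = float(np.max(np.abs(data))) if data.size else 0.0
    phys_max = max(1.0, math.ceil(maxabs * 1.01))
    step = phys_max / _EDF_DIG_MAX
    digital = np.rint(data / step).astype(np.int64)
    digital = np.clip(digital, -_EDF_DIG_MAX, _EDF_DIG_MAX).astype("<i2")

    n_rec = max(1, math.ceil(recording.n_samples / fs_i))
    # annotations grouped into the 1 s record containing each event
    rec_tals: list[bytes] = []
    by_record: dict[int, list[str]] = {}
    for e in sorted(recording.events, key=lambda ev: ev.sample):
        by_record.setdefault(e.sample // fs_i, []).append(
            _event_annotation(e, fs)
        )
    for r in range(n_rec):
        tal = f"+{r}\x14\x14\x00" + "".join(by_record.get(r, []))
        rec_tals.append(tal.encode("utf-8"))
    ann_bytes = max(len(b) for b in rec_tals) + 2
    ann_samples = math.ceil(ann_bytes / 2)

    n_ch = recording.n_channels
    ns = n_ch + 1
    header_bytes = 256 * (ns + 1)
    pid = (recording.participant_id or "X").replace(" ", "_")

    with open(path, "wb") as fh:
        fh.write(_edf_field("0", 8))
        fh.write(_edf_field(f"{pid} X X X", 80))
        fh.write(_edf_field("Startdate 01-JAN-2000 X X X", 80))
        fh.write(_edf_field("01.01.00", 8))
        fh.write(_edf_field("00.00.00", 8))
        fh.write(_edf_field(header_bytes, 8))
        fh.write(_edf_field("EDF+C", 44))
        fh.write(_edf_field(n_rec, 8))
        fh.write(_edf_field(1, 8))  # record duration, seconds
        fh.write(_edf_field(ns, 4))

        labels = [str(l) for l in recording.channel_labels] + ["EDF Annotations"]
        for lab in labels:
            fh.write(_edf_field(lab[:16], 16))
        for _ in labels:
            fh.write(_edf_field("", 80))  # transducer
        for i in range(ns):
            fh.write(_edf_field("uV" if i < n_ch else "", 8))
        for i in range(ns):
            fh.write(_edf_field(_format_phys(-phys_max) if i < n_ch else -32768, 8))
        for i in range(ns):
            fh.write(_edf_field(_format_phys(phys_max) if i < n_ch else 32767, 8))
        for i in range(ns):
            fh.write(_edf_field(-_EDF_DIG_MAX if i < n_ch else -32768, 8))
        for _ in range(ns):
            fh.write(_edf_field(_EDF_DIG_MAX, 8))
        for _ in range(ns):
            fh.write(_edf_field("", 80))  # prefiltering
        for i in range(ns):
            fh.write(_edf_field(fs_i if i < n_ch else ann_samples, 8))
        for _ in range(ns):
            fh.write(_edf_field("", 32))

        pad_len = n_rec * fs_i - recording.n_samples
        if pad_len:
            digital = np.pad(digital, ((0, 0), (0, pad_len)))
        for r in range(n_rec):
            fh.write(digital[:, r * fs_i:(r + 1) * fs_i].tobytes())
            ann = rec_tals[r].ljust(ann_samples * 2, b"\x00")
            fh.write(ann)


def default_label_parser(description: str) -> Event | None:
    """Parse this package's own ``type|trial|condition`` annotation format."""
    parts = description.split("|")
    if len(parts) != 3 or parts[0] not in EVENT_TYPES:
        return None
    return Event(
        sample=0, type=parts[0], trial=int(parts[1]), condition=parts[2] or None
    )


def read_edf(
    path: str | Path,
    label_map: Callable[[str], Event | None] | dict[str, str] | None = None,
    strict: bool = False,
) -> Recording:
    """Read an EDF(+) file via MNE and map annotations to events.

    ``label_map`` may be a callable returning an :class:`Event` template
    (its ``sample`` field is ignored) or ``None`` for unmapped labels, or a
    dict mapping foreign annotation strings to event-type names.  Unmapped
    annotations are dropped with a warning, or raise under ``strict``.
    """
    import mne

    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:
        raise FormatError(f"{path}: unreadable EDF file ({exc})") from exc
    fs = float(raw.info["sfreq"])
    data = raw.get_data() * 1e6  # MNE returns volts for uV-dimensioned EEG

    if label_map is None:
        parser: Callable[[str], Event | None] = default_label_parser
    elif isinstance(label_map, dict):
        def parser(desc: str, _m=label_map) -> Event | None:
            t = _m.get(desc)
            return None if t is None else Event(sample=0, type=t, trial=0)
    else:
        parser = label_map

    events: list[Event] = []
    unmapped: list[str] = []
    for onset, desc in zip(raw.annotations.onset, raw.annotations.description):
        template = parser(str(desc))
        if template is None:
            unmapped.append(str(desc))
            continue
        events.append(
            Event(
                sample=int(round(onset * fs)),
                type=template.type,
                trial=template.trial,
                condition=template.condition,
            )
        )
    if unmapped:
        if strict:
            raise FormatError(
                f"{path}: unmapped annotation labels: {sorted(set(unmapped))}"
            )
        warnings.warn(
            f"{path}: dropped {len(unmapped)} unmapped annotations "
            f"({sorted(set(unmapped))[:5]} ...)",
            stacklevel=2,
        )
    if not events:
        warnings.warn(f"{path}: no events found in annotations", stacklevel=2)
    return Recording(
        data=data,
        fs=fs,
        channel_labels=list(raw.ch_names),
        events=events,
        participant_id=None,
        metadata={"source": str(path)},
    )


# ---------------------------------------------------------------------------
# Internal format: .data.npy + .meta.json + .events.tsv
# ---------------------------------------------------------------------------

def _internal_paths(stem: str | Path) -> tuple[Path, Path, Path]:
    stem = Path(stem)
    base = stem.parent / stem.name
    return (
        base.with_suffix(".data.npy"),
        base.with_suffix(".meta.json"),
        base.with_suffix(".events.tsv"),
    )


def write_internal(recording: Recording, stem: str | Path) -> None:
    data_p, meta_p, ev_p = _internal_paths(stem)
    np.save(data_p, recording.data)
    meta = {
        "fs": recording.fs,
        "channel_labels": list(recording.channel_labels),
        "participant_id": recording.participant_id,
        "metadata": recording.metadata,
    }
    meta_p.write_text(json.dumps(meta, indent=1))
    write_events_tsv(recording.events, ev_p)


def read_internal(stem: str | Path) -> Recording:
    data_p, meta_p, ev_p = _internal_paths(stem)
    if not data_p.exists() or not meta_p.exists():
        raise FormatError(f"missing internal-format files for {stem}")
    meta = json.loads(meta_p.read_text())
    events = read_events_tsv(ev_p) if ev_p.exists() else []
    if not events:
        warnings.warn(f"{stem}: no events", stacklevel=2)
    return Recording(
        data=np.load(data_p),
        fs=meta["fs"],
        channel_labels=meta["channel_labels"],
        events=events,
        participant_id=meta.get("participant_id"),
        metadata=meta.get("metadata", {}),
    )


def write_recording(recording: Recording, path: str | Path, format: str = "edf") -> None:
    if format == "edf":
        write_edf(recording, path)
    elif format == "internal":
        write_internal(recording, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_recording(path: str | Path, format: str = "edf", **kwargs) -> Recording:
    if format == "edf":
        return read_edf(path, **kwargs)
    if format == "internal":
        return read_internal(path)
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Feature and result tables (CSV)
# ---------------------------------------------------------------------------

FEATURE_COLUMNS = [
    "participant", "group", "context", "location", "feature", "value",
    "n_trials", "aux_linear",
]

RESULT_COLUMNS = [
    "family", "feature", "feature_name", "location", "t", "df", "p",
    "p_holm", "reject", "mean_a", "mean_b", "n_a", "n_b",
]


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write the long-format feature table (one row per participant,
    context, location, feature)."""
    out = table.reindex(columns=[c for c in FEATURE_COLUMNS if c in table.columns])
    out.to_csv(path, index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_results_table(results: pd.DataFrame, path: str | Path) -> None:
    """Write comparison results: one row per (family, feature, location)."""
    out = results.reindex(columns=[c for c in RESULT_COLUMNS if c in results.columns])
    out.to_csv(path, index=False)


def read_results_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
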