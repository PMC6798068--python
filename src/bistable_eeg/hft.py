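"""Hidden Figures Test scoring, FD/FN/FI classification and reliability.

The HFT is a 32-item embedded-figures instrument administered in two equal
parts.  The score is the number of correct responses minus the number of
incorrect ones (blanks contribute nothing).  Participants are classified as
Field Dependent (low scores), Field Neutral, or Field Independent (high
scores); the published classification cutoffs are not part of the test
manual excerpted here, so cutoffs are an explicit input with an empirical
tertile split as the documented default.  Internal consistency is measured
by Cronbach's alpha on 0/1 item scores (correct = 1, else 0).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

CLASSES = ("FD", "FN", "FI")


def _as_matrix(responses: np.ndarray) -> np.ndarray:
    m = np.asarray(responses)
    if m.ndim != 2:
        raise ValueError("responses must be participants x items")
    if not np.isin(m, (-1, 0, 1)).all():
        raise ValueError("entries must be 1 (correct), -1 (incorrect) or 0 (blank)")
    return m


def score_hft(responses: np.ndarray) -> np.ndarray:
    """Per-participant score: #correct - #incorrect (blanks contribute 0)."""
    m = _as_matrix(responses)
    return (m == 1).sum(axis=1) - (m == -1).sum(axis=1)


def classify_fdi(
    scores: np.ndarray, cutoffs: tuple[float, float] | str = "tertile"
) -> np.ndarray:
    """Threshold scores into FD / FN / FI.

    Explicit cutoffs ``(low, high)``: score <= low -> FD, score >= high ->
    FI, otherwise FN.  ``"tertile"`` uses the empirical 33.3/66.7
    percentiles; scores tied with a boundary go to the lower class (i.e.
    the boundary itself already satisfies ``<= low`` resp. needs to be
    strictly above the upper percentile to reach FI).
    """
    s = np.asarray(scores, dtype=float)
    if s.size == 0:
        raise ValueError("scores must be non-empty")
    if isinstance(cutoffs, str):
        if cutoffs != "tertile":
            raise ValueError(f"unknown cutoff rule {cutoffs!r}")
        low = float(np.percentile(s, 100 / 3))
        high = float(np.percentile(s, 200 / 3))
        out = np.where(s <= low, "FD", np.where(s > high, "FI", "FN"))
        return out.astype(object)
    low, high = cutoffs
    if low >= high:
        raise ValueError(f"cutoffs must satisfy low < high, got {cutoffs}")
    return np.where(s <= low, "FD", np.where(s >= high, "FI", "FN")).astype(object)


def cronbach_alpha(responses: np.ndarray) -> float:
    """Cronbach's alpha on the 0/1 item matrix (blank/incorrect -> 0).

    alpha = k/(k-1) * (1 - sum of item variances / variance of totals).
    """
    m = _as_matrix(responses)
    items = (m == 1).astype(float)
    n, k = items.shape
    if k < 2 or n < 2:
        raise ValueError("need >= 2 items and >= 2 participants")
    totals = items.sum(axis=1)
    total_var = totals.var(ddof=1)
    if total_var == 0:
        raise ValueError("zero total-score variance; alpha undefined")
    item_var = items.var(axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_var / total_var))


def hft_results(
    responses: np.ndarray,
    participants: list[str] | None = None,
    cutoffs: tuple[float, float] | str = "tertile",
) -> pd.DataFrame:
    """Score and classify a response matrix into a tidy results table."""
    scores = score_hft(responses)
    classes = classify_fdi(scores, cutoffs)
    if participants is None:
        participants = [f"P{i + 1:02d}" for i in range(len(scores))]
    return pd.DataFrame(
        {"participant": participants, "score": scores, "class": classes}
    )
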