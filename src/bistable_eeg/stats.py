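"""Channel-wise comparison matrix with Holm-Bonferroni control.

Three comparison families are run over the 30 analysis locations:

(a) bistable vs. unambiguous condition (c1 vs. c2), stimulus-locked
    features 1-9, paired within participant;
(b) first vs. second button press (stability vs. reversal), pre-button
    features 10-12, bistable trials only, paired within participant;
(c) Field-Dependent vs. Field-Independent group, all 12 features on the
    bistable condition (button features on the reversal epoch), two-sample
    with pooled (Student) variance -- the design degrees of freedom
    n_a + n_b - 2 require the pooled test.

Holm's step-down correction is applied per family scope (default: within
each feature, across its locations).  Results always carry both the raw
and the Holm-adjusted p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

from .features_spec import FEATURE_NAMES


class UndefinedStatisticError(ValueError):
    """Zero variance (or too few observations) makes the t undefined."""


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int


def paired_ttest(x: np.ndarray, y: np.ndarray) -> TTestResult:
    """Two-sided paired t-test; pairs with a missing value are dropped."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = x.size
    if n < 2:
        raise UndefinedStatisticError(f"need >= 2 complete pairs, have {n}")
    d = x - y
    if d.std(ddof=1) == 0.0:
        if d.mean() == 0.0:
            # x == y exactly: no evidence of a difference
            return TTestResult(0.0, n - 1, 1.0, float(x.mean()), float(y.mean()), n, n)
        raise UndefinedStatisticError("zero difference variance")
    res = sstats.ttest_rel(x, y)
    return TTestResult(float(res.statistic), n - 1, float(res.pvalue),
                       float(x.mean()), float(y.mean()), n, n)


def two_sample_ttest(a: np.ndarray, b: np.ndarray) -> TTestResult:
    """Two-sided pooled-variance (Student) t-test; NaNs are dropped."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise UndefinedStatisticError(
            f"need >= 2 observations per group, have {a.size} and {b.size}"
        )
    df = a.size + b.size - 2
    sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
    if sp2 == 0.0:
        if a.mean() == b.mean():
            return TTestResult(0.0, df, 1.0, float(a.mean()), float(b.mean()),
                               a.size, b.size)
        raise UndefinedStatisticError("zero pooled variance")
    res = sstats.ttest_ind(a, b, equal_var=True)
    return TTestResult(float(res.statistic), df, float(res.pvalue),
                       float(a.mean()), float(b.mean()), a.size, b.size)


def holm_bonferroni(
    p_values: np.ndarray, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Holm step-down adjustment: (adjusted p, reject flags).

    Rejection under ``adjusted p <= alpha`` coincides with the classical
    step-down procedure comparing p_(i) to alpha / (m - i + 1).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy(), np.zeros(0, dtype=bool)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="holm")
    return p_adj, reject


_FAMILIES = {
    "a_condition": dict(kind="paired", features=tuple(range(1, 10)),
                        contexts=("c1", "c2")),
    "b_button": dict(kind="paired", features=(10, 11, 12),
                     contexts=("b1", "b2")),
    "c_group": dict(kind="two_sample", features=tuple(range(1, 13)),
                    groups=("FD", "FI")),
}


def _pivot(table: pd.DataFrame, feature: int, context: str) -> pd.Series:
    sel = table[(table["feature"] == feature) & (table["context"] == context)]
    return sel.set_index(["participant", "location"])["value"]


def run_comparisons(
    feature_table: pd.DataFrame,
    alpha: float = 0.05,
    family_scope: str = "feature",
    group_column: str = "group",
) -> pd.DataFrame:
    """Run the full comparison matrix on a long-format feature table.

    ``feature_table`` columns: participant, group, context, location,
    feature, value.  Contexts are ``c1``/``c2`` for stimulus-locked
    features and ``b1``/``b2`` for button-locked ones.  ``family_scope``
    controls the Holm family: ``"feature"`` (per feature across locations,
    default), ``"global"`` (whole family at once) or ``"none"``.
    """
    if family_scope not in ("feature", "global", "none"):
        raise ValueError(f"unknown family_scope {family_scope!r}")
    rows: list[dict] = []
    for fam_name, fam in _FAMILIES.items():
        fam_rows: list[dict] = []
        for feat in fam["features"]:
            locations = [
                loc for loc in feature_table.loc[
                    feature_table["feature"] == feat, "location"].unique()
            ]
            if not locations:
                continue
            if fam["kind"] == "paired":
                ctx_a, ctx_b = fam["contexts"]
                va, vb = _pivot(feature_table, feat, ctx_a), _pivot(feature_table, feat, ctx_b)
                for loc in locations:
                    xa = va.xs(loc, level="location")
                    xb = vb.xs(loc, level="location")
                    joined = pd.concat([xa, xb], axis=1, join="inner")
                    try:
                        r = paired_ttest(joined.iloc[:, 0].values, joined.iloc[:, 1].values)
                    except UndefinedStatisticError:
                        continue
                    fam_rows.append(_result_row(fam_name, feat, loc, r))
            else:
                ga, gb = fam["groups"]
                ctx = "c1"
                sub = feature_table[(feature_table["feature"] == feat)]
                if feat >= 10:
                    ctx = "b2"
                sub = sub[sub["context"] == ctx]
                for loc in locations:
                    at = sub[(sub["location"] == loc) & (sub[group_column] == ga)]["value"].values
                    bt = sub[(sub["location"] == loc) & (sub[group_column] == gb)]["value"].values
                    try:
                        r = two_sample_ttest(at, bt)
                    except UndefinedStatisticError:
                        continue
                    fam_rows.append(_result_row(fam_name, feat, loc, r))
        if not fam_rows:
            raise ValueError(f"comparison family {fam_name!r} is empty")
        rows.extend(_apply_holm(fam_rows, alpha, family_scope))
    out = pd.DataFrame(rows)
    return out.reset_index(drop=True)


def _result_row(family: str, feat: int, loc: str, r: TTestResult) -> dict:
    return {
        "family": family, "feature": feat, "feature_name": FEATURE_NAMES[feat],
        "location": loc, "t": r.t, "df": r.df, "p": r.p,
        "mean_a": r.mean_a, "mean_b": r.mean_b, "n_a": r.n_a, "n_b": r.n_b,
    }


def _apply_holm(fam_rows: list[dict], alpha: float, scope: str) -> list[dict]:
    if scope == "none":
        for row in fam_rows:
            row["p_holm"] = row["p"]
            row["reject"] = row["p"] <= alpha
        return fam_rows
    df = pd.DataFrame(fam_rows)
    if scope == "feature":
        for _, idx in df.groupby("feature").groups.items():
            p_adj, rej = holm_bonferroni(df.loc[idx, "p"].values, alpha)
            df.loc[idx, "p_holm"] = p_adj
            df.loc[idx, "reject"] = rej
    else:  # global
        p_adj, rej = holm_bonferroni(df["p"].values, alpha)
        df["p_holm"] = p_adj
        df["reject"] = rej
    df["reject"] = df["reject"].astype(bool)
    return df.to_dict("records")


def format_results(results: pd.DataFrame, alpha: float = 0.05,
                   use_adjusted: bool = False) -> str:
    """Human-readable per-feature listing of threshold-passing locations.

    Each line mirrors the reporting style ``LOC [t(df) = x, p = y,
    m_a = ..., m_b = ...]``; both the raw and the Holm-adjusted decisions
    are derivable from the emitted columns, and the header states which
    column selected the listed rows.
    """
    crit = "p_holm" if use_adjusted else "p"
    lines = [f"Locations passing {crit} <= {alpha:g} per feature", "=" * 54]
    means = {"a_condition": ("m_c1", "m_c2"), "b_button": ("m_b1", "m_b2"),
             "c_group": ("m_FD", "m_FI")}
    for fam, fdf in results.groupby("family", sort=True):
        la, lb = means.get(fam, ("m_a", "m_b"))
        lines.append(f"\n[{fam}]")
        for feat, sub in fdf.groupby("feature"):
            hits = sub[sub[crit] <= alpha]
            name = FEATURE_NAMES.get(feat, str(feat))
            if hits.empty:
                lines.append(f"  {feat:>2} {name}: none")
                continue
            parts = [
                f"{r.location} [t({r.df}) = {r.t:.3f}, p = {r.p:.3g}, "
                f"p_holm = {r.p_holm:.3g}, {la} = {r.mean_a:.3g}, {lb} = {r.mean_b:.3g}]"
                for r in hits.itertuples(index=False)
            ]
            lines.append(f"  {feat:>2} {name}: " + "; ".join(parts))
    return "\n".join(lines) + "\n"
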