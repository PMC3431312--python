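"""Two-condition comparison of fitted half-lives.

For every transcript with accepted half-lives in both conditions (>= 2
reliable replicates each), the reliable replicate half-lives are compared by
a two-sided two-sample Student t-test (pooled variance; Welch available via
``equal_var=False``).  The half-life fold change is the ratio of
per-condition mean half-lives — a ratio of means, not a mean of ratios,
because replicates are not paired.  Transcripts are classed stabilized
(fold change > 1, p < alpha), destabilized (< 1, p < alpha), unchanged, or
unmatched when either condition lacks an accepted half-life.

No multiple-testing correction is applied to the calls (raw p < alpha); a
Benjamini-Hochberg q-value column is emitted for information only.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "StabilityComparison",
    "compare_halflives",
    "compare_conditions",
    "signed_fold_change",
    "stability_table",
]


@dataclass(frozen=True)
class StabilityComparison:
    """Per-transcript two-condition stability result."""

    ctrl_thalf: float
    kd_thalf: float
    fc_thalf: float
    ttest_p: float
    class_label: str


def _ttest(ctrl: np.ndarray, kd: np.ndarray, equal_var: bool) -> float:
    if len(ctrl) < 2 or len(kd) < 2:
        return math.nan
    v_ctrl = ctrl.var(ddof=1)
    v_kd = kd.var(ddof=1)
    if v_ctrl == 0 and v_kd == 0:
        if ctrl.mean() == kd.mean():
            return 1.0
        warnings.warn(
            "zero variance in both replicate groups with unequal means; p set to 0",
            RuntimeWarning,
            stacklevel=3,
        )
        return 0.0
    return float(stats.ttest_ind(ctrl, kd, equal_var=equal_var).pvalue)


def compare_halflives(
    ctrl: Sequence[float],
    kd: Sequence[float],
    alpha: float = 0.05,
    equal_var: bool = True,
) -> StabilityComparison:
    """Compare reliable replicate half-lives between two conditions.

    ``ctrl`` and ``kd`` are the reliable replicate half-lives (minutes) of
    one transcript in the reference and perturbed condition.  The fold
    change is mean(kd)/mean(ctrl); the p-value is a two-sided two-sample
    Student t-test (NaN when either group has fewer than 2 replicates, in
    which case no class is assigned beyond "unchanged").
    """
    ctrl = np.asarray(ctrl, dtype=float)
    kd = np.asarray(kd, dtype=float)
    if len(ctrl) == 0 or len(kd) == 0:
        return StabilityComparison(math.nan, math.nan, math.nan, math.nan, "unmatched")
    m_ctrl = float(ctrl.mean())
    m_kd = float(kd.mean())
    fc = m_kd / m_ctrl
    p = _ttest(ctrl, kd, equal_var)
    if p < alpha:
        label = "stabilized" if fc > 1 else "destabilized" if fc < 1 else "unchanged"
    else:
        label = "unchanged"
    return StabilityComparison(m_ctrl, m_kd, fc, p, label)


def compare_conditions(
    fits: pd.DataFrame,
    summary: pd.DataFrame,
    conditions: tuple[str, str],
    alpha: float = 0.05,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-transcript differential-stability table from a batch of fits.

    ``fits``/``summary`` are the outputs of :func:`decaychase.fitting.fit_all`.
    Only transcripts accepted in *both* conditions (>= 2 reliable replicates
    each) are tested; the rest are classed "unmatched" with NaN fields.

    Returns a DataFrame with columns transcript_id, ctrl_thalf, kd_thalf,
    fc_thalf, ttest_p, bh_q, class_label.
    """
    ref, pert = conditions
    rel = fits[fits["reliable"]]
    groups = {
        cond: {
            tid: sub["t_half"].to_numpy()
            for tid, sub in rel[rel["condition"] == cond].groupby("transcript_id", sort=False)
        }
        for cond in (ref, pert)
    }
    ok = summary[summary["condition_reliable"]]
    ok_ref = set(ok.loc[ok["condition"] == ref, "transcript_id"])
    ok_pert = set(ok.loc[ok["condition"] == pert, "transcript_id"])

    rows = []
    for tid in summary["transcript_id"].unique():
        if tid in ok_ref and tid in ok_pert:
            c = compare_halflives(groups[ref][tid], groups[pert][tid], alpha, equal_var)
            rows.append((tid, c.ctrl_thalf, c.kd_thalf, c.fc_thalf, c.ttest_p, c.class_label))
        else:
            rows.append((tid, np.nan, np.nan, np.nan, np.nan, "unmatched"))
    out = pd.DataFrame(
        rows,
        columns=["transcript_id", "ctrl_thalf", "kd_thalf", "fc_thalf", "ttest_p", "class_label"],
    )
    tested = out["ttest_p"].notna()
    out["bh_q"] = np.nan
    if tested.any():
        out.loc[tested, "bh_q"] = multipletests(out.loc[tested, "ttest_p"], method="fdr_bh")[1]
    return out


def signed_fold_change(ratio: float) -> float:
    """Symmetric +/- fold-change convention: +r for r >= 1, -1/r for r < 1.

    The magnitude is always >= 1, so a halving and a doubling print as -2.00
    and +2.00.
    """
    ratio = float(ratio)
    if not ratio > 0:
        raise ValueError("ratio must be positive")
    return ratio if ratio >= 1 else -1.0 / ratio


def stability_table(
    comparisons: pd.DataFrame,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split significant comparisons into stabilized and destabilized tables.

    Each table carries transcript_id, per-condition half-lives, the t-test
    p-value, the half-life fold change rounded to 2 decimals (computed from
    unrounded means) and, when a ``fc_abundance`` column is present, the
    signed abundance fold change.  Rows are sorted by transcript id.
    """
    sig = comparisons[(comparisons["ttest_p"] < alpha) & comparisons["fc_thalf"].notna()]
    cols = ["transcript_id", "ctrl_thalf", "kd_thalf", "ttest_p"]

    def build(sub: pd.DataFrame) -> pd.DataFrame:
        tab = sub[cols].copy()
        tab["fc_thalf"] = sub["fc_thalf"].round(2)
        if "fc_abundance" in sub.columns:
            tab["signed_fc_abundance"] = [
                round(signed_fold_change(r), 2) if r > 0 else np.nan
                for r in sub["fc_abundance"].fillna(-1.0)
            ]
        return tab.sort_values("transcript_id").reset_index(drop=True)

    stabilized = build(sig[sig["fc_thalf"] > 1])
    destabilized = build(sig[sig["fc_thalf"] < 1])
    return stabilized, destabilized
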