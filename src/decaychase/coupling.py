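"""Abundance changes and decay-transcription coupling.

Steady-state abundance under first-order turnover obeys the balance

    A = s * t_half / ln2

(abundance = synthesis rate x mean lifetime), so fold changes factor as
fc_A = fc_s * fc_thalf and a transcription-rate change can be inferred from
measured abundance and half-life changes as fc_s = fc_A / fc_thalf.  This
balance is an interpretive model: it assumes the perturbed condition has
reached a new steady state.

Abundance is estimated from the t=0 arrays of the chase (mean over
replicates), the chase's own baseline: transcriptional buffering then shows
up as stabilized transcripts whose abundance does not rise, and as a
negative rank correlation between half-life fold change and abundance fold
change among transcripts with a significant stability change.  Nascent
pre-mRNA measurements (4sU-style, reference-normalized) give an independent
check of the inferred transcription changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .differential import signed_fold_change, _ttest

__all__ = [
    "CouplingResult",
    "abundance_at_t0",
    "abundance_census",
    "coupling_scatter",
    "infer_synthesis_change",
    "premrna_consistency",
]


def abundance_at_t0(
    matrix: pd.DataFrame,
    conditions: tuple[str, str],
) -> pd.DataFrame:
    """Estimate per-transcript abundance from the t=0 arrays.

    Returns a DataFrame with the per-condition mean t=0 intensities, the
    perturbed/reference abundance fold change and its signed form.  Only
    transcripts present at t=0 in both conditions get a fold change.
    """
    ref, pert = conditions
    t0 = matrix[matrix["time_min"] == 0]
    if t0.empty:
        raise ValueError("matrix has no t=0 rows; abundance needs the 0-minute arrays")
    means = (
        t0.groupby(["transcript_id", "condition"], sort=False)["intensity"]
        .mean()
        .unstack("condition")
    )
    for cond in (ref, pert):
        if cond not in means.columns:
            means[cond] = np.nan
    out = pd.DataFrame(
        {
            "transcript_id": means.index,
            "mean_t0_ref": means[ref].to_numpy(),
            "mean_t0_pert": means[pert].to_numpy(),
        }
    ).reset_index(drop=True)
    out["fc_abundance"] = out["mean_t0_pert"] / out["mean_t0_ref"]
    out["signed_fc_abundance"] = [
        signed_fold_change(r) if r > 0 else np.nan for r in out["fc_abundance"].fillna(-1.0)
    ]
    return out


def abundance_census(abundances: pd.DataFrame, threshold: float = 1.5) -> dict:
    """Count transcripts whose abundance changed ``threshold``-fold or more.

    Uses the signed convention: a transcript is affected when its signed
    abundance fold change has magnitude >= threshold.  Reports the up/down
    split and the fraction of affected transcripts that are down-regulated.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1 (signed fold-change magnitude)")
    fc = abundances["fc_abundance"].dropna()
    up = int((fc >= threshold).sum())
    down = int((fc <= 1.0 / threshold).sum())
    affected = up + down
    return {
        "n_total": int(fc.size),
        "threshold": float(threshold),
        "n_affected": affected,
        "n_up": up,
        "n_down": down,
        "down_fraction": down / affected if affected else math.nan,
    }


def infer_synthesis_change(fc_abundance: float, fc_thalf: float) -> float:
    """Transcription-rate fold change implied by the steady-state balance.

    fc_s = fc_A / fc_thalf: e.g. an unchanged abundance despite a doubled
    half-life implies synthesis halved (perfect buffering).
    """
    if not (fc_abundance > 0 and fc_thalf > 0):
        raise ValueError("fold changes must be positive")
    return fc_abundance / fc_thalf


@dataclass(frozen=True)
class CouplingResult:
    """Joined per-transcript coupling table plus cohort statistics.

    ``table`` has one row per transcript with fc_thalf, fc_abundance and
    inferred_fc_synthesis (= fc_abundance / fc_thalf, an exact identity).
    ``rho``/``rho_p`` are the Spearman rank correlation between half-life and
    abundance fold changes over transcripts with a significant stability
    change (NaN when fewer than 3 such transcripts or no spread).
    """

    table: pd.DataFrame
    rho: float
    rho_p: float
    n_significant: int
    census: dict


def coupling_scatter(
    comparisons: pd.DataFrame,
    abundances: pd.DataFrame,
    abundance_threshold: float = 1.5,
) -> CouplingResult:
    """Join stability and abundance results and quantify their coupling.

    The per-transcript table is plot-ready (one point per transcript with a
    class label); the cohort statistic is a rank correlation, robust to the
    ratio scale, computed over significantly stabilized/destabilized
    transcripts.
    """
    table = comparisons.merge(
        abundances[["transcript_id", "fc_abundance", "signed_fc_abundance"]],
        on="transcript_id",
        how="left",
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        table["inferred_fc_synthesis"] = table["fc_abundance"] / table["fc_thalf"]

    sig = table[
        table["class_label"].isin(["stabilized", "destabilized"])
        & table["fc_abundance"].notna()
    ]
    rho = rho_p = math.nan
    if len(sig) >= 3:
        x = sig["fc_thalf"].to_numpy()
        y = sig["fc_abundance"].to_numpy()
        if np.unique(x).size > 1 and np.unique(y).size > 1:
            res = stats.spearmanr(x, y)
            rho, rho_p = float(res.statistic), float(res.pvalue)
    census = abundance_census(abundances, abundance_threshold)
    return CouplingResult(
        table=table, rho=rho, rho_p=rho_p, n_significant=int(len(sig)), census=census
    )


def premrna_consistency(
    pre: pd.DataFrame,
    coupling: pd.DataFrame | CouplingResult,
    conditions: tuple[str, str],
    alpha: float = 0.05,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Check measured nascent pre-mRNA changes against inferred transcription.

    Per transcript: two-sample t-test of reference-normalized pre-mRNA
    quantities between conditions, the measured pre-mRNA fold change
    (perturbed/reference mean), and whether its direction agrees with the
    inferred synthesis fold change.  Agreement is "agree"/"disagree" when
    the pre-mRNA difference is significant, "indeterminate" otherwise (or
    when either fold change is exactly 1).  With a single replicate per
    condition the test is skipped and only the fold change is reported.
    """
    table = coupling.table if isinstance(coupling, CouplingResult) else coupling
    inferred = table.set_index("transcript_id")["inferred_fc_synthesis"]

    ref, pert = conditions
    rows = []
    for tid, sub in pre.groupby("transcript_id", sort=False):
        a = sub.loc[sub["condition"] == ref, "relative_quantity"].to_numpy(dtype=float)
        b = sub.loc[sub["condition"] == pert, "relative_quantity"].to_numpy(dtype=float)
        if len(a) == 0 or len(b) == 0:
            continue
        fc = float(b.mean() / a.mean())
        p = _ttest(a, b, equal_var)
        fc_s = float(inferred.get(tid, math.nan))
        if not (p < alpha) or math.isnan(fc_s) or fc == 1.0 or fc_s == 1.0:
            agreement = "indeterminate"
        elif (fc > 1) == (fc_s > 1):
            agreement = "agree"
        else:
            agreement = "disagree"
        rows.append((tid, fc, p, fc_s, agreement))
    return pd.DataFrame(
        rows,
        columns=[
            "transcript_id",
            "fc_premrna",
            "ttest_p",
            "inferred_fc_synthesis",
            "agreement",
        ],
    )
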