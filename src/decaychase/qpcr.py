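"""qPCR validation arm: Ct tables -> relative abundance -> half-lives.

Relative abundance follows the delta-Ct convention against a stable
reference gene (a Gapdh-like transcript measured in the same sample):

    quantity = efficiency ** -(Ct_target - Ct_reference)

with a perfect-doubling efficiency of 2.0 by default.  Each
(transcript, condition) series is then rescaled so the mean t=0 quantity is
1, putting qPCR series on the same footing as array series so both share
the same decay fitter.
"""

from __future__ import annotations

import pandas as pd

from .fitting import fit_all

__all__ = ["relative_abundance", "qpcr_halflife"]


def relative_abundance(ct: pd.DataFrame, efficiency: float = 2.0) -> pd.DataFrame:
    """Convert a Ct table into reference-normalized relative abundances.

    ``ct`` is long with columns transcript_id, condition, replicate,
    time_min, ct_target, ct_reference.  Returns the same keys with a
    ``relative_quantity`` column, rescaled so that the mean t=0 quantity per
    (transcript, condition) equals 1.  Adding any constant to both Ct
    columns leaves the result unchanged (reference-gene invariance).
    """
    if not efficiency > 1:
        raise ValueError("amplification efficiency must exceed 1")
    required = ["transcript_id", "condition", "replicate", "time_min", "ct_target", "ct_reference"]
    missing = [c for c in required if c not in ct.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    bad = ct.index[ct["ct_reference"].isna() | ct["ct_target"].isna()]
    if len(bad):
        raise ValueError(f"missing Ct value(s) in rows {list(bad[:5])}")

    out = ct[required[:4]].copy()
    dct = ct["ct_target"].to_numpy(dtype=float) - ct["ct_reference"].to_numpy(dtype=float)
    out["relative_quantity"] = float(efficiency) ** (-dct)

    t0_mean = (
        out[out["time_min"] == 0]
        .groupby(["transcript_id", "condition"], sort=False)["relative_quantity"]
        .mean()
    )
    key = pd.MultiIndex.from_frame(out[["transcript_id", "condition"]])
    out["relative_quantity"] = out["relative_quantity"].to_numpy() / t0_mean.loc[key].to_numpy()
    return out


def qpcr_halflife(
    series: pd.DataFrame,
    alpha: float = 0.05,
    min_reliable: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit half-lives to qPCR relative-abundance series.

    Delegates to the shared decay fitter; returns per-replicate fits and a
    per-(transcript, condition) summary with the mean half-life over
    reliable replicates and its standard error.
    """
    df = series.rename(columns={"relative_quantity": "intensity"})
    fits, summary = fit_all(df, alpha=alpha, min_reliable=min_reliable)
    se = (
        fits[fits["reliable"]]
        .groupby(["transcript_id", "condition"], sort=False)["t_half"]
        .sem()
        .rename("se_thalf")
    )
    summary = summary.merge(se, on=["transcript_id", "condition"], how="left")
    return fits, summary
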