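"""Array-level normalization and expression filtering.

An "array" is one (condition, replicate, time) slice of the long expression
matrix: all transcripts hybridized together.  Raw matrices are first
median-scaled (every array's median is brought to the global median of
per-array medians), then each value is divided by its own array's 5th
percentile, so that low-end signal is on a common footing across arrays.
Finally, transcripts are declared expressed when their detection p-value at
t=0 is below alpha in at least ``min_detected`` replicates.

Known limitation: per-array scaling across chase time points removes any
global decay component shared by all transcripts.  Without spike-ins this
cannot be avoided; half-lives are therefore relative to the bulk.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = [
    "NormalizationError",
    "FilterError",
    "median_scale",
    "percentile_floor_scale",
    "detection_filter",
]

log = logging.getLogger(__name__)

ARRAY_KEY = ["condition", "replicate", "time_min"]


class NormalizationError(ValueError):
    """Raised when an array slice cannot be rescaled."""


class FilterError(ValueError):
    """Raised when the detection filter lacks its inputs."""


def _check_columns(matrix: pd.DataFrame, cols) -> None:
    missing = [c for c in cols if c not in matrix.columns]
    if missing:
        raise ValueError(f"expression matrix missing columns: {missing}")


def median_scale(matrix: pd.DataFrame) -> pd.DataFrame:
    """Rescale every array multiplicatively so all array medians are equal.

    The common target is the median of the per-array medians (a symmetric,
    scale-free choice).  Returns a normalized copy; the input is untouched.
    """
    _check_columns(matrix, ARRAY_KEY + ["intensity"])
    out = matrix.copy()
    medians = out.groupby(ARRAY_KEY, sort=True)["intensity"].median()
    bad = medians[medians <= 0]
    if len(bad):
        slice_name = tuple(bad.index[0])
        raise NormalizationError(
            f"array slice {dict(zip(ARRAY_KEY, slice_name))} has non-positive median; "
            "cannot median-scale"
        )
    target = float(np.median(medians.to_numpy()))
    factors = target / medians
    out["intensity"] = out["intensity"].to_numpy() * factors.loc[
        pd.MultiIndex.from_frame(out[ARRAY_KEY])
    ].to_numpy()
    return out


def percentile_floor_scale(matrix: pd.DataFrame, pct: float = 5.0) -> pd.DataFrame:
    """Divide every value by its own array's ``pct``-th percentile.

    After the operation the ``pct``-th percentile of every array equals 1.
    Percentiles use linear interpolation between order statistics.
    """
    if not (0 <= pct <= 100):
        raise ValueError("pct must lie in [0, 100]")
    _check_columns(matrix, ARRAY_KEY + ["intensity"])
    out = matrix.copy()
    floors = out.groupby(ARRAY_KEY, sort=True)["intensity"].quantile(pct / 100.0)
    bad = floors[floors <= 0]
    if len(bad):
        slice_name = tuple(bad.index[0])
        raise NormalizationError(
            f"array slice {dict(zip(ARRAY_KEY, slice_name))} has {pct}th percentile <= 0"
        )
    out["intensity"] = out["intensity"].to_numpy() / floors.loc[
        pd.MultiIndex.from_frame(out[ARRAY_KEY])
    ].to_numpy()
    return out


def detection_filter(
    matrix: pd.DataFrame,
    alpha: float = 0.05,
    min_detected: int = 2,
) -> pd.DataFrame:
    """Keep transcripts detected above background at the t=0 arrays.

    A transcript is kept for a condition when ``detection_p < alpha``
    (strictly; a p exactly equal to alpha does not count) in at least
    ``min_detected`` replicates at time 0 in that condition.  Filtering is
    per condition: a transcript can be expressed in one condition only.
    """
    _check_columns(matrix, ARRAY_KEY + ["transcript_id", "intensity"])
    if "detection_p" not in matrix.columns:
        raise FilterError(
            "detection_p column absent: supply detection p-values at t=0 "
            "or skip the detection filter"
        )
    t0 = matrix[matrix["time_min"] == 0]
    if t0["detection_p"].isna().all():
        raise FilterError(
            "no detection p-values at t=0: supply them or skip the detection filter"
        )
    hits = (
        t0.assign(hit=t0["detection_p"] < alpha)
        .groupby(["transcript_id", "condition"], sort=False)["hit"]
        .sum()
    )
    keep = hits[hits >= min_detected].index
    key = pd.MultiIndex.from_frame(matrix[["transcript_id", "condition"]])
    out = matrix[key.isin(keep)].reset_index(drop=True)

    n_pairs = hits.shape[0]
    log.info(
        "detection filter: kept %d of %d (transcript, condition) pairs "
        "(alpha=%g, min_detected=%d)",
        len(keep),
        n_pairs,
        alpha,
        min_detected,
    )
    return out
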