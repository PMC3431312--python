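"""First-order decay fitting with reliability assessment.

Each transcript/replicate time series is fit in linear intensity space by
nonlinear least squares to

    y(t) = y0 * exp(-k * t),    k >= 0,

and the half-life is t_half = ln2 / k.  The two-parameter model is solved by
profiling: for fixed k the optimal y0 is closed-form, leaving a 1-D search
over k on [0, K_MAX] (bounded Brent, then Newton polish on the profiled
objective), which is fast enough to fit hundreds of thousands of series in
simulation studies and recovers noiseless series to machine precision.

A fit is *reliable* when (i) it shows significant decay (one-sided Wald test
of H0: k=0 on k/se(k) against a t distribution with n-2 degrees of freedom,
p < alpha) and (ii) the 95% confidence interval for the half-life is
narrower than twice the half-life.  The interval is Wald on k and then
inverted to the half-life scale (the half-life's own sampling distribution
is heavily right-skewed at 5 points, so a symmetric interval on t_half would
misbehave).  A condition's half-life is accepted when at least two
replicates are reliable; the condition half-life is the mean over reliable
replicates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from .config import LN2

__all__ = [
    "DecayFit",
    "fit_decay",
    "fit_pvalue",
    "halflife_ci",
    "is_reliable",
    "fit_all",
]

#: upper bound on the decay rate during optimization (1/min); t_half ~ 0.35 min
K_MAX = 2.0
#: below this rate the fit is treated as sitting on the k = 0 boundary
K_BOUNDARY = 1e-8


@dataclass(frozen=True)
class DecayFit:
    """One replicate's fitted first-order decay.

    ``t_half`` is ln2/k in minutes (+inf at the k=0 boundary); ``ci95_thalf``
    is the Wald-on-k interval inverted to the half-life scale; ``fit_p`` is
    the one-sided p-value for decay (H0: k=0).
    """

    y0: float
    k: float
    t_half: float
    se_k: float
    ci95_thalf: tuple[float, float]
    fit_p: float
    converged: bool
    n_points: int
    residual_ss: float


def _profile_terms(k: float, t: Sequence[float], y: Sequence[float]):
    """Sums needed by the profiled objective and its gradient at rate k."""
    see = sye = a = b = 0.0
    for ti, yi in zip(t, y):
        e = math.exp(-k * ti)
        see += e * e
        sye += yi * e
        a += ti * yi * e
        b += ti * e * e
    return see, sye, a, b


def _objective(k: float, t, y) -> float:
    # SS(k) minus the constant sum(y^2): minimizing this minimizes SS
    see, sye, _, _ = _profile_terms(k, t, y)
    return -sye * sye / see


def _gradient(k: float, t, y) -> float:
    see, sye, a, b = _profile_terms(k, t, y)
    return 2.0 * sye * (a * see - sye * b) / (see * see)


def fit_decay(times: Iterable[float], values: Iterable[float]) -> DecayFit:
    """Least-squares fit of y0 * exp(-k t) with k constrained non-negative.

    Requires at least 3 distinct, finite time points and finite values.  A
    non-decaying series comes back at the k=0 boundary with t_half = +inf,
    fit_p = 1 and converged=True; genuine optimizer failure is reported as
    converged=False and treated as unreliable downstream.
    """
    t = [float(x) for x in times]
    y = [float(x) for x in values]
    if len(t) != len(y):
        raise ValueError("times and values must have equal length")
    if len(set(t)) < 3:
        raise ValueError("need at least 3 distinct time points")
    if not all(math.isfinite(x) for x in t + y):
        raise ValueError("times and values must be finite")
    n = len(t)

    try:
        res = minimize_scalar(
            _objective,
            bounds=(0.0, K_MAX),
            args=(t, y),
            method="bounded",
            options={"xatol": 1e-6},
        )
        k_hat = float(res.x)
        # Newton polish on the profiled objective; bounded Brent alone stops
        # short of the precision needed for exact noiseless recovery
        for _ in range(12):
            if k_hat <= K_BOUNDARY:
                break
            g = _gradient(k_hat, t, y)
            h = 1e-7 * max(k_hat, 1e-3)
            curv = (_gradient(k_hat + h, t, y) - _gradient(k_hat - h, t, y)) / (2 * h)
            if curv <= 0 or not math.isfinite(curv):
                break
            step = g / curv
            k_new = min(max(k_hat - step, 0.0), K_MAX)
            if abs(k_new - k_hat) <= 1e-14 * max(k_hat, 1e-6):
                k_hat = k_new
                break
            k_hat = k_new
    except Exception:
        nan = float("nan")
        return DecayFit(nan, nan, nan, nan, (nan, nan), nan, False, n, nan)

    if k_hat <= K_BOUNDARY or _objective(0.0, t, y) <= _objective(k_hat, t, y):
        y0 = sum(y) / n
        rss = sum((yi - y0) ** 2 for yi in y)
        return DecayFit(
            y0=y0,
            k=0.0,
            t_half=math.inf,
            se_k=math.nan,
            ci95_thalf=(math.nan, math.inf),
            fit_p=1.0,
            converged=True,
            n_points=n,
            residual_ss=rss,
        )

    see, sye, _, b = _profile_terms(k_hat, t, y)
    y0 = sye / see
    rss = sum((yi - y0 * math.exp(-k_hat * ti)) ** 2 for ti, yi in zip(t, y))
    rss = max(rss, 0.0)
    # se(k) from the Gauss-Newton curvature (J^T J) at the optimum
    d2 = sum(ti * ti * math.exp(-2 * k_hat * ti) for ti in t)
    det = see * d2 - b * b
    s2 = rss / (n - 2)
    se_k = math.sqrt(s2 * see / (y0 * y0 * det)) if det > 0 and y0 != 0 else math.nan

    fit = DecayFit(
        y0=y0,
        k=k_hat,
        t_half=LN2 / k_hat,
        se_k=se_k,
        ci95_thalf=(math.nan, math.nan),
        fit_p=math.nan,
        converged=True,
        n_points=n,
        residual_ss=rss,
    )
    fit = replace(fit, fit_p=fit_pvalue(fit), ci95_thalf=halflife_ci(fit))
    return fit


def fit_pvalue(fit: DecayFit) -> float:
    """One-sided p-value for decay: H0 k=0 vs k>0, from k/se(k) ~ t(n-2).

    A fit at the k=0 boundary has p=1 by convention; a perfect fit (zero
    residual standard error with k>0) has p=0.
    """
    if not fit.converged:
        return math.nan
    if fit.k <= 0:
        return 1.0
    if not (fit.se_k > 0):
        if fit.se_k == 0:
            warnings.warn(
                "zero standard error on the decay rate (perfect fit); p-value set to 0",
                RuntimeWarning,
                stacklevel=2,
            )
            return 0.0
        return math.nan
    return float(stats.t.sf(fit.k / fit.se_k, fit.n_points - 2))


def halflife_ci(fit: DecayFit, confidence: float = 0.95) -> tuple[float, float]:
    """Confidence interval for the half-life: Wald on k, inverted.

    The rate interval k -+ t_crit * se(k) maps to half-lives
    (ln2/k_high, ln2/k_low); when the rate interval reaches 0 the upper
    half-life bound is +inf (and the width criterion of the reliability
    filter necessarily fails).
    """
    if not (0 < confidence < 1):
        raise ValueError("confidence must lie in (0, 1)")
    if fit.k <= 0:
        raise ValueError("half-life CI undefined for k <= 0")
    if fit.se_k == 0:
        return (fit.t_half, fit.t_half)
    if not (fit.se_k > 0):
        return (math.nan, math.nan)
    t_crit = float(stats.t.ppf(0.5 + confidence / 2.0, fit.n_points - 2))
    k_lo = fit.k - t_crit * fit.se_k
    k_hi = fit.k + t_crit * fit.se_k
    low = LN2 / k_hi
    high = LN2 / k_lo if k_lo > 0 else math.inf
    return (low, high)


def is_reliable(fit: DecayFit, alpha: float = 0.05) -> bool:
    """Two-part reliability rule for one fitted half-life.

    True iff the fit converged, shows significant decay (fit_p < alpha) and
    its 95% half-life interval is narrower than twice the half-life.  An
    infinite upper bound fails the width criterion.
    """
    if not fit.converged:
        return False
    if not (fit.fit_p < alpha):
        return False
    low, high = fit.ci95_thalf
    if not (math.isfinite(low) and math.isfinite(high) and math.isfinite(fit.t_half)):
        return False
    return (high - low) < 2.0 * fit.t_half


def fit_all(
    matrix: pd.DataFrame,
    alpha: float = 0.05,
    min_reliable: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit every transcript/condition/replicate series of a long matrix.

    Returns ``(fits, summary)``:

    * ``fits`` — one row per series with the fitted parameters, the 95%
      half-life interval, the fit p-value and the reliability flag;
    * ``summary`` — one row per (transcript, condition) with the count of
      reliable replicates, the condition-level acceptance flag
      (>= ``min_reliable`` reliable replicates) and the mean half-life over
      reliable replicates (NaN when none).

    Per-series failures are recorded as unreliable; the batch never aborts.
    """
    cols = ["transcript_id", "condition", "replicate", "time_min", "intensity"]
    missing = [c for c in cols if c not in matrix.columns]
    if missing:
        raise ValueError(f"expression matrix missing columns: {missing}")

    df = matrix.sort_values(cols[:4], kind="mergesort")
    keys = df[cols[:3]].drop_duplicates().to_numpy()
    sizes = df.groupby(cols[:3], sort=False).size().to_numpy()
    t_arr = df["time_min"].to_numpy(dtype=float)
    y_arr = df["intensity"].to_numpy(dtype=float)

    records = []
    nan = float("nan")
    pos = 0
    uniform = sizes.min() == sizes.max()
    times_ref = tuple(t_arr[: sizes[0]]) if uniform else None
    for (tid, cond, rep), size in zip(keys, sizes):
        t = t_arr[pos : pos + size]
        y = y_arr[pos : pos + size]
        pos += size
        ok = np.isfinite(y)
        try:
            if ok.all() and uniform and tuple(t) == times_ref:
                fit = fit_decay(t, y)
            else:
                fit = fit_decay(t[ok], y[ok])
        except ValueError:
            fit = DecayFit(nan, nan, nan, nan, (nan, nan), nan, False, int(ok.sum()), nan)
        records.append(
            (
                tid,
                cond,
                rep,
                fit.n_points,
                fit.y0,
                fit.k,
                fit.t_half,
                fit.se_k,
                fit.ci95_thalf[0],
                fit.ci95_thalf[1],
                fit.fit_p,
                fit.converged,
                is_reliable(fit, alpha),
                fit.residual_ss,
            )
        )

    fits = pd.DataFrame(
        records,
        columns=[
            "transcript_id",
            "condition",
            "replicate",
            "n_points",
            "y0",
            "k",
            "t_half",
            "se_k",
            "ci_low",
            "ci_high",
            "fit_p",
            "converged",
            "reliable",
            "residual_ss",
        ],
    )

    grp = fits.groupby(["transcript_id", "condition"], sort=False)
    summary = grp.agg(
        n_replicates=("replicate", "size"),
        n_reliable=("reliable", "sum"),
    ).reset_index()
    mean_thalf = (
        fits[fits["reliable"]]
        .groupby(["transcript_id", "condition"], sort=False)["t_half"]
        .mean()
        .rename("mean_thalf")
    )
    summary = summary.merge(mean_thalf, on=["transcript_id", "condition"], how="left")
    summary["condition_reliable"] = summary["n_reliable"] >= min_reliable
    return fits, summary
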