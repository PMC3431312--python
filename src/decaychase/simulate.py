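"""Synthetic chase-experiment generator.

Generates ground-truth transcriptomes and simulates the three kinds of
measurement the analysis consumes:

* array-style expression matrices over an actinomycin-D chase time course,
* qPCR Ct tables (target + stable reference gene) for the validation arm,
* nascent pre-mRNA relative quantities (4sU-style), a proxy for transcription.

The generative model is first-order decay from a steady state set by the
balance A = s * t_half / ln2 (abundance = synthesis rate x mean lifetime).
A perturbed condition multiplies half-lives of a planted subset and couples
synthesis inversely through the buffering exponent beta, so the generator can
realize anything from uncoupled stabilization (beta=0, abundance rises with
half-life) to over-compensated buffering (beta>1, stabilized transcripts lose
abundance).

Determinism: every stochastic draw flows from ``config.seed`` through
stage-keyed :func:`numpy.random.default_rng` streams (truth=0, chase=1,
qpcr=2, pre-mRNA=3), with array draws made in a single documented call each,
so identical (config, design, seed) give byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import LN2, ChaseDesign, SimConfig

__all__ = [
    "SyntheticTruth",
    "generate_truth",
    "simulate_chase",
    "simulate_qpcr",
    "simulate_pre_mrna",
]

_STREAM_TRUTH = 0
_STREAM_CHASE = 1
_STREAM_QPCR = 2
_STREAM_PREMRNA = 3

#: spread (natural-log sd) of the log-normal background distribution used by
#: the detection p-value surrogate
BACKGROUND_SIGMA = 1.0


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(stream)])


def _lognormal_eps(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative log-normal noise with mean 1 and coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma2 = math.log1p(cv * cv)
    mu = -0.5 * sigma2
    return rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=size)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth for one simulated two-condition transcriptome.

    ``table`` is long over (transcript_id, condition) with columns
    ``true_thalf`` (min), ``true_synthesis`` (units/min), ``true_steady_state``
    (intensity units, = synthesis * thalf / ln2), ``class_label``
    ({stabilized, destabilized, unchanged}) and ``thalf_multiplier`` (the
    perturbed/reference half-life ratio; 1 for unchanged transcripts).
    """

    table: pd.DataFrame
    config: SimConfig
    design: ChaseDesign

    @property
    def seed(self) -> int:
        return self.config.seed

    @property
    def transcripts(self) -> list[str]:
        return list(self.table["transcript_id"].unique())

    def condition_table(self, condition: str) -> pd.DataFrame:
        t = self.table[self.table["condition"] == condition]
        if t.empty:
            raise KeyError(f"unknown condition {condition!r}")
        return t.set_index("transcript_id")

    def classes(self) -> pd.Series:
        """Per-transcript class label, indexed by transcript id."""
        ref = self.condition_table(self.design.reference)
        return ref["class_label"]


def generate_truth(config: SimConfig, design: ChaseDesign) -> SyntheticTruth:
    """Draw per-transcript ground-truth half-lives and synthesis rates.

    Reference half-lives and synthesis rates are log-normal.  The first
    ``round(frac_stabilized * n)`` transcripts of a seeded permutation are
    stabilized with a half-life multiplier drawn uniformly from
    ``stabilization_fc_range``; the next ``round(frac_destabilized * n)``
    are destabilized with the reciprocal of such a draw.  Perturbed synthesis
    is ``reference * multiplier ** (-beta)`` and steady states are recomputed
    from the balance A = s * t_half / ln2.
    """
    rng = _rng(config.seed, _STREAM_TRUTH)
    n = config.n_transcripts

    thalf_ref = rng.lognormal(math.log(config.thalf_log_median), config.thalf_log_sigma, n)
    synth_ref = rng.lognormal(math.log(config.synth_log_median), config.synth_log_sigma, n)

    n_stab = int(round(config.frac_stabilized * n))
    n_destab = int(round(config.frac_destabilized * n))
    order = rng.permutation(n)
    lo, hi = config.stabilization_fc_range
    mult = np.ones(n)
    mult[order[:n_stab]] = rng.uniform(lo, hi, n_stab)
    mult[order[n_stab : n_stab + n_destab]] = 1.0 / rng.uniform(lo, hi, n_destab)

    labels = np.full(n, "unchanged", dtype=object)
    labels[order[:n_stab]] = "stabilized"
    labels[order[n_stab : n_stab + n_destab]] = "destabilized"

    beta = config.buffering_exponent_beta
    thalf_kd = thalf_ref * mult
    synth_kd = synth_ref * mult ** (-beta)

    ids = [f"T{i:05d}" for i in range(n)]
    ref, kd = _make_condition_frames(
        design, ids, labels, mult, thalf_ref, synth_ref, thalf_kd, synth_kd
    )
    table = pd.concat([ref, kd], ignore_index=True)
    return SyntheticTruth(table=table, config=config, design=design)


def _make_condition_frames(design, ids, labels, mult, thalf_ref, synth_ref, thalf_kd, synth_kd):
    def frame(cond, thalf, synth):
        return pd.DataFrame(
            {
                "transcript_id": ids,
                "condition": cond,
                "true_thalf": thalf,
                "true_synthesis": synth,
                "true_steady_state": synth * thalf / LN2,
                "class_label": labels,
                "thalf_multiplier": mult,
            }
        )

    return frame(design.reference, thalf_ref, synth_ref), frame(
        design.perturbed, thalf_kd, synth_kd
    )


def detection_pvalue(intensity, background_level: float, sigma: float = BACKGROUND_SIGMA):
    """Detection p-value surrogate: upper-tail probability of an intensity
    under a log-normal background distribution with median ``background_level``.

    High signal-to-background gives p near 0; signal at the background median
    gives p = 0.5.  With ``background_level`` 0 every positive intensity is
    detected with p = 0.  This preserves the semantics of a probe-level
    detection-above-background test without probe data.
    """
    intensity = np.asarray(intensity, dtype=float)
    if background_level <= 0:
        return np.where(intensity > 0, 0.0, 1.0)
    z = (np.log(np.maximum(intensity, np.finfo(float).tiny)) - math.log(background_level)) / sigma
    return stats.norm.sf(z)


def simulate_chase(
    truth: SyntheticTruth,
    design: ChaseDesign | None = None,
    config: SimConfig | None = None,
) -> pd.DataFrame:
    """Simulate the chase expression matrix implied by ``truth``.

    Measured intensity for transcript i, condition c, replicate r, time t is

        A(i, c) * exp(-ln2 * t / t_half(i, c)) * eps + background_level

    with eps log-normal (mean 1, CV ``noise_cv``) independent across
    observations.  Decay runs over the recorded time points only; t=0 is the
    end of the Act-D pretreatment.  A detection p-value is attached to every
    t=0 row, computed from the measured t=0 intensity against the background
    distribution (NaN on later rows).

    Returns a long DataFrame with columns transcript_id, condition,
    replicate, time_min, intensity, detection_p.
    """
    design = design or truth.design
    config = config or truth.config
    rng = _rng(config.seed, _STREAM_CHASE)

    times = np.asarray(design.time_points)
    conditions = list(design.conditions)
    n_rep = design.n_replicates

    ref = truth.condition_table(conditions[0])
    ids = list(ref.index)
    n_t, n_c, n_k = len(ids), len(conditions), len(times)

    A = np.empty((n_t, n_c))
    thalf = np.empty((n_t, n_c))
    for j, cond in enumerate(conditions):
        tab = truth.condition_table(cond).loc[ids]
        A[:, j] = tab["true_steady_state"].to_numpy()
        thalf[:, j] = tab["true_thalf"].to_numpy()

    # one draw call in documented axis order: transcript x condition x replicate x time
    eps = _lognormal_eps(rng, config.noise_cv, (n_t, n_c, n_rep, n_k))
    signal = A[:, :, None, None] * np.exp(
        -LN2 * times[None, None, None, :] / thalf[:, :, None, None]
    )
    intensity = signal * eps + config.background_level

    det = np.full((n_t, n_c, n_rep, n_k), np.nan)
    det[:, :, :, 0] = detection_pvalue(intensity[:, :, :, 0], config.background_level)

    idx = pd.MultiIndex.from_product(
        [ids, conditions, range(1, n_rep + 1), times],
        names=["transcript_id", "condition", "replicate", "time_min"],
    )
    out = pd.DataFrame(
        {"intensity": intensity.ravel(), "detection_p": det.ravel()}, index=idx
    ).reset_index()
    return out


def simulate_qpcr(
    truth: SyntheticTruth,
    design: ChaseDesign | None = None,
    transcripts: Sequence[str] | None = None,
    noise_sd_cycles: float = 0.2,
    c0_target: float = 30.0,
    c0_reference: float = 20.0,
) -> pd.DataFrame:
    """Simulate a qPCR Ct table over the chase for selected transcripts.

    Ct_target = c0_target - log2(true quantity at t) + Gaussian noise;
    Ct_reference comes from a stable unit reference quantity (a Gapdh-like
    gene), so it is c0_reference + noise at every time point.

    Returns a long DataFrame with columns transcript_id, condition,
    replicate, time_min, ct_target, ct_reference.
    """
    design = design or truth.design
    if noise_sd_cycles < 0:
        raise ValueError("noise_sd_cycles must be >= 0")
    rng = _rng(truth.seed, _STREAM_QPCR)

    known = set(truth.transcripts)
    if transcripts is None:
        transcripts = truth.transcripts
    unknown = [t for t in transcripts if t not in known]
    if unknown:
        raise KeyError(f"unknown transcript ids: {unknown}")

    times = np.asarray(design.time_points)
    conditions = list(design.conditions)
    n_rep = design.n_replicates
    n_t, n_c, n_k = len(transcripts), len(conditions), len(times)

    A = np.empty((n_t, n_c))
    thalf = np.empty((n_t, n_c))
    for j, cond in enumerate(conditions):
        tab = truth.condition_table(cond).loc[list(transcripts)]
        A[:, j] = tab["true_steady_state"].to_numpy()
        thalf[:, j] = tab["true_thalf"].to_numpy()

    quantity = A[:, :, None, None] * np.exp(
        -LN2 * times[None, None, None, :] / thalf[:, :, None, None]
    )
    shape = (n_t, n_c, n_rep, n_k)
    noise_t = rng.normal(0.0, noise_sd_cycles, shape) if noise_sd_cycles else np.zeros(shape)
    noise_r = rng.normal(0.0, noise_sd_cycles, shape) if noise_sd_cycles else np.zeros(shape)

    ct_target = c0_target - np.log2(quantity) + noise_t
    ct_reference = c0_reference + noise_r

    idx = pd.MultiIndex.from_product(
        [list(transcripts), conditions, range(1, n_rep + 1), times],
        names=["transcript_id", "condition", "replicate", "time_min"],
    )
    return pd.DataFrame(
        {"ct_target": ct_target.ravel(), "ct_reference": ct_reference.ravel()}, index=idx
    ).reset_index()


def simulate_pre_mrna(
    truth: SyntheticTruth,
    n_replicates: int = 3,
    noise_cv: float = 0.1,
    transcripts: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Simulate nascent pre-mRNA relative quantities (4sU-style).

    relative_quantity is proportional to the true synthesis rate with
    multiplicative log-normal noise; the proportionality constant (the
    reference-RNA normalization, a 7SL-like stable RNA) is the same in both
    conditions, so condition ratios reflect transcription-rate ratios.

    Returns a long DataFrame with columns transcript_id, condition,
    replicate, relative_quantity.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = _rng(truth.seed, _STREAM_PREMRNA)

    if transcripts is None:
        transcripts = truth.transcripts
    conditions = list(truth.design.conditions)
    n_t, n_c = len(transcripts), len(conditions)

    synth = np.empty((n_t, n_c))
    for j, cond in enumerate(conditions):
        synth[:, j] = truth.condition_table(cond).loc[list(transcripts), "true_synthesis"].to_numpy()

    eps = _lognormal_eps(rng, noise_cv, (n_t, n_c, n_replicates))
    rq = synth[:, :, None] * eps

    idx = pd.MultiIndex.from_product(
        [list(transcripts), conditions, range(1, n_replicates + 1)],
        names=["transcript_id", "condition", "replicate"],
    )
    return pd.DataFrame({"relative_quantity": rq.ravel()}, index=idx).reset_index()
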