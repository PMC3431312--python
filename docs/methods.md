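# Methods

## The measurement and the model

`decaychase` analyzes transcription-shutoff ("chase") experiments: cells are
treated with actinomycin D to stop transcription, and transcript abundance
is measured at a handful of later time points. With synthesis off, each
mRNA's abundance follows first-order decay,

    y(t) = y0 · exp(−k t),        t½ = ln2 / k,

and the package estimates `k` (and hence the half-life t½) per transcript,
per replicate, per condition, then asks which transcripts decay at
significantly different rates between two conditions (e.g. a knockdown of a
decay factor versus control), and finally how those decay changes relate to
abundance and transcription.

The default chase design is five time points at 0, 10, 50, 110 and 230
minutes in three biological replicates, with t=0 taken 30 minutes after
drug addition (the pretreatment interval is metadata only: a fixed time
offset multiplies every point of an exponential by the same constant and
therefore cancels in the rate estimate).

## Decay fitting

Fitting is nonlinear least squares in linear intensity space with the rate
constrained non-negative. The amplitude is profiled out analytically — for
fixed `k` the optimal `y0` is `Σy·e / Σe²` with `e = exp(−kt)` — leaving a
one-dimensional objective in `k` minimized by bounded Brent search on
[0, 2 min⁻¹] followed by Newton polishing on the profiled gradient. This
recovers noiseless series to ~1e−15 relative error and costs well under a
millisecond per series, which keeps 10⁵-series calibration studies cheap.

Uncertainty comes from the Gauss–Newton curvature at the optimum:
`cov = s² (JᵀJ)⁻¹` with `s² = RSS/(n−2)`. Three derived quantities drive
everything downstream:

* **fit p-value** — one-sided Wald test of H₀: k=0 using k/se(k) against a
  t distribution with n−2 degrees of freedom. One-sided because the filter
  asks "does this series decay at all"; a residual-bootstrap null
  reproduces this p-value within Monte-Carlo error in the test suite.
* **half-life CI** — Wald on `k`, inverted: (ln2/k_hi, ln2/k_lo). The
  interval is built on the rate scale because the half-life's sampling
  distribution at n=5 is strongly right-skewed; if the rate interval
  reaches zero the upper half-life bound is +∞.
* **reliability** — a fitted half-life is accepted when the fit p-value is
  < 0.05 *and* the 95% CI is narrower than twice the half-life. A
  condition's half-life for a transcript is accepted when at least two
  replicates are reliable, and equals the mean over reliable replicates.

Boundary and degenerate cases: a non-decaying (flat or rising) series sits
at k=0 with t½=+∞, p=1, converged — and is simply unreliable, not an error.
A perfect fit (zero residuals) yields se(k)=0, p=0 and a point interval.
Series with fewer than three usable points are recorded as unconverged;
batch fitting never aborts on a single bad series.

Calibration, measured by the acceptance script rather than asserted:
at 15% measurement CV the 95% intervals cover the truth ~94% of the time
(Wald-on-k under-covers slightly at n=5), the null decay test fires at
~3.5–4.5%, slightly conservative because of the k≥0 boundary and because
the noise is multiplicative while the objective is unweighted.

## Differential stability

Per transcript with accepted half-lives in both conditions, the reliable
replicate half-lives are compared by a two-sided two-sample Student t-test
(pooled variance; Welch is a flag — groups are small and equally sized, so
pooling is the default). The half-life fold change is the ratio of
per-condition means (replicates are unpaired, so a mean of ratios has no
referent). Calls use raw p < 0.05 with no multiplicity correction — the
census-style outputs mirror how such screens are usually reported — but a
Benjamini–Hochberg q-value column is included for information. Zero-variance
groups are handled explicitly: equal means → p=1, unequal → p=0 with a
warning (this makes noiseless simulations behave exactly).

Reported fold changes are rounded to two decimals from unrounded means, and
abundance fold changes use the symmetric signed convention (+r for r≥1,
−1/r otherwise).

## Normalization and the detection filter

For raw array-style matrices, each array (one condition/replicate/time
slice) is first median-scaled to the median of per-array medians, then every
value is divided by its array's 5th percentile so low-end signal aligns
across arrays. Percentiles use linear interpolation. Both steps are
multiplicative, so the pipeline is invariant to per-array scale factors
(checked by a property test). A transcript counts as expressed in a
condition when its detection p-value at t=0 is strictly below 0.05 in at
least two replicates.

Two documented caveats. First, per-array normalization across chase time
points removes any decay component shared by *all* transcripts; without
spike-ins this is unavoidable, and half-lives are therefore relative to the
bulk. Second, simulator output is generated background-corrected on a
common scale and is treated as already normalized: re-scaling decaying
arrays to a common median would inject exactly the artifact above, which is
why `input_kind` distinguishes raw from normalized matrices.

## Abundance, coupling, and the steady-state balance

Abundance is estimated from the t=0 arrays (mean over replicates) — the
chase's own baseline. Under first-order turnover at steady state

    A = s · t½ / ln2,

so fold changes factor exactly as `fc_A = fc_s · fc_t½` and a
transcription-rate change is inferred as `fc_s = fc_A / fc_t½`. This balance
is an interpretive model (it assumes the perturbed cells reached a new
steady state); the package keeps it as an exact bookkeeping identity.
Transcriptional buffering — synthesis falling when decay slows — appears as
stabilized transcripts with flat or reduced abundance, a negative Spearman
correlation between half-life and abundance fold changes among significant
transcripts (rank-based, robust on the ratio scale; computed only when ≥3
significant transcripts with spread), and measured nascent pre-mRNA fold
changes below 1. The pre-mRNA check is a per-transcript two-sample t-test
on reference-normalized quantities with a sign-agreement verdict
(agree/disagree when significant, indeterminate otherwise).

The ≥1.5-fold abundance census uses the signed-magnitude convention
(`fc ≥ 1.5` or `fc ≤ 1/1.5`), reporting the up/down split and the down
fraction.

## qPCR arm

Ct tables are converted by the ΔCt rule `q = E^−(Ct_target − Ct_ref)` with
amplification efficiency E=2 by default (perfect doubling; exposed as a
parameter — no standard-curve estimation is attempted). Each
transcript/condition series is rescaled so the mean t=0 quantity is 1,
which makes the series unit-free and lets the same decay fitter serve both
arrays and qPCR. Adding any constant to both Ct columns changes nothing
(reference-gene invariance).

## What the simulator emulates — and what it does not

`generate_truth` draws reference half-lives log-normal(median 120 min,
σ=0.6 — most mass in the 50–400 min range typical of the transcripts such
chases resolve) and synthesis rates log-normal(median 1 unit/min, σ=0.8).
By default 2.9% of transcripts are stabilized with a half-life multiplier
uniform on [1.2, 2.4] and 1.73% destabilized with the reciprocal, matching
the effect sizes and prevalence such a knockdown screen reports. The
buffering exponent β sets perturbed synthesis to `reference · mult^(−β)`:
β=0 uncoupled, β=1 perfect buffering (abundance unchanged), β>1 overshoot
(stabilized transcripts lose abundance). β=1 is the default;
`log fc_A = (1−β) log mult` holds exactly by construction.

`simulate_chase` realizes exactly the model the fitter assumes: steady
state × exponential decay × i.i.d. log-normal noise with mean 1 and a
configurable CV (default 0.15 — the underlying array study reports no noise
magnitude, so this is an assumption, chosen to make the reliability filter
bite realistically), plus an optional additive background floor. The
detection p-value is a surrogate for a probe-level
detection-above-background test: the upper-tail probability of the measured
t=0 intensity under a log-normal background distribution (median
`background_level`, σ=1). With the default background of 0 (fully
background-corrected intensities) every positive signal is detected.

Deliberately not emulated: probe-level structure and GC-content background,
correlated noise between replicates or across time (noise is i.i.d.), decay
during the 30-min pretreatment, non-exponential (biphasic/delayed) decay,
secondary transcriptome-wide abundance shifts, and any sequence features.
Passing tests therefore demonstrate correctness of the estimation machinery
under the model's own assumptions, not robustness to array artifacts.

Determinism: all draws descend from one integer seed through stage-keyed
`numpy` generator streams (truth 0, chase 1, qPCR 2, pre-mRNA 3), each
stage drawing its arrays in one documented axis order, so identical
configurations reproduce outputs byte for byte.

## Problem sizes and numerical choices

The calibration studies use 500 transcripts (noiseless recovery), 1000
(noisy recovery/coverage), 10×2000 (global-null type-I error), 4×400 (noise
sweep) and 400 (buffering phenotypes) — large enough that binomial error on
the measured rates is a few tenths of a percent, small enough that the
whole suite runs in minutes on one core. Optimizer tolerances: Brent xatol
1e−6 then ≤12 Newton steps to machine precision; rates below 1e−8 min⁻¹
are treated as the k=0 boundary (t½ ≈ 10⁸ min is indistinguishable from
flat on a 230-min chase).

## Known limitations

* Wald intervals on k under-cover slightly at n=5 (measured ~94%, nominal 95%).
* Unweighted least squares with multiplicative noise down-weights late,
  low-signal points less than a variance-weighted fit would; at CV ≤ 0.2
  the effect on recovered half-lives is small (median error ~7% at CV 0.15).
* The goodness-of-fit filter tests "decays at all", not curve-shape
  adequacy; a biphasic transcript can pass with a biased half-life.
* Half-lives longer than ~3× the last chase point are rarely reliable on
  the default grid — a property of the design, not the estimator.
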