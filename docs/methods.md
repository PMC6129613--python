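# Methods

This note documents the models and procedures the package implements,
the parameter choices that matter, and what the synthetic-data
generators do and do not emulate.

## Direct multifractal spectrum estimation

The estimator operates on a non-negative series — for audio, the
absolute value of the pressure waveform.  Magnitudes are used because
the method is undefined for non-positive measures and, for signals
symmetric about zero, the sign sequence is redundant with the
magnitude sequence.  The direct (partition-based) method is preferred
here over variance-scaling alternatives (multifractal DFA,
wavelet-modulus-maxima) because the quasi-periodic, strongly
nonstationary character of audio defeats polynomial detrending.

For bin size `L` the series is cut into nonoverlapping bins from the
start, the trailing remainder discarded, and bin mass fractions
`P_i(L)` formed.  A one-parameter family of measures
`μ_i(q, L) = P_i^q / Σ_j P_j^q` re-weights the bins toward
concentrated (`q > 0`) or rarefied (`q < 0`) regions.  Two quantities
are regressed against `ln L` by ordinary least squares across scales:
`Σ_i μ_i ln P_i`, whose slope is the singularity strength `α(q)`, and
the Shannon entropy `Σ_i μ_i ln μ_i`, whose slope is the dimension
`f(q)`.  A moment order `q` is retained only when both regressions are
close to linear, `|r| > r_min` jointly (the retention rule is stated
ambiguously in the source literature between joint and separate
application; joint is implemented and is the stricter reading).  The
summary statistic is the spectrum width `w_MF = α_max − α_min` over
retained `q`, computed as a plain max−min even when the retained set
is non-contiguous.

Defaults and rationale:

- **q grid**: integers −300…300 in steps of 5, with 0 and 1 always
  included (μ(0) uniform and μ(1) = P are exact identities used as
  internal checks).  The range matches the analysis the package
  reimplements; the step is a cost/coverage compromise — endpoints of
  the spectrum are reached by |q| ≈ 50 on the signals used here.
- **Scales**: powers of two from 4 up to length/4.  The source
  analysis does not state its scale range; powers of two keep the bins
  nested and give the reference cascade exactly linear scaling.
- **r_min = 0.995**, as specified for the original analysis.
- **Zero-mass bins** are excluded at every scale, with renormalization
  over the retained bins.  Audio magnitudes contain exact zeros
  (silences, zero crossings); without exclusion every negative-q
  moment diverges, and an epsilon floor would put an arbitrary scale
  into the measure.  The exclusion is applied per scale before any μ
  is formed, so `Σ_i P_i = Σ_i μ_i = 1` holds exactly at every (q, L).
- **Numerical stability**: μ is computed entirely in log space via
  log-sum-exp; `P^±300` overflows double precision otherwise.  Bins
  whose μ underflows to zero contribute exactly zero to the entropy
  summand (the `x ln x → 0` limit).

Validation oracle: the binomial multiplicative cascade with weight
`p`, whose spectrum is known in closed form — the singularity
exponents span `[−log2 max(p, 1−p), −log2 min(p, 1−p)]`, so the width
for `p = 0.7` is ≈ 1.2224.  On a 2¹⁴-cell cascade the estimator
recovers this to well within 0.01; the `p = 0.5` cascade (a uniform
measure) and constant series give widths below 10⁻¹².

Scale invariance: the width is mathematically invariant under
`u → c·u, c > 0`.  In IEEE-754 arithmetic the invariance is bit-exact
when `c` is a power of two and holds to ~10⁻⁹ (accumulated ulps in
the renormalization) for arbitrary `c`; the tests assert both forms.

## IAAFT surrogates and t_MF

Each surrogate starts from a seeded random permutation of the original
values and alternates two projections: imposing the original amplitude
spectrum (keeping current phases) and rank-matching back onto the
original value multiset.  The iteration count is fixed at 1000 with an
early exit when the rank permutation stops changing — an exact fixed
point, after which further iterations are no-ops.  Structured noise
(AR(1), cascades) typically converges within tens of iterations;
strongly quasi-periodic audio generally runs the full budget.  The
value multiset is conserved exactly by construction; spectral fidelity
is tracked per surrogate as the relative amplitude-spectrum error.

Surrogates are generated on the *signed* waveform and magnitudes taken
afterwards, mirroring the order of the original analysis: the linear
structure being tested lives in the signed series.  Surrogate `i` of
an ensemble uses `base_seed + i`, so ensembles are reproducible and
streams independent.

The statistic is
`t_MF = (w_MF − mean(w_Surr)) / SE(w_Surr)` over a 50-surrogate
ensemble; positive values mean the original spectrum is wider than its
linear expectation.  The denominator follows the literal
standard-error reading, `SD(w_Surr)/√50`; a `se_mode="sd"` switch
provides the plain-SD variant.  **The choice matters**: the two
versions differ by a factor of √50 ≈ 7.07, and under the default the
statistic's null distribution on linear controls has a standard
deviation near 7, not 1.  Any reported t must state its denominator.
Calibration checks in this package (null centering on AR(1) controls,
|t| > 3 rarity, cascade positivity) are therefore run on the
ensemble-SD scale, where a ±3 band is meaningful; on AR(1) controls
the SD-scaled statistic has mean ≈ −0.3 and exceeds |3| in under 5%
of runs, while multiplicative cascades give t in the hundreds.

## Stimulus synthesis and pitch-period shuffling

Targets and contexts are synthesized by impulse-train excitation
through cascaded second-order (Klatt-style) resonators, one per
formant, with linearly interpolated center frequencies — the simplest
source–filter architecture that produces genuine pitch periods for the
shuffling procedure.  The target continuum follows the published
recipe exactly: 11 steps of 215 ms, F3 onset 1800 + 100k Hz gliding to
a 2500 Hz offset, F1 500→800 Hz, F2 1600→1200 Hz, F4 constant at
3500 Hz.  Contexts are 375 ms; tone analogs are pure sinusoids at the
liquid's F3 offset (2600 Hz for [al], 1820 Hz for [aɹ]),
intensity-matched to the speech-like contexts by RMS.

Unstated parameters, fixed once: sampling rate 22.05 kHz (the original
recordings' rate is unreported; any rate ≥ 4× the highest formant
works and the rate is a parameter everywhere), glottal f0 100 Hz (a
plausible male voice, giving 10 ms pitch periods so that 11 periods
occupy 110 ms of the vowel), vowel/liquid boundary at 60% of the
context (the source describes shuffling "before the liquid" without a
boundary).

Shuffling: the pitch period is estimated from the autocorrelation peak
of the vowel region (50–400 Hz search band); segment boundaries are
the positive-going zero crossings nearest integer multiples of that
period, which avoids audible clicks without crossfading.  Eight
distinct non-identity permutations of the 11 segments are drawn
uniformly without replacement, seeded.  Shuffling provably preserves
duration, RMS, and the sample multiset of the shuffled span, and every
sample outside the span — including the liquid formant offsets that
carry the spectral-contrast cue — is bit-identical to the original.

## Trajectory measures

The straight reference is the chord from the first to the last
recorded sample.  MD is the maximum perpendicular distance to that
chord; AUC is the unsigned area between polyline and chord
(trapezoidal integration in chord-aligned coordinates, opposite-side
lobes summed); x-flips counts sign changes of successive x-differences
after zero differences are dropped (a stationary cursor is not a
reversal).

The entropy covariates are a documented stand-in: the published
decomposition is described only functionally in the source analysis,
so ψ is defined here as the Shannon entropy (natural log) of a 16-bin
histogram of chord-orthogonal deviations over all samples, and ξ the
same entropy over samples whose gradient-based speed exceeds the
trajectory mean.  On a constant-speed path no sample is strictly above
the mean and ξ falls back to all samples (ξ = ψ).  These covariates
preserve the slow/fast decomposition role in the regression models but
must not be claimed identical to the published estimator.  No
temporal-correlation corrections are applied: at 58 Hz and ~650 ms
responses, trajectories are ~30–40 samples, too short to estimate
them.

## Response models

Cumulative "GA" counts across a participant's 176 trials are modeled
by Poisson regression with a log link (the marginal probability of one
more event); trialwise responses by logistic regression.  Step enters
through degree-1/2 orthogonal polynomial codes over the 11 levels
(QR-orthogonalized Vandermonde, zero mean, unit norm, linear code
increasing).  Model terms are interaction families: each family
expands to all lower-order interactions and main effects, deduplicated
across families.  Context is dummy-coded with real speech as the
reference level; Precursor is coded 1 ([al]) / 2 ([aɹ]) — the source
text is internally inconsistent about this coding, so it is data, not
hard-coded, in this package.  Participant intercepts are fixed-effect
dummies (the documented fallback for random intercepts; statsmodels
offers no Wald-table GLMM).  A consequence worth knowing: with
participant dummies, between-participant factors such as Context are
aliased and must be dropped from the fixed part — the pipeline's
demonstration fits therefore pool over participants, while the
parameter-recovery fits (whose terms all vary within participant) keep
the dummies.  No multiple-testing correction is applied; p-values are
raw Wald tests.

The multifractal coefficient block `(B_W, B_t, B_Wt)` implies a
closed-form percent probability of one more event,
`100·exp(B_W·w + B_t·t + B_Wt·w·t)`, which the package evaluates for
each context token's covariates; with the published block
(−0.34, 0.06, −0.39) this reproduces the published predicted
probabilities (91.10 / 71.36 / 37.33%) to two decimals.  The published
real-speech [aɹ] entry (68.89%) is *not* recovered from the rounded
coefficients (closed form gives 68.74%) and is excluded from checks.

## Synthetic-data generators

The generators produce data with the statistical structure the
analysis assumes, at the study's stated design sizes: 42 participants,
176 trials each (16 × 11 steps), precursors balanced 88/88, 8 blocks
of 22 trials (the block partition is implied, not stated, in the
source; 8 × 22 is the documented default), counterbalancing alternating
across participants.  Responses come from a logistic forward model
whose linear predictor contains the multifractal block evaluated at
per-token covariates; real-speech and tone tokens carry the published
(w_MF, t_MF) pairs and the eight simulated-speech variants are spread
evenly over the published per-precursor ranges.  RTs are log-normal
with mean 650 ms and log-SD 0.31, putting the 5th–95th percentiles
near 400–1100 ms (the source states only the mean; log-normal is a
convention, not a claim).  Trajectories are minimum-jerk paths sampled
at 58 Hz with seeded Gaussian jitter and a known number k of injected
x-reversals, k following a quadratic ambiguity profile peaking at the
continuum midpoint; with zero jitter the measured flip count equals k
exactly, which is the ground-truth contract the metric tests use.

What passing tests on these data do *not* show: that real speech obeys
the forward model (responses here are generated by the very model form
later fitted, which is the point of a recovery study but says nothing
about human behavior); that the synthesized stimuli are acoustically
equivalent to the original recordings (the published per-stimulus
w_MF/t_MF values derive from unreleased audio and are treated as
inputs, not reproduction targets); or that the entropy stand-ins match
the published covariates.

## Problem sizes and determinism

Reference computations use 2¹⁴-cell cascades for estimator validation,
4096-sample AR(1) controls with 50 surrogates × 1000 iterations for
calibration, and 20 replicates of a 42 × 176 cohort for parameter
recovery; these sizes put every quantity's sampling error well inside
the tolerances asserted.  Every stochastic function takes an explicit
seed, derived deterministically for sub-streams (surrogate i uses
seed + i), and identical (config, seed) pairs reproduce every file the
pipeline writes bit-for-bit.
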