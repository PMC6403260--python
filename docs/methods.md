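# Methods

## The model

An observer awaits a brief, near-threshold target whose onset time is drawn
uniformly from a known interval range `[t_min, t_max]` (in the two designs
emulated here, 700–1300 ms and 500–3000 ms after a temporal cue).  The
package models the moment-by-moment allocation of visual attention as a
function of the conditional probability that the target is *about to become
relevant*, built up in four steps.

**Miss-corrected hazard.**  With density `f(t)` and CDF `F(t)`, the hazard
of the target appearing now, given that it has not yet been *detected*, is

    h(t) = f(t) / (1 − k·F(t)),            k = 1 − P(ND | A),

where `P(ND|A)` is the probability that a presented target goes unnoticed.
For threshold-level targets `P(ND|A) ≈ 0.5`, so `k = 0.5` throughout (fixed,
never fitted).  `k → 1` recovers the classical hazard `f/(1−F)`; `k = 0`
(every presentation missed) reduces to the plain density.

**Scalar timing noise.**  Elapsed time is known only through a measurement
`m` with likelihood `p(m|t) = N(t, (w·t)²)` — the SD grows linearly with
elapsed time with Weber fraction `w` (dimensionless; fitted values near
0.1–0.15 are typical for interval timing).  The *subjective* hazard given a
measurement is the ratio of blurred integrals

    ĥ(m) = ∫ f(t) p(m|t) dt / ∫ (1 − k F(t)) p(m|t) dt.

**Predictive look-ahead.**  Because attention must be in place *before* the
stimulus, the current attention level is assumed to reflect not only the
hazard now but the probability of the target arriving in the near future,
weighted by a decaying exponential with time constant `mu` (seconds):

    h_pred(t) = [ (1/mu) ∫_t^∞ f(τ) e^{−(τ−t)/mu} dτ ] / (1 − k F(t)).

For the uniform distribution the numerator has a closed form, implemented
piecewise (below, inside and above the support).  `mu = 0` is the exact
non-predictive limit.  The subjective predictive hazard replaces `f` in the
numerator of `ĥ(m)` with this look-ahead numerator; the denominator keeps
`1 − k F(t)` (the look-ahead modifies what the observer is preparing for,
not the conditioning on non-detection).

**Threshold read-out.**  The measurement on a given trial is unobservable,
so the predicted contrast threshold at true time `t` averages over it:

    y(t) = β0 + β1 · ∫ ĥ(m) p(m|t) dm,

with `β0, β1` free scaling parameters per experiment (percent Michelson
contrast; `β1 < 0` whenever more anticipation means lower thresholds).

## Numerical evaluation

All integrals use fixed grids with composite Simpson weights.  The t-domain
is the support extended by `trunc_sd · w · t_max` on each side (clipped
below at `t_min/10`), split at `t_min` and `t_max` so every integrand is
smooth within a segment; nodes are allocated across segments in proportion
to log-length (the SD `w·t` shrinks with `t`), with at least 45% reserved
for the support segment.  Defaults: `n_grid = 512` nodes, `trunc_sd = 8`.
The truncated Gaussians are *not* renormalised; truncation error is
controlled by the 8-SD half-width.

Two regimes need special handling:

* **Small `mu`.**  The look-ahead numerator has boundary layers of width
  `mu` at the support edges.  They are integrated exactly in the
  substituted variable `s = (edge − t)/mu` (truncated at 45 e-foldings), so
  the `mu → 0` collapse onto the classical subjective hazard holds to
  better than 1e-3 down to `mu = 1e-6` s, and `mu = 0` falls back to the
  classical code path identically.
* **Small `w`.**  When the measurement SD falls below ~5 grid cells (and
  `trunc_sd·w < 0.5`), each measurement gets its own window covering ±8 of
  its SDs, again split at the support edges.  This resolves the `w → 0`
  collapse onto the noiseless hazards without moving the truncation domain.

A halved-grid convergence contract (`quadrature_error`) verifies that
halving `n_grid` changes the subjective hazards by < 1e-4 relative; it is
enforced in tests for measurements from `t_min` up to `1.1·t_max`, the
region that carries essentially all of the weight in the threshold
read-out.  For measurements on the far sub-support tail the halved (256-
node) grid is the limiting factor (~1e-3 there, while the full default grid
is accurate to ~1e-5); values in that regime are validated against an
independent Monte-Carlo importance-weighting oracle instead.

The m-integral in `y(t)` spans `t ± trunc_sd·w·t` with Simpson weights; a
grid-refinement check (512 vs 1024 nodes) agrees to < 1e-4 relative.

## Estimation

**Shared-slope psychometric MLE (per subject).**  2AFC accuracy is modelled
as `P(correct) = 0.5 + (0.5 − λ)·Φ((log10 c − log10 α_j)/σ)` with lapse
`λ = 0.01` fixed, one threshold per interval level and one slope shared
across levels; the reported threshold is the contrast at 75% correct.
Counts are aggregated per (level, contrast) cell and the joint binomial
likelihood maximised by L-BFGS-B from three slope starts.  Degenerate data
are rejected: fewer than 3 distinct contrasts per level, all-correct or
all-wrong levels, and — for guess-rate responding, which leaves the MLE
interior but flat — a likelihood probe requiring that shifting any level's
threshold by a decade costs at least 2 nats.

**Group bootstrap (wide-range design).**  All subjects' trials are pooled
and fitted with the shared-slope model; `n_boot` replicates resample
subjects with replacement and refit, giving a bootstrap SD per interval.
Degenerate replicates are redrawn (max 10 attempts).

**Hierarchical Bayesian duration judgments.**  Each subject's probability
of judging interval `x` "longer than one second" is `Φ((x − PSE_i)/σ_i)`;
subject PSEs and slopes are drawn from Gaussian population distributions
with wide uniform hyperpriors (PSE mean ∈ [0.2, 3.0] s, PSE SD ∈ (0, 1.5] s,
slope mean ∈ [0.01, 2.0] s, slope SD ∈ (0, 1.0] s).  Sampling is
random-walk Metropolis–Hastings with block updates — all subject PSEs
jointly (subjects are conditionally independent), all slopes, then each
hyperparameter — with proposal scales adapted during burn-in toward ~30%
acceptance.  Defaults: 4 chains × 20,000 iterations, 50% burn-in; the fit
refuses to report if the post-tuning acceptance rate leaves [0.05, 0.8].
The population-mean PSE is summarised by the mode of a Gaussian KDE
(Silverman bandwidth) and the central 2.5–97.5% interval of the pooled
post-burn-in samples.  Negative-slope proposals are rejected, which
truncates the Gaussian slope population at zero without renormalising it; a
known, second-order approximation.

**Joint attention-model fit.**  The narrow-range curve (7 smoothed points)
and the wide-range curve (11 points) are fitted together by least squares
with shared `w` (and `mu` in the predictive variant) and per-curve
`β0, β1`.  The betas are profiled out in closed form, leaving a 1–2
dimensional objective minimised by Nelder–Mead from ≥ 10 log-scaled
Latin-hypercube starts; the predictive fit adds one start at the classical
optimum with `mu = 0`, where the two objectives coincide exactly, so the
nested-model inequality `RSS_full ≤ RSS_reduced` holds by construction
(`mu` is bounded in [0, 2] s, `w` in [0.01, 0.5]).  Fitting uses a lighter
128-node quadrature by default — its error (~1e-6 relative) is orders of
magnitude below the residual noise.  Variants are compared with the
extra-sum-of-squares F test: `F = (ΔRSS/1)/(RSS_full/12)` on 18 points with
6 vs 5 parameters; a Gaussian likelihood-ratio χ² form is available as an
alternative (`method="chi2"`).

**Pipeline order (narrow-range analysis).**  Per-subject thresholds on the
9 raw levels → per-subject permutation test for short-term fluctuation (SD
of successive-interval differences, labels shuffled 10,000 times, one-sided
upper tail, add-one p estimator) → window-3 moving average (9 → 7 points)
→ subject centering (subtract subject mean, add grand mean) → one-way
repeated-measures ANOVA (no sphericity correction; partial η² =
SS_effect/(SS_effect+SS_error)) and Fisher-LSD pairwise comparisons using
the ANOVA's pooled error.  This order matches the df structure of a 15 × 7
design.  The wide-range analysis centres per-subject correction rates on
all 11 levels (no smoothing) and estimates thresholds at group level only.
Note two properties of this centering chain that are weaker than one might
expect: adding a constant to one subject shifts *every* centered profile by
`c/n` through the grand mean (patterns are unchanged), and smoothing and
centering commute only up to a final re-centering, because valid-region
means differ from raw means.

## Synthetic observers

The generator emulates the three designs so the whole chain is testable
without any data download.  Its defaults are the study conditions, chosen
once:

* **Attention truth**: `w = 0.11`, `mu = 0.106` s, `k = 0.5` — the model's
  plausible operating point.  Scaling: narrow range `β0 = 0.81`,
  `β1 = −0.16` (curve ≈ 0.51–0.63% contrast); wide range `β0 = 2.06`,
  `β1 = −1.6` (≈ 1.1–1.6%).  These place the curves on the percent-contrast
  scales typical of each design and give modulation depths comparable to
  the between-subject error-bar scale.
* **Psychometric slopes** 0.14 (narrow) / 0.10 (wide) on the log10 axis,
  matching the spread implied by contrast ranges that span the 52.5%- to
  97.5%-correct anchor rule; lapse 0.01.
* **Between-subject spread**: additive threshold offsets with SD 0.05%
  (narrow) / 0.12% (wide) contrast.
* **Contrast placement**: the calibration block is not simulated; the 10
  log-spaced contrasts are anchored analytically on each observer's own
  mean psychometric curve (52.5→97.5% correct; 85→97.5% for the judged
  low-contrast design; one fixed contrast at 2.3× the 97.5% anchor for the
  judged high-contrast design).
* **Duration judgments**: perceived duration ~ `N(x/PSE, 0.1·x)`; "longer"
  iff it exceeds 1 s, so the 50% point is exactly the PSE.  PSEs are drawn
  from `N(1.29, 0.15²)` s.  Detection probability is
  `Φ(1.6·(log10 c − log10 c75)/σ)` — 50% at the 75%-correct contrast
  (consistent with `k = 0.5`) and steep enough that the judged low-contrast
  design keeps ≈ 330 of 360 trials, with misses recorded as no-response.
* **Trial counts**: 900 (narrow 2AFC), 360 (judged designs), 1100 (wide
  2AFC; ten 110-trial blocks inferred from the 11 × 10 design grid).
  Intervals and contrasts are drawn with equal probability per trial.

What the generator does *not* emulate: learning or fatigue across blocks,
lapses that vary with time-on-task, serial dependence between trials,
subject-specific Weber fractions or slopes, and any stimulus-driven
oscillatory component.  Passing recovery tests therefore show that the
estimators are consistent and calibrated under the model's own assumptions,
not that those assumptions hold of any particular dataset.

## Recovery studies and problem sizes

`recover_attention_params` fits 20 noise-perturbed replicate curve pairs
(noise SD = 5% of each curve's range) and reports per-replicate `(w, mu)`;
medians recover the generating values well within 15%/30%.
`recover_duration_pse` simulates full 15-subject judgment studies and
reports the posterior KDE mode per seed; 10 seeds give a median within
0.05 s of the generating 1.29 s.  Calibration suites use 2000 null profiles
(permutation test) and 200 null curve replicates (nested F test), the
latter with a 96-node quadrature and 3 optimiser starts — sizes chosen so
the full validation suite runs in minutes on one CPU while keeping Monte
Carlo error well below the tolerance being asserted.

## Known limitations

* Only the uniform interval distribution is closed-form-accelerated; the
  quadrature structure assumes its piecewise geometry.
* The `w → 0` and `mu → 0` corner (both simultaneously tiny, measurement
  near a support edge) is accurate only to ~1e-3.
* The nested F test treats `mu = 0` as an interior point; under the null
  the parameter sits on its boundary, and the observed type-I error (~5–8%
  at α = 0.05) reflects that approximation.
* Posterior summaries assume unimodal, well-mixed chains; no R-hat
  diagnostic is computed (chains are pooled after fixed burn-in).
* The hierarchical slope population is truncated at zero by rejection
  without renormalising the Gaussian population density.
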