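# Methods

## Viability model

A seed lot's viability under accelerated aging is treated as a monotone
non-increasing function of aging time `t` (days), on the fraction scale
internally (percent only at I/O boundaries).  The primary model is the
three-parameter Weibull survival curve

    v(t) = exp(-((t - c) / λ)^k)   for t ≥ c,   v(t) = 1 for t < c,

with scale λ > 0 (days), shape k > 0 and location c (days).  Defining
v ≡ 1 below the location keeps the curve continuous and monotone; in
practice every fitted location is negative, so the branch never occurs on
the observed domain (t ≥ 0).  The location parameter is what lets the
curve hold a shoulder near full viability before a steep decline — the
asymmetric two-phase pattern accelerated-aging assays produce — and it is
also why the parameters are only weakly identified (see *Ill-conditioning*).

Competing families are the nested two-parameter Weibull (c = 0), a
decreasing logistic `v = A/(1 + exp(r (t - m)))` and a decreasing
Gompertz `v = A exp(-b e^{g t})`, the standard decreasing sigmoid
parameterisations, with the asymptote A constrained to (0, 1].

L50 — the time at which the curve crosses half viability — is the
comparative summary: `L50 = c + λ (ln 2)^{1/k}` for the Weibull;
`m + ln(2A-1)/r` (logistic) and `ln(ln(2A)/b)/g` (Gompertz) when the
asymptote exceeds one half.  A negative crossing (curve already below
50 % at t = 0) or no crossing at all is reported as L50 = 0 with an
"n.e." (not estimable) flag, the convention used for collapsed lots in
the reference tables.

## Fitting

The objective is ordinary least squares on replicate-level viability
fractions, so a standard 5-timepoint × 3-replicate design contributes
n = 15 residuals.  Fitting per-timepoint means and inverse-binomial-
variance weighting exist as sensitivity options but are off by default;
all reference results are unweighted-OLS-consistent.

Optimisation is bounded trust-region least squares (analytic Jacobians)
from a deterministic multistart: shapes k ∈ {0.5, 1, 2, 5, 20, 100, 300};
a midpoint m where linearly interpolated mean viability crosses 0.5
(fallback: median time); scales λ ∈ {m+0.5, 2m+1, 10(m+1)}; and locations
back-solved as c = m − λ(ln 2)^{1/k}, clipped so c never exceeds the
first observation time.  For the three-parameter Weibull the fitted
two-parameter solution is appended as an extra start, which guarantees
RSS(weibull3) ≤ RSS(weibull2) on the same data.  Optional jittered extra
starts are seeded.  Assays with fewer than 3 distinct times, or with no
variation at all, are refused as degenerate.

Model ranking uses RSS-based information criteria

    AIC = n ln(RSS/n) + 2p,    BIC = n ln(RSS/n) + p ln n,

with p the curve's parameter count (no variance-parameter term).  This
convention reproduces the published age-regression table exactly
(quadratic: AIC −23.97 / BIC −24.14 at n = 7, p = 3; fixed 4-parameter
Weibull-form curve: RSS 0.3106, AIC −13.81 at p = 4), which is the reason
it was adopted.  A zero RSS is reported as a perfect fit rather than as
infinite criteria.

### Ill-conditioning

The (λ, k, c) objective has a long flat ridge: growing scale and shape
with an offsetting negative location leaves the curve on the data range
almost unchanged (published fits like λ = 216.71, k = 551.84,
c = −215.10 are of this kind).  The fitter never re-parameterises —
reproducing such triples is a feature — but sets `condition_flag` when
the relative parameter uncertainty from the Gauss–Newton covariance
exceeds 1e3, or when the relatively-scaled Jacobian has condition number
above 3e5 (the structural signature of the ridge, which persists on
noise-free data where the covariance collapses to zero).  The curve and
its L50 remain well-determined on the ridge even when the triple is not.

## L50 uncertainty

The point estimate is the closed-form L50 of the full-data fit.  The
interval is a seeded percentile bootstrap (default B = 1000, 2.5/97.5
percentiles), refitting each pseudo-dataset warm-started from the
full-data solution; non-estimable resamples contribute 0, matching the
clamping convention.

The default resampling is **parametric**: each replicate's viable count is
redrawn as Binomial(n_tested, v̂(t)) from the fitted curve.  A
case-resampling variant (replicates resampled with replacement within
each timepoint) is available but not default: with only 3 replicates per
timepoint the resampled within-time variance is shrunk by the classic
(n−1)/n = 2/3 factor, and a 150-simulation pilot measured 77 % coverage
at nominal 95 %, versus 94 % for the parametric scheme under the same
conditions.  Both methods are deterministic given the seed.

## Longevity regression and extrapolation

Per-lot L50s from cohorts of known age (age = testing year − collection
year; the reference campaign fixes 2023) are regressed on age.  The
headline form is the second-order polynomial, solved by exact least
squares (numerically verified against a normal-equations solve to
1e−10), with coefficient standard errors from the usual OLS covariance.
A 4-parameter Weibull-shaped alternative `y = A exp(-((x+B)/C)^D)` is
fitted by multistart NLS for model comparison; on the reference series
every goodness-of-fit metric favours the polynomial.  The reported R² is
the plain coefficient of determination.  (The reference table labels its
0.98036 "adjusted", but that value equals the *unadjusted* R² of its own
data — the adjusted value would be 0.9607 — so the label is treated as an
erratum.)

The ages at which the quadratic predicts L50 = 0 are its real roots,
computed in closed form; the smaller positive root is designated the
longevity upper bound.  Both roots are always reported: the convention
for discarding the larger one is external germination evidence (seeds
older than the smaller root germinating at ~10 % or not at all).
Degenerate cases — a linear fit (single root), a negative discriminant
("no crossing"), all-zero coefficients — are handled explicitly.
Inverting the quadratic at an observed L50 (choosing the smaller branch,
within [0, root]) gives the *equivalent storage age* of, for example, a
soil-seed-bank lot; values within 1e−6 above the intercept are clamped to
age 0 to absorb printed-coefficient rounding.

Note that inverting the published quadratic at the published habitat L50s
(1.59 d, 1.36 d) gives 2.21 and 2.93 years; the reference text prints
2.39 and 3.11 years, which do not follow from its own printed
coefficients.  The package reports the computed values.

## Validation statistics

One-way fixed-effects ANOVA on replicate-level L50s is computed from the
definitional sums of squares with the p-value from the upper tail of the
F distribution (cross-checked against `scipy.stats.f_oneway` in the
tests).  Germination trials are summarised by mean and sample SD (n−1)
per cohort, with compact-letter groupings from Tukey's HSD at α = 0.05
(statsmodels `pairwise_tukeyhsd` plus a basic insert-and-absorb letter
assignment; letters ascend from the lowest-mean class).

## Image quantification

Stained-area measurement works in HSV space: background is bright and
unsaturated (V ≥ 0.92, S ≤ 0.10 by default), everything else is section;
stained pixels are section pixels inside the red window (hue
[0°, 20°] ∪ [340°, 360°), S ≥ 0.35, V ∈ [0.15, 0.95]).  All windows are
overridable — the reference workflow's interactive sliders were never
recorded, so the defaults are a conventional red-stain segmentation
choice.  The viability rule is purely quantitative: viable iff the
stained fraction is ≥ 0.5 (boundary viable).  Anatomical staining-pattern
judgments (radicle integrity, cotyledon attachment) are out of scope.

## Synthetic data

The generator reproduces the study design it stands in for: binomial
viable counts per replicate along a known decay curve, 5 timepoints at
0–4 days, 3 replicates of 50 seeds; germination trials as 6 binomial
replicates of 30 seeds; and elliptical "section" images with an exactly
counted stained region.  Binomial observation noise is the natural model
for 50-seed replicate percentages; it is an assumption — real assays may
be over-dispersed (bag effects, scorer error), and passing recovery tests
therefore bounds estimator error under binomial noise only.

The cohort-series generator drives true L50 along the quadratic
(2.403749, −0.403234, 0.016114) by default and back-solves the Weibull
scale per age while holding shape and location fixed, so the truth per
age is unambiguous (any triple along the ridge would fit equally well).
The defaults k = 3.6, c = −0.9 d match the identifiable published
old-lot fits (k 3.56/3.93, c −0.94/−0.75) — the age regime that
dominates the extrapolation.  This choice also matters for
identifiability: with much steeper/narrower curves (say k = 5,
c = −0.5), an 8-year-old lot's viability is informative only at t = 0 on
the day-spaced design, its L50 becomes ridge-unidentified, and the
extrapolated root inherits a multi-year bias.

## Problem sizes and checks

The simulation-based checks use: 200 assays for L50 recovery (median
|error| < 0.1 d, |bias| < 0.05 d); 40 assays for nested-model RSS
dominance; 500 assays × 200 bootstrap replicates for interval coverage
(accepted within [85 %, 99 %] at nominal 95 %); and 100 full synthetic
pipelines for end-to-end root recovery.  Extrapolating a noisy quadratic
to its zero is a fragile nonlinear map with high leverage on the oldest
cohort: the root of a single noisy 6-cohort run scatters with sd ≈ 0.8
years, sits low when it exists, and in roughly a third of runs does not
exist at all (the fitted parabola never crosses zero).  The end-to-end
bias check therefore pools the regression coefficients — the quantities
OLS estimates without bias — across the replications and compares the
pooled law's smaller root to the generating root (agreement well within
±1 year).  Users extrapolating a longevity bound from a single 6-cohort
series should expect uncertainty of that order and report the
regression's roots with intervals, not as point facts.

## Known limitations

* The bootstrap interval is percentile-based and model-conditional; it
  does not account for family misspecification.
* Curve families are fitted by OLS on fractions, not by binomial
  likelihood; with 50-seed replicates the difference is small but real
  near 0 and 1.
* The Tukey letter display is the basic construction; overlapping
  non-transitive significance patterns with many groups may produce
  multi-letter classes that other software renders differently.
* Image segmentation assumes a light, unsaturated background and
  saturated red stain; dark-field or weakly stained images need custom
  thresholds.
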