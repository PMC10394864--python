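# Methods

## Problem and estimand

`tlcausal` estimates the marginal effect of a binary point treatment on a
binary outcome from observational cohort data `O = (Y, A, W)`: outcome
indicator `Y`, treatment indicator `A` (any-vs-none when treatment is
recorded as a non-negative total dose), and baseline covariates `W`. The
primary estimand is the adjusted risk difference

    psi = E[ E(Y | A=1, W) - E(Y | A=0, W) ],

which identifies the average treatment effect `E[Y_1 - Y_0]` under
consistency, positivity and no unmeasured confounding. Risk-ratio and
odds-ratio contrasts are derived from the same targeted arm means. A
continuous dose–response curve is deliberately out of scope: with total
dose accumulated over time, relative timing of dose and covariates
unrecorded, and the possibility that the outcome itself truncates dosing,
no statistical functional of these data corresponds to a causal dose
curve. The package therefore treats dose only descriptively (crude
event proportions by dose group, and a main-terms logistic dose model
retained strictly as a baseline comparison).

## Estimator

Estimation is targeted minimum loss-based estimation (TMLE):

1. **Initial fits.** The outcome regression `Qbar(A, W)` is fitted on
   `(W, A)` and the propensity score `g(W) = P(A=1 | W)` on `W`, both by a
   cross-validated convex-combination ensemble (super learner; below).
   `g` is truncated two-sided to `[b, 1-b]` with default
   `b = 5 / (sqrt(n) ln n)` (0.0615 at n = 225, reported alongside as
   0.06 at two decimals). The auto bound is undefined (raises) for
   n <= 14, where the formula is not below 0.5.
2. **Targeting.** A single-coefficient logistic fluctuation with the
   signed clever covariate `H(A, W) = A/g - (1-A)/(1-g)` is fitted by an
   offset-logistic MLE (safeguarded Newton, score tolerance 1e-12 per
   observation, max 100 iterations; steps clamped to ±5 on the logit
   scale). One signed `H` rather than two arm-specific coefficients is
   used because it solves the ATE estimating equation directly and
   matches common practice. `Qbar(1, W)` and `Qbar(0, W)` are updated
   with `H = 1/g` and `H = -1/(1-g)` respectively.
3. **Inference.** The influence curve
   `IC_i = H_i (Y_i - Qbar*_i) + Qbar*(1,W_i) - Qbar*(0,W_i) - RD` has
   empirical mean zero after targeting (asserted at 1e-8 in the tests);
   `SE = sd(IC)/sqrt(n)` and Wald intervals use exact normal quantiles.
   RR/OR intervals are delta-method on the log scale and exponentiated.

No cross-fitting (CV-TMLE) is implemented; the plain TMLE matches the
workflow the package automates, and cross-fitting is noted as a possible
extension. Outcome-regression probabilities are clipped to
`[1e-9, 1 - 1e-9]` before the logit transform so saturated (0/1 cell
mean) fits remain usable in tests.

For discrete covariates the package ships `gcomp_oracle`, the fully
stratified plug-in `sum_w phat(w) [ybar(1,w) - ybar(0,w)]`. With
saturated nuisance fits the fluctuation coefficient is exactly zero and
TMLE coincides with this oracle; the test suite uses the equivalence as
an independent check of the targeting algebra.

## Super learner

The ensemble minimizes the cross-validated mean negative Bernoulli
log-likelihood of a convex combination of out-of-fold learner
predictions. Weights are found by SLSQP over the simplex, refined with
multiplicative-gradient steps and compared against all vertex solutions,
so the fitted ensemble's CV risk never exceeds the best single learner's
(the inequality is asserted exactly in tests). Folds are stratified on
the binary response — V = 20 by default, chosen with event-scarce
cohorts in mind — and all randomness is governed by one seed.

The built-in library: unpenalized logistic regression; L1-penalized
logistic regression with the penalty chosen by inner cross-validation on
training folds only; an additive spline logistic regression (cubic
splines, 4 knots, mild ridge) playing the generalized-additive-model
role; and bagged shallow decision trees (50 trees, depth 5, minimum leaf
10) playing the flexible tree-ensemble role. A learner that fails on a
fold contributes the training-fold event rate for that fold and the
failure is logged; fitting never aborts on a single learner.

## Sensitivity analysis

Violations of the identifying assumptions are summarized by the causal
gap `delta = psi_stat - psi_causal`. For hypothesized `delta` the
bias-corrected estimate is `psi_hat - delta` with both CI bounds shifted
equally. The scan (default grid: 81 points spanning ±4 SE units) emits a
table of shifted estimates and intervals plus two closed-form
thresholds: the G-value
`min(|psi - z sigma - null|, |psi + z sigma - null|)` — the smallest
|delta| that negates the finding — and the reversal threshold
`|psi + z sigma - null|` at which the whole interval crosses the null.
Ratio scales are handled on the log scale with null 0. Exact normal
quantiles are the default; a `z_compat` argument fixes z (e.g. 1.96) to
reproduce two-decimal published arithmetic. Gap magnitudes are also
reported in SE units, unrounded.

## Synthetic cohorts

The generator emulates the structure of a twin-pregnancy tocolysis
safety cohort: n = 225 by default; covariates age (discretized normal,
16–45), height and weight (correlated normals, r ≈ 0.5), BMI derived
from them, an obesity indicator (BMI ≥ 25), and five Bernoulli
indicators (first pregnancy, single placenta, assistive reproductive
technology, magnesium, corticosteroid). Continuous covariates enter the
linear predictors standardized by fixed constants so coefficients share
an O(1) scale and the Monte-Carlo oracle integrates the same mechanism.

Default mechanism (chosen once): treated fraction ≈ 0.36, marginal event
rate ≈ 0.17, and a treatment coefficient of 1.5 on the logit scale
calibrated so the true marginal risk difference is ≈ 0.21 — the effect
size regime the package is designed to interrogate. Measured confounding
runs through BMI, age and co-medication indicators.

Injectable violations:

- **Latent confounding.** A Bernoulli `U` (prevalence 0.5) enters both
  linear predictors with a common strength. The resulting causal gap is
  computed exactly: the W-adjusted estimand uses the posterior of `U`
  given `(A, W)` (analytic, since both mechanisms are logistic in `U`),
  and `delta = psi_stat - rd`. With strength 0 the gap is exactly 0.
- **Contraindication.** Exactly `floor(f * n)` randomly chosen subjects
  get structural propensity 0. The stratum is latent (independent of
  `W` and `U` and without a direct outcome effect), so it violates
  positivity without by itself biasing the W-adjusted estimand; its
  effect on `psi_stat` enters only through the `U`-posterior tilt of the
  untreated mixture, which the gap oracle accounts for.
- **Dose cohorts.** Treated subjects are spread over six positive dose
  categories ((0,10], (10,20], …, (50,∞) on a 72 mg/24 h unit scale)
  with uniform doses within category, and outcomes drawn from per-group
  event-rate targets; the default targets rise toward the 41–50 category
  and fall beyond it, reproducing a non-monotonic crude dose–response.
  These cohorts exist to exercise the descriptive dose diagnostics, not
  causal estimation.

Truth is computed by `true_effect_oracle`: Monte-Carlo integration over
fresh covariate draws (default 100,000) with the Bernoulli outcome
expectation taken analytically, returning `E[Y_1]`, `E[Y_0]`, the true
risk difference with its MC standard error, and the injected gap.

What the generator does **not** emulate: empirical marginals of any real
dataset (emulation is structural), covariate measurement error, missing
data (the cohort contract rejects missingness), time-varying treatment,
or informative dosing. Passing tests therefore demonstrate estimator
correctness under a known logistic data-generating process with full
overlap — not robustness to the messiness of real registry data.

## Diagnostics

- Per-stratum treated/control counts with empty-cell flags; collapsing
  of sparse categories is user-declared and restricted to
  order-respecting (contiguous) merges, with totals conserved.
- Propensity discrimination by the C-statistic (Mann–Whitney, ties
  counted 1/2) and overlap by shared-bin histogram mass plus per-arm
  ranges — deterministic summaries rather than density estimates — with
  a flag when no score reaches the truncation bound ("truncation had no
  impact").
- Dose-group labels like ">0–10, 11–20, …" are interpreted as half-open
  intervals (0,10], (10,20], … on the continuous dose scale: doses are
  continuous, and half-open bins make integer-looking labels exhaustive.
  The convention is configurable via the cut points.
- The baseline main-terms logistic dose model reports the exponentiated
  dose coefficient with a Wald CI. Callers choose the adjustment set;
  covariates measured after the outcome should be excluded (a cause must
  precede its effect), which is why the default uses only the cohort's
  declared baseline covariates.

## Pipeline behavior

Strict-positivity mode aborts estimation (exit code 3 from the CLI) when
any declared categorical stratification has an empty treated or control
cell; permissive mode records the flags and proceeds under truncation.
Both behaviors are legitimate: an estimand can be abandoned as
unidentifiable, or rescued by clinically justified coarsening. Reports
are deterministic functions of (config, seed, input); the JSON report
validates against a structural schema shipped in `tlcausal.report`.

## Numerical choices and test problem sizes

- Weight-optimization tolerance 1e-12 (SLSQP ftol); simplex weights sum
  to 1 within 1e-8.
- Fluctuation Newton tolerance 1e-12 per observation; the EIF mean is
  checked at 1e-8.
- Learner probability outputs clipped to [1e-6, 1 - 1e-6].
- Repeated-sampling checks use 200 cohorts of n = 1000 with
  single-learner (well-specified logistic) libraries and V = 10 — sizes
  chosen so the full property battery runs in a few minutes while Monte
  Carlo error stays well below the asserted bias (0.01) and coverage
  ([0.91, 0.985]) bands.

## Known limitations

- No CV-TMLE / cross-fitting; with very aggressive learners the
  influence-curve SE can be anticonservative.
- No missing-data or censoring machinery; the cohort contract is
  complete data.
- The BART and GAM roles in the learner library are filled by bagged
  trees and spline logistic regression; results with small libraries
  depend on the library's expressiveness in the usual way.
- The G-value and gap scan are non-parametric summaries of *external*
  bias; they do not model any specific confounding mechanism.
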