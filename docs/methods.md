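# Methods

## Exposure accumulation

Each exposure series lives on the study exam schedule (years 0, 2, 5, 7,
10, 15, 20 since baseline). Accumulating exposures combine each pair of
consecutive exams with an endpoint statistic, multiply by the interval
length in years, sum over intervals, and divide by a unit conversion:

* smoking — **sum** of the two endpoint daily cigarette counts × interval
  / 20 (cigarettes per pack), giving cumulative packs;
* alcohol and physical activity — **mean** of the endpoints × interval
  (the trapezoidal rule on the piecewise-linear trajectory);
* diet score and sleep hours — plain mean of available exams;
* education — years attained at the last exam.

The smoking convention (sum rather than mean of endpoints) is deliberately
asymmetric: it follows the construction used for cumulative pack totals in
the cohort this package emulates, and `default_recipe(uniform_mean=True)`
switches smoking to the mean convention for sensitivity analysis, which
scales the column by exactly ½ (and therefore leaves every downstream
rank-, quantile- and z-score-based analysis unchanged).

Participants missing an exposure entirely, or with fewer than two exams
for an accumulating exposure, are removed complete-case and counted in a
drop log. No within-series imputation is performed: available consecutive
pairs only.

**Transform.** All six columns are log1p-transformed and z-scored.
log1p rather than log because never-smokers contribute raw zeros; log1p
preserves them (log1p 0 = 0), is monotone, and needs no ad-hoc offset.
The test suite documents that log1p z-scores are *not* invariant to
rescaling the raw values (a plain z-score is), so unit conventions of the
raw inputs matter and are treated as opaque pass-through. Z-scoring is
computed on the table actually being fit, and is recomputed within strata
(a config flag reuses the full-sample scale instead).

## Epigenetic age acceleration

EAA = residual of OLS(epigenetic age ~ chronological age) with intercept.
Residuals have mean zero and zero correlation with age by construction
(tolerance 1e-8 in the tests). The operation is clock-agnostic. In
stratified analyses the residualization is computed **once** on the full
sample, so all strata are compared on a single acceleration scale; a
config flag (`eaa_per_stratum`) recomputes it per stratum.

## Quantile g-computation

Quantile coding uses interior empirical quantiles with the linear-
interpolation (type-7) definition; a value equal to a cut-point goes to
the upper bin. With fewer than q distinct values, coding falls back to
average-rank binning with a warning; a constant column cannot be coded,
is excluded from the mixture, and surfaces as NA in reports (this is what
happens to smoking inside a never-smoker stratum).

Because the index model is linear, ψ = Σβⱼ is the exact g-computation
estimand and Var(ψ) = 1ᵀΣ_β1 over the exposure block gives a closed-form
Wald interval (t critical value, residual df). The percentile bootstrap
(participant resampling, quantile cuts recomputed per resample) is kept as
a cross-check only; on noiseless data its width shrinks with n but does
not vanish at fixed n, because cut-point re-estimation moves boundary
participants between bins.

Weights are β_k divided by the same-direction coefficient sum, so the
positive map sums to +1 and the negative map to −1 (tolerance 1e-10).
Coefficients within 1e-10 (relative) of zero are treated as numerically
zero and carry no weight. Covariates: sex, race and field center
reference-coded, BMI continuous; chronological age joins the covariate set
only when `include_age` is on (default off, matching the adjustment set
used in the main analyses this pipeline reproduces; both configurations
are supported because the two are reported inconsistently in practice).

## Bayesian kernel machine regression

Marginalizing the kernel machine h ~ GP(0, λσ²K) gives
y ~ N(Xβ, σ²(I + λK)). Priors: flat on β; InverseGamma(1e-3, 1e-3) on σ²;
per-exposure spike-and-slab with Bernoulli(0.5) inclusion and a
Uniform(0, 100) slab on the kernel scale rₘ; half-Cauchy(scale 10) on λ.
These are weakly informative defaults in the spirit of the established
kernel-machine implementations; the data dominate them in every test.

**Convention.** When every exposure is excluded (all rₘ = 0) the h term is
dropped entirely, V = I, and the model is exactly the Bayesian linear
model — this makes the null state meaningful and is verified against the
closed-form normal-inverse-gamma posterior (KS distance < 0.1).

**Sampler.** Per iteration: Gibbs draw of β (conditional Gaussian) and σ²
(conditional inverse-gamma); MH on log λ with step size adapted toward
35% acceptance during burn-in and frozen afterwards (a warning fires if
the post-adaptation rate leaves [0.1, 0.6]); and one randomly chosen
component gets a birth/death/jitter move on (δₘ, rₘ) — birth proposes rₘ
from a lognormal centred at 0.1 (the scale relevant for z-scored
exposures), death zeroes it, jitter multiplies it by exp(N(0, 0.5²)).
Random-scan single-component updates are the standard choice for this
model class and keep the per-iteration cost at one Cholesky per move.
Defaults: 50,000 iterations, 50% burn-in, thinning 10, all configurable;
chains are bit-reproducible given the seed. A jitter of 1e-8 is added to
the diagonal of I + λK before factorization; this is part of the
numerical contract (perturbing it by 1e-10 moves log-likelihoods by
< 1e-6).

**Summaries.** PIPₘ = fraction of retained draws with rₘ > 0. For h at
new points, each retained draw samples h from its exact conditional
Gaussian (mean λK₍new₎V⁻¹(y−Xβ)) rather than plugging in the mean, so
credible bands have correct width. Only h *differences* are identified
against the intercept, so the collective association is reported as
h(z₇₅) − h(z₂₅) (component-wise empirical percentiles) and univariate
curves are referenced to the all-median profile — the per-draw value at
the reference profile is subtracted, cancelling the common level and all
covariate contrasts; a single-point grid therefore reads exactly zero,
and an exposure absent from the kernel gives an exactly flat curve.

## Synthetic cohort generator

The generator emulates the analytic structure of a midlife biracial
cardiovascular cohort at the exam where blood methylation was assayed:

* **Marginals** (means/SDs follow the published cohort table): smoking
  zero-inflated lognormal — point mass 0.617 at zero (never smokers),
  positive part mean 1717.5, SD 3348.4 packs; alcohol lognormal
  (227.5, 341.6); diet score Normal(67.6, 11.8); education years
  Normal(15.1, 2.5) rounded to integers; activity score lognormal
  (350.9, 279.0); sleep Normal(6.7, 1.3). Age Normal(45.9, 3.5), BMI
  Normal(29.3, 6.4), sex 52.6% men, race 59.1% White, four field centers
  at the published proportions.
* **Dependence** via a Gaussian copula. Target Spearman anchors:
  diet–education 0.36 and smoking–alcohol 0.33; all other pairs default to
  a small generic 0.10 (not published values — chosen once to keep the
  mixture mildly collinear). Because ties (the never-smoker mass, integer
  education) attenuate observed Spearman correlations, the latent Pearson
  correlations are calibrated numerically: the tie-aware population
  Spearman (Pearson correlation of midrank transforms) is evaluated on a
  fixed 65,536-point Sobol grid and solved for the latent value by Brent's
  method. For continuous pairs this reduces to the classical
  2 sin(πρ_s/6) conversion (verified in the tests). If pairwise
  calibration ever leaves the matrix non-positive-definite it is repaired
  by eigenvalue clipping with a warning.
* **Outcome.** epigenetic age = chronological age + Σ bⱼ zⱼ +
  c(z_alc² − 1) + covariate effects + N(0, 3²), with zⱼ the log1p
  z-scores. Default effects (years per SD): smoking 2.0, alcohol 0.6,
  diet −0.9, education −0.8, activity 0.10, sleep 0.05; alcohol curvature
  c = 0.5. These were fixed once to reproduce the qualitative published
  pattern — smoking dominant and positive, diet/education protective, a
  U-shaped alcohol response, inert activity and sleep — at effect sizes a
  cohort of several hundred can resolve. Covariate effects: men +0.8 y,
  White −0.5 y, +0.06 y per BMI unit, small center offsets. The noise SD
  of 3 years is of the order of the residual spread of modern epigenetic
  clocks. A `quantile_effects` mode instead builds the outcome from
  quartile-coded exposures with known per-quantile coefficients, so the
  QGC estimand is exactly known (true ψ = Σ effects) for recovery studies.
* **Ground truth** returned with each draw: effect vector, realized
  noise-free signal, and the true 75th-vs-25th percentile contrast of the
  generating surface evaluated at the sample's empirical percentiles.
* A long-format emitter produces per-exam records whose standard
  accumulation reproduces the cumulative table exactly (flat
  trajectories), for end-to-end tests of the accumulation stage.

**What the generator does not emulate:** real exam-to-exam within-person
trajectories (emitted series are flat), item nonresponse patterns,
measurement error in self-report, exposure–covariate dependence (e.g.
smoking by sex), or any genuine methylation array structure. Passing
recovery tests therefore certify the estimators under a correctly
specified, moderately collinear mixture — not robustness to those
real-data features.

## Problem sizes used in validation

QGC recovery: 200 replicates of n = 1,000 (bias within 2 Monte-Carlo SEs,
Wald coverage within [92%, 98%]). BKMR recovery: 50 replicates of n = 200
with 5,000-iteration chains (credible-interval coverage ≥ 90%, the
dominant exposure's PIP ranked first in ≥ 95% of chains); curve shapes
from one n = 500 chain. Generator calibration is checked on an n = 10,000
draw (anchor Spearman entries within ±0.02, the full matrix within ±0.03,
marginal means within 3 Monte-Carlo SEs). The 50,000-iteration production
default is asserted directly and the sampler mechanics exercised at
reduced size.

## Known limitations

* The BKMR sampler is a faithful but deliberately compact implementation:
  single-chain, no grouped/hierarchical selection, no split-R-hat
  computation (determinism and recovery are tested instead).
* Bootstrap QGC inference resamples participants only; no stratified or
  cluster bootstrap.
* The copula calibration targets pairwise Spearman values; higher-order
  dependence (tail dependence, three-way structure) is whatever the
  Gaussian copula implies.
* Education discretization ignores the (negligible) probability mass the
  normal places below zero.
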