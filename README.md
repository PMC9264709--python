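# eaamix

Exposure-mixture analysis of epigenetic age acceleration.

Lifestyle exposures — smoking, alcohol, diet quality, education, physical
activity, sleep — are correlated with one another, so single-exposure
regressions of epigenetic aging are confounded by the rest of the mixture.
`eaamix` implements the two complementary mixture methods epidemiologists
use to apportion a *collective* association among its components, wired
into a full pipeline from longitudinal exam records to a final report, and
validated against a synthetic cohort generator with known ground truth.

## What it computes

**Cumulative exposures.** Repeated exam measurements are reduced to one
value per participant: endpoint-pair accumulation over the exam schedule
for smoking (packs), alcohol, and activity; averaging for diet score and
sleep; attained years for education. Exposures are then log1p-transformed
and z-scored.

**Epigenetic age acceleration (EAA).** The residual of epigenetic age
(e.g. a GrimAge- or PhenoAge-style clock) regressed on chronological age;
positive values mean faster epigenetic aging.

**Quantile-based g-computation (QGC).** Each exposure is coded to its
empirical quartile q_j ∈ {0,1,2,3} and the linear index model

    EAA_i = β₀ + Σⱼ βⱼ qᵢⱼ + covariatesᵢᵀγ + εᵢ

is fit by OLS. The collective association ψ = Σⱼ βⱼ is the expected EAA
change, in years, when *every* exposure rises one quartile together; each
direction's weights w_k = β_k / Σ(same-sign βⱼ) sum to 1 (positive) and −1
(negative). ψ carries a closed-form Wald CI (exact for the linear model),
with a participant-resampling bootstrap as a cross-check.

**Bayesian kernel machine regression (BKMR).** The semiparametric model

    EAA_i = h(z_i) + covariatesᵢᵀβ + εᵢ,   K(z, z′) = exp(−Σₘ rₘ (zₘ − z′ₘ)²)

with a Gaussian-kernel machine h and spike-and-slab selection on each
kernel scale rₘ. An in-package MCMC sampler (Gibbs for β, σ²;
Metropolis–Hastings for the variance ratio λ and for each (δₘ, rₘ) pair)
yields posterior inclusion probabilities (PIPs) that rank exposure
importance, the collective association h(z₇₅) − h(z₂₅) with a credible
interval, and univariate exposure–response curves that capture
nonlinearity (e.g. a U-shaped alcohol response) with all other exposures
held at their medians.

**Synthetic cohorts.** A Gaussian-copula generator draws the six exposures
with tie-aware calibrated Spearman structure (diet–education 0.36,
smoking–alcohol 0.33), published-style marginals (zero-inflated lognormal
smoking with a 61.7% never-smoker mass, mean age 45.9 ± 3.5, …),
demographic covariates, and an outcome with known linear effects plus a
quadratic alcohol term — so every estimator can be checked by
parameter-recovery simulation.

## Worked example

```sh
eaamix simulate --n 744 --seed 1 --out cohort.tsv --truth truth.json
eaamix qgc  --input cohort.tsv --out qgc.json
eaamix bkmr --input cohort.tsv --iters 5000 --seed 1 --out bkmr.json
```

prints

```
wrote 744 participants to cohort.tsv
psi = 2.830 (95% CI 2.183, 3.476)
collective association = 1.533 (95% CrI 0.900, 2.252)
```

and the JSON reports contain

```
weights_pos {alcohol: 0.120, physical_activity: 0.021, sleep: 0.044, smoking: 0.815}
weights_neg {diet: -0.468, education: -0.532}
pips        {smoking: 1.0, alcohol: 1.0, diet: 1.0, education: 1.0,
             physical_activity: 0.0, sleep: 0.0}
```

Reading: a simultaneous one-quartile rise in all six exposures associates
with ψ ≈ 2.8 years more age acceleration; smoking carries 81.5% of the
positive direction while diet and education pull the other way; BKMR's
75th-vs-25th percentile contrast is 1.5 years (95% CrI 0.90–2.25), against
a generator ground truth of 2.28 years for this draw. PIPs select the four
exposures with real generating effects and reject the two inert ones.

The full pipeline — exposures, EAA, Spearman matrix, QGC, BKMR, linear
comparison, optional strata (sex, race, ever/never smoking, where a
constant exposure such as smoking among never smokers is dropped and
reported NA) — runs with `eaamix run --input cohort.tsv --out report.json`.

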