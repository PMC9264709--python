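"""Synthetic cohort generation with controlled rank-correlation structure.

Generates analytic cohorts that emulate a midlife cardiovascular-cohort
sample: six cumulative lifestyle exposures (smoking pack-total, alcohol,
diet quality, education years, physical activity, sleep hours) with a
prescribed Spearman correlation structure, demographic covariates, and an
epigenetic-age outcome driven by a known ground-truth model.  Because the
ground truth is known, every downstream estimator (quantile g-computation,
kernel machine regression, plain linear models) can be validated by
parameter-recovery simulation.

Correlated exposures are drawn through a Gaussian copula.  The latent
Pearson correlations are calibrated numerically so that the *observed*
Spearman correlations of the generated columns — including the attenuation
caused by ties (the never-smoker point mass, integer education years) —
match the requested targets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq
from scipy.stats import norm, qmc

#: canonical exposure column order used throughout the package
EXPOSURES = ("smoking", "alcohol", "diet", "education", "physical_activity", "sleep")

CENTERS = ("Birmingham", "Chicago", "Minnesota", "Oakland")


# ---------------------------------------------------------------------------
# marginal distributions
# ---------------------------------------------------------------------------

class NormalMargin:
    """Gaussian marginal, optionally truncated below at zero on the draw."""

    def __init__(self, mean: float, sd: float):
        self.mean, self.sd = float(mean), float(sd)

    def ppf(self, u):
        return np.maximum(norm.ppf(u, loc=self.mean, scale=self.sd), 0.0)

    def rank(self, u):
        # continuous: population fractional rank is the copula uniform itself
        return np.asarray(u, dtype=float)

    def signature(self):
        return ("normal", self.mean, self.sd)


class LognormalMargin:
    """Lognormal parameterized by its arithmetic mean and SD."""

    def __init__(self, mean: float, sd: float):
        self.mean, self.sd = float(mean), float(sd)
        s2 = np.log1p((sd / mean) ** 2)
        self.sigma = float(np.sqrt(s2))
        self.mu = float(np.log(mean) - s2 / 2.0)

    def ppf(self, u):
        return np.exp(self.mu + self.sigma * norm.ppf(u))

    def rank(self, u):
        return np.asarray(u, dtype=float)

    def signature(self):
        return ("lognormal", self.mean, self.sd)


class ZeroInflatedLognormalMargin:
    """Point mass at zero (e.g. never smokers) plus a lognormal positive part.

    ``mean``/``sd`` describe the positive part only, matching how cohort
    tables report smoking dose "for former and current smokers".
    """

    def __init__(self, p_zero: float, mean: float, sd: float):
        if not 0.0 <= p_zero < 1.0:
            raise ValueError("p_zero must be in [0, 1)")
        self.p_zero = float(p_zero)
        self._pos = LognormalMargin(mean, sd)

    def ppf(self, u):
        u = np.asarray(u, dtype=float)
        out = np.zeros_like(u)
        pos = u >= self.p_zero
        rescaled = (u[pos] - self.p_zero) / (1.0 - self.p_zero)
        # keep strictly inside (0,1) for the ppf
        rescaled = np.clip(rescaled, 1e-12, 1 - 1e-12)
        out[pos] = self._pos.ppf(rescaled)
        return out

    def rank(self, u):
        u = np.asarray(u, dtype=float)
        # all zeros share the midrank of the zero block
        return np.where(u < self.p_zero, self.p_zero / 2.0, u)

    def signature(self):
        return ("zilognormal", self.p_zero, self._pos.mean, self._pos.sd)


class DiscretizedNormalMargin:
    """Normal rounded to the nearest non-negative integer (education years)."""

    def __init__(self, mean: float, sd: float):
        self.mean, self.sd = float(mean), float(sd)

    def ppf(self, u):
        return np.maximum(np.rint(norm.ppf(u, loc=self.mean, scale=self.sd)), 0.0)

    def rank(self, u):
        k = self.ppf(u)
        lo = norm.cdf((k - 0.5 - self.mean) / self.sd)
        hi = norm.cdf((k + 0.5 - self.mean) / self.sd)
        return lo + 0.5 * (hi - lo)

    def signature(self):
        return ("discnormal", self.mean, self.sd)


# ---------------------------------------------------------------------------
# copula calibration
# ---------------------------------------------------------------------------

_SOBOL_CACHE: dict[int, np.ndarray] = {}
_LATENT_CACHE: dict[tuple, np.ndarray] = {}


def _sobol_normals(n_pow2: int = 16) -> np.ndarray:
    """Fixed low-discrepancy standard-normal pairs used for calibration."""
    if n_pow2 not in _SOBOL_CACHE:
        eng = qmc.Sobol(d=2, scramble=True, seed=20220707)
        u = eng.random_base2(n_pow2)
        _SOBOL_CACHE[n_pow2] = norm.ppf(u)
    return _SOBOL_CACHE[n_pow2]


def _model_spearman(rho: float, margin_a, margin_b) -> float:
    """Population Spearman of the two mapped margins under latent Pearson rho.

    Ties are handled with average ranks, i.e. the Spearman statistic is the
    Pearson correlation of the population midrank transforms.  Evaluated by
    quasi-Monte-Carlo integration on a fixed Sobol grid (deterministic).
    """
    z = _sobol_normals()
    z2 = rho * z[:, 0] + np.sqrt(max(1.0 - rho * rho, 0.0)) * z[:, 1]
    r1 = margin_a.rank(norm.cdf(z[:, 0]))
    r2 = margin_b.rank(norm.cdf(z2))
    r1 = r1 - r1.mean()
    r2 = r2 - r2.mean()
    return float(r1 @ r2 / np.sqrt((r1 @ r1) * (r2 @ r2)))


def latent_correlation(target_spearman: float, margin_a, margin_b) -> float:
    """Latent Gaussian Pearson correlation reproducing a target Spearman.

    For two continuous margins this is close to the classical conversion
    ``2 sin(pi * rho_s / 6)``; tied margins (zero inflation, integer
    discretization) attenuate the observed Spearman, so the latent value is
    solved for numerically against the tie-aware population Spearman.
    """
    if target_spearman == 0.0:
        return 0.0
    key = (round(target_spearman, 10), margin_a.signature(), margin_b.signature())
    if key not in _LATENT_CACHE:
        f = lambda r: _model_spearman(r, margin_a, margin_b) - target_spearman
        _LATENT_CACHE[key] = brentq(f, -0.995, 0.995, xtol=1e-6)
    return _LATENT_CACHE[key]


def nearest_positive_definite(corr: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Eigenvalue-clipping repair of a correlation matrix."""
    sym = (corr + corr.T) / 2.0
    w, v = np.linalg.eigh(sym)
    if w.min() > eps:
        return sym
    w = np.clip(w, eps, None)
    fixed = v @ np.diag(w) @ v.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed


# ---------------------------------------------------------------------------
# cohort specification
# ---------------------------------------------------------------------------

def _default_spearman_targets() -> pd.DataFrame:
    """Target rank-correlation matrix for the six exposures.

    The diet–education (0.36) and smoking–alcohol (0.33) entries are the
    calibration anchors; the remaining off-diagonals are filled with a small
    generic positive correlation (0.10) to keep the mixture mildly
    collinear, as lifestyle exposures typically are.
    """
    m = np.full((6, 6), 0.10)
    np.fill_diagonal(m, 1.0)
    tgt = pd.DataFrame(m, index=EXPOSURES, columns=EXPOSURES)
    tgt.loc["diet", "education"] = tgt.loc["education", "diet"] = 0.36
    tgt.loc["smoking", "alcohol"] = tgt.loc["alcohol", "smoking"] = 0.33
    return tgt


def _default_marginals() -> dict:
    return {
        "smoking": ZeroInflatedLognormalMargin(p_zero=0.617, mean=1717.5, sd=3348.4),
        "alcohol": LognormalMargin(mean=227.5, sd=341.6),
        "diet": NormalMargin(mean=67.6, sd=11.8),
        "education": DiscretizedNormalMargin(mean=15.1, sd=2.5),
        "physical_activity": LognormalMargin(mean=350.9, sd=279.0),
        "sleep": NormalMargin(mean=6.7, sd=1.3),
    }


@dataclass
class SyntheticSpec:
    """Calibration of the synthetic cohort generator.

    Exposure effects act on the standardized scale actually analysed
    downstream: z-scores of log1p-transformed raw exposures.  The outcome is
    an epigenetic age equal to chronological age plus the exposure signal,
    covariate effects, and Gaussian noise, so that residualizing epigenetic
    age on chronological age recovers the signal as age acceleration.
    """

    n: int = 744
    seed: int = 0
    spearman_targets: pd.DataFrame = field(default_factory=_default_spearman_targets)
    marginals: dict = field(default_factory=_default_marginals)
    # linear effects per 1 SD of log1p exposure (years of age acceleration)
    effects: dict = field(default_factory=lambda: {
        "smoking": 2.0, "alcohol": 0.6, "diet": -0.9,
        "education": -0.8, "physical_activity": 0.10, "sleep": 0.05,
    })
    #: curvature of the centered quadratic alcohol term (U-shape); the term
    #: is c * (z_alc^2 - 1) so it has mean ~0 and leaves the linear part alone
    alcohol_curvature: float = 0.5
    #: if set, the outcome uses per-quantile (q=4) exposure effects instead
    #: of the continuous z-scale effects; keys are exposures, values are
    #: years per one-quantile step
    quantile_effects: dict | None = None
    noise_sd: float = 3.0
    age_mean: float = 45.9
    age_sd: float = 3.5
    bmi_mean: float = 29.3
    bmi_sd: float = 6.4
    p_male: float = 391 / 744
    p_white: float = 440 / 744
    center_probs: tuple = (197 / 744, 174 / 744, 181 / 744, 192 / 744)
    covariate_effects: dict = field(default_factory=lambda: {
        "sex_male": 0.8, "race_white": -0.5, "bmi_per_unit": 0.06,
        "center": (0.0, 0.2, -0.2, 0.1),
    })

    def __post_init__(self):
        if self.n < 50:
            raise ValueError("cohort size must be at least 50")
        tg = np.asarray(self.spearman_targets, dtype=float)
        if not np.allclose(tg, tg.T) or not np.allclose(np.diag(tg), 1.0):
            raise ValueError("spearman_targets must be symmetric with unit diagonal")

    def latent_matrix(self) -> np.ndarray:
        """Pairwise-calibrated latent Pearson matrix (PD-repaired if needed)."""
        m = len(EXPOSURES)
        latent = np.eye(m)
        tg = self.spearman_targets
        for i in range(m):
            for j in range(i + 1, m):
                r = latent_correlation(
                    float(tg.iloc[i, j]),
                    self.marginals[EXPOSURES[i]],
                    self.marginals[EXPOSURES[j]],
                )
                latent[i, j] = latent[j, i] = r
        if np.linalg.eigvalsh(latent).min() <= 0:
            warnings.warn("latent correlation matrix not positive definite; "
                          "applying eigenvalue-clipping repair")
            latent = nearest_positive_definite(latent)
        return latent


def standardize_exposures(raw: pd.DataFrame) -> pd.DataFrame:
    """log1p then z-score each exposure column (the analysis scale)."""
    z = np.log1p(raw[list(EXPOSURES)])
    return (z - z.mean()) / z.std(ddof=1)


def generate_cohort(spec: SyntheticSpec, n: int | None = None,
                    seed: int | None = None) -> tuple[pd.DataFrame, dict]:
    """Draw a cohort table and return it with its ground-truth record.

    Returns
    -------
    cohort : DataFrame with columns ``participant_id, age, sex, race, bmi,
        center, epigenetic_age`` plus the six raw exposure columns.
    truth : dict with the generating effect sizes, the realized noise-free
        signal, and the true 75th-vs-25th percentile contrast of the
        exposure-response surface evaluated on this sample.
    """
    if n is not None or seed is not None:
        spec = replace(spec, n=n if n is not None else spec.n,
                       seed=seed if seed is not None else spec.seed)
    rng = np.random.default_rng(spec.seed)
    m = len(EXPOSURES)

    latent = spec.latent_matrix()
    chol = np.linalg.cholesky(latent)
    z_latent = rng.standard_normal((spec.n, m)) @ chol.T
    u = norm.cdf(z_latent)

    raw = {}
    for j, name in enumerate(EXPOSURES):
        raw[name] = spec.marginals[name].ppf(u[:, j])
    exposures = pd.DataFrame(raw)

    age = rng.normal(spec.age_mean, spec.age_sd, spec.n)
    sex = np.where(rng.random(spec.n) < spec.p_male, "Men", "Women")
    race = np.where(rng.random(spec.n) < spec.p_white, "White", "Black")
    bmi = rng.normal(spec.bmi_mean, spec.bmi_sd, spec.n)
    center = rng.choice(CENTERS, size=spec.n, p=spec.center_probs)

    zstd = standardize_exposures(exposures)

    ce = spec.covariate_effects
    cov_signal = (
        ce["sex_male"] * (sex == "Men")
        + ce["race_white"] * (race == "White")
        + ce["bmi_per_unit"] * (bmi - spec.bmi_mean)
        + np.asarray(ce["center"])[np.searchsorted(CENTERS, center)]
    )

    if spec.quantile_effects is not None:
        from .qgc import quantize
        qmat = {k: quantize(exposures[k].to_numpy(), 4) for k in EXPOSURES}
        exp_signal = sum(b * qmat[k] for k, b in spec.quantile_effects.items())
        exp_signal = np.asarray(exp_signal, dtype=float)
    else:
        exp_signal = sum(spec.effects[k] * zstd[k].to_numpy() for k in EXPOSURES)
        exp_signal = exp_signal + spec.alcohol_curvature * (
            zstd["alcohol"].to_numpy() ** 2 - 1.0)

    noise = rng.normal(0.0, spec.noise_sd, spec.n)
    epigenetic_age = age + exp_signal + cov_signal + noise

    cohort = pd.DataFrame({
        "participant_id": [f"P{i:05d}" for i in range(spec.n)],
        "age": age, "sex": sex, "race": race, "bmi": bmi, "center": center,
        "epigenetic_age": epigenetic_age,
    })
    cohort = pd.concat([cohort, exposures], axis=1)

    truth = {
        "effects": dict(spec.effects),
        "alcohol_curvature": spec.alcohol_curvature,
        "quantile_effects": (dict(spec.quantile_effects)
                             if spec.quantile_effects is not None else None),
        "covariate_effects": dict(ce),
        "noise_sd": spec.noise_sd,
        "signal": exp_signal,
    }
    if spec.quantile_effects is not None:
        truth["true_psi"] = float(sum(spec.quantile_effects.values()))
    else:
        truth["true_contrast_75_25"] = true_percentile_contrast(
            zstd, spec.effects, spec.alcohol_curvature)
    return cohort, truth


def true_percentile_contrast(zstd: pd.DataFrame, effects: dict,
                             alcohol_curvature: float,
                             q_hi: float = 0.75, q_lo: float = 0.25) -> float:
    """True h(z_hi) - h(z_lo) of the generating exposure-response surface,
    with z_q the vector of component-wise empirical q-th percentiles."""
    z_hi = zstd.quantile(q_hi)
    z_lo = zstd.quantile(q_lo)
    delta = sum(effects[k] * (z_hi[k] - z_lo[k]) for k in EXPOSURES)
    delta += alcohol_curvature * (z_hi["alcohol"] ** 2 - z_lo["alcohol"] ** 2)
    return float(delta)


def spearman_matrix(cohort: pd.DataFrame) -> pd.DataFrame:
    """Spearman rank correlations (average-rank ties) among the exposures."""
    sub = cohort[list(EXPOSURES)]
    if len(sub) < 3:
        raise ValueError("need at least 3 rows")
    const = [c for c in sub.columns if sub[c].nunique() <= 1]
    if const:
        warnings.warn(f"constant columns have undefined rank correlation: {const}")
    rho, _ = stats.spearmanr(sub.to_numpy())
    return pd.DataFrame(rho, index=EXPOSURES, columns=EXPOSURES)


# ---------------------------------------------------------------------------
# long-format exam-series emitter (for end-to-end pipeline tests)
# ---------------------------------------------------------------------------

#: exam schedule in years since baseline
EXAM_SCHEDULE = (0, 2, 5, 7, 10, 15, 20)


def to_exam_records(cohort: pd.DataFrame) -> pd.DataFrame:
    """Emit per-exam longitudinal records consistent with the cumulative table.

    Each exposure's trajectory is flat at the level that makes the standard
    accumulation recipe reproduce the cohort's cumulative value exactly:
    pack accumulation sums endpoint pairs over intervals and divides by 20,
    alcohol/activity average endpoint pairs, diet/sleep are plain means, and
    education is the single value recorded at the final exam.
    """
    rows = []
    span = EXAM_SCHEDULE[-1] - EXAM_SCHEDULE[0]
    for _, r in cohort.iterrows():
        pid = r["participant_id"]
        # sum-stat with divisor 20: constant c gives 2*c*span/20 packs
        cigs = r["smoking"] * 20.0 / (2.0 * span)
        for y in EXAM_SCHEDULE:
            rows.append((pid, "smoking", y, cigs))
        for name in ("alcohol", "physical_activity"):
            level = r[name] / span  # mean-stat constant c accumulates to c*span
            for y in EXAM_SCHEDULE:
                rows.append((pid, name, y, level))
        for y in (0, 7, 20):
            rows.append((pid, "diet", y, r["diet"]))
        for y in (15, 20):
            rows.append((pid, "sleep", y, r["sleep"]))
        rows.append((pid, "education", 20, r["education"]))
    return pd.DataFrame(rows, columns=["participant_id", "exposure",
                                       "exam_year", "value"])
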