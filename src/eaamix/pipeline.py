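"""Full-analysis orchestration: exposures -> EAA -> QGC + BKMR + linear model.

Runs the whole mixture analysis on a wide per-participant table and
(optionally) within strata, producing a JSON-serializable report that
mirrors the usual mixture-analysis layout: per-exposure QGC weights and
BKMR posterior inclusion probabilities, each method's collective
association with its interval, the plain linear-regression comparison, and
the exposure Spearman matrix.  A report is regenerable bit-identically
from the same configuration and seed.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from . import __version__
from .simulate import EXPOSURES
from .eaa import residualize
from .qgc import fit_qgc, bootstrap_psi, _dummy_code, _check_full_rank
from .bkmr import BKMRConfig, mcmc_sample, compute_pips, overall_association
from .simulate import spearman_matrix

DEFAULT_COVARIATES = ("sex", "race", "bmi", "center")


@dataclass
class AnalysisConfig:
    """Settings for one end-to-end run."""

    outcome_label: str = "GrimAA"
    q: int = 4
    n_boot: int = 0                       # 0 = Wald interval only
    covariates: tuple = DEFAULT_COVARIATES
    include_age: bool = False             # add chronological age as covariate
    strata: tuple = ()                    # subset of {"sex","race","smoking_status"}
    bkmr_iters: int = 50_000
    bkmr_burn_frac: float = 0.5
    bkmr_thin: int = 10
    seed: int = 0
    #: recompute the EAA residualization within each stratum instead of
    #: carrying the full-sample residuals (default: one residualization,
    #: so all strata are compared on a single acceleration scale)
    eaa_per_stratum: bool = False
    #: reuse full-sample standardization and quantile cuts inside strata
    #: instead of recomputing them per stratum
    reuse_full_sample_scale: bool = False


def covariate_table(cohort: pd.DataFrame, config: AnalysisConfig) -> pd.DataFrame:
    cols = list(config.covariates)
    if config.include_age and "age" not in cols:
        cols = ["age"] + cols
    return cohort[cols]


def linear_comparison(outcome, exposures_std: pd.DataFrame,
                      covariates: pd.DataFrame | None) -> pd.DataFrame:
    """Conventional joint linear model: all standardized exposures at once.

    Coefficients are the mean outcome change per 1 SD of each (log-scale)
    exposure, with 95% CIs and two-sided p-values.
    """
    cov = _dummy_code(covariates)
    design = exposures_std if cov is None else pd.concat(
        [exposures_std, cov.set_axis(exposures_std.index)], axis=1)
    design = sm.add_constant(design, prepend=True)
    _check_full_rank(design)
    res = sm.OLS(np.asarray(outcome, float), design.to_numpy(float)).fit()
    ci = res.conf_int(alpha=0.05)
    out = pd.DataFrame({
        "coef": res.params, "se": res.bse,
        "ci_low": ci[:, 0], "ci_high": ci[:, 1], "p": res.pvalues,
    }, index=design.columns)
    return out.loc[list(exposures_std.columns)]


def _standardize_block(raw: pd.DataFrame) -> tuple[pd.DataFrame, list]:
    """log1p + z-score; constant columns are dropped and reported NA."""
    logged = np.log1p(raw)
    sd = logged.std(ddof=1)
    dead = sd.index[(sd == 0) | sd.isna()].tolist()
    kept = [c for c in raw.columns if c not in dead]
    z = (logged[kept] - logged[kept].mean()) / sd[kept]
    return z, dead


def _analyse_subset(cohort: pd.DataFrame, eaa: np.ndarray,
                    config: AnalysisConfig, label: str,
                    full_scale: pd.DataFrame | None = None) -> dict:
    raw = cohort[list(EXPOSURES)]
    if config.reuse_full_sample_scale and full_scale is not None:
        zstd = full_scale.loc[cohort.index]
        dropped = [c for c in EXPOSURES if raw[c].nunique() <= 1]
        zstd = zstd[[c for c in zstd.columns if c not in dropped]]
    else:
        zstd, dropped = _standardize_block(raw)
    active = list(zstd.columns)
    covs = covariate_table(cohort, config)
    # drop covariates that are constant within the stratum
    covs = covs[[c for c in covs.columns if covs[c].nunique() > 1]]
    y = eaa

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sp = spearman_matrix(cohort)
        fit = fit_qgc(y, raw[active], covs, q=config.q)
        lin = linear_comparison(y, zstd, covs)

    bcfg = BKMRConfig(n_iter=config.bkmr_iters, burn_frac=config.bkmr_burn_frac,
                      thin=config.bkmr_thin, seed=config.seed)
    Xcov = _dummy_code(covs)
    Xmat = None if Xcov is None else Xcov.to_numpy(float)
    post = mcmc_sample(y, Xmat, zstd.to_numpy(float), bcfg,
                       exposure_names=active)
    pips = compute_pips(post)
    est, lo, hi = overall_association(post, y, Xmat, zstd.to_numpy(float))

    def weight_of(name):
        if name in fit.weights_positive:
            return fit.weights_positive[name]
        if name in fit.weights_negative:
            return fit.weights_negative[name]
        return 0.0

    report = {
        "label": label,
        "n": int(len(cohort)),
        "exposures": {
            name: {
                "qgc_weight": None if name in dropped + fit.excluded
                else float(weight_of(name)),
                "pip": None if name in dropped else float(pips[name]),
                "linear_coef_per_sd": None if name in dropped
                else float(lin.loc[name, "coef"]),
                "linear_p": None if name in dropped
                else float(lin.loc[name, "p"]),
            } for name in EXPOSURES
        },
        "qgc": {
            "psi": fit.psi, "psi_se": fit.psi_se,
            "ci_low": fit.psi_ci_low, "ci_high": fit.psi_ci_high,
            "p": fit.psi_p,
        },
        "bkmr": {
            "overall_association": est, "cri_low": lo, "cri_high": hi,
            "n_retained_draws": post.n_retained,
            "lambda_accept_rate": post.lambda_accept_rate,
        },
        "spearman": {a: {b: (None if np.isnan(sp.loc[a, b])
                             else round(float(sp.loc[a, b]), 6))
                         for b in EXPOSURES} for a in EXPOSURES},
        "dropped_exposures": dropped,
    }
    if config.n_boot > 0:
        blo, bhi = bootstrap_psi(y, raw[active], covs, config.q,
                                 n_boot=config.n_boot, seed=config.seed)
        report["qgc"]["bootstrap_ci"] = [blo, bhi]
    return report


def _strata_masks(cohort: pd.DataFrame, name: str):
    if name == "smoking_status":
        ever = cohort["smoking"] > 0
        yield "ever_smokers", ever
        yield "never_smokers", ~ever
    elif name in cohort.columns:
        for level in sorted(cohort[name].unique()):
            yield f"{name}={level}", cohort[name] == level
    else:
        raise ValueError(f"unknown stratum variable {name!r}")


def run_analysis(cohort: pd.DataFrame,
                 config: AnalysisConfig | None = None) -> dict:
    """Execute the full pipeline on a wide cohort table.

    The table needs the six exposure columns plus ``participant_id, age,
    epigenetic_age`` and the configured covariates.  Returns the nested
    report dict (JSON-serializable).
    """
    config = config or AnalysisConfig()
    cohort = cohort.reset_index(drop=True)
    v = residualize(cohort["epigenetic_age"], cohort["age"])
    eaa_full = v.eaa

    full_scale, _ = _standardize_block(cohort[list(EXPOSURES)])

    analyses = {"overall": _analyse_subset(cohort, eaa_full, config, "overall",
                                           full_scale)}
    for strat in config.strata:
        for label, mask in _strata_masks(cohort, strat):
            sub = cohort[mask]
            if len(sub) < 50:
                analyses[label] = {"label": label, "n": int(len(sub)),
                                   "skipped": "stratum too small"}
                continue
            if config.eaa_per_stratum:
                y = residualize(sub["epigenetic_age"], sub["age"]).eaa
            else:
                y = eaa_full[mask.to_numpy()]
            analyses[label] = _analyse_subset(sub, y, config, label, full_scale)

    cfg_hash = hashlib.sha256(
        json.dumps(asdict(config), sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    return {
        "outcome": config.outcome_label,
        "eaa_fit": {"intercept": v.fit_intercept, "slope": v.fit_slope},
        "analyses": analyses,
        "metadata": {
            "seed": config.seed,
            "config_hash": cfg_hash,
            "package_version": __version__,
            "config": asdict(config),
        },
    }


def report_json(report: dict) -> str:
    """Stable serialization (byte-identical for identical config + seed)."""
    return json.dumps(report, sort_keys=True, indent=2, default=str)
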