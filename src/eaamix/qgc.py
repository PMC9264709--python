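"""Quantile-based g-computation for exposure mixtures.

Each exposure is mapped to its empirical quantile category (0..q-1), and
the outcome is regressed on all quantized exposures jointly plus
covariates.  Because the model is linear in the quantized exposures, the
g-computation estimand — the change in outcome per simultaneous
one-quantile increase in every exposure — is exactly the sum of the
exposure coefficients, psi = sum_j beta_j, with a closed-form Wald
interval from the coefficient covariance.  Per-exposure weights
w_k = beta_k / sum(same-sign beta_j) partition each direction's effect:
positive weights sum to 1 and negative weights to -1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)


def quantize(values, q: int = 4) -> np.ndarray:
    """Empirical q-quantile codes in {0, ..., q-1}.

    Cut-points are the interior empirical quantiles (linear-interpolation
    definition); a value equal to a cut-point is assigned to the upper bin.
    If the data have fewer than q distinct values the quantile cut-points
    collapse, and coding falls back to average-rank binning (constant
    input: all zeros) with a warning.
    """
    v = np.asarray(values, dtype=float)
    if q < 2:
        raise ValueError("q must be at least 2")
    if v.ndim != 1 or len(v) < q:
        raise ValueError("need a 1-D vector with length >= q")
    distinct = np.unique(v)
    if len(distinct) < q:
        warnings.warn(f"fewer than q={q} distinct values; "
                      "falling back to rank-based binning")
        if len(distinct) == 1:
            return np.zeros(len(v), dtype=int)
        ranks = stats.rankdata(v, method="average")
        codes = np.floor((ranks - 0.5) / len(v) * q).astype(int)
        return np.clip(codes, 0, q - 1)
    cuts = np.quantile(v, np.arange(1, q) / q)
    return np.searchsorted(cuts, v, side="right").astype(int)


@dataclass
class QGCFit:
    q: int
    beta0: float
    betas: "pd.Series"                 # per-exposure, years per quantile step
    covariate_coefs: "pd.Series"
    psi: float
    psi_se: float
    psi_ci_low: float
    psi_ci_high: float
    psi_p: float
    weights_positive: dict
    weights_negative: dict
    residual_variance: float
    excluded: list = field(default_factory=list)  # degenerate exposures (NA)
    nobs: int = 0


def _dummy_code(covariates: pd.DataFrame | None) -> pd.DataFrame | None:
    """Reference-coded design for the covariate table (categoricals dummied)."""
    if covariates is None or covariates.shape[1] == 0:
        return None
    return pd.get_dummies(covariates, drop_first=True, dtype=float)


def _check_full_rank(design: pd.DataFrame) -> None:
    x = design.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # name the columns whose removal restores full rank
        bad = []
        cols = list(design.columns)
        for j in range(x.shape[1]):
            keep = [k for k in range(x.shape[1]) if k != j]
            if np.linalg.matrix_rank(x[:, keep]) == rank:
                bad.append(cols[j])
        raise ValueError(f"design matrix is rank deficient; collinear "
                         f"column(s): {bad or cols}")


def fit_qgc(outcome, exposures: pd.DataFrame,
            covariates: pd.DataFrame | None = None, q: int = 4) -> QGCFit:
    """Fit the quantized linear index model and summarize psi and weights.

    Exposures that are constant in the sample (e.g. smoking within a
    never-smoker stratum) cannot be quantized and are excluded from the
    model; they appear in ``excluded`` and carry no weight (reported NA
    downstream).
    """
    y = np.asarray(outcome, dtype=float)
    quantized = {}
    excluded = []
    for name in exposures.columns:
        col = exposures[name].to_numpy(dtype=float)
        if np.ptp(col) == 0:
            excluded.append(name)
            warnings.warn(f"exposure {name!r} is constant; excluded from the "
                          "mixture (weight NA)")
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            quantized[name] = quantize(col, q)
    if not quantized:
        raise ValueError("no non-degenerate exposures to fit")
    qdf = pd.DataFrame(quantized, index=exposures.index).astype(float)

    cov = _dummy_code(covariates)
    design = qdf if cov is None else pd.concat(
        [qdf, cov.set_axis(qdf.index)], axis=1)
    design = sm.add_constant(design, prepend=True)
    _check_full_rank(design)

    res = sm.OLS(y, design.to_numpy(dtype=float)).fit()
    names = list(design.columns)
    params = pd.Series(res.params, index=names)
    exp_names = list(qdf.columns)
    betas = params[exp_names]

    idx = [names.index(n) for n in exp_names]
    cov_beta = res.cov_params()[np.ix_(idx, idx)]
    psi = float(betas.sum())
    psi_se = float(np.sqrt(np.ones(len(idx)) @ cov_beta @ np.ones(len(idx))))
    tcrit = stats.t.ppf(0.975, res.df_resid)
    psi_p = float(2 * stats.t.sf(abs(psi / psi_se), res.df_resid)) if psi_se > 0 else 0.0

    # numerically-zero coefficients carry no weight in either direction
    tol = 1e-10 * max(1.0, float(np.abs(betas).max()))
    pos = betas[betas > tol]
    neg = betas[betas < -tol]
    weights_positive = (pos / pos.sum()).to_dict() if len(pos) else {}
    weights_negative = (neg / abs(neg.sum())).to_dict() if len(neg) else {}

    cov_names = [n for n in names if n not in exp_names and n != "const"]
    return QGCFit(
        q=q, beta0=float(params["const"]), betas=betas,
        covariate_coefs=params[cov_names],
        psi=psi, psi_se=psi_se,
        psi_ci_low=psi - tcrit * psi_se, psi_ci_high=psi + tcrit * psi_se,
        psi_p=psi_p,
        weights_positive=weights_positive, weights_negative=weights_negative,
        residual_variance=float(res.mse_resid), excluded=excluded,
        nobs=int(res.nobs),
    )


def bootstrap_psi(outcome, exposures: pd.DataFrame,
                  covariates: pd.DataFrame | None = None, q: int = 4,
                  n_boot: int = 500, seed: int = 0) -> tuple[float, float]:
    """Percentile bootstrap interval for psi (participant resampling).

    Quantile cut-points are recomputed within each resample.  A cross-check
    of the closed-form Wald interval, which is exact under the linear
    model.  Rank-deficient resamples are skipped and counted in the log.
    """
    if n_boot < 200:
        raise ValueError("n_boot must be at least 200")
    rng = np.random.default_rng(seed)
    y = np.asarray(outcome, dtype=float)
    n = len(y)
    psis = []
    skipped = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = fit_qgc(y[idx], exposures.iloc[idx].reset_index(drop=True),
                              None if covariates is None
                              else covariates.iloc[idx].reset_index(drop=True), q)
        except ValueError:
            skipped += 1
            continue
        psis.append(fit.psi)
    if skipped:
        logger.info("bootstrap skipped %d rank-deficient resamples", skipped)
    lo, hi = np.percentile(psis, [2.5, 97.5])
    return float(lo), float(hi)
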