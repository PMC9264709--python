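"""Epigenetic age acceleration (EAA).

EAA is the residual from an ordinary least-squares regression of epigenetic
age (e.g. GrimAge or PhenoAge) on chronological age.  A positive value
means a participant is epigenetically older than their chronological age
predicts.  By construction the residuals have mean zero and are
uncorrelated with chronological age, so EAA comparisons are free of the
cross-sectional age trend of the clock itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class EAAVector:
    participant_ids: list
    eaa: np.ndarray          # years; may be negative
    fit_intercept: float     # years
    fit_slope: float         # dimensionless


def residualize(epigenetic_age, chronological_age, participant_ids=None) -> EAAVector:
    """OLS residuals of epigenetic age on chronological age (with intercept)."""
    y = np.asarray(epigenetic_age, dtype=float)
    x = np.asarray(chronological_age, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("age vectors must be 1-D and of equal length")
    if len(y) < 3:
        raise ValueError("need at least 3 participants")
    if np.ptp(x) == 0:
        raise ValueError("degenerate regression: chronological age is constant")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    if participant_ids is None:
        participant_ids = list(range(len(y)))
    return EAAVector(list(participant_ids), resid, float(intercept), float(slope))


def eaa_frame(cohort: pd.DataFrame, clock_col: str = "epigenetic_age",
              age_col: str = "age") -> pd.DataFrame:
    """Residualize a wide cohort table; returns `participant_id, eaa`."""
    v = residualize(cohort[clock_col], cohort[age_col],
                    cohort["participant_id"].tolist())
    return pd.DataFrame({"participant_id": v.participant_ids, "eaa": v.eaa})
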