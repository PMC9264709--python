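"""Cumulative exposure construction from longitudinal exam records.

Six lifestyle exposures are reduced from repeated exam measurements to a
single per-participant value: smoking and drinking accumulate over the
follow-up (endpoint statistic per consecutive exam pair, scaled by the
interval length in years), diet and sleep average the available exams, and
education is the attained years at the final exam.  The resulting raw
matrix is log1p-transformed and z-scored to give the analysis-scale
exposure matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .simulate import EXPOSURES

logger = logging.getLogger(__name__)

#: exam years since baseline on the study schedule
EXAM_SCHEDULE = (0, 2, 5, 7, 10, 15, 20)


@dataclass
class ExamSeries:
    """One participant's repeated measurements of one exposure."""

    participant_id: str
    exposure_name: str
    observations: Sequence[tuple[int, float]]  # (exam_year, value)

    def __post_init__(self):
        years = [y for y, _ in self.observations]
        values = [v for _, v in self.observations]
        if any(b <= a for a, b in zip(years, years[1:])):
            raise ValueError("exam years must be strictly increasing")
        if any(y not in EXAM_SCHEDULE for y in years):
            raise ValueError(f"exam years must be on the study schedule {EXAM_SCHEDULE}")
        if any(v < 0 for v in values):
            raise ValueError("exposure values must be non-negative")


def accumulate_interval(series: ExamSeries, interval_stat: str = "mean",
                        divisor: float = 1.0) -> float:
    """Accumulate an exposure over consecutive exam intervals.

    For each pair of consecutive exams, the endpoint statistic (``mean`` or
    ``sum`` of the two values) is multiplied by the interval length in
    years; the per-interval products are summed and divided by ``divisor``.
    ``divisor=20`` converts cigarettes to packs; otherwise 1.

    With ``interval_stat="mean"`` this is the trapezoidal rule applied to
    the piecewise-linear exposure trajectory.
    """
    if interval_stat not in ("mean", "sum"):
        raise ValueError("interval_stat must be 'mean' or 'sum'")
    if divisor <= 0:
        raise ValueError("divisor must be positive")
    obs = list(series.observations)
    if len(obs) < 2:
        raise ValueError("insufficient exams: need at least 2 observations")
    total = 0.0
    for (ya, va), (yb, vb) in zip(obs, obs[1:]):
        stat = (va + vb) / 2.0 if interval_stat == "mean" else (va + vb)
        total += stat * (yb - ya)
    return total / divisor


def average_over_exams(series: ExamSeries) -> float:
    """Arithmetic mean of the available observations (absent exams skipped)."""
    obs = list(series.observations)
    if not obs:
        raise ValueError("empty series: need at least 1 observation")
    return float(np.mean([v for _, v in obs]))


def value_at_last_exam(series: ExamSeries) -> float:
    """Value recorded at the participant's latest exam (attained education)."""
    obs = list(series.observations)
    if not obs:
        raise ValueError("empty series: need at least 1 observation")
    return float(obs[-1][1])


@dataclass
class ExposureRecipe:
    """How each exposure is reduced to one per-participant number."""

    method: str                 # "accumulate" | "average" | "last"
    interval_stat: str = "mean"
    divisor: float = 1.0


def default_recipe(uniform_mean: bool = False) -> dict[str, ExposureRecipe]:
    """Standard reduction recipe for the six exposures.

    Smoking sums the endpoint cigarette counts per interval (then /20 to
    packs) while alcohol and activity average them; ``uniform_mean=True``
    forces the mean-of-endpoints convention for smoking as well, for
    sensitivity analysis of that convention.
    """
    smoking_stat = "mean" if uniform_mean else "sum"
    return {
        "smoking": ExposureRecipe("accumulate", smoking_stat, 20.0),
        "alcohol": ExposureRecipe("accumulate", "mean", 1.0),
        "physical_activity": ExposureRecipe("accumulate", "mean", 1.0),
        "diet": ExposureRecipe("average"),
        "sleep": ExposureRecipe("average"),
        "education": ExposureRecipe("last"),
    }


def _reduce(series: ExamSeries, recipe: ExposureRecipe) -> float:
    if recipe.method == "accumulate":
        return accumulate_interval(series, recipe.interval_stat, recipe.divisor)
    if recipe.method == "average":
        return average_over_exams(series)
    if recipe.method == "last":
        return value_at_last_exam(series)
    raise ValueError(f"unknown reduction method {recipe.method!r}")


@dataclass
class ExposureMatrix:
    """Per-participant exposures on the raw and analysis (log1p, z) scales."""

    participant_ids: list[str]
    raw: pd.DataFrame
    standardized: pd.DataFrame
    transform_log: dict[str, str]
    dropped: list[str] = field(default_factory=list)


def standardize(raw: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, str]]:
    """log1p then z-score each column; errors on zero-variance columns."""
    logged = np.log1p(raw)
    sd = logged.std(ddof=1)
    dead = sd.index[(sd == 0) | sd.isna()].tolist()
    if dead:
        raise ValueError(f"zero-variance exposure(s): {dead}; z-score undefined")
    z = (logged - logged.mean()) / sd
    return z, {c: "log1p" for c in raw.columns}


def build_exposure_matrix(cohort_long: pd.DataFrame,
                          recipe: dict[str, ExposureRecipe] | None = None,
                          exposures: Sequence[str] = EXPOSURES) -> ExposureMatrix:
    """Reduce a long-format exam table to the standardized exposure matrix.

    ``cohort_long`` has columns ``participant_id, exposure, exam_year,
    value``.  Participants missing any exposure entirely (or with too few
    exams for an accumulating exposure) are dropped, complete-case, and
    recorded in the drop log.
    """
    recipe = recipe if recipe is not None else default_recipe()
    values: dict[str, dict[str, float]] = {}
    dropped: list[str] = []
    for pid, grp in cohort_long.groupby("participant_id", sort=True):
        row = {}
        try:
            for name in exposures:
                sub = grp[grp["exposure"] == name].sort_values("exam_year")
                if sub.empty:
                    raise ValueError(f"missing exposure {name!r}")
                series = ExamSeries(str(pid), name,
                                    list(zip(sub["exam_year"].astype(int),
                                             sub["value"].astype(float))))
                row[name] = _reduce(series, recipe[name])
        except ValueError as exc:
            dropped.append(str(pid))
            logger.info("dropped participant %s: %s", pid, exc)
            continue
        values[str(pid)] = row
    if not values:
        raise ValueError("zero retained participants after complete-case filtering")
    if dropped:
        logger.info("complete-case filter dropped %d of %d participants",
                    len(dropped), len(dropped) + len(values))
    raw = pd.DataFrame.from_dict(values, orient="index")[list(exposures)]
    z, transform_log = standardize(raw)
    return ExposureMatrix(participant_ids=list(raw.index), raw=raw,
                          standardized=z, transform_log=transform_log,
                          dropped=dropped)


def long_from_csv(path) -> pd.DataFrame:
    """Read the long-format exam CSV (`participant_id,exposure,exam_year,value`)."""
    df = pd.read_csv(path)
    required = {"participant_id", "exposure", "exam_year", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"long-format CSV missing columns: {sorted(missing)}")
    return df
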