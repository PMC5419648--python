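"""External validation of a population model: prediction errors, MDPE/MDAPE
and bootstrap confidence intervals.

For each serum sample the relative prediction error is

    PE = 100 * (Cpredicted - Cobserved) / Cobserved   [%]

MDPE (the median PE, bias) and MDAPE (the median absolute PE, precision)
summarise a cohort; nonparametric 95% confidence intervals come from a
percentile bootstrap of the prediction errors.  Predictions are made either
a priori (population medians, no fitting) or — the default, matching
one-cycle Bayesian evaluation of predictive power — from a single MAP fit of
each course against the fixed population model, whose population values are
never updated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .estimation import FitError, FitSettings, map_fit
from .pkmodel import CourseRecord, PopulationModel, concentration

__all__ = [
    "PredictionPair",
    "ValidationSummary",
    "predict_cohort",
    "prediction_errors",
    "mdpe",
    "mdape",
    "bootstrap_validation",
    "validate_cohort",
]

logger = logging.getLogger(__name__)

Mode = Literal["posterior", "a_priori"]


@dataclass(frozen=True)
class PredictionPair:
    """One observed/predicted concentration pair of a validation course."""

    course_id: str
    time_h: float
    c_observed: float
    c_predicted: float
    mode: Mode

    def __post_init__(self) -> None:
        if self.c_observed <= 0:
            raise ValueError("observed concentration must be positive (PE undefined)")


@dataclass(frozen=True)
class ValidationSummary:
    """Cohort-level validation metrics (all in %)."""

    pe_list: tuple[float, ...]
    mdpe: float
    mdape: float
    ci_mdpe: tuple[float, float]
    ci_mdape: tuple[float, float]
    n_samples: int
    n_courses: int
    n_courses_excluded: int = 0


def predict_cohort(
    cohort: Sequence[CourseRecord],
    model: PopulationModel,
    mode: Mode = "posterior",
    settings: FitSettings | None = None,
) -> list[PredictionPair]:
    """Predict every observation of every course under a fixed population model.

    ``posterior`` (default): each course is MAP-fitted once against the model
    and its observations are predicted from the fitted individual parameters
    (one cycle; the population values never move).  ``a_priori``: predictions
    use the population medians and ignore the observed values entirely.
    Courses that fail to fit are excluded with a logged warning.
    """
    settings = settings or FitSettings()
    pairs: list[PredictionPair] = []
    n_excluded = 0
    for record in cohort:
        if not record.observations:
            raise ValueError(f"course {record.course_id!r} has no observations")
        try:
            if mode == "posterior":
                fit = map_fit(record, model, settings)
                est = fit.estimate
            elif mode == "a_priori":
                from .pkmodel import individual_parameters
                est = individual_parameters(
                    model.medians(), record.covariates,
                    at_time=record.doses[0].start_time_h,
                    f_fat=settings.f_fat, weight_metric=settings.weight_metric)
            else:
                raise ValueError(f"unknown prediction mode {mode!r}")
        except FitError as exc:
            logger.warning("course %s excluded from validation: %s",
                           record.course_id, exc)
            n_excluded += 1
            continue
        t = np.array([o.time_h for o in record.observations])
        pred = np.atleast_1d(np.asarray(
            concentration(est.cl_l_per_h, est.v_l, record.doses, t)))
        for o, c_hat in zip(record.observations, pred):
            pairs.append(PredictionPair(
                course_id=record.course_id, time_h=o.time_h,
                c_observed=o.conc_mg_per_l, c_predicted=float(c_hat), mode=mode))
    if n_excluded:
        logger.warning("%d course(s) excluded from validation", n_excluded)
    return pairs


def prediction_errors(pairs: Sequence[PredictionPair]) -> np.ndarray:
    """Relative prediction errors in %: 100*(Cpred - Cobs)/Cobs."""
    obs = np.array([p.c_observed for p in pairs])
    if np.any(obs <= 0):
        raise ValueError("observed concentrations must be positive")
    pred = np.array([p.c_predicted for p in pairs])
    return 100.0 * (pred - obs) / obs


def mdpe(pe_list: Sequence[float]) -> float:
    """Median prediction error (%), a measure of bias.

    Even-length lists use the midpoint of the two central order statistics.
    """
    pe = np.asarray(pe_list, dtype=float)
    if pe.size == 0:
        raise ValueError("empty prediction-error list")
    return float(np.median(pe))


def mdape(pe_list: Sequence[float]) -> float:
    """Median absolute prediction error (%), a measure of precision."""
    pe = np.asarray(pe_list, dtype=float)
    if pe.size == 0:
        raise ValueError("empty prediction-error list")
    return float(np.median(np.abs(pe)))


def bootstrap_validation(
    pe_list: Sequence[float],
    reps: int = 10_000,
    seed: int = 0,
    course_ids: Sequence[str] | None = None,
    by_course: bool = False,
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Percentile-bootstrap 95% CIs for MDPE and MDAPE.

    Resamples individual prediction errors with replacement by default; with
    ``by_course=True`` whole courses are resampled instead (``course_ids``
    required, one id per error).  Deterministic given ``seed``.
    """
    pe = np.asarray(pe_list, dtype=float)
    if pe.size == 0:
        raise ValueError("empty prediction-error list")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    if by_course:
        if course_ids is None:
            raise ValueError("by_course resampling requires course_ids")
        ids = np.asarray(course_ids)
        unique = np.unique(ids)
        groups = [pe[ids == u] for u in unique]
        med_pe = np.empty(reps)
        med_ape = np.empty(reps)
        for r in range(reps):
            pick = rng.integers(0, len(groups), len(groups))
            sample = np.concatenate([groups[i] for i in pick])
            med_pe[r] = np.median(sample)
            med_ape[r] = np.median(np.abs(sample))
    else:
        idx = rng.integers(0, pe.size, size=(reps, pe.size))
        samples = pe[idx]
        med_pe = np.median(samples, axis=1)
        med_ape = np.median(np.abs(samples), axis=1)
    ci_mdpe = (float(np.percentile(med_pe, 2.5)), float(np.percentile(med_pe, 97.5)))
    ci_mdape = (float(np.percentile(med_ape, 2.5)), float(np.percentile(med_ape, 97.5)))
    return ci_mdpe, ci_mdape


def validate_cohort(
    cohort: Sequence[CourseRecord],
    model: PopulationModel,
    mode: Mode = "posterior",
    reps: int = 10_000,
    seed: int = 0,
    settings: FitSettings | None = None,
) -> ValidationSummary:
    """Full external validation: predictions, PEs, MDPE/MDAPE and bootstrap CIs."""
    pairs = predict_cohort(cohort, model, mode=mode, settings=settings)
    pe = prediction_errors(pairs)
    ci_pe, ci_ape = bootstrap_validation(pe, reps=reps, seed=seed)
    courses_used = {p.course_id for p in pairs}
    return ValidationSummary(
        pe_list=tuple(float(x) for x in pe),
        mdpe=mdpe(pe), mdape=mdape(pe),
        ci_mdpe=ci_pe, ci_mdape=ci_ape,
        n_samples=len(pairs), n_courses=len(courses_used),
        n_courses_excluded=len(cohort) - len(courses_used),
    )
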