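"""Synthetic treatment-course generator with the statistical structure the
analysis assumes.

Emulates once-daily gentamicin cohorts: demographics drawn as truncated
normals inside published ranges, true individual parameters drawn log-normally
from a population model, 3 mg/kg 30-minute infusions every 24 h, a fixed-count
sampling scheme (a "peak" 0.5 h after end of infusion and a mid-interval
sample 4 h after end of infusion, on successive dosing occasions) and additive
assay noise with the concentration-dependent polynomial SD.  The generator
returns the course records together with a hidden truth table so parameter
recovery can be scored.

Sample counts are distributed deterministically across courses so cohort
totals (221 samples over 65 modeling courses; 30 over 14 validation courses)
are exact and tests are stable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimation import PopulationFit
from .forecasting import Regimen
from .pkmodel import (
    LOQ_MG_PER_L,
    CourseRecord,
    DoseEvent,
    Observation,
    PatientCovariates,
    PopulationModel,
    assay_sd,
    individual_parameters,
    load_preset,
)

__all__ = ["CohortSpec", "generate_cohort", "truth_recovery_report"]

_CG_SEX_FACTOR = {"male": 1.23, "female": 1.04}


@dataclass(frozen=True)
class CohortSpec:
    """Study-design parameters of a synthetic cohort.

    Defaults reproduce the modeling cohort design: 65 courses, 221 samples,
    endocarditis-model truth, demographics with the published means and
    ranges (truncated normals, SD = range width / 4), creatinine chosen to
    induce the published creatinine-clearance range, and 2-7 once-daily
    3 mg/kg doses per course.  :meth:`validation` gives the 14-course,
    30-sample external-validation design.
    """

    n_courses: int = 65
    target_total_samples: int = 221
    truth_model: PopulationModel | None = None  # None -> endocarditis preset
    age_mean: float = 69.3
    age_range: tuple[float, float] = (32.0, 92.0)
    weight_mean: float = 76.2
    weight_range: tuple[float, float] = (46.0, 121.0)
    height_mean: float = 173.9
    height_range: tuple[float, float] = (149.0, 193.0)
    female_fraction: float = 21 / 65
    clcr_mean: float = 64.3
    clcr_range: tuple[float, float] = (8.7, 157.5)
    regimen: Regimen = field(default_factory=lambda: Regimen(
        dose_per_kg=3.0, interval_h=24.0, infusion_h=0.5))
    n_doses_range: tuple[int, int] = (2, 7)
    peak_offset_h: float = 0.5  # after end of infusion
    mid_offset_h: float = 4.0   # after end of infusion
    add_noise: bool = True
    rng_seed: int = 0
    id_prefix: str = "mod"

    def __post_init__(self) -> None:
        if self.n_courses < 1:
            raise ValueError("n_courses must be >= 1")
        if self.target_total_samples < self.n_courses:
            raise ValueError("need at least one observation per course")

    @staticmethod
    def modeling(**overrides) -> "CohortSpec":
        return CohortSpec(**overrides)

    @staticmethod
    def validation(**overrides) -> "CohortSpec":
        defaults = dict(
            n_courses=14, target_total_samples=30,
            age_mean=63.4, age_range=(30.0, 88.0),
            weight_mean=80.3, weight_range=(65.0, 90.0),
            height_mean=177.7, height_range=(169.0, 195.0),
            female_fraction=3 / 14,
            clcr_mean=75.5, clcr_range=(28.4, 181.5),
            id_prefix="val",
        )
        defaults.update(overrides)
        return CohortSpec(**defaults)

    def resolved_truth_model(self) -> PopulationModel:
        return self.truth_model if self.truth_model is not None else load_preset("endocarditis")


def _truncated_normal(rng: np.random.Generator, mean: float,
                      lo: float, hi: float) -> float:
    """Normal(mean, (hi-lo)/4) rejected outside [lo, hi]."""
    sd = (hi - lo) / 4.0
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(min(max(mean, lo), hi))


def _samples_per_course(n_courses: int, total: int) -> list[int]:
    base, extra = divmod(total, n_courses)
    return [base + 1 if i < extra else base for i in range(n_courses)]


def _draw_truth(model: PopulationModel, rng: np.random.Generator) -> dict[str, float]:
    theta = {}
    for p in model.params:
        if p.setting == "Fixed" or p.omega2 == 0.0:
            theta[p.name] = p.median
        else:
            theta[p.name] = float(np.exp(rng.normal(p.log_mu, p.omega)))
    return theta


def generate_cohort(spec: CohortSpec) -> tuple[list[CourseRecord], pd.DataFrame]:
    """Generate course records plus the hidden per-course truth table.

    Deterministic given ``spec.rng_seed``.  The truth table carries one row
    per course (true clm/fr/vd and derived CL, V) and the generating
    population means in ``DataFrame.attrs['truth_means']``.
    """
    rng = np.random.default_rng(spec.rng_seed)
    truth_model = spec.resolved_truth_model()
    counts = _samples_per_course(spec.n_courses, spec.target_total_samples)
    records: list[CourseRecord] = []
    truth_rows: list[dict] = []

    for i, n_samples in enumerate(counts):
        course_id = f"{spec.id_prefix}-{i + 1:03d}"
        age = _truncated_normal(rng, spec.age_mean, *spec.age_range)
        weight = _truncated_normal(rng, spec.weight_mean, *spec.weight_range)
        height = _truncated_normal(rng, spec.height_mean, *spec.height_range)
        sex = "female" if rng.random() < spec.female_fraction else "male"
        clcr_target = _truncated_normal(rng, spec.clcr_mean, *spec.clcr_range)
        # invert Cockcroft-Gault (total-BW variant) for the creatinine value
        scr = _CG_SEX_FACTOR[sex] * (140.0 - age) * weight / clcr_target
        cov = PatientCovariates(
            age_y=age, sex=sex, weight_kg=weight, height_cm=height,
            creatinine_series=((0.0, scr),),
        )

        occasions = math.ceil(n_samples / 2)
        lo, hi = spec.n_doses_range
        n_doses = int(rng.integers(lo, hi + 1))
        n_doses = max(n_doses, occasions)
        doses = tuple(
            DoseEvent(start_time_h=j * spec.regimen.interval_h,
                      amount_mg=spec.regimen.dose_for(weight),
                      infusion_h=spec.regimen.infusion_h)
            for j in range(n_doses)
        )

        theta = _draw_truth(truth_model, rng)
        est = individual_parameters(theta, cov, at_time=0.0)

        sample_times: list[float] = []
        for occ in range(occasions):
            t0 = doses[occ].start_time_h + doses[occ].infusion_h
            sample_times.append(t0 + spec.peak_offset_h)
            sample_times.append(t0 + spec.mid_offset_h)
        sample_times = sorted(sample_times[:n_samples])

        t_arr = np.array(sample_times)
        c_true = np.atleast_1d(np.asarray(_conc(est, doses, t_arr)))
        if spec.add_noise:
            noise = rng.normal(0.0, 1.0, c_true.shape) * np.asarray(
                assay_sd(c_true, truth_model.assay_error_coeffs))
            c_obs = c_true + noise
        else:
            c_obs = c_true.copy()
        below = c_obs < LOQ_MG_PER_L
        c_obs = np.maximum(c_obs, LOQ_MG_PER_L)
        observations = tuple(
            Observation(time_h=float(t), conc_mg_per_l=float(c),
                        below_loq=bool(b))
            for t, c, b in zip(sample_times, c_obs, below)
        )
        records.append(CourseRecord(course_id=course_id, covariates=cov,
                                    doses=doses, observations=observations))
        truth_rows.append({
            "course_id": course_id, **theta,
            "cl_l_per_h": est.cl_l_per_h, "v_l": est.v_l,
        })

    truth = pd.DataFrame(truth_rows)
    truth.attrs["truth_means"] = {p.name: p.mean for p in truth_model.params}
    truth.attrs["truth_sds"] = {p.name: p.sd for p in truth_model.params}
    return records, truth


def _conc(est, doses, t):
    from .pkmodel import concentration
    return concentration(est.cl_l_per_h, est.v_l, doses, t)


def truth_recovery_report(
    cohort: list[CourseRecord],
    truth: pd.DataFrame,
    fit: PopulationFit,
) -> dict[str, dict[str, float]]:
    """Per-parameter recovery metrics of a population fit on synthetic data.

    bias  = (estimated population mean - truth population mean) / truth mean
    rmse  = root-mean-square relative error of the individual estimates
            against the hidden truth values.
    """
    ids_cohort = [r.course_id for r in cohort]
    if list(truth["course_id"]) != ids_cohort:
        raise ValueError("truth table course ids do not match the cohort")
    fit_by_id = {f.course_id: f for f in fit.fits}
    if set(fit_by_id) != set(ids_cohort):
        raise ValueError("fit course ids do not match the cohort")
    truth_means = truth.attrs["truth_means"]
    report: dict[str, dict[str, float]] = {}
    for p in fit.model.params:
        name = p.name
        est_i = np.array([fit_by_id[cid].estimate.theta[name] for cid in ids_cohort])
        true_i = truth[name].to_numpy()
        rel_err = est_i / true_i - 1.0
        report[name] = {
            "bias": (p.mean - truth_means[name]) / truth_means[name],
            "rmse": float(np.sqrt(np.mean(rel_err**2))),
            "estimated_mean": p.mean,
            "truth_mean": truth_means[name],
        }
    return report
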