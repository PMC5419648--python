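"""Dataset readers/writers and report serialisation.

A cohort is stored as two UTF-8 comma-separated files with fixed column
names (units are embedded in the names to prevent silent unit errors):

courses table
    ``course_id, age_y, sex, weight_kg, height_cm``
events table
    ``course_id, event_type, time_h, amount_mg, infusion_h, conc_mg_per_l,
    scr_umol_per_l`` with ``event_type`` one of ``dose``, ``obs``,
    ``creatinine``; fields irrelevant to an event type are left empty.

Events are sorted per course on read regardless of file order; unknown
columns are preserved on read but ignored.  Numbers are serialised with 12
significant digits, which makes write -> read -> write byte-stable.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .estimation import PopulationFit
from .pkmodel import (
    LOQ_MG_PER_L,
    CourseRecord,
    DoseEvent,
    Observation,
    PatientCovariates,
    PopulationModel,
)
from .validation import PredictionPair, ValidationSummary

__all__ = [
    "COURSE_COLUMNS",
    "EVENT_COLUMNS",
    "read_dataset",
    "write_dataset",
    "load_model",
    "save_model",
    "fit_report",
    "validation_report",
    "write_prediction_pairs",
]

logger = logging.getLogger(__name__)

COURSE_COLUMNS = ["course_id", "age_y", "sex", "weight_kg", "height_cm"]
EVENT_COLUMNS = ["course_id", "event_type", "time_h", "amount_mg",
                 "infusion_h", "conc_mg_per_l", "scr_umol_per_l"]


def _fmt(x: float | None) -> str:
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return ""
    return format(float(x), ".12g")


def write_dataset(cohort: Sequence[CourseRecord], courses_path, events_path) -> None:
    """Write a cohort to the two-file CSV layout."""
    course_lines = [",".join(COURSE_COLUMNS)]
    event_lines = [",".join(EVENT_COLUMNS)]
    for rec in cohort:
        cov = rec.covariates
        course_lines.append(",".join([
            rec.course_id, _fmt(cov.age_y), cov.sex,
            _fmt(cov.weight_kg), _fmt(cov.height_cm)]))
        for t, scr in cov.creatinine_series:
            event_lines.append(",".join([
                rec.course_id, "creatinine", _fmt(t), "", "", "", _fmt(scr)]))
        for d in rec.doses:
            event_lines.append(",".join([
                rec.course_id, "dose", _fmt(d.start_time_h),
                _fmt(d.amount_mg), _fmt(d.infusion_h), "", ""]))
        for o in rec.observations:
            event_lines.append(",".join([
                rec.course_id, "obs", _fmt(o.time_h), "", "",
                _fmt(o.conc_mg_per_l), ""]))
    Path(courses_path).write_text("\n".join(course_lines) + "\n", encoding="utf-8")
    Path(events_path).write_text("\n".join(event_lines) + "\n", encoding="utf-8")


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")


def read_dataset(courses_path, events_path) -> list[CourseRecord]:
    """Read and validate a cohort from the two-file CSV layout.

    Observations at or below the assay LOQ (0.2 mg/L) are flagged; downstream
    fitting excludes them by default.  A parse report (course/dose/observation
    counts and the number of flagged samples) is logged.
    """
    courses = pd.read_csv(courses_path, dtype={"course_id": str})
    events = pd.read_csv(events_path, dtype={"course_id": str})
    _require_columns(courses, COURSE_COLUMNS, courses_path)
    _require_columns(events, EVENT_COLUMNS, events_path)

    known_ids = set(courses["course_id"])
    unknown = set(events["course_id"]) - known_ids
    if unknown:
        raise ValueError(
            f"{events_path}: events reference unknown course(s): {sorted(unknown)}")

    records: list[CourseRecord] = []
    n_doses = n_obs = n_flagged = 0
    for _, crow in courses.iterrows():
        cid = crow["course_id"]
        ev = events[events["course_id"] == cid]
        creat: list[tuple[float, float]] = []
        doses: list[DoseEvent] = []
        obs: list[Observation] = []
        for idx, erow in ev.iterrows():
            etype = erow["event_type"]
            t = float(erow["time_h"])
            if etype == "creatinine":
                creat.append((t, float(erow["scr_umol_per_l"])))
            elif etype == "dose":
                infusion = float(erow["infusion_h"])
                if not infusion > 0:
                    raise ValueError(
                        f"{events_path} row {idx + 2}: dose with infusion_h "
                        f"{erow['infusion_h']!r} (must be > 0)")
                doses.append(DoseEvent(start_time_h=t,
                                       amount_mg=float(erow["amount_mg"]),
                                       infusion_h=infusion))
            elif etype == "obs":
                c = float(erow["conc_mg_per_l"])
                flagged = c <= LOQ_MG_PER_L
                n_flagged += flagged
                obs.append(Observation(time_h=t, conc_mg_per_l=max(c, LOQ_MG_PER_L),
                                       below_loq=flagged))
            else:
                raise ValueError(
                    f"{events_path} row {idx + 2}: unknown event_type {etype!r}")
        if obs and not doses:
            raise ValueError(f"course {cid!r} has observations but no dose event")
        if not doses:
            raise ValueError(f"course {cid!r} has no dose events (>=1 required)")
        cov = PatientCovariates(
            age_y=float(crow["age_y"]), sex=str(crow["sex"]),
            weight_kg=float(crow["weight_kg"]), height_cm=float(crow["height_cm"]),
            creatinine_series=tuple(sorted(creat)),
        )
        records.append(CourseRecord(course_id=cid, covariates=cov,
                                    doses=tuple(doses), observations=tuple(obs)))
        n_doses += len(doses)
        n_obs += len(obs)
    logger.info("read %d courses, %d doses, %d observations (%d at/below LOQ)",
                len(records), n_doses, n_obs, n_flagged)
    return records


# ---------------------------------------------------------------------------
# Model presets and reports
# ---------------------------------------------------------------------------


def load_model(path) -> PopulationModel:
    return PopulationModel.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


def save_model(model: PopulationModel, path) -> None:
    Path(path).write_text(json.dumps(model.to_dict(), indent=2) + "\n",
                          encoding="utf-8")


def fit_report(fit: PopulationFit) -> dict:
    """JSON-serialisable report of a converged population fit."""
    return {
        "model": fit.model.to_dict(),
        "aic": fit.aic,
        "sum_wss_over_df": fit.sum_wss_over_df,
        "df": fit.df,
        "iterations_run": fit.iterations_run,
        "converged": fit.converged,
        "iteration_trace": list(fit.trace),
        "courses": [
            {
                "course_id": f.course_id,
                "theta": f.estimate.theta,
                "cl_l_per_h": f.estimate.cl_l_per_h,
                "v_l": f.estimate.v_l,
                "wss_concentrations": f.wss_concentrations,
                "wss_parameters": f.wss_parameters,
                "n_observations_used": f.n_observations_used,
                "log_posterior_sd": f.estimate.log_posterior_sd,
            }
            for f in fit.fits
        ],
    }


def validation_report(summary: ValidationSummary) -> dict:
    return {
        "mdpe_percent": summary.mdpe,
        "mdape_percent": summary.mdape,
        "ci_mdpe_percent": list(summary.ci_mdpe),
        "ci_mdape_percent": list(summary.ci_mdape),
        "n_samples": summary.n_samples,
        "n_courses": summary.n_courses,
        "n_courses_excluded": summary.n_courses_excluded,
        "pe_percent": list(summary.pe_list),
    }


def write_prediction_pairs(pairs: Sequence[PredictionPair], path,
                           assay_coeffs=None) -> None:
    """CSV of observed/predicted pairs plus weighted residuals.

    Provides the data behind the two standard diagnostic plots: observed vs
    predicted, and weighted residuals ((obs - pred)/assay SD at the observed
    concentration) vs observed.
    """
    from .pkmodel import DEFAULT_ASSAY_COEFFS, assay_sd
    coeffs = assay_coeffs or DEFAULT_ASSAY_COEFFS
    lines = ["course_id,time_h,c_observed_mg_per_l,c_predicted_mg_per_l,"
             "weighted_residual,mode"]
    for p in pairs:
        wres = (p.c_observed - p.c_predicted) / float(assay_sd(p.c_observed, coeffs))
        lines.append(",".join([p.course_id, _fmt(p.time_h), _fmt(p.c_observed),
                               _fmt(p.c_predicted), _fmt(wres), p.mode]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
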