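"""Structural one-compartment infusion model, covariate submodels and assay error.

Gentamicin disposition is described by a one-compartment model with
first-order elimination, parameterised by three covariate-scaled population
parameters:

* ``clm`` — metabolic (non-renal) clearance, L/h per 70 kg total body weight;
* ``fr``  — renal clearance expressed as a fraction of the Cockcroft–Gault
  creatinine clearance (dimensionless);
* ``vd``  — volume of distribution, L per kg of fat-corrected lean body
  mass (LBMc).

Individual clearance and volume follow::

    CL = clm * (BW / 70) + fr * CLcr        [L/h]
    V  = vd * LBMc                          [L]

Inter-individual variability of each parameter is log-normal; population
priors are stated as arithmetic mean and SD and converted internally with the
exact log-normal moment relations.  The residual (assay) error is a
concentration-dependent polynomial SD.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "LOQ_MG_PER_L",
    "DEFAULT_ASSAY_COEFFS",
    "PatientCovariates",
    "DoseEvent",
    "Observation",
    "CourseRecord",
    "ParamSpec",
    "PopulationModel",
    "IndividualEstimate",
    "IncompleteRecordError",
    "creatinine_clearance",
    "lean_body_mass",
    "lean_body_mass_corrected",
    "body_surface_area",
    "individual_parameters",
    "concentration",
    "assay_sd",
    "load_preset",
]

# Lower limit of quantification of the EMIT gentamicin assay, mg/L.
LOQ_MG_PER_L = 0.2

# Assay-error polynomial SD(C) = a0 + a1*C + a2*C^2 (EMIT).
DEFAULT_ASSAY_COEFFS = (0.0766, 0.0006, 0.0064)

# Cockcroft-Gault sex factors for the SI-unit form (Scr in umol/L).
_CG_SEX_FACTOR = {"male": 1.23, "female": 1.04}

Sex = Literal["male", "female"]
Setting = Literal["Bayesian", "FPB", "Fixed"]


class IncompleteRecordError(ValueError):
    """A course record lacks data required for the requested computation."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PatientCovariates:
    """Demographics and the serum-creatinine history of one treatment course.

    ``creatinine_series`` is an ordered list of ``(time_h, scr_umol_per_l)``
    pairs; the value in force at any time is the last observation carried
    forward.
    """

    age_y: float
    sex: Sex
    weight_kg: float
    height_cm: float
    creatinine_series: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if self.age_y < 18:
            raise ValueError(f"age must be >= 18 y (adult cohort), got {self.age_y}")
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.weight_kg <= 0 or self.height_cm <= 0:
            raise ValueError("weight and height must be positive")
        series = tuple((float(t), float(s)) for t, s in self.creatinine_series)
        if not series:
            raise ValueError("creatinine series must contain at least one entry")
        times = [t for t, _ in series]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("creatinine times must be strictly increasing")
        if any(s <= 0 for _, s in series):
            raise ValueError("creatinine values must be positive")
        object.__setattr__(self, "creatinine_series", series)

    def creatinine_at(self, at_time: float) -> float:
        """Serum creatinine (umol/L) in force at ``at_time`` (LOCF)."""
        value = None
        for t, s in self.creatinine_series:
            if t <= at_time:
                value = s
            else:
                break
        if value is None:
            raise IncompleteRecordError(
                f"no creatinine value at or before t={at_time} h "
                f"(first entry at t={self.creatinine_series[0][0]} h)"
            )
        return value


@dataclass(frozen=True)
class DoseEvent:
    """One intravenous infusion: ``amount_mg`` given over ``infusion_h``."""

    start_time_h: float
    amount_mg: float
    infusion_h: float

    def __post_init__(self) -> None:
        if self.amount_mg <= 0:
            raise ValueError("dose amount must be positive")
        if self.infusion_h <= 0:
            raise ValueError("infusion duration must be positive")
        if self.start_time_h < 0:
            raise ValueError("dose start time must be >= 0")

    @property
    def rate_mg_per_h(self) -> float:
        return self.amount_mg / self.infusion_h


@dataclass(frozen=True)
class Observation:
    """A timed serum gentamicin concentration.

    ``below_loq`` marks samples at or below the assay's lower limit of
    quantification; by default such samples are excluded from fitting.
    """

    time_h: float
    conc_mg_per_l: float
    below_loq: bool = False

    def __post_init__(self) -> None:
        if self.time_h < 0:
            raise ValueError("observation time must be >= 0")
        if self.conc_mg_per_l < LOQ_MG_PER_L and not self.below_loq:
            raise ValueError(
                f"concentration {self.conc_mg_per_l} mg/L is below the LOQ "
                f"({LOQ_MG_PER_L} mg/L) and must be flagged below_loq"
            )
        if self.conc_mg_per_l < 0:
            raise ValueError("concentration must be >= 0")


@dataclass(frozen=True)
class CourseRecord:
    """One treatment episode: covariates, dose events and observations.

    A patient with separate treatment episodes contributes separate courses.
    """

    course_id: str
    covariates: PatientCovariates
    doses: tuple[DoseEvent, ...]
    observations: tuple[Observation, ...] = ()

    def __post_init__(self) -> None:
        doses = tuple(sorted(self.doses, key=lambda d: d.start_time_h))
        if not doses:
            raise ValueError(f"course {self.course_id!r} has no dose events")
        obs = tuple(sorted(self.observations, key=lambda o: o.time_h))
        object.__setattr__(self, "doses", doses)
        object.__setattr__(self, "observations", obs)

    def usable_observations(self, loq_policy: str = "exclude") -> tuple[Observation, ...]:
        """Observations entering a fit.

        ``loq_policy='exclude'`` drops below-LOQ samples; ``'half_loq'``
        retains them at LOQ/2.
        """
        if loq_policy == "exclude":
            return tuple(o for o in self.observations if not o.below_loq)
        if loq_policy == "half_loq":
            return tuple(
                replace(o, conc_mg_per_l=LOQ_MG_PER_L / 2) if o.below_loq else o
                for o in self.observations
            )
        raise ValueError(f"unknown loq_policy {loq_policy!r}")


@dataclass(frozen=True)
class ParamSpec:
    """Population prior for one PK parameter (arithmetic mean and SD).

    ``setting`` carries the estimation semantics: ``Bayesian`` parameters are
    estimated per individual and their population mean/SD are updated during
    population fitting; ``FPB`` (fixed population Bayesian) parameters are
    estimated per individual against a prior whose population values never
    move; ``Fixed`` parameters are held at the population value everywhere
    (SD treated as 0).
    """

    name: Literal["clm", "fr", "vd"]
    mean: float
    sd: float
    setting: Setting = "Bayesian"

    def __post_init__(self) -> None:
        if self.mean <= 0:
            raise ValueError(f"{self.name}: population mean must be positive")
        if self.sd < 0:
            raise ValueError(f"{self.name}: population SD must be >= 0")
        if self.setting not in ("Bayesian", "FPB", "Fixed"):
            raise ValueError(f"{self.name}: unknown setting {self.setting!r}")

    # -- log-normal moment conversions ------------------------------------
    @property
    def effective_sd(self) -> float:
        """SD used in estimation: 0 for Fixed parameters."""
        return 0.0 if self.setting == "Fixed" else self.sd

    @property
    def omega2(self) -> float:
        """Between-subject variance on the log scale."""
        sd = self.effective_sd
        return math.log1p((sd / self.mean) ** 2)

    @property
    def omega(self) -> float:
        return math.sqrt(self.omega2)

    @property
    def log_mu(self) -> float:
        """Mean of log(parameter): log of the log-normal median."""
        return math.log(self.mean) - self.omega2 / 2

    @property
    def median(self) -> float:
        return math.exp(self.log_mu)

    @staticmethod
    def from_log_moments(name: str, log_mu: float, omega2: float, setting: Setting) -> "ParamSpec":
        """Build a spec from log-scale moments (inverse of the conversion)."""
        mean = math.exp(log_mu + omega2 / 2)
        sd = mean * math.sqrt(math.expm1(omega2))
        return ParamSpec(name=name, mean=mean, sd=sd, setting=setting)  # type: ignore[arg-type]


@dataclass(frozen=True)
class PopulationModel:
    """Population priors for (clm, fr, vd) plus the assay-error polynomial."""

    clm: ParamSpec
    fr: ParamSpec
    vd: ParamSpec
    assay_error_coeffs: tuple[float, float, float] = DEFAULT_ASSAY_COEFFS
    name: str = ""

    def __post_init__(self) -> None:
        for attr in ("clm", "fr", "vd"):
            spec = getattr(self, attr)
            if spec.name != attr:
                raise ValueError(f"ParamSpec in slot {attr!r} is named {spec.name!r}")

    @property
    def params(self) -> tuple[ParamSpec, ParamSpec, ParamSpec]:
        return (self.clm, self.fr, self.vd)

    def param(self, name: str) -> ParamSpec:
        return {"clm": self.clm, "fr": self.fr, "vd": self.vd}[name]

    def with_settings(self, clm: Setting | None = None, fr: Setting | None = None,
                      vd: Setting | None = None) -> "PopulationModel":
        """Copy of the model with estimation settings overridden."""
        out = self
        if clm is not None:
            out = replace(out, clm=replace(out.clm, setting=clm))
        if fr is not None:
            out = replace(out, fr=replace(out.fr, setting=fr))
        if vd is not None:
            out = replace(out, vd=replace(out.vd, setting=vd))
        return out

    def medians(self) -> dict[str, float]:
        return {p.name: p.median for p in self.params}

    # -- JSON round trip ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "parameters": {
                p.name: {"mean": p.mean, "sd": p.sd, "setting": p.setting}
                for p in self.params
            },
            "assay_error_coeffs": list(self.assay_error_coeffs),
        }

    @staticmethod
    def from_dict(d: dict) -> "PopulationModel":
        specs = {
            name: ParamSpec(name=name, **vals)  # type: ignore[arg-type]
            for name, vals in d["parameters"].items()
        }
        return PopulationModel(
            clm=specs["clm"], fr=specs["fr"], vd=specs["vd"],
            assay_error_coeffs=tuple(d.get("assay_error_coeffs", DEFAULT_ASSAY_COEFFS)),
            name=d.get("name", ""),
        )


def load_preset(name: str) -> PopulationModel:
    """Load a shipped population-model preset: 'icu', 'standard' or 'endocarditis'."""
    ref = resources.files("gentapk").joinpath(f"presets/{name}.json")
    try:
        text = ref.read_text(encoding="utf-8")
    except FileNotFoundError:
        raise ValueError(f"unknown preset {name!r}; shipped: icu, standard, endocarditis")
    return PopulationModel.from_dict(json.loads(text))


@dataclass(frozen=True)
class IndividualEstimate:
    """MAP (or true) parameter values of one course with derived CL, V, k.

    ``log_posterior_sd`` holds the curvature-based posterior SD of each
    parameter on the log scale (0 for parameters held fixed).
    """

    clm_i: float
    fr_i: float
    vd_i: float
    cl_l_per_h: float
    v_l: float
    log_posterior_sd: dict[str, float] = field(default_factory=dict)

    @property
    def k_per_h(self) -> float:
        return self.cl_l_per_h / self.v_l

    @property
    def half_life_h(self) -> float:
        k = self.k_per_h
        return math.log(2) / k if k > 0 else math.inf

    @property
    def theta(self) -> dict[str, float]:
        return {"clm": self.clm_i, "fr": self.fr_i, "vd": self.vd_i}


# ---------------------------------------------------------------------------
# Covariate submodels
# ---------------------------------------------------------------------------


def body_surface_area(weight_kg: float, height_cm: float) -> float:
    """Du Bois body surface area in m^2."""
    return 0.007184 * weight_kg**0.425 * height_cm**0.725


def lean_body_mass(cov: PatientCovariates) -> float:
    """Lean body mass (kg) by the sex-specific quadratic formula.

    male:   LBM = 1.10 W - 128 (W/H)^2
    female: LBM = 1.07 W - 148 (W/H)^2      (W in kg, H in cm)
    """
    w, h = cov.weight_kg, cov.height_cm
    if cov.sex == "male":
        lbm = 1.10 * w - 128.0 * (w / h) ** 2
    else:
        lbm = 1.07 * w - 148.0 * (w / h) ** 2
    if lbm <= 0:
        raise ValueError(
            f"computed lean body mass {lbm:.2f} kg <= 0 for weight {w} kg, "
            f"height {h} cm: implausible anthropometrics"
        )
    return lbm


def lean_body_mass_corrected(cov: PatientCovariates, f_fat: float = 0.4) -> float:
    """Lean body mass corrected for fat distribution (LBMc, kg).

    LBMc = LBM + f_fat * (W - LBM) when W > LBM, else W.  The correction adds
    back a fraction ``f_fat`` of the fat mass, reflecting aminoglycoside
    distribution into a share of adipose extracellular water.
    """
    lbm = lean_body_mass(cov)
    w = cov.weight_kg
    if w <= lbm:
        return w
    return lbm + f_fat * (w - lbm)


def creatinine_clearance(
    cov: PatientCovariates,
    at_time: float = 0.0,
    normalize_bsa: bool = False,
    weight_metric: str = "bw",
    f_fat: float = 0.4,
) -> float:
    """Cockcroft–Gault creatinine clearance, ml/min (or ml/min/1.73 m^2).

    SI-unit form with sex factor F (male 1.23, female 1.04)::

        CLcr = F * (140 - age) * W / Scr     [Scr in umol/L]

    ``weight_metric`` selects the weight entering the formula: total body
    weight (``'bw'``, default), lean body mass (``'lbm'``) or fat-corrected
    lean body mass (``'lbmc'``).  The serum creatinine in force at ``at_time``
    is used (last observation carried forward).  Ages >= 140 y clamp the
    result to 0 with a warning.
    """
    if at_time < 0:
        raise ValueError("at_time must be >= 0")
    scr = cov.creatinine_at(at_time)
    if cov.age_y >= 140:
        warnings.warn("age >= 140 y: Cockcroft-Gault clamped to 0", stacklevel=2)
        return 0.0
    if weight_metric == "bw":
        w = cov.weight_kg
    elif weight_metric == "lbm":
        w = lean_body_mass(cov)
    elif weight_metric == "lbmc":
        w = lean_body_mass_corrected(cov, f_fat=f_fat)
    else:
        raise ValueError(f"unknown weight_metric {weight_metric!r}")
    clcr = _CG_SEX_FACTOR[cov.sex] * (140.0 - cov.age_y) * w / scr
    if normalize_bsa:
        clcr *= 1.73 / body_surface_area(cov.weight_kg, cov.height_cm)
    return clcr


def individual_parameters(
    theta: Sequence[float] | dict[str, float],
    cov: PatientCovariates,
    at_time: float = 0.0,
    f_fat: float = 0.4,
    weight_metric: str = "bw",
    log_posterior_sd: dict[str, float] | None = None,
) -> IndividualEstimate:
    """Map (clm, fr, vd) through the covariate model to CL (L/h) and V (L).

    CL = clm*(BW/70) + fr*CLcr with CLcr un-normalised and converted
    ml/min -> L/h; V = vd*LBMc.  ``theta`` components must be positive
    (clm/fr may be 0, giving a degenerate CL = 0 flagged by an infinite
    half-life).
    """
    if isinstance(theta, dict):
        clm, fr, vd = theta["clm"], theta["fr"], theta["vd"]
    else:
        clm, fr, vd = theta
    if clm < 0 or fr < 0 or vd <= 0:
        raise ValueError("clm and fr must be >= 0 and vd > 0")
    clcr_l_per_h = creatinine_clearance(cov, at_time, weight_metric=weight_metric,
                                        f_fat=f_fat) * 60.0 / 1000.0
    cl = clm * (cov.weight_kg / 70.0) + fr * clcr_l_per_h
    v = vd * lean_body_mass_corrected(cov, f_fat=f_fat)
    return IndividualEstimate(
        clm_i=clm, fr_i=fr, vd_i=vd, cl_l_per_h=cl, v_l=v,
        log_posterior_sd=dict(log_posterior_sd or {}),
    )


# ---------------------------------------------------------------------------
# Structural model
# ---------------------------------------------------------------------------


def concentration(
    cl: float | np.ndarray,
    v: float | np.ndarray,
    doses: Sequence[DoseEvent],
    t: float | np.ndarray,
) -> np.ndarray | float:
    """Serum concentration (mg/L) of a one-compartment infusion model.

    Exact closed-form superposition over dose events.  For a dose with rate
    R over [t0, t0+T] and k = CL/V::

        during:  C += (R/CL) * (1 - exp(-k (t-t0)))
        after:   C += (R/CL) * (1 - exp(-k T)) * exp(-k (t-t0-T))

    ``cl``, ``v`` and ``t`` broadcast against each other, so population
    draws and time grids evaluate in one vectorised call.  Times before all
    doses give 0.
    """
    cl_arr = np.asarray(cl, dtype=float)
    v_arr = np.asarray(v, dtype=float)
    if np.any(cl_arr <= 0) or np.any(v_arr <= 0):
        raise ValueError("CL and V must be positive (k = CL/V > 0)")
    t_arr = np.asarray(t, dtype=float)
    k = cl_arr / v_arr
    out = np.zeros(np.broadcast_shapes(cl_arr.shape, v_arr.shape, t_arr.shape))
    for dose in doses:
        dt = t_arr - dose.start_time_h
        r_over_cl = dose.rate_mg_per_h / cl_arr
        during = (dt > 0) & (dt <= dose.infusion_h)
        after = dt > dose.infusion_h
        # np.where evaluates both branches; clip dt to keep exponents tame
        dt_pos = np.maximum(dt, 0.0)
        c_during = r_over_cl * (-np.expm1(-k * dt_pos))
        c_after = (
            r_over_cl * (-np.expm1(-k * dose.infusion_h))
            * np.exp(-k * np.maximum(dt_pos - dose.infusion_h, 0.0))
        )
        out = out + np.where(during, c_during, 0.0) + np.where(after, c_after, 0.0)
    if out.ndim == 0:
        return float(out)
    return out


def concentration_profile(
    est: IndividualEstimate, doses: Sequence[DoseEvent], t: float | np.ndarray
) -> np.ndarray | float:
    """Concentration at ``t`` for an individual estimate (convenience wrapper)."""
    return concentration(est.cl_l_per_h, est.v_l, doses, t)


def assay_sd(
    c: float | np.ndarray,
    coeffs: tuple[float, float, float] = DEFAULT_ASSAY_COEFFS,
) -> np.ndarray | float:
    """Assay-error SD (mg/L) at concentration ``c``: a0 + a1*c + a2*c^2."""
    c_arr = np.asarray(c, dtype=float)
    if np.any(c_arr < 0):
        raise ValueError("concentration must be >= 0")
    a0, a1, a2 = coeffs
    out = a0 + a1 * c_arr + a2 * c_arr**2
    if out.ndim == 0:
        return float(out)
    return out
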