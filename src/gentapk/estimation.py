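"""MAP Bayesian individual fitting and iterative two-stage Bayesian (ITSB)
population fitting.

Individual (MAP) stage
    For one course the objective is the penalised weighted sum of squares

        O(theta) = sum_j (Cpred(theta, t_j) - Cobs_j)^2 / SD(Cobs_j)^2
                 + sum_p (ln theta_p - ln mu_p)^2 / omega_p^2

    where SD(.) is the concentration-dependent assay error and the prior
    penalty runs over the parameters with setting Bayesian or FPB (log-normal
    priors; Fixed parameters are held at their population value).  The
    optimum, the two WSS components and curvature-based posterior SDs on the
    log scale are returned.

Population (ITSB) stage
    Alternates MAP fits of every course against the current population
    parameters with a log-scale update of each Bayesian parameter's
    population mean and SD from the individual estimates, until the
    population values are fixed (relative change below tolerance).  The
    between-subject log-variance update adds the mean individual posterior
    log-variance (shrinkage correction); a naive mode using the sample
    variance of the point estimates alone is available for comparison.

Goodness of fit is summarised by AIC and the summed WSS divided by the
degrees of freedom (total measurements minus estimated population and
individual parameters).  Absolute AIC values are implementation-defined
(they include the Gaussian normalising constants spelled out below); only
differences between candidate settings on the same data are meaningful.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .pkmodel import (
    CourseRecord,
    IndividualEstimate,
    ParamSpec,
    PopulationModel,
    assay_sd,
    concentration,
    individual_parameters,
)

__all__ = [
    "FitSettings",
    "IndividualFit",
    "PopulationFit",
    "FitError",
    "map_fit",
    "itsb_fit",
    "goodness_of_fit",
    "bootstrap_population",
]

# Free parameters with prior log-SD below this are held at the prior median:
# the infinite-weight penalty limit, which makes FPB with SD -> 0 coincide
# with Fixed.
_OMEGA_FLOOR = 1e-8

_LN_2PI = math.log(2 * math.pi)


class FitError(RuntimeError):
    """Optimisation failed; ``best`` carries the best fit found so far."""

    def __init__(self, message: str, best=None, trace=None):
        super().__init__(message)
        self.best = best
        self.trace = trace


@dataclass(frozen=True)
class FitSettings:
    """Knobs of the MAP and ITSB fitters.

    ``relative_tolerance`` applies to the population means and SDs between
    ITSB cycles (SD changes are measured relative to the mean so that SDs
    collapsing to zero still converge).  ``residual_sd_reference`` selects
    the concentration at which the assay SD weighting the residual is
    evaluated (observed by default).
    """

    max_iterations: int = 200
    relative_tolerance: float = 1e-4
    map_tolerance: float = 1e-12
    bootstrap_reps: int = 1000
    rng_seed: int = 0
    loq_policy: str = "exclude"
    residual_sd_reference: str = "observed"
    shrinkage: bool = True
    f_fat: float = 0.4
    weight_metric: str = "bw"

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.relative_tolerance <= 0 or self.map_tolerance <= 0:
            raise ValueError("tolerances must be positive")
        if self.residual_sd_reference not in ("observed", "predicted"):
            raise ValueError("residual_sd_reference must be 'observed' or 'predicted'")


@dataclass(frozen=True)
class IndividualFit:
    """MAP fit of one course: estimate plus the two WSS components.

    ``ln_normalisation`` is the sum of the Gaussian log-normalising constants
    ln(2*pi*SD_j^2) over observations plus ln(2*pi*omega_p^2) over estimated
    parameters; added to the WSS it gives the joint -2 log posterior, the
    quantity the ITSB cycle descends.  ``m2ll`` is the Laplace-approximate
    marginal -2 log likelihood of the course (individual parameters
    integrated out), the quantity the AIC is built on: a random effect whose
    variance collapses to zero contributes nothing to it, so adding
    population parameters is never rewarded for free.
    """

    course_id: str
    estimate: IndividualEstimate
    wss_concentrations: float
    wss_parameters: float
    n_observations_used: int
    n_params_estimated: int
    ln_normalisation: float
    m2ll: float
    free_names: tuple[str, ...]
    log_posterior_cov: np.ndarray | None = None  # over free_names, log scale


@dataclass(frozen=True)
class PopulationFit:
    """Converged ITSB result: posterior model, per-course fits and fit metrics."""

    model: PopulationModel
    fits: tuple[IndividualFit, ...]
    aic: float
    sum_wss_over_df: float
    df: int
    iterations_run: int
    converged: bool
    trace: tuple[dict, ...] = field(default_factory=tuple)

    @property
    def sum_wss(self) -> float:
        return sum(f.wss_concentrations + f.wss_parameters for f in self.fits)


# ---------------------------------------------------------------------------
# MAP individual fit
# ---------------------------------------------------------------------------


def _prior_median_estimate(model: PopulationModel, record: CourseRecord,
                           settings: FitSettings,
                           free: Sequence[ParamSpec]) -> IndividualEstimate:
    theta = {p.name: p.median for p in model.params}
    return individual_parameters(
        theta, record.covariates, at_time=record.doses[0].start_time_h,
        f_fat=settings.f_fat, weight_metric=settings.weight_metric,
        log_posterior_sd={p.name: p.omega for p in free},
    )


def map_fit(record: CourseRecord, model: PopulationModel,
            settings: FitSettings | None = None) -> IndividualFit:
    """MAP Bayesian fit of one course against population priors.

    Parameters with setting Bayesian or FPB are estimated on the log scale
    (positivity by construction); Fixed parameters (and free parameters whose
    prior SD is numerically zero) are held at the prior median.  With zero
    usable observations the prior medians are returned with zero WSS.
    Optimisation retries from 5 jittered starts before raising
    :class:`FitError` with the best fit so far attached.
    """
    settings = settings or FitSettings()
    obs = record.usable_observations(settings.loq_policy)
    free = [p for p in model.params
            if p.setting in ("Bayesian", "FPB") and p.omega > _OMEGA_FLOOR]
    free_names = tuple(p.name for p in free)
    anchor = record.doses[0].start_time_h
    ln_norm_priors = sum(math.log(2 * math.pi * p.omega2) for p in free)

    if not obs or not free:
        est = _prior_median_estimate(model, record, settings, free)
        wss_c = 0.0
        if obs and not free:
            pred = concentration(est.cl_l_per_h, est.v_l, record.doses,
                                 np.array([o.time_h for o in obs]))
            sd = _residual_sd(np.array([o.conc_mg_per_l for o in obs]), pred,
                              model, settings)
            wss_c = float(np.sum(((pred - np.array([o.conc_mg_per_l for o in obs])) / sd) ** 2))
        ln_norm = ln_norm_priors
        ln_obs_norm = 0.0
        if obs:
            c_obs = np.array([o.conc_mg_per_l for o in obs])
            sd = _residual_sd(c_obs, c_obs, model, settings)
            ln_obs_norm = float(np.sum(np.log(2 * np.pi * sd**2)))
            ln_norm += ln_obs_norm
        cov = np.diag([p.omega2 for p in free]) if free else None
        # no free parameters (or no data): the Laplace correction cancels the
        # prior normalisation exactly, leaving the data terms
        m2ll = wss_c + ln_obs_norm
        return IndividualFit(
            course_id=record.course_id, estimate=est,
            wss_concentrations=wss_c, wss_parameters=0.0,
            n_observations_used=len(obs), n_params_estimated=len(free),
            ln_normalisation=ln_norm, m2ll=m2ll, free_names=free_names,
            log_posterior_cov=cov,
        )

    t_obs = np.array([o.time_h for o in obs])
    c_obs = np.array([o.conc_mg_per_l for o in obs])
    log_mu = np.array([p.log_mu for p in free])
    omega = np.array([p.omega for p in free])
    held = {p.name: p.median for p in model.params if p.name not in free_names}

    cov_patient = record.covariates
    bw = cov_patient.weight_kg

    # CLcr (L/h) and LBMc are covariate constants of the course
    from .pkmodel import creatinine_clearance, lean_body_mass_corrected
    clcr_lh = creatinine_clearance(cov_patient, anchor,
                                   weight_metric=settings.weight_metric,
                                   f_fat=settings.f_fat) * 0.06
    lbmc = lean_body_mass_corrected(cov_patient, f_fat=settings.f_fat)

    def theta_of(x: np.ndarray) -> dict[str, float]:
        th = dict(held)
        th.update({n: math.exp(v) for n, v in zip(free_names, x)})
        return th

    def residuals(x: np.ndarray) -> np.ndarray:
        th = theta_of(x)
        cl = th["clm"] * (bw / 70.0) + th["fr"] * clcr_lh
        v = th["vd"] * lbmc
        pred = np.asarray(concentration(cl, v, record.doses, t_obs))
        sd = _residual_sd(c_obs, pred, model, settings)
        r_conc = (pred - c_obs) / sd
        r_prior = (x - log_mu) / omega
        return np.concatenate([np.atleast_1d(r_conc), r_prior])

    # prior-median start, then up to 5 jittered restarts on non-convergence;
    # jitter stream keyed to the course id so results are cohort-order invariant
    tol = settings.map_tolerance
    best = None
    converged_res = None
    rng = np.random.default_rng(zlib.crc32(record.course_id.encode()) & 0x7FFFFFFF)
    for attempt in range(6):
        x0 = log_mu if attempt == 0 else log_mu + rng.normal(0.0, 0.5, len(free))
        res = least_squares(residuals, x0, method="lm", xtol=tol, ftol=tol, gtol=tol)
        if best is None or res.cost < best.cost:
            best = res
        if res.status > 0:
            converged_res = res
            break
    if converged_res is None:
        raise FitError(f"MAP fit did not converge for course {record.course_id!r} "
                       "after 5 jittered restarts", best=best)
    res = converged_res

    x_hat = res.x
    th = theta_of(x_hat)
    r = residuals(x_hat)
    n_obs = len(obs)
    wss_c = float(np.sum(r[:n_obs] ** 2))
    wss_p = float(np.sum(r[n_obs:] ** 2))

    # Laplace approximation: O(theta) = sum r^2 is -2 log posterior + const,
    # so cov_log = (J^T J)^{-1} under the Gauss-Newton curvature.
    jtj = res.jac.T @ res.jac
    try:
        cov_log = np.linalg.inv(jtj)
    except np.linalg.LinAlgError:
        cov_log = np.linalg.pinv(jtj)
    post_sd = {n: float(math.sqrt(max(cov_log[i, i], 0.0)))
               for i, n in enumerate(free_names)}

    est = individual_parameters(
        th, cov_patient, at_time=anchor, f_fat=settings.f_fat,
        weight_metric=settings.weight_metric, log_posterior_sd=post_sd,
    )
    pred = np.asarray(concentration(est.cl_l_per_h, est.v_l, record.doses, t_obs))
    sd = _residual_sd(c_obs, pred, model, settings)
    ln_norm = float(np.sum(np.log(2 * np.pi * sd**2))) + ln_norm_priors
    # Laplace approximation of the marginal -2 log likelihood:
    #   m2ll = O(theta_hat) + ln_norm - d ln(2 pi) - ln det(cov_log)
    # (for an uninformative direction the prior normalisation and the
    # posterior determinant cancel, so the course contributes as if the
    # parameter were fixed)
    sign, logdet = np.linalg.slogdet(cov_log)
    if sign <= 0:
        logdet = float(np.sum(np.log(np.maximum(np.diag(cov_log), 1e-300))))
    m2ll = (wss_c + wss_p + ln_norm - len(free) * _LN_2PI - logdet)
    return IndividualFit(
        course_id=record.course_id, estimate=est,
        wss_concentrations=wss_c, wss_parameters=wss_p,
        n_observations_used=n_obs, n_params_estimated=len(free),
        ln_normalisation=ln_norm, m2ll=m2ll, free_names=free_names,
        log_posterior_cov=cov_log,
    )


def _residual_sd(c_obs: np.ndarray, c_pred: np.ndarray, model: PopulationModel,
                 settings: FitSettings) -> np.ndarray:
    ref = c_obs if settings.residual_sd_reference == "observed" else np.maximum(c_pred, 0.0)
    return np.asarray(assay_sd(ref, model.assay_error_coeffs))


# ---------------------------------------------------------------------------
# ITSB population fit
# ---------------------------------------------------------------------------


def _stage2_update(model: PopulationModel, fits: Sequence[IndividualFit],
                   bayes_names: Sequence[str], shrinkage: bool) -> PopulationModel:
    out = model
    for name in bayes_names:
        lnth = np.log([f.estimate.theta[name] for f in fits])
        mu = float(lnth.mean())
        omega2 = float(lnth.var())
        if shrinkage:
            omega2 += float(np.mean(
                [f.estimate.log_posterior_sd.get(name, 0.0) ** 2 for f in fits]))
        new = ParamSpec.from_log_moments(name, mu, omega2, "Bayesian")
        out = replace(out, **{name: new})
    return out


def itsb_fit(cohort: Sequence[CourseRecord], init: PopulationModel,
             settings: FitSettings | None = None) -> PopulationFit:
    """Iterative two-stage Bayesian population fit.

    Stage 1 MAP-fits every course against the current population parameters;
    stage 2 re-estimates the population mean and SD of each Bayesian
    parameter from the individual estimates on the log scale.  The cycle
    repeats, using the previous population parameters as priors, until every
    updated mean and SD changes by less than ``relative_tolerance`` (SD
    changes measured relative to the mean) or ``max_iterations`` is reached.
    FPB parameters are estimated per individual but their population values
    never move; Fixed parameters never move at all.
    """
    settings = settings or FitSettings()
    if len(cohort) < 2:
        raise ValueError("ITSB needs at least 2 courses")
    # canonical order: stage-2 reductions are then independent of the order
    # the caller supplies the courses in (bit-identical results)
    cohort = sorted(cohort, key=lambda r: r.course_id)
    bayes_names = [p.name for p in init.params if p.setting == "Bayesian"]
    if not bayes_names:
        raise ValueError("ITSB needs at least one parameter with setting 'Bayesian'")

    model = init
    trace: list[dict] = []
    prev_obj = math.inf
    n_increases = 0
    converged = False
    iterations = 0
    fits: list[IndividualFit] = []

    for iterations in range(1, settings.max_iterations + 1):
        fits = [map_fit(r, model, settings) for r in cohort]
        # The traced objective is the quantity the active stage-2 update
        # descends: the shrinkage (EM-like) update monotonically improves the
        # Laplace marginal -2 log likelihood, the naive update is exact
        # coordinate descent on the joint -2 log posterior.  Raw WSS alone is
        # monotone in neither mode because SD updates re-weight the prior
        # penalty.
        if settings.shrinkage:
            obj = sum(f.m2ll for f in fits)
        else:
            obj = sum(f.wss_concentrations + f.wss_parameters + f.ln_normalisation
                      for f in fits)
        trace.append({
            "iteration": iterations,
            "means": {p.name: p.mean for p in model.params},
            "sds": {p.name: p.sd for p in model.params},
            "objective": obj,
        })
        # Three consecutive substantial increases mean divergence.  The naive
        # update descends this objective exactly; the shrinkage (EM-like)
        # update can raise the approximate marginal by tiny amounts on small
        # cohorts or along unidentifiable-variance ridges, so only increases
        # beyond the slack count.
        slack = 1e-8 if not settings.shrinkage else 1e-3
        if obj > prev_obj + slack * max(1.0, abs(prev_obj)):
            n_increases += 1
            if n_increases >= 3:
                raise FitError(
                    "ITSB objective increased on 3 consecutive iterations "
                    f"(divergence) at iteration {iterations}",
                    trace=tuple(trace),
                )
        else:
            n_increases = 0
        prev_obj = obj

        new_model = _stage2_update(model, fits, bayes_names, settings.shrinkage)
        max_rel = 0.0
        for name in bayes_names:
            old, new = model.param(name), new_model.param(name)
            max_rel = max(max_rel, abs(new.mean - old.mean) / old.mean,
                          abs(new.sd - old.sd) / max(old.mean, 1e-12))
        model = new_model
        if max_rel < settings.relative_tolerance:
            converged = True
            break

    # final stage-1 pass so the individual fits are consistent with the
    # converged population parameters
    fits = [map_fit(r, model, settings) for r in cohort]
    aic, swss_df, df = _goodness(fits, bayes_names)
    return PopulationFit(
        model=model, fits=tuple(fits), aic=aic, sum_wss_over_df=swss_df, df=df,
        iterations_run=iterations, converged=converged, trace=tuple(trace),
    )


# ---------------------------------------------------------------------------
# Goodness of fit
# ---------------------------------------------------------------------------


def _goodness(fits: Sequence[IndividualFit],
              bayes_names: Sequence[str]) -> tuple[float, float, int]:
    n_obs = sum(f.n_observations_used for f in fits)
    n_pop = 2 * len(bayes_names)  # mean and SD of every Bayesian parameter
    n_ind = sum(f.n_params_estimated for f in fits)
    df = n_obs - n_pop - n_ind
    if df <= 0:
        raise ValueError(
            f"degrees of freedom {df} <= 0: {n_obs} observations cannot support "
            f"{n_pop} population + {n_ind} individual parameters")
    swss = sum(f.wss_concentrations + f.wss_parameters for f in fits)
    # -2 log joint posterior density plus 2 per estimated parameter.  Both
    # population parameters (mean and SD of every Bayesian parameter) and
    # per-course individual parameters count as estimated, mirroring the df
    # definition; without the individual-parameter penalty a candidate model
    # could buy fit quality with unidentifiable per-course parameters at no
    # cost.
    aic = sum(f.wss_concentrations + f.wss_parameters + f.ln_normalisation
              for f in fits) + 2 * (n_pop + n_ind)
    return aic, swss / df, df


def goodness_of_fit(fit: PopulationFit) -> tuple[float, float]:
    """(AIC, sum WSS / df) of a converged population fit.

    AIC = [sum over observations of (wres^2 + ln(2 pi SD^2))] + [the
    analogous prior terms over estimated individual parameters] + 2 times
    the number of estimated parameters — population (mean and SD of each
    Bayesian parameter) and individual (one per course per Bayesian/FPB
    parameter), the same count the degrees of freedom use.  Absolute values
    are implementation-defined; compare only across candidate settings
    fitted to the same data.
    """
    bayes_names = [p.name for p in fit.model.params if p.setting == "Bayesian"]
    aic, swss_df, _ = _goodness(fit.fits, bayes_names)
    return aic, swss_df


# ---------------------------------------------------------------------------
# Population bootstrap
# ---------------------------------------------------------------------------


def bootstrap_population(
    cohort: Sequence[CourseRecord],
    init: PopulationModel,
    settings: FitSettings | None = None,
    reps: int = 1000,
    seed: int = 0,
) -> dict:
    """Nonparametric bootstrap of the ITSB population parameters.

    Courses are resampled with replacement; ITSB is re-run per replicate and
    the 2.5/97.5 percentiles of each parameter's population mean and SD are
    returned.  Replicates that fail to fit are dropped and counted; more than
    10% dropped raises.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    settings = settings or FitSettings()
    rng = np.random.default_rng(seed)
    n = len(cohort)
    means: dict[str, list[float]] = {p.name: [] for p in init.params}
    sds: dict[str, list[float]] = {p.name: [] for p in init.params}
    dropped = 0
    for _ in range(reps):
        idx = rng.integers(0, n, n)
        sample = [cohort[i] for i in idx]
        try:
            fit = itsb_fit(sample, init, settings)
        except (FitError, ValueError):
            dropped += 1
            continue
        for p in fit.model.params:
            means[p.name].append(p.mean)
            sds[p.name].append(p.sd)
    if dropped > 0.1 * reps:
        raise FitError(f"{dropped}/{reps} bootstrap replicates failed to converge")
    out = {"n_dropped": dropped, "reps": reps, "parameters": {}}
    for name in means:
        m = np.array(means[name])
        s = np.array(sds[name])
        out["parameters"][name] = {
            "mean_ci": (float(np.percentile(m, 2.5)), float(np.percentile(m, 97.5))),
            "sd_ci": (float(np.percentile(s, 2.5)), float(np.percentile(s, 97.5))),
        }
    return out
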