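"""MAP individual fitting, ITSB population fitting and goodness of fit."""

import dataclasses
import math

import numpy as np
import pytest

from gentapk import (
    DoseEvent,
    FitSettings,
    Observation,
    ParamSpec,
    assay_sd,
    bootstrap_population,
    concentration,
    goodness_of_fit,
    itsb_fit,
    map_fit,
)
from gentapk.pkmodel import creatinine_clearance, lean_body_mass_corrected

from conftest import make_course


def grid_search_oracle(record, model, n=400, stages=3, span_omegas=3.0):
    """Exhaustive log-grid search of the MAP objective for 2 free parameters.

    Evaluates the penalised WSS on an n-by-n log grid, then refines the grid
    around the argmin; independent of the derivative-based optimizer.
    """
    free = [p for p in model.params if p.setting in ("Bayesian", "FPB") and p.sd > 0]
    assert len(free) == 2
    held = {p.name: p.median for p in model.params if p not in free}
    cov = record.covariates
    clcr_lh = creatinine_clearance(cov) * 0.06
    lbmc = lean_body_mass_corrected(cov)
    t = np.array([o.time_h for o in record.observations])
    c_obs = np.array([o.conc_mg_per_l for o in record.observations])
    w = np.asarray(assay_sd(c_obs, model.assay_error_coeffs))

    centers = np.array([p.log_mu for p in free])
    widths = np.array([span_omegas * p.omega for p in free])
    for _ in range(stages):
        ax0 = np.linspace(centers[0] - widths[0], centers[0] + widths[0], n)
        ax1 = np.linspace(centers[1] - widths[1], centers[1] + widths[1], n)
        g0, g1 = np.meshgrid(ax0, ax1, indexing="ij")
        theta = {free[0].name: np.exp(g0).ravel(), free[1].name: np.exp(g1).ravel()}
        theta = {**{k: np.full(n * n, v) for k, v in held.items()}, **theta}
        cl = theta["clm"] * (cov.weight_kg / 70) + theta["fr"] * clcr_lh
        v = theta["vd"] * lbmc
        pred = np.asarray(concentration(cl[:, None], v[:, None], record.doses,
                                        t[None, :]))
        obj = np.sum(((pred - c_obs) / w) ** 2, axis=1)
        obj += ((g0.ravel() - free[0].log_mu) / free[0].omega) ** 2
        obj += ((g1.ravel() - free[1].log_mu) / free[1].omega) ** 2
        i = int(np.argmin(obj))
        centers = np.array([g0.ravel()[i], g1.ravel()[i]])
        step = np.array([ax0[1] - ax0[0], ax1[1] - ax1[0]])
        widths = 2 * step
    return {free[0].name: math.exp(centers[0]), free[1].name: math.exp(centers[1])}


def noise_free_course(cov, theta, model, times, course_id="nf", n_doses=3):
    from gentapk import individual_parameters
    dose = round(3.0 * cov.weight_kg)
    doses = tuple(DoseEvent(24.0 * i, dose, 0.5) for i in range(n_doses))
    est = individual_parameters(theta, cov)
    c = np.atleast_1d(np.asarray(concentration(est.cl_l_per_h, est.v_l, doses,
                                               np.asarray(times))))
    obs = tuple(Observation(float(t), float(ci)) for t, ci in zip(times, c))
    return make_course(cov, course_id, doses=doses, observations=obs)


class TestMapFit:
    def test_zero_observations_returns_prior_medians(self, standard_cov, endo_model):
        rec = make_course(standard_cov, observations=())
        fit = map_fit(rec, endo_model)
        assert fit.wss_parameters == 0.0 and fit.wss_concentrations == 0.0
        assert fit.estimate.theta == pytest.approx(endo_model.medians())

    def test_observation_at_prior_prediction_keeps_medians(self, standard_cov, endo_model):
        from gentapk import individual_parameters
        est = individual_parameters(endo_model.medians(), standard_cov)
        doses = (DoseEvent(0.0, 229.0, 0.5),)
        c = float(concentration(est.cl_l_per_h, est.v_l, doses, 1.0))
        rec = make_course(standard_cov, doses=doses,
                          observations=(Observation(1.0, c),))
        fit = map_fit(rec, endo_model)
        assert fit.wss_concentrations == pytest.approx(0.0, abs=1e-14)
        for name, val in fit.estimate.theta.items():
            assert val == pytest.approx(endo_model.medians()[name], rel=1e-6)

    def test_two_parameter_recovery_matches_grid_oracle(self, standard_cov, endo_model):
        # noise-free data from known (fr, vd), priors inflated 10x
        truth = {"clm": endo_model.clm.mean, "fr": 0.55, "vd": 0.38}
        rec = noise_free_course(standard_cov, truth, endo_model,
                                times=[1.0, 2.5, 4.5, 25.0, 28.5, 47.0])
        wide = dataclasses.replace(
            endo_model,
            fr=dataclasses.replace(endo_model.fr, sd=endo_model.fr.sd * 10),
            vd=dataclasses.replace(endo_model.vd, sd=endo_model.vd.sd * 10))
        fit = map_fit(rec, wide)
        oracle = grid_search_oracle(rec, wide)
        for name in ("fr", "vd"):
            assert fit.estimate.theta[name] == pytest.approx(truth[name], rel=0.01)
            assert fit.estimate.theta[name] == pytest.approx(oracle[name], rel=1e-3)

    def test_fixed_equals_fpb_with_vanishing_sd(self, standard_cov, endo_model, fig2_record):
        fixed = endo_model.with_settings(clm="Fixed")
        fpb_tiny = dataclasses.replace(
            endo_model, clm=ParamSpec(name="clm", mean=0.277, sd=1e-12, setting="FPB"))
        f1 = map_fit(fig2_record, fixed)
        f2 = map_fit(fig2_record, fpb_tiny)
        assert f1.n_params_estimated == f2.n_params_estimated
        for name in ("clm", "fr", "vd"):
            assert f1.estimate.theta[name] == pytest.approx(
                f2.estimate.theta[name], rel=1e-9)

    def test_reproducible_bit_for_bit(self, fig2_record, icu_model):
        a = map_fit(fig2_record, icu_model)
        b = map_fit(fig2_record, icu_model)
        assert a.estimate.theta == b.estimate.theta
        assert a.wss_concentrations == b.wss_concentrations


class TestItsb:
    def test_fixed_point_at_zero_variability(self, standard_cov, endo_model):
        # courses simulated exactly at the init medians, no noise: the naive
        # update leaves the means and collapses the SDs
        truth = endo_model.medians()
        cohort = [noise_free_course(standard_cov, truth, endo_model,
                                    times=[1.0 + 0.1 * i, 4.5, 25.0], course_id=f"c{i}")
                  for i in range(8)]
        fit = itsb_fit(cohort, endo_model,
                       FitSettings(shrinkage=False, relative_tolerance=1e-5))
        for name in ("fr", "vd"):
            assert fit.model.param(name).median == pytest.approx(truth[name], rel=1e-3)
            assert fit.model.param(name).sd < 0.05 * endo_model.param(name).sd

    def test_objective_monotone_non_increasing(self, small_cohort, endo_model):
        cohort, _ = small_cohort
        # naive update: exact coordinate descent on the joint -2 log posterior
        fit = itsb_fit(cohort, endo_model, FitSettings(shrinkage=False))
        objs = [t["objective"] for t in fit.trace]
        for a, b in zip(objs, objs[1:]):
            assert b <= a + 1e-8 * max(1.0, abs(a))
        # shrinkage update: approximate marginal, monotone up to the
        # Laplace-approximation error
        fit = itsb_fit(cohort, endo_model)
        objs = [t["objective"] for t in fit.trace]
        for a, b in zip(objs, objs[1:]):
            assert b <= a + 1e-3 * max(1.0, abs(a))

    def test_cohort_order_invariance(self, small_cohort, endo_model):
        cohort, _ = small_cohort
        f1 = itsb_fit(cohort, endo_model)
        f2 = itsb_fit(list(reversed(cohort)), endo_model)
        assert {p.name: (p.mean, p.sd) for p in f1.model.params} == \
               {p.name: (p.mean, p.sd) for p in f2.model.params}
        assert f1.aic == f2.aic

    def test_init_robustness_icu_vs_standard_priors(self, small_cohort, endo_model):
        # same model structure (CLm fixed at 0.277), fr/vd starting priors
        # taken from the ICU vs the standard model: the converged population
        # values must agree
        from gentapk import load_preset
        cohort, _ = small_cohort
        settings = FitSettings(relative_tolerance=1e-6, max_iterations=300)
        fits = {}
        for name in ("icu", "standard"):
            src = load_preset(name)
            init = dataclasses.replace(
                endo_model,
                fr=dataclasses.replace(endo_model.fr, mean=src.fr.mean, sd=src.fr.sd),
                vd=dataclasses.replace(endo_model.vd, mean=src.vd.mean, sd=src.vd.sd))
            fits[name] = itsb_fit(cohort, init, settings)
        for name in ("fr", "vd"):
            assert fits["icu"].model.param(name).mean == pytest.approx(
                fits["standard"].model.param(name).mean,
                rel=2 * settings.relative_tolerance)

    def test_requires_bayesian_parameter_and_two_courses(self, small_cohort, endo_model):
        cohort, _ = small_cohort
        all_fixed = endo_model.with_settings(clm="Fixed", fr="FPB", vd="FPB")
        with pytest.raises(ValueError):
            itsb_fit(cohort, all_fixed)
        with pytest.raises(ValueError):
            itsb_fit(cohort[:1], endo_model)

    def test_df_definition(self, small_cohort, endo_model):
        cohort, _ = small_cohort
        fit = itsb_fit(cohort, endo_model)
        n_obs = sum(f.n_observations_used for f in fit.fits)
        n_ind = sum(f.n_params_estimated for f in fit.fits)
        assert fit.df == n_obs - 2 * 2 - n_ind  # fr and vd Bayesian: mean+SD each


class TestGoodnessOfFit:
    def test_perfect_fit_gives_zero_wss(self, standard_cov, endo_model):
        truth = endo_model.medians()
        cohort = [noise_free_course(standard_cov, truth, endo_model,
                                    times=[1.0, 4.5, 25.0], course_id=f"c{i}")
                  for i in range(6)]
        fit = itsb_fit(cohort, endo_model, FitSettings(shrinkage=False))
        assert fit.sum_wss == pytest.approx(0.0, abs=1e-6)
        assert fit.sum_wss_over_df == pytest.approx(0.0, abs=1e-8)

    def test_each_population_parameter_costs_two(self, small_cohort, endo_model):
        # same individual fits, one more Bayesian parameter declared (mean and
        # SD are two estimated population parameters -> AIC rises by 4)
        cohort, _ = small_cohort
        fit = itsb_fit(cohort, endo_model)
        widened = dataclasses.replace(
            fit, model=fit.model.with_settings(clm="Bayesian"))
        aic_base, _ = goodness_of_fit(fit)
        aic_more, _ = goodness_of_fit(widened)
        assert aic_more - aic_base == pytest.approx(2 * 2, abs=1e-9)


class TestBootstrapPopulation:
    def test_identical_courses_give_zero_width_ci(self, standard_cov, endo_model):
        rec = noise_free_course(standard_cov, {"clm": 0.277, "fr": 0.6, "vd": 0.35},
                                endo_model, times=[1.0, 4.5, 25.0])
        cohort = [dataclasses.replace(rec, course_id=f"c{i}") for i in range(5)]
        out = bootstrap_population(cohort, endo_model, reps=8, seed=3)
        for name in ("fr", "vd"):
            lo, hi = out["parameters"][name]["mean_ci"]
            assert hi - lo == pytest.approx(0.0, abs=1e-9)

    def test_seed_determinism(self, small_cohort, endo_model):
        cohort, _ = small_cohort
        a = bootstrap_population(cohort, endo_model, reps=5, seed=11)
        b = bootstrap_population(cohort, endo_model, reps=5, seed=11)
        assert a == b
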