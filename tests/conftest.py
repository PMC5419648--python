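import pytest

from gentapk import (
    CohortSpec,
    CourseRecord,
    DoseEvent,
    Observation,
    PatientCovariates,
    generate_cohort,
    load_preset,
)


@pytest.fixture(scope="session")
def standard_cov():
    """The 'standard patient': male, 70 y, 76.2 kg, 174 cm, Scr 86 umol/L."""
    return PatientCovariates(
        age_y=70, sex="male", weight_kg=76.2, height_cm=174,
        creatinine_series=((0.0, 86.0),),
    )


@pytest.fixture(scope="session")
def endo_model():
    return load_preset("endocarditis")


@pytest.fixture(scope="session")
def icu_model():
    return load_preset("icu")


@pytest.fixture(scope="session")
def modeling_cohort():
    """Default synthetic modeling cohort (65 courses, 221 samples)."""
    return generate_cohort(CohortSpec(rng_seed=0))


@pytest.fixture(scope="session")
def small_cohort():
    """A light 12-course cohort for fast population-fit tests."""
    return generate_cohort(CohortSpec(n_courses=12, target_total_samples=40,
                                      rng_seed=7))


def make_course(cov, course_id="c1", doses=None, observations=()):
    doses = doses if doses is not None else (DoseEvent(0.0, 240.0, 0.5),)
    return CourseRecord(course_id=course_id, covariates=cov, doses=tuple(doses),
                        observations=tuple(observations))


@pytest.fixture()
def fig2_record(standard_cov):
    """Standard patient with the two TDM samples: 8 mg/L at 1 h, 5 mg/L at 4.5 h."""
    dose = round(3.0 * standard_cov.weight_kg)
    return make_course(
        standard_cov, "fig2",
        doses=(DoseEvent(0.0, dose, 0.5),),
        observations=(Observation(1.0, 8.0), Observation(4.5, 5.0)),
    )
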