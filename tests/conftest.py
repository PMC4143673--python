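import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def null_cohort_small():
    """An 80-individual, 100-marker cohort with a genotype-independent trait."""
    from admixscan.simulate import simulate_null_cohort

    return simulate_null_cohort(n_individuals=80, n_markers=100, seed=20)


# Published model-4 coefficient estimates at the significant marker (log DBP),
# used as fixed inputs for prediction arithmetic.
TABLE3_PARAMS = {
    "const": 4.162,
    "ga_N": -0.099,
    "ga_A": -0.325,
    "med": 0.124,
    "D_EN": 0.138,
    "D_EA": -0.053,
    "D_NN": 0.145,
    "D_NA": 0.131,
    "gxD_EE": 0.123,
    "gxD_EN": 0.049,
    "gxD_EA": -0.039,
    "gxD_NN": -0.069,
    "gxD_NA": -0.122,
}

# Profile of a person with average global ancestry proportions, no medication
# use, entirely European local ancestry and no minor alleles.
BASELINE_PROFILE = {
    "ga_N": 0.453,
    "ga_A": 0.056,
    "med": 0.0,
    "D_EN": 0.0,
    "D_EA": 0.0,
    "D_NN": 0.0,
    "D_NA": 0.0,
    "gxD_EE": 0.0,
    "gxD_EN": 0.0,
    "gxD_EA": 0.0,
    "gxD_NN": 0.0,
    "gxD_NA": 0.0,
}


@pytest.fixture(scope="session")
def table3_params():
    return dict(TABLE3_PARAMS)


@pytest.fixture(scope="session")
def baseline_profile():
    return dict(BASELINE_PROFILE)
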