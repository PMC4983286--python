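import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ebfit.astrand import AstrandTable
from ebfit.cohort import CohortSpec, add_derived_columns, generate

settings.register_profile(
    "default", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.filter_too_much])
settings.load_profile("default")


@pytest.fixture(scope="session")
def nomogram() -> AstrandTable:
    return AstrandTable.default()


@pytest.fixture(scope="session")
def exact_male_cohort():
    """Noise-free male cohort generated from the published male equation."""
    spec = CohortSpec(n_male=500, n_female=0, mode="exact_model",
                      ln_noise_sd=0.0, seed=42)
    return add_derived_columns(generate(spec))


@pytest.fixture(scope="session")
def exact_female_cohort():
    spec = CohortSpec(n_male=0, n_female=500, mode="exact_model",
                      ln_noise_sd=0.0, seed=43)
    return add_derived_columns(generate(spec))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)
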