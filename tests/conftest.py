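import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from neonorm import (
    GeneratorParams,
    fit_normative_models,
    generate_chd_cohort,
    generate_normative_cohort,
)

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def params():
    return GeneratorParams()


@pytest.fixture(scope="session")
def normative_cohort(params):
    """Study-sized normative sample (n=219)."""
    return generate_normative_cohort(219, params, seed=11)


@pytest.fixture(scope="session")
def chd_cohort(params):
    """Study-sized CHD sample (n=66)."""
    return generate_chd_cohort(66, params, seed=22)


@pytest.fixture(scope="session")
def models(normative_cohort):
    """Per-region normative GP models fitted once per test session."""
    return fit_normative_models(normative_cohort, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
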