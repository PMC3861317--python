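import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def thrombosis_cohort():
    """Full-size thrombosis-profile cohort shared across tests (read-only)."""
    from mechphen.synthetic import CohortSpec, generate_cohort

    return generate_cohort(CohortSpec.thrombosis(n_snps=60), seed=123)


@pytest.fixture(scope="session")
def carriers(thrombosis_cohort):
    return thrombosis_cohort.carrier_matrix()


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
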