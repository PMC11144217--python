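import numpy as np
import pytest

from gpadelta.synthgen import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def default_config():
    return GeneratorConfig(n_pairs=3000, seed=11, n_gps=5)


@pytest.fixture(scope="session")
def cohort(default_config):
    """Mid-size synthetic cohort shared across tests (no attrition)."""
    return generate_cohort(default_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
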