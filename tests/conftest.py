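import numpy as np
import pytest

from clinlens import EcologyConfig, generate_ecology


@pytest.fixture(scope="session")
def big_case_pool():
    """A large case pool at the default ecology calibration."""
    return generate_ecology(EcologyConfig(n_cases=10_000, seed=42))


@pytest.fixture(scope="session")
def default_config():
    return EcologyConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(0)
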