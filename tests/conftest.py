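import numpy as np
import pytest

from effortpath.design import TaskConfig, generate_session
from effortpath.model import ModelParams, simulate_choices


@pytest.fixture(scope="session")
def config():
    return TaskConfig()


@pytest.fixture(scope="session")
def session_blocks(config):
    return generate_session(config, first_domain="physical", seed=123)


@pytest.fixture(scope="session")
def moderate_params():
    """Parameters producing mixed HE/LE choices in both domains."""
    return ModelParams(kR=1.0, kP=1.0, kEp=0.8, kEm=0.5,
                       kFp=0.8, kLm=0.3, kBias=0.1)


@pytest.fixture(scope="session")
def simulated_choices(session_blocks, moderate_params):
    rng = np.random.default_rng(2024)
    return simulate_choices(session_blocks, moderate_params, rng)
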