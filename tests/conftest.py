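import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fracsmoke import InitialState, ModelParams

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def params() -> ModelParams:
    return ModelParams()


@pytest.fixture
def init() -> InitialState:
    return InitialState()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230)


def random_rates(rng: np.random.Generator) -> ModelParams:
    """Random non-negative rate set of the same magnitude as the defaults."""
    return ModelParams(
        theta=rng.uniform(0, 0.2),
        chi1=rng.uniform(0, 0.005),
        chi2=rng.uniform(0, 0.005),
        gamma=rng.uniform(0, 0.01),
        rho=rng.uniform(0, 0.1),
        lam=rng.uniform(0, 0.01),
        beta=rng.uniform(0, 0.01),
        mu=rng.uniform(0, 0.01),
        sigma=rng.uniform(0, 0.01),
    )


def random_initial_state(rng: np.random.Generator) -> InitialState:
    vals = rng.uniform(0, 80, size=5)
    return InitialState(*vals)
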