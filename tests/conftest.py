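import numpy as np
import pytest

from twostep import (
    ModelParams,
    TaskConfig,
    TransitionStructure,
    build_session,
    simulate_agent,
)


@pytest.fixture(scope="session")
def task_config() -> TaskConfig:
    return TaskConfig()


@pytest.fixture(scope="session")
def structure() -> TransitionStructure:
    return TransitionStructure(common_prob=0.7)


@pytest.fixture(scope="session")
def default_params() -> ModelParams:
    return ModelParams(beta1=5.0, beta2=5.0, alpha1=0.6, alpha2=0.6,
                       lam=0.5, persev=0.2, w=0.8)


@pytest.fixture(scope="session")
def session_env(task_config):
    return build_session(task_config, walk_id=0, seed=11)


@pytest.fixture(scope="session")
def simulated_trials(default_params, session_env):
    return simulate_agent(default_params, session_env, seed=42)


def random_params(rng: np.random.Generator, beta_max: float = 8.0) -> ModelParams:
    """Draw a parameter vector uniformly inside its bounds."""
    return ModelParams(
        beta1=rng.uniform(0, beta_max),
        beta2=rng.uniform(0, beta_max),
        alpha1=rng.uniform(0, 1),
        alpha2=rng.uniform(0, 1),
        lam=rng.uniform(0, 1),
        persev=rng.normal(0, 0.5),
        w=rng.uniform(0, 1),
    )
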