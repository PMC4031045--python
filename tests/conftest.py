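import numpy as np
import pytest

from optiprior.task import TaskConfig, generate_schedule
from optiprior.cohort import simulate_subject
from optiprior.bayes import BayesParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def exp1_config():
    return TaskConfig()


@pytest.fixture
def small_config():
    # 10 fractals keeps schedule-level tests quick
    return TaskConfig(n_fractals=10)


@pytest.fixture
def small_schedule(small_config, rng):
    return generate_schedule(small_config, rng)


@pytest.fixture
def bayes_subject(small_schedule, rng):
    """One simulated subject from a moderately optimistic Bayesian agent."""
    params = BayesParams(alpha=1.2, beta=0.8, gamma=8.0)
    return simulate_subject(params, small_schedule, "bayes", rng, trait_score=17)
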