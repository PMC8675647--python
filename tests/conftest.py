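import numpy as np
import pytest

from subjopt.task import TaskSpec, ValueParams
from subjopt.synth import simulate_agent_dataset


@pytest.fixture(scope="session")
def k5_spec():
    return TaskSpec(K=5, n_rounds=200)


@pytest.fixture(scope="session")
def fig2_params():
    """Group-mean subjective-valuation parameters of the K=5 cohort."""
    return ValueParams(r=110.51, rho=0.62, cost=0.0, s=10.0)


@pytest.fixture(scope="session")
def small_dataset(k5_spec, fig2_params):
    """One simulated subject, 200 rounds, subjective-optimality agent."""
    return simulate_agent_dataset(
        fig2_params, "subjective", k5_spec, np.random.default_rng(42),
        rt_spec={},
    )
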