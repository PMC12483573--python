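import numpy as np
import pandas as pd
import pytest

from contlearn import agents, rl_models, task_design


@pytest.fixture(scope="session")
def reward_schedule():
    return task_design.build_reward_schedule()


@pytest.fixture(scope="session")
def learning_schedule():
    return task_design.build_learning_schedule(seed=1)


@pytest.fixture(scope="session")
def test_schedule():
    return task_design.build_test_schedule(seed=1)


@pytest.fixture(scope="session")
def value_schedule():
    return task_design.build_value_schedule(seed=1)


@pytest.fixture(scope="session")
def feature_decay_agent():
    params = rl_models.ParamVector(
        w_leg=0.0, w_antennae=4.0, w_mandible=0.0, bias=0.0,
        alpha_reward=0.4, alpha_unreward=0.3, decay=0.1,
    )
    return agents.GeneratingValueAgent("feature", params, decay=True, seed=42)


@pytest.fixture(scope="session")
def value_log(value_schedule, reward_schedule, feature_decay_agent):
    return agents.simulate_value_agent(value_schedule, reward_schedule, feature_decay_agent)


def make_tiny_log(n=10, seed=0):
    """A short hand-checkable value-task log for likelihood oracles."""
    rng = np.random.default_rng(seed)
    rows = []
    for t in range(n):
        left, right = rng.choice(8, size=2, replace=False)
        rows.append(
            {
                "trial_index": t,
                "block": 1,
                "left_stimulus_id": int(left),
                "right_stimulus_id": int(right),
                "response": int(rng.integers(2)),
                "reward": int(rng.integers(2)),
            }
        )
    return pd.DataFrame(rows)


@pytest.fixture()
def tiny_log():
    return make_tiny_log()
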