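import numpy as np
import pytest

from gatingrl.experiment import SessionSchedule
from gatingrl.rl_core import GatingAgent, HyperParams
from gatingrl.task_env import TaskConfig


@pytest.fixture
def config5() -> TaskConfig:
    return TaskConfig(n_central=5)


@pytest.fixture
def schedule() -> SessionSchedule:
    return SessionSchedule()


@pytest.fixture
def sarsa_agent() -> GatingAgent:
    return GatingAgent.fresh("sarsa", HyperParams(0.31, 0.13, 0.03))


@pytest.fixture
def ac_agent() -> GatingAgent:
    return GatingAgent.fresh("actor-critic", HyperParams(0.14, 1.38, 0.93))


@pytest.fixture
def rng():
    return np.random.RandomState(1234)
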