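import numpy as np
import pytest

from reachframes.tasks import delay_task_conditions, screening_task_conditions
from reachframes.units import UnitSpec


@pytest.fixture(scope="session")
def screening_conditions():
    return screening_task_conditions(15.0)


@pytest.fixture(scope="session")
def delay_conditions():
    return delay_task_conditions(15.0)


@pytest.fixture
def eye_unit():
    return UnitSpec("eye_0", "eye", u=0.0, v=-30.0, gain_sign=1)


@pytest.fixture
def hand_unit():
    return UnitSpec("hand_0", "hand", u=0.0)


@pytest.fixture
def eye_hand_unit():
    return UnitSpec("eye_hand_0", "eye_hand", u=0.0, v=-15.0, gain_sign=1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
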