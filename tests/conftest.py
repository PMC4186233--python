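import numpy as np
import pytest

from hrlplan.envs import load_map
from hrlplan.options import make_doorway_options
from hrlplan.planners import ActionSet


@pytest.fixture(scope="session")
def rooms():
    """Default four-room map: 104 free cells, 4 doorways."""
    return load_map("rooms_default.map")


@pytest.fixture(scope="session")
def corridor():
    return load_map("corridor.map")


@pytest.fixture(scope="session")
def two_rooms():
    return load_map("two_rooms.map")


@pytest.fixture(scope="session")
def chain7():
    """Linear 8-cell chain: 7 actions from start to goal."""
    return load_map("chain7.map")


@pytest.fixture(scope="session")
def rooms_options(rooms):
    return make_doorway_options(rooms)


@pytest.fixture(scope="session")
def rooms_action_sets(rooms, rooms_options):
    return {
        "flat": ActionSet.flat(),
        "hierarchical": ActionSet.hierarchical(rooms_options),
        "saltatory": ActionSet.saltatory(rooms, rooms_options),
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
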