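import numpy as np
import pytest

from shakesense import MotionParams, Protocol, SensorPosition, default_protocol
from shakesense.synthetic import simulate_session


@pytest.fixture(scope="session")
def motion_params() -> MotionParams:
    return MotionParams()


@pytest.fixture(scope="session")
def small_protocol() -> Protocol:
    """All 18 tasks, 2 participants, 2 positions: fast but structurally complete."""
    base = default_protocol()
    return Protocol(
        tasks=base.tasks,
        n_participants=2,
        positions=[SensorPosition.HEAD, SensorPosition.LEFT_LEG],
    )


@pytest.fixture(scope="session")
def small_session(small_protocol, motion_params):
    return simulate_session(small_protocol, motion_params, seed=7)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
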