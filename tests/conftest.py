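import numpy as np
import pytest

from copsway import CopTrajectory, ParticipantParams, SimulationConfig, StimulusSchedule


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig()


@pytest.fixture(scope="session")
def fast_config():
    """Short record for IO/plumbing tests: two pannings, six seconds."""
    return SimulationConfig(
        duration_s=6.0,
        schedule=StimulusSchedule(n_pannings=2, pause_s=1.0),
    )


@pytest.fixture
def participant():
    return ParticipantParams(participant_id="P01")


@pytest.fixture
def small_trajectory():
    return CopTrajectory(
        t=[0.0, 0.01, 0.02, 0.03],
        x=[0.0, 0.1, 0.2, 0.1],
        y=[0.0, -0.2, -0.1, 0.3],
        condition="silent",
        participant_id="P99",
    )
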