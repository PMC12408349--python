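import numpy as np
import pytest

from bwmap import synthetic_data as sd


@pytest.fixture(scope="session")
def tuned_session():
    """One tuned session: visual region driven by right stimuli, motor
    region by movements; moderate drift.  Shared across tests."""
    return sd.generate_session(
        session_id="tuned-0",
        cfg=sd.TaskConfig(session_length=450),
        agent=sd.AgentParams(),
        region_neurons={"VIS": 8, "MOT": 8},
        region_tuning=sd.DEFAULT_TUNING_MAP,
        seed=1234,
        drift=dict(sd.NULL_DRIFT),
    )


@pytest.fixture(scope="session")
def null_session():
    """Drift-only session: no neuron carries any event tuning."""
    return sd.generate_session(
        session_id="null-0",
        cfg=sd.TaskConfig(session_length=450),
        agent=sd.AgentParams(),
        region_neurons={"A": 6, "B": 6},
        region_tuning={},
        seed=4321,
        drift=dict(sd.NULL_DRIFT),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
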