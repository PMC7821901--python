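import logging

import numpy as np
import pytest

from stoptrace.synthetic import (
    GroundTruthCell,
    SimulationConfig,
    simulate_behavior,
)

# dual-flag conflicts are expected for planted tonic/suppressed cells
logging.getLogger("stoptrace.classify").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def session_config():
    """A mid-sized behavioral session shared across read-only tests."""
    return SimulationConfig(duration_s=330.0, seed=1)


@pytest.fixture(scope="session")
def session_behavior(session_config):
    return simulate_behavior(session_config)


@pytest.fixture(scope="session")
def stop_onsets_cal(session_config, session_behavior):
    schedule, _, _ = session_behavior
    return np.rint(schedule.onsets("stop") * session_config.calcium_rate_hz).astype(int)


def make_cell(cls="stop_excited", **kw):
    defaults = dict(reliability_p=0.8, response_amp=0.5, sustained=False)
    defaults.update(kw)
    return GroundTruthCell(cell_id="c0", cell_class=cls, **defaults)
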