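import numpy as np
import pytest

import rerpsim as rs


@pytest.fixture(scope="session")
def sr_world():
    """Noise-free SR world shared across tests: recording, events, details."""
    cfg = rs.default_sr_config(seed=7, n_trials=200)
    recording, events, details = rs.assemble_recording(cfg, return_details=True)
    events = rs.assign_rt_categories(events)
    return cfg, recording, events, details


@pytest.fixture(scope="session")
def ramp_world():
    cfg = rs.default_ramp_config(seed=7, n_trials=200)
    recording, events = rs.assemble_recording(cfg)
    events = rs.assign_rt_categories(events)
    return cfg, recording, events


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
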