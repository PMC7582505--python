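"""Shared fixtures: small synthetic recordings and datasets.

Everything is generated at test time from the package's own simulator;
session-scoped fixtures keep the expensive signal generation to one pass.
"""

from dataclasses import replace

import numpy as np
import pytest

from eegmotor import default_montage
from eegmotor.simulate import SimPoolSpec, SimSpec, simulate_pool, \
    simulate_session


@pytest.fixture(scope="session")
def montage():
    return default_montage()


@pytest.fixture(scope="session")
def sim_spec_small():
    return replace(SimSpec(), n_events=6)


@pytest.fixture(scope="session")
def session_recording(sim_spec_small):
    """One left-hand session, FMA 45, six events."""
    return simulate_session(45, "left", sim_spec_small, seed=101,
                            participant_id="P1", session_id="b1")


@pytest.fixture(scope="session")
def tiny_pool():
    """Two participants (one healthy, one stroke), 20 train + 5 test trials
    each: the smallest pool that exercises every bookkeeping path."""
    spec = SimPoolSpec(n_healthy=1, n_stroke=1, train_trials=20,
                       test_trials=5)
    return simulate_pool(spec, seed=202)


@pytest.fixture(scope="session")
def tiny_train(tiny_pool):
    return tiny_pool[0]


@pytest.fixture(scope="session")
def tiny_test(tiny_pool):
    return tiny_pool[1]


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
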