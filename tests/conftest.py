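"""Shared fixtures: one simulation per scenario kind, reused across tests."""

import numpy as np
import pytest
from hypothesis import settings

import metaswitch as ms

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def params():
    return ms.default_params()


@pytest.fixture(scope="session")
def batch_result(params):
    """Default closed-culture run (glucose 22 mM + malate 50 mM)."""
    return ms.simulate_batch(params, ms.batch_scenario(seed=1))


@pytest.fixture(scope="session")
def mm_lineage():
    """Mother-machine run in the acetate-rich (alsS-pulsing) condition."""
    p, cfg = ms.alsS_mother_machine(seed=3, n_channels=12, duration=2160.0)
    lin = ms.simulate_mother_machine(p, cfg)
    lin.attrs["params"] = p
    lin.attrs["config"] = cfg
    return lin


@pytest.fixture(scope="session")
def pad_result(params):
    """Default agarose-pad microcolony run (20 mM starting acetate)."""
    return ms.simulate_pad(params, ms.pad_scenario(seed=2))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
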