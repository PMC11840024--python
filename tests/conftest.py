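import logging

import numpy as np
import pytest
from hypothesis import settings

import pleiosweep as ps

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

logging.getLogger("pleiosweep").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def planted_run():
    """One mid-size run with planted shared signal, reused across tests."""
    cfg = ps.SimConfig(seed=11, pi_shared=0.005, rho_beta=0.8)
    panel, truth, blocks = ps.simulate_panel(cfg)
    return cfg, panel, truth, blocks


@pytest.fixture(scope="session")
def null_run():
    """A global-null panel: no causal variants in either trait."""
    cfg = ps.SimConfig(seed=12, pi1=0.0, pi2=0.0, pi_shared=0.0,
                       h2_1=0.0, h2_2=0.0)
    panel, truth, blocks = ps.simulate_panel(cfg)
    return cfg, panel, truth, blocks


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
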