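import numpy as np
import pytest
from hypothesis import settings

import goldsip as g

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def paper_like():
    """One simulated desk-scale acquisition with truth, shared read-only."""
    cfg = g.paper_like_scenario(seed=1)
    session, truth = g.simulate_session(cfg)
    return cfg, session, truth


@pytest.fixture(scope="session")
def control():
    return g.ControlStats(mean_atpct=0.362, sd_atpct=0.045, k_sigma=6.0)


@pytest.fixture(scope="session")
def processed(paper_like, control):
    """Full pipeline run on the shared acquisition."""
    _, session, truth = paper_like
    result = g.process_session(session, control, dilution=g.dilution_factor(0.39))
    return result, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
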