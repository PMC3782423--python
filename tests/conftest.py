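import numpy as np
import pytest

import trajbayes as tb
from trajbayes.behavior import BeliefArrays


@pytest.fixture(scope="session")
def default_config() -> tb.EnvironmentConfig:
    return tb.EnvironmentConfig(seed=7)


@pytest.fixture(scope="session")
def default_session(default_config) -> tb.Session:
    return tb.generate_session(default_config)


@pytest.fixture(scope="session")
def session_beliefs(default_session) -> BeliefArrays:
    """Aligned statistical/dynamic beliefs over the analysis trials."""
    stat = tb.run_filter(default_session)
    dyn = tb.run_dynamic(default_session)
    return BeliefArrays.from_beliefs(stat, dyn, default_session.analysis_mask)


@pytest.fixture(scope="session")
def small_grid() -> tb.GridConfig:
    """Coarse observer lattice for fast unit tests."""
    return tb.GridConfig(n_mu=30, n_sigma=12, n_alpha=4)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
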