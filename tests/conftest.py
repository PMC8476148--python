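"""Shared fixtures: small engine configurations and a session-scoped
selection cache under the default truth demography (built once, ~15 s)."""

import numpy as np
import pytest

from jointdfe import (
    EngineConfig,
    SampleConfig,
    ThetaConfig,
    build_cache,
    build_gamma_grid,
)
from jointdfe.simulate import (
    DEFAULT_THETA_NS,
    DEFAULT_TRUTH_DEMO,
    DEFAULT_TRUTH_DFE,
)


@pytest.fixture(scope="session")
def truth_demo():
    return DEFAULT_TRUTH_DEMO


@pytest.fixture(scope="session")
def truth_dfe():
    return DEFAULT_TRUTH_DFE


@pytest.fixture(scope="session")
def theta_ns():
    return ThetaConfig.from_theta_sel(DEFAULT_THETA_NS)


@pytest.fixture(scope="session")
def sample20():
    return SampleConfig(20, 20)


@pytest.fixture(scope="session")
def truth_cache(truth_demo, sample20):
    """25-point cache at n = 20+20 under the truth demography (h = 0.5)."""
    return build_cache(truth_demo, sample20, build_gamma_grid(25))


@pytest.fixture(scope="session")
def small_cache(truth_demo):
    """Fast 12-point cache at n = 6+6 for structural tests."""
    return build_cache(truth_demo, SampleConfig(6, 6), build_gamma_grid(12))


@pytest.fixture()
def rng():
    return np.random.default_rng(20210527)
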