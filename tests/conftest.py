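import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import autoimmsim as ai

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fx():
    return ai.default_fixture()


@pytest.fixture(scope="session")
def t_grid():
    return ai.default_time_grid()


@pytest.fixture(scope="session")
def reduced_constants(fx):
    return ai.derive_reduced_constants(fx.sp, fx.psi, fx.ds, fx.T)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def diffusion_cfg():
    """Rapid-kinetics configuration in the linear-buffering regime."""
    return ai.DiffusionConfig(
        L=1.0,
        n_x=400,
        D0=1.0,
        DM=0.1,
        DN=0.05,
        kM_plus=500.0,
        kM_minus=1000.0,
        kN_plus=500.0,
        kN_minus=1000.0,
        B_M=4.0,
        B_N=2.0,
    )
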