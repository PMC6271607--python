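import numpy as np
import pytest

from hdpslds import ContinuousStateParams, DGPConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def scalar_ou():
    """Scalar OU: PhiB = 2 /s, D = 0.01 um^2/s, rbar = 0.5 um."""
    return ContinuousStateParams.from_rates(
        rbar=[0.5], rates=[2.0], D=0.01, R=[[0.0009]])


@pytest.fixture
def confined_3d():
    return ContinuousStateParams.from_rates(
        rbar=[0.1, -0.2, 0.0], rates=[1.0, 2.0, 0.5], D=0.01,
        R=0.03 ** 2 * np.eye(3))


@pytest.fixture
def tiny_dgp():
    """Small benchmark DGP for fast end-to-end checks."""
    return DGPConfig(n_obs=300, n_traj=4, seed=123)
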