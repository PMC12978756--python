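import numpy as np
import pytest

from pulsarch.cardiac_waveform import WaveformParams
from pulsarch.rheology import RheologyParams, default_registry


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def waveform():
    return WaveformParams()


def newtonian(mu: float, lam: float = 1.0, k: float = 0.5) -> RheologyParams:
    """Constant-viscosity parameter set (both plateaus equal)."""
    return RheologyParams(name=f"newtonian-{mu}", k=k, lam=lam, mu0=mu, mu_inf=mu)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260922)
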