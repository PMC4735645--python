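import numpy as np
import pytest

from phasegraph import Coupling, SimulationConfig, generate_recording


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20160202)


def random_weights(rng, n, density=0.7, seedless=False):
    """Random symmetric weight matrix with zero diagonal, weights in (0,1)."""
    w = rng.uniform(0.05, 0.95, size=(n, n))
    mask = rng.uniform(size=(n, n)) < density
    w = np.triu(w * mask, k=1)
    w = w + w.T
    return w


@pytest.fixture(scope="session")
def coupled_recording():
    """30 s, 6 channels, pink background, one strong alpha1 coupling 0-1."""
    cfg = SimulationConfig(
        n_channels=6, duration_s=30.0, rate=128.0, alpha_exponent=1.0,
        couplings=[Coupling.in_band(0, 1, "alpha1", np.pi / 2, 3.0)],
        noise_sd=0.0, seed=7)
    return generate_recording(cfg)
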