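import numpy as np
import pytest

from qustc.envelope import build_hk_lookup
from qustc.simulate import SimConfig, simulate_rf_frame


@pytest.fixture(scope="session")
def small_hk_lookup():
    """Coarse homodyned-K lookup table shared across tests (fast to build)."""
    return build_hk_lookup(n_k=16, n_mu=16, mc_samples=100_000, seed=0)


@pytest.fixture(scope="session")
def speckle_frame():
    """Fully developed speckle frame, no coherent component, no attenuation."""
    cfg = SimConfig(
        n_lines=160,
        n_samples=1200,
        scatterers_per_resolution_cell=12.0,
        background_scatterers_per_cell=12.0,
        coherent_amplitude_ratio=0.0,
        attenuation=0.0,
        seed=42,
    )
    return simulate_rf_frame(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
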