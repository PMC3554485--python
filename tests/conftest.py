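import numpy as np
import pytest

from quorumsync.fuzzy_ts import build_fuzzy_model
from quorumsync.genetic_network import (
    ExtrinsicNoiseSpec,
    FluctuationAmplitudes,
    RepressilatorParams,
)
from quorumsync.sde_sim import attractor_segment


@pytest.fixture(scope="session")
def params():
    """Design-example kinetic constants."""
    return RepressilatorParams()


@pytest.fixture(scope="session")
def amplitudes():
    """Design-example fluctuation amplitudes."""
    return FluctuationAmplitudes()


@pytest.fixture(scope="session")
def zero_amplitudes():
    return FluctuationAmplitudes.zero()


@pytest.fixture(scope="session")
def ai_noise():
    """Extrinsic noise entering through the autoinducer channel."""
    h = np.zeros(7)
    h[6] = 1.0
    return ExtrinsicNoiseSpec(h_cell=h)


@pytest.fixture(scope="session")
def quiet_noise():
    h = np.zeros(7)
    h[6] = 1.0
    return ExtrinsicNoiseSpec(h_cell=h, sigma_v=0.0)


@pytest.fixture(scope="session")
def fuzzy_model_8(params, amplitudes):
    """Full-cycle 8-rule base (shared across tests; construction is ~1s)."""
    return build_fuzzy_model(params, amplitudes, L=8)


@pytest.fixture(scope="session")
def attractor(params):
    """Settled noise-free single-cell trajectory segment."""
    return attractor_segment(params)


def random_states(rng, n, scale=5.0):
    """Nonnegative random cell states, species on the last axis."""
    return rng.uniform(0.0, scale, size=(n, 7))
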