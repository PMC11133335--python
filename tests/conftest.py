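import numpy as np
import pytest

from era_lfp import (
    MultiChannelRecording,
    generate_state_space_system,
    impulse_response,
)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def order3_system():
    """Random stable order-3 SISO-ish system used across ERA tests."""
    return generate_state_space_system(3, n_inputs=1, n_outputs=2,
                                       spectral_radius=0.8, seed=3)


@pytest.fixture()
def order3_series(order3_system):
    """Noise-free impulse response y_1..y_39 of the order-3 system."""
    return impulse_response(order3_system, 40).samples[:, 1:]


@pytest.fixture()
def small_recording(rng):
    samples = rng.standard_normal((3, 500))
    return MultiChannelRecording(samples=samples, rate=100.0, group="AW")
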