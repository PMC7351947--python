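import numpy as np
import pytest

from gevisim.evaluate import SimConfigLike
from gevisim.synth import generate_footprint, generate_spike_train, generate_voltage_trace


@pytest.fixture(scope="session")
def small_cfg():
    """Reduced-scale simulation config used throughout the suite."""
    return SimConfigLike(n_frames=4000, mean_spikes=10)


@pytest.fixture()
def spike_train():
    return generate_spike_train(4000, 400.0, 10, seed=7)


@pytest.fixture()
def voltage_trace(spike_train):
    return generate_voltage_trace(spike_train, seed=11)


@pytest.fixture()
def footprint():
    return generate_footprint((40, 40), (20.0, 20.0), radius_px=3.0)
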