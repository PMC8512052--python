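import numpy as np
import pytest

from pwus import ArrayGeometry, PlaneWaveSequence
from pwus.experiments import simulate_wire


@pytest.fixture(scope="session")
def geometry():
    return ArrayGeometry()


@pytest.fixture(scope="session")
def seq21():
    return PlaneWaveSequence.from_span(21, 16.0)


@pytest.fixture(scope="session")
def wire10_data():
    """Noise-free 21-angle channel data for a wire at 10 mm (shared; expensive)."""
    return simulate_wire(10.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
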