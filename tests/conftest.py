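import numpy as np
import pytest

from qdti import OpticalConfig
from qdti.acquisition import DetectorModel


@pytest.fixture
def fine_config():
    """High-resolution grid for PSF width measurements."""
    return OpticalConfig(dx=10.0, dy=10.0, dz=30.0)


@pytest.fixture
def coarse_config():
    """Acquisition-scale grid (50 nm lateral / 150 nm axial)."""
    return OpticalConfig(dx=50.0, dy=50.0, dz=150.0)


@pytest.fixture
def noise_free_detector():
    return DetectorModel(quantum_efficiency=1.0, gain=1.0, offset=0.0,
                         read_noise_sd=0.0, bit_depth=16)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
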