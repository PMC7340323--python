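import numpy as np
import pytest

from rlm.optics import CameraModel, OpticalSystem
from rlm.simulator import ScintillatorStack


@pytest.fixture
def optics():
    return OpticalSystem()


@pytest.fixture
def camera():
    return CameraModel()


@pytest.fixture
def quiet_camera():
    """Noise-free camera (no read noise, dark current or bias, unit gain)."""
    return CameraModel(read_noise_e=0.0, dark_rate_e_per_s=0.0, em_gain=1.0,
                       bias_offset_adu=0.0)


@pytest.fixture
def single_stack():
    return ScintillatorStack()


@pytest.fixture
def dual_stack():
    return ScintillatorStack(gap_top_um=5.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
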