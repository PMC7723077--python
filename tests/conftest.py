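import numpy as np
import pytest

from rootpi.synth.acquisition import AcquisitionModel
from rootpi.synth.sensor import SensorModel


@pytest.fixture
def sensor():
    return SensorModel(kd=7.4, r_min=1.0, r_max=3.0)


@pytest.fixture
def noiseless_acq():
    return AcquisitionModel(shot_noise=False, read_noise_sd=0.0)


@pytest.fixture
def default_acq():
    return AcquisitionModel()


@pytest.fixture
def small_mask():
    mask = np.zeros((16, 16), dtype=bool)
    mask[2:-2, 2:-2] = True
    return mask
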