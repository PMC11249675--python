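import numpy as np
import pytest

from tfsofi import CameraModel, make_gaussian_psf


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def psf274():
    """Detection PSF with the measured 274 nm lateral / 680 nm axial FWHM."""
    return make_gaussian_psf(274.0, 680.0)


@pytest.fixture
def noiseless_camera():
    return CameraModel.noiseless()
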