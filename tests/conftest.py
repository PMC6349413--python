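import numpy as np
import pytest

from holofoci import OpticsConfig


@pytest.fixture(scope="session")
def default_config() -> OpticsConfig:
    """The full-size projector profile (600 px SLM, 20x objective window)."""
    return OpticsConfig()


@pytest.fixture(scope="session")
def small_config() -> OpticsConfig:
    """A reduced SLM grid for fast unit tests (dx_max = 24 um)."""
    return OpticsConfig(slm_pixels=128, fov_aperture_halfwidth=8.0)


@pytest.fixture(scope="session")
def pupil_512():
    """512^2 normalized pupil grid for Zernike quadrature checks."""
    c = (np.arange(512) - 256) * (2.0 / 512)
    u, v = np.meshgrid(c, c)
    return u, v
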