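import numpy as np
import pytest

from musical.optics import OpticsConfig


@pytest.fixture
def optics_20x() -> OpticsConfig:
    """Low-magnification widefield acquisition (20x/0.80, 6.45 µm camera)."""
    return OpticsConfig(wavelength_em=0.460, numerical_aperture=0.80,
                        magnification=20, refractive_index=1.0,
                        pixel_pitch=6.45)


@pytest.fixture
def optics_100x() -> OpticsConfig:
    """Well-sampled acquisition: PSF σ ≈ 1.9 camera pixels."""
    return OpticsConfig(wavelength_em=0.460, numerical_aperture=0.80,
                        magnification=100, refractive_index=1.0,
                        pixel_pitch=6.45)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
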