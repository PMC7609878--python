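import numpy as np
import pytest

from laurdangp.spectral_io import channel_grid
from laurdangp.synthetic import (
    BasisSpectra,
    CellPhantomConfig,
    make_basis_spectra,
    make_cell_image,
)


@pytest.fixture(scope="session")
def imaging_grid() -> np.ndarray:
    return channel_grid(415.0, 691.0, 8.9)


@pytest.fixture(scope="session")
def basis(imaging_grid) -> BasisSpectra:
    return make_basis_spectra(imaging_grid)


@pytest.fixture(scope="session")
def noiseless_phantom(basis):
    """Small two-compartment phantom without noise, plus its labels."""
    config = CellPhantomConfig(
        image_size=(32, 32),
        outer_radius=12.0,
        ring_thickness=3.0,
        interior_order=0.3,
        membrane_order=0.8,
        brightness=500.0,
        noise_model="none",
        seed=0,
    )
    image, labels = make_cell_image(config, basis)
    return config, image, labels


@pytest.fixture(scope="session")
def noisy_phantom(basis):
    """Two-compartment phantom with Poisson noise (seeded)."""
    config = CellPhantomConfig(
        image_size=(48, 48),
        outer_radius=18.0,
        ring_thickness=3.0,
        interior_order=0.3,
        membrane_order=0.8,
        brightness=500.0,
        noise_model="poisson",
        seed=11,
    )
    image, labels = make_cell_image(config, basis)
    return config, image, labels


def band_sum_oracle(wavelengths, intensities, center, halfwidth):
    """Brute-force mean over in-band samples, written independently of
    laurdangp.gp.band_intensity (explicit loop, no vectorization)."""
    total = 0.0
    count = 0
    for wl, it in zip(wavelengths, intensities):
        if center - halfwidth <= wl <= center + halfwidth:
            total += it
            count += 1
    assert count > 0
    return total / count


def gp_oracle(wavelengths, intensities):
    """Independent GP: brute-force band means and the ratio formula."""
    i440 = band_sum_oracle(wavelengths, intensities, 440.0, 10.0)
    i490 = band_sum_oracle(wavelengths, intensities, 490.0, 10.0)
    return (i440 - i490) / (i440 + i490)
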