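import numpy as np
import pytest

from hawkman import ReconstructionImage


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def ridge_image(
    columns, n=128, sigma_px=2.0, pixel_size_nm=10.0, amplitudes=None
) -> ReconstructionImage:
    """Vertical Gaussian ridges at the given columns (synthetic test image)."""
    x = np.arange(n, dtype=float)
    amplitudes = amplitudes or [1.0] * len(columns)
    prof = sum(
        a * np.exp(-((x - c) ** 2) / (2.0 * sigma_px**2))
        for a, c in zip(amplitudes, columns)
    )
    return ReconstructionImage(np.tile(prof, (n, 1)), pixel_size_nm, name="ridges")


def two_ridge_image(sigma_px, sep_px=20, n=128, pixel_size_nm=10.0):
    """Two equal ridges around the centre; trough depth set by sigma_px."""
    c1 = n / 2.0 - sep_px / 2.0
    c2 = n / 2.0 + sep_px / 2.0
    x = np.arange(n, dtype=float)
    prof = np.exp(-((x - c1) ** 2) / (2 * sigma_px**2)) + np.exp(
        -((x - c2) ** 2) / (2 * sigma_px**2)
    )
    prof = prof / prof.max()
    img = ReconstructionImage(np.tile(prof, (n, 1)), pixel_size_nm, name="two-ridge")
    return img, int(round(c1)), int(round(c2))


def smooth_random_image(rng, n=32, pixel_size_nm=10.0) -> ReconstructionImage:
    """Non-negative random image with spatial structure at several scales."""
    from scipy import ndimage

    base = rng.random((n, n))
    smooth = ndimage.gaussian_filter(base, 2.0, mode="constant")
    pixels = smooth + 0.2 * rng.random((n, n))
    pixels -= pixels.min()
    pixels[pixels < np.percentile(pixels, 20)] = 0.0
    return ReconstructionImage(pixels, pixel_size_nm, name="random")


@pytest.fixture
def crossing_image():
    """256x256 synthetic crossing-lines image rendered from the simulator."""
    from hawkman import SimulationConfig, generate_fixture

    cfg = SimulationConfig(structure="crossing", field_size_nm=2560.0, seed=7)
    return generate_fixture(cfg).test
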