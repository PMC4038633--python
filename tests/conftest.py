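import numpy as np
import pytest

from collafluor.spectra import Spectrum, SpectrumMeta


def gaussian_spectrum(
    grid=None,
    peaks=((405.0, 18.0, 0.36), (455.0, 28.0, 1.0)),
    baseline=(0.0, 0.0),
    meta=None,
):
    """Analytic multi-Gaussian spectrum: peaks = (center, sigma, amp)."""
    if grid is None:
        grid = np.arange(320.0, 551.0, 1.0)
    y = baseline[0] + baseline[1] * (grid - grid[0])
    for center, sigma, amp in peaks:
        y = y + amp * np.exp(-0.5 * ((grid - center) / sigma) ** 2)
    return Spectrum(grid, y, meta or SpectrumMeta())


@pytest.fixture
def grid():
    return np.arange(320.0, 551.0, 1.0)


@pytest.fixture
def two_peak_spectrum(grid):
    return gaussian_spectrum(grid)


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
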