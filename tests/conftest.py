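import numpy as np
import pytest

from anapquench import Spectrum


@pytest.fixture
def nm_grid():
    return np.arange(380.0, 601.0, 1.0)


@pytest.fixture
def gaussian_spectrum(nm_grid):
    def make(peak=451.0, fwhm=60.0, amplitude=1000.0, meta=None):
        sigma = fwhm / 2.3548200450309493
        return Spectrum(
            nm_grid, amplitude * np.exp(-0.5 * ((nm_grid - peak) / sigma) ** 2), meta or {}
        )

    return make
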