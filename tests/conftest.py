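import numpy as np
import pytest

from nirsel.dataset import SpectraSet


@pytest.fixture
def rng():
    return np.random.default_rng(20240517)


def make_spectra(n_samples=25, n_wavelengths=30, seed=0, informative=(10, 18), noise=0.02):
    """Small synthetic SpectraSet: y drives a contiguous band of columns."""
    rng = np.random.default_rng(seed)
    wl = 1000.0 + 2.0 * np.arange(n_wavelengths)
    y = rng.normal(30.0, 4.0, size=n_samples)
    X = rng.normal(0.0, noise, size=(n_samples, n_wavelengths))
    lo, hi = informative
    band = np.exp(-0.5 * ((np.arange(n_wavelengths) - (lo + hi) / 2) / ((hi - lo) / 4)) ** 2)
    X += np.outer(y, 0.01 * band)
    X += np.outer(rng.normal(1.0, 0.1, size=n_samples), 0.05 * np.ones(n_wavelengths))
    return SpectraSet(wavelengths=wl, absorbance=X, reference=y)


@pytest.fixture
def small_data():
    return make_spectra()
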