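import numpy as np
import pytest

from ramanid import RamanSpectrum
from ramanid.library import load_library


def lorentzian(nu, center, height, fwhm):
    gamma = fwhm / 2.0
    return height * gamma**2 / ((nu - center) ** 2 + gamma**2)


def make_peak_spectrum(
    peaks=((600, 1.0, 10), (1000, 0.6, 10), (1400, 0.3, 10)),
    baseline_slope=0.0,
    noise_sd=0.0,
    seed=0,
    lo=400.0,
    hi=1700.0,
    **meta,
):
    """Synthetic spectrum with known ground truth for oracle tests."""
    nu = np.arange(lo, hi + 0.5, 1.0)
    y = baseline_slope * (nu - lo)
    for c, h, fw in peaks:
        y = y + lorentzian(nu, c, h, fw)
    if noise_sd:
        y = y + np.random.default_rng(seed).normal(0, noise_sd, nu.size)
    return RamanSpectrum(nu, y, **meta)


@pytest.fixture(scope="session")
def library():
    return load_library()


@pytest.fixture
def three_peak_spectrum():
    return make_peak_spectrum()
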