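import numpy as np
import pytest

from fragscreen.spectra import Spectrum, SpectralSeries


@pytest.fixture
def flat_spectrum():
    """Constant emission spectrum on a 1-nm grid, value 3.0."""
    axis = np.arange(450.0, 521.0)
    return Spectrum("wavelength_nm", axis, np.full(axis.size, 3.0))


@pytest.fixture
def ramp_spectrum():
    """Linear ramp y = x on a uniform wavelength grid."""
    axis = np.arange(400.0, 501.0)
    return Spectrum("wavelength_nm", axis, axis.copy())


def make_series(values_by_time, axis=None, replicate=0, modality="tht_emission"):
    """Series of constant spectra: {time_h: constant intensity}."""
    if axis is None:
        axis = np.arange(450.0, 521.0)
    spectra = [
        Spectrum("wavelength_nm", axis, np.full(axis.size, v), time_h=t, replicate=replicate)
        for t, v in sorted(values_by_time.items())
    ]
    return SpectralSeries(modality, spectra)


@pytest.fixture
def make_constant_series():
    return make_series
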