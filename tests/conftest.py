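import numpy as np
import pytest

from tissuelight.spectra_io import SpectrumRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_record(wavelength, intensity, mode="transmission", power=150.0, rep=1):
    return SpectrumRecord(
        wavelength_nm=np.asarray(wavelength, float),
        intensity=np.asarray(intensity, float),
        mode=mode,
        power_mw=power,
        replicate_id=rep,
        sample_id="test",
    )


@pytest.fixture
def flat_record():
    wl = np.linspace(750.0, 860.0, 221)
    return make_record(wl, np.full(wl.size, 100.0))
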