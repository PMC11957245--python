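import numpy as np
import pytest
from hypothesis import settings

import tamraspec as ts

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")


@pytest.fixture(scope="session")
def model():
    return ts.build_surrogate()


@pytest.fixture(scope="session")
def b3lyp_set():
    """The two printed hybrid-functional states of the planar dye."""
    return ts.ExcitationSet.from_pairs("B3LYP", [(2.69, 0.8692), (2.92, 0.1259)])


@pytest.fixture(scope="session")
def planar_spectrum(model):
    return ts.broaden(model.reference_excitations)


@pytest.fixture
def simple_spectrum():
    """A single symmetric Gaussian band centered at 500 nm."""
    wl = np.arange(300.0, 800.0, 0.5)
    return ts.Spectrum(wl, np.exp(-((wl - 500.0) ** 2) / (2 * 20.0**2)))
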