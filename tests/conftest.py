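import numpy as np
import pytest

from translume import hypercube as hc


@pytest.fixture
def rng():
    return np.random.default_rng(20260)


def make_hsc(spectra: np.ndarray, wavelength_nm: np.ndarray) -> hc.HyperSpectralCube:
    """Cube from an (nx, ny, n_lambda) spectra array on a unit-mm grid."""
    nx, ny, _ = spectra.shape
    return hc.HyperSpectralCube(
        intensity=spectra,
        x_mm=np.arange(nx, dtype=float),
        y_mm=np.arange(ny, dtype=float),
        wavelength_nm=wavelength_nm,
    )


@pytest.fixture
def hsc_factory():
    return make_hsc
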