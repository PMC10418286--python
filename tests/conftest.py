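import numpy as np
import pytest

from specklesim import OpticalMedium, SpeckleOptics


@pytest.fixture(scope="session")
def tissue_medium() -> OpticalMedium:
    """Tissue-mimicking optical properties at 785 nm."""
    return OpticalMedium(
        mu_a=0.1, mu_s_prime=10.0, n_index=1.33, alpha_Db=1e-8, wavelength=785.0
    )


@pytest.fixture(scope="session")
def unpolarized_optics() -> SpeckleOptics:
    """3-pixel speckles from an unpolarized source (beta = 0.5)."""
    return SpeckleOptics(speckle_diameter=3, beta=0.5)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
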