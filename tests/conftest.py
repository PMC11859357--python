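import numpy as np
import pytest

from nirskin import (
    ChromophoreSet,
    default_skin_model,
    gen_chromophore_fixture,
)


@pytest.fixture(scope="session")
def chromophores() -> ChromophoreSet:
    return gen_chromophore_fixture()


@pytest.fixture(scope="session")
def skin_model(chromophores):
    return default_skin_model(chromophores)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_chromophores() -> ChromophoreSet:
    """A coarse three-point grid with hand-pickable values."""
    wl = np.array([1000.0, 1350.0, 1700.0])
    return ChromophoreSet(
        wavelengths=wl,
        mu_a_water=np.array([0.5, 10.0, 5.0]),
        mu_a_blood=np.array([2.0, 8.0, 7.0]),
        mu_a_other=np.array([1.0, 3.0, 2.0]),
    )
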