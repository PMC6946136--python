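import numpy as np
import pytest

from zetasim import Domain, FullParams


@pytest.fixture
def table_params() -> FullParams:
    """The standard physical parameterization: glucose-like resource
    diffusion, 1000x slower bacterial diffusion, 10% mutant benefit."""
    return FullParams(D_B=1.8e-5, D_R=1.8e-2, mu=(0.11, 0.10),
                      k=1.0, lam=1.0, R0=100.0)


@pytest.fixture
def small_torus() -> Domain:
    return Domain(nx=21, ny=21, dx=5.0 / 21, boundary="torus")


@pytest.fixture
def small_square() -> Domain:
    return Domain(nx=21, ny=21, dx=5.0 / 21, boundary="no_flux")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
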