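import numpy as np
import pytest

from elastishape.meshkit import (
    hex_fan,
    icosphere,
    noisy,
    plane_grid,
    single_triangle,
    two_triangle_square,
)


@pytest.fixture(scope="session")
def unit_triangle():
    return single_triangle()


@pytest.fixture(scope="session")
def unit_square():
    return two_triangle_square()


@pytest.fixture(scope="session")
def fan():
    return hex_fan()


@pytest.fixture(scope="session")
def grid():
    return plane_grid(6, 6)


@pytest.fixture(scope="session")
def sphere1():
    """Icosphere at subdivision 1: 42 vertices, 80 faces."""
    return icosphere(1)


@pytest.fixture(scope="session")
def bumpy_sphere():
    """A seeded, slightly jittered sphere: generic geometry, no symmetries."""
    return noisy(icosphere(1), 0.02, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
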