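import numpy as np
import pytest

from hexamig.grid import Grid2D
from hexamig.patic_core import MaterialParams


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def params():
    return MaterialParams()


@pytest.fixture(scope="session")
def grid32():
    return Grid2D(32, 32)


def smooth_random_psi(grid, rng, amp=0.3, kmax=3):
    """Band-limited random complex field around unit magnitude."""
    ny, nx = grid.shape
    f = np.zeros((ny, nx), dtype=complex)
    for _ in range(6):
        kx = rng.integers(-kmax, kmax + 1)
        ky = rng.integers(-kmax, kmax + 1)
        c = rng.normal() + 1j * rng.normal()
        x, y = grid.coords()
        f += c * np.exp(2j * np.pi * (kx * x / (nx * grid.dx)
                                      + ky * y / (ny * grid.dy)))
    f /= max(1.0, np.abs(f).max())
    return (1.0 + amp * f) * np.exp(1j * amp * f.imag)


@pytest.fixture(scope="session")
def thermalized_quadrupole(params):
    """Shared thermalised quadrupole on a 96x96 grid (ell=7, R_D=28)."""
    from hexamig.hydro import init_quadrupole, thermalize

    g = Grid2D(96, 96)
    st = init_quadrupole(g, ell=7.0, R_D=28.0, seed=1)
    return thermalize(st, params)
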