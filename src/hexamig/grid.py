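"""Doubly periodic square grid and centred finite-difference operators.

All fields in this package live on a 2D torus with array shape ``(ny, nx)``,
row index = y, column index = x, and unit spacing by default (the lattice
units of the continuum model).  Derivatives are second-order centred
stencils; the spectral Poisson inverse used by the flow solver is exact for
the discrete Fourier modes of the torus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class Grid2D:
    """Periodic rectangular grid.

    Attributes
    ----------
    nx, ny : int
        Number of nodes along x (columns) and y (rows).  At least 8 each.
    dx, dy : float
        Grid spacings; unity in the model's lattice units.
    """

    nx: int
    ny: int
    dx: float = 1.0
    dy: float = 1.0

    def __post_init__(self) -> None:
        if self.nx < 8 or self.ny < 8:
            raise ValueError(f"grid too small: {self.nx} x {self.ny} (need >= 8)")
        if self.dx <= 0 or self.dy <= 0:
            raise ValueError("grid spacings must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)

    @property
    def area(self) -> float:
        return self.nx * self.dx * self.ny * self.dy

    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Node coordinates ``(x, y)``, each of shape (ny, nx)."""
        x = np.arange(self.nx) * self.dx
        y = np.arange(self.ny) * self.dy
        return np.meshgrid(x, y)

    def centered_coords(self, x0: float, y0: float) -> tuple[np.ndarray, np.ndarray]:
        """Minimum-image displacements from ``(x0, y0)`` to every node."""
        x, y = self.coords()
        lx, ly = self.nx * self.dx, self.ny * self.dy
        dx = (x - x0 + lx / 2) % lx - lx / 2
        dy = (y - y0 + ly / 2) % ly - ly / 2
        return dx, dy

    # -- centred stencils ---------------------------------------------------

    def ddx(self, f: np.ndarray) -> np.ndarray:
        return (np.roll(f, -1, axis=1) - np.roll(f, 1, axis=1)) / (2 * self.dx)

    def ddy(self, f: np.ndarray) -> np.ndarray:
        return (np.roll(f, -1, axis=0) - np.roll(f, 1, axis=0)) / (2 * self.dy)

    def laplacian(self, f: np.ndarray) -> np.ndarray:
        return ((np.roll(f, -1, axis=1) + np.roll(f, 1, axis=1) - 2 * f) / self.dx**2
                + (np.roll(f, -1, axis=0) + np.roll(f, 1, axis=0) - 2 * f) / self.dy**2)

    def dminus(self, f: np.ndarray) -> np.ndarray:
        """Complex derivative (d/dx - i d/dy): lowers the spin of a harmonic."""
        return self.ddx(f) - 1j * self.ddy(f)

    def dplus(self, f: np.ndarray) -> np.ndarray:
        """Complex derivative (d/dx + i d/dy): raises the spin of a harmonic."""
        return self.ddx(f) + 1j * self.ddy(f)

    def apply_n(self, op, f: np.ndarray, n: int) -> np.ndarray:
        for _ in range(n):
            f = op(f)
        return f

    # -- spectral Poisson inverse ------------------------------------------

    def poisson_periodic(self, rhs: np.ndarray) -> np.ndarray:
        """Solve lap(u) = rhs on the torus; the zero mode of rhs is discarded
        and the solution has zero mean.  Uses the eigenvalues of the 5-point
        Laplacian so that ``laplacian(poisson_periodic(r)) == r`` discretely.
        """
        ky = np.fft.fftfreq(self.ny) * 2 * np.pi
        kx = np.fft.fftfreq(self.nx) * 2 * np.pi
        ex = (2 * np.cos(kx) - 2) / self.dx**2
        ey = (2 * np.cos(ky) - 2) / self.dy**2
        eig = ey[:, None] + ex[None, :]
        eig[0, 0] = 1.0
        rh = np.fft.fft2(rhs)
        rh[0, 0] = 0.0
        u = np.fft.ifft2(rh / eig)
        return u.real if np.isrealobj(rhs) else u
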