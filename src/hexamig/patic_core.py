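"""Hexatic (p = 6) order parameter: free energy, molecular field, stresses.

The order parameter is the complex field ``psi = |Psi6| e^{6 i theta}`` on a
periodic grid.  All rank-6 tensor operations are carried out in the complex
representation (see :mod:`hexamig.tensors`), in which the order tensor is
``q = psi / 8`` and the Landau free energy

    F = int dA [ L6/2 |grad Q6|^2 + A6/2 |Q6|^2 + B6/4 |Q6|^4 ]

becomes, using |Q6|^2 = |psi|^2 / 2,

    F = int dA [ L6/4 |grad psi|^2 + A6/4 |psi|^2 + B6/16 |psi|^4 ].

Spin bookkeeping for the stress formulas: contracting k indices of a
traceless-symmetric rank-p tensor with derivatives maps the complex
representation ``t -> (d/dx - i d/dy)^k t`` (spin lowering); the
traceless-symmetric projection of ``grad^{(x)4} (x) u`` maps the strain's
representation ``s_u -> (d/dx + i d/dy)^4 s_u / 16`` (spin raising).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .grid import Grid2D

__all__ = [
    "MaterialParams",
    "equilibrium_magnitude",
    "active_length",
    "free_energy",
    "molecular_field",
    "relaxation_rhs",
    "stresses",
]


@dataclass(frozen=True)
class MaterialParams:
    """Material constants of the active hexatic continuum, in lattice units.

    Defaults are the reference parameter set used throughout: rho = 1,
    eta = 1, L6 = 0.5, A6 = -0.2, B6 = 0.4 (so the equilibrium magnitude is
    exactly 1), Gamma6 = 1, lambda6 = 1.11.  The higher-order flow coupling
    nu6 has no published reference value and defaults to zero.  alpha6 < 0
    is extensile activity, alpha6 > 0 contractile.
    """

    L6: float = 0.5
    A6: float = -0.2
    B6: float = 0.4
    Gamma6: float = 1.0
    lambda6: float = 1.11
    nu6: float = 0.0
    eta: float = 1.0
    rho: float = 1.0
    alpha6: float = 0.0

    def __post_init__(self) -> None:
        if self.B6 <= 0 or self.eta <= 0 or self.rho <= 0 or self.Gamma6 <= 0:
            raise ValueError("require B6, eta, rho, Gamma6 > 0")

    def with_(self, **kw) -> "MaterialParams":
        return replace(self, **kw)


def equilibrium_magnitude(A6: float, B6: float) -> float:
    """Magnitude |Psi6| minimising the uniform Landau energy: sqrt(-2 A6/B6)."""
    if A6 >= 0 or B6 <= 0:
        raise ValueError("ordered state requires A6 < 0 and B6 > 0")
    return float(np.sqrt(-2.0 * A6 / B6))


def active_length(alpha6: float, L6: float) -> float:
    """Active hexatic length ell6 = sqrt(|alpha6| / L6): cluster size above
    which activity overcomes the passive Coulomb-like defect attraction."""
    if L6 <= 0:
        raise ValueError("L6 must be positive")
    return float(np.sqrt(abs(alpha6) / L6))


def free_energy(psi: np.ndarray, params: MaterialParams, grid: Grid2D):
    """Total orientational free energy and its areal density map.

    Returns ``(F, density)`` with centred-difference gradients.
    """
    # forward differences: the discrete adjoint of the 5-point Laplacian in
    # the molecular field, so H is the exact functional gradient of F
    px = (np.roll(psi, -1, axis=1) - psi) / grid.dx
    py = (np.roll(psi, -1, axis=0) - psi) / grid.dy
    grad2 = np.abs(px) ** 2 + np.abs(py) ** 2
    mag2 = np.abs(psi) ** 2
    dens = (params.L6 / 4.0) * grad2 + (params.A6 / 4.0) * mag2 + (params.B6 / 16.0) * mag2**2
    return float(dens.sum() * grid.dx * grid.dy), dens


def molecular_field(psi: np.ndarray, params: MaterialParams, grid: Grid2D) -> np.ndarray:
    """Variational derivative H = -dF/dpsi* of the implemented functional.

    Vanishes for any uniform state at the equilibrium magnitude.  With the
    pairing <H, dpsi> = 2 Re int conj(H) dpsi, this is minus the functional
    gradient of F.
    """
    lap = grid.laplacian(psi)
    return 0.25 * (params.L6 * lap - params.A6 * psi
                   - 0.5 * params.B6 * np.abs(psi) ** 2 * psi)


def relaxation_rhs(psi: np.ndarray, params: MaterialParams, grid: Grid2D) -> np.ndarray:
    """Time derivative of psi under pure rotational relaxation.

    This is the scalar transcription of the tensor law dQ6/dt = Gamma6 H6;
    translating the tensor mobility to the psi normalisation gives
    dpsi/dt = 4 Gamma6 H(psi).
    """
    return 4.0 * params.Gamma6 * molecular_field(psi, params, grid)


def _strain_rep(vx: np.ndarray, vy: np.ndarray, grid: Grid2D) -> np.ndarray:
    """Complex representation of the traceless strain rate:
    s_u = (u_xx - u_yy)/2 + i u_xy."""
    uxx = grid.ddx(vx)
    uyy = grid.ddy(vy)
    uxy = 0.5 * (grid.ddx(vy) + grid.ddy(vx))
    return 0.5 * (uxx - uyy) + 1j * uxy


def stresses(psi: np.ndarray, velocity, params: MaterialParams, grid: Grid2D) -> dict:
    """All stress contributions as explicit 2x2 tensor fields.

    Returns a dict with keys ``viscous``, ``elastic``, ``reactive``,
    ``active``, each of shape (ny, nx, 2, 2).

    * viscous:  2 eta [[u]]
    * elastic:  sigma^e_ij = -L6  d_i Q6 . d_j Q6   (full contraction;
      carries an isotropic part that is physically absorbed by pressure)
    * reactive: -lambda6 grad^{(x)4} . H6  (symmetric, traceless)
      + 3 (Q6 . H6 - H6 . Q6) (antisymmetric; the dot contracts all but one
      index of each factor, the only pairing that yields a rank-2 stress)
    * active:   alpha6 grad^{(x)4} . Q6
    """
    ny, nx = psi.shape
    if velocity is None:
        vx = np.zeros((ny, nx))
        vy = np.zeros((ny, nx))
    else:
        vx, vy = velocity

    out = {}

    # viscous: 2 eta [[u]]; with incompressible flow u is already traceless
    uxx = grid.ddx(vx)
    uyy = grid.ddy(vy)
    uxy = 0.5 * (grid.ddx(vy) + grid.ddy(vx))
    tl = 0.5 * (uxx - uyy)
    visc = np.empty((ny, nx, 2, 2))
    visc[..., 0, 0] = 2 * params.eta * tl
    visc[..., 1, 1] = -2 * params.eta * tl
    visc[..., 0, 1] = visc[..., 1, 0] = 2 * params.eta * uxy
    out["viscous"] = visc

    # elastic: -L6 d_i Q6 . d_j Q6 = -(L6/2) Re(d_i psi conj(d_j psi))
    px = grid.ddx(psi)
    py = grid.ddy(psi)
    el = np.empty((ny, nx, 2, 2))
    el[..., 0, 0] = -(params.L6 / 2) * (px * np.conj(px)).real
    el[..., 1, 1] = -(params.L6 / 2) * (py * np.conj(py)).real
    el[..., 0, 1] = el[..., 1, 0] = -(params.L6 / 2) * (px * np.conj(py)).real
    out["elastic"] = el

    # reactive: symmetric part -lambda6 D^4 h6 with h6 = H_psi/8 in the
    # tensor normalisation; antisymmetric part 3(Q.H - H.Q), whose xy
    # component is 96 Im(conj(q) h) = (3/2) Im(conj(psi) H_psi).
    hpsi = 4.0 * molecular_field(psi, params, grid)  # tensor-normalised, psi units
    s_r = -(params.lambda6 / 8.0) * grid.apply_n(grid.dminus, hpsi, 4)
    tau = 1.5 * (np.conj(psi) * hpsi).imag
    re = np.empty((ny, nx, 2, 2))
    re[..., 0, 0] = s_r.real
    re[..., 1, 1] = -s_r.real
    re[..., 0, 1] = s_r.imag + tau
    re[..., 1, 0] = s_r.imag - tau
    out["reactive"] = re

    # active: alpha6 D^4 q6, q6 = psi/8
    s_a = (params.alpha6 / 8.0) * grid.apply_n(grid.dminus, psi, 4)
    ac = np.empty((ny, nx, 2, 2))
    ac[..., 0, 0] = s_a.real
    ac[..., 1, 1] = -s_a.real
    ac[..., 0, 1] = ac[..., 1, 0] = s_a.imag
    out["active"] = ac

    return out
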