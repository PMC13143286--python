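"""Closed-form fields of the +-1/6 disclination quadrupole.

The quadrupole is the defect signature of the four-cell (5-7-5-7) cluster at
the midpoint of a T1 rearrangement: two -1/6 disclinations on the x-axis at
(+-ell, 0) and two +1/6 disclinations on the y-axis at (0, +-ell).  This
module provides

* the exact orientation field ``theta_exact`` (sum of the four defect
  angles) and its quadrupolar far field ``theta_farfield``;
* the electrostatic-style multipole coefficients of the dual potential;
* the closed-form active force sourced by the quadrupole's hexatic stress;
* the Stokes flow it drives, both as a numerical Oseen quadrature over the
  annulus ell < r' < R and as its closed-form evaluation, plus the compact
  near-cluster approximation (stagnation / convergent-extension flow).

A note on branches: the four-term angle sum must use the full two-argument
polar angle of each displacement.  Its 2*pi jumps enter theta as pi/3 jumps,
invisible in e^{6 i theta}; a single-argument arctan of the coordinate ratio
cannot represent +-1/6 defects at all.  All angular comparisons should be
made on e^{6 i theta} or after mod-pi/3 reduction.

A note on amplitudes: expanding the exact sum at r >> ell gives
theta = -ell^2 sin(2 phi) / (3 r^2), the amplitude also implied by the
multipole coefficient a2 = -ell^2/3 and by the closed-form active force; the
far-field function here uses that self-consistent amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "QuadrupoleSpec",
    "MultipoleResult",
    "theta_exact",
    "theta_farfield",
    "multipole_coefficients",
    "active_force",
    "flow_nearfield",
    "flow_full",
    "oseen_point_force",
    "oseen_flow_numeric",
]


@dataclass(frozen=True)
class QuadrupoleSpec:
    """Geometry and material constants of the defect quadrupole.

    ``ell`` is the half-spacing (distance from the cluster centre to each
    core); charges are fixed: -1/6 at (+-ell, 0), +1/6 at (0, +-ell).
    """

    ell: float = 1.0
    alpha6: float = 1.0
    eta: float = 1.0

    def __post_init__(self) -> None:
        if self.ell <= 0:
            raise ValueError("ell must be positive")

    @property
    def charges_positions(self):
        e = self.ell
        return [(-1 / 6, (e, 0.0)), (-1 / 6, (-e, 0.0)),
                (+1 / 6, (0.0, e)), (+1 / 6, (0.0, -e))]


@dataclass(frozen=True)
class MultipoleResult:
    a: np.ndarray
    b: np.ndarray


def theta_exact(x, y, spec: QuadrupoleSpec = QuadrupoleSpec()):
    """Exact quadrupole orientation: signed sum of the four polar angles.

    Reported in (-pi, pi]; physically meaningful modulo pi/3.  Raises if
    evaluated exactly at a defect core.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    th = np.zeros(np.broadcast(x, y).shape)
    for s, (cx, cy) in spec.charges_positions:
        ddx, ddy = x - cx, y - cy
        if np.any((ddx == 0) & (ddy == 0)):
            raise ValueError("evaluation at a defect core")
        th = th + 6 * s * np.arctan2(ddy, ddx)
    th = th / 6.0
    th = np.angle(np.exp(1j * th))
    return th if th.shape else float(th)


def theta_farfield(x, y, spec: QuadrupoleSpec = QuadrupoleSpec()):
    """Leading far-field orientation -ell^2 sin(2 phi) / (3 r^2).

    The dipole moment of the quadrupole vanishes, and so do all corrections
    up to relative order (ell/r)^4, so |theta_exact - theta_farfield|
    decays as r^-6.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    r2 = x * x + y * y
    if np.any(r2 == 0):
        raise ValueError("far field undefined at the origin")
    # sin(2 phi)/r^2 = 2 x y / r^4
    out = -spec.ell**2 * (2 * x * y) / (3 * r2 * r2)
    return out if out.shape else float(out)


def multipole_coefficients(spec: QuadrupoleSpec, n_max: int) -> MultipoleResult:
    """Multipole coefficients of the dual (electrostatic) potential.

    a_n = (1/n) sum_k s_k r_k^n cos(n phi_k), likewise b_n with sin; a_0 is
    the total strength.  For the quadrupole a0 = a1 = b1 = 0 and
    a2 = -ell^2/3, b2 = 0.
    """
    if n_max < 2:
        raise ValueError("n_max must be >= 2")
    a = np.zeros(n_max + 1)
    b = np.zeros(n_max + 1)
    scale = np.zeros(n_max + 1)
    for s, (cx, cy) in spec.charges_positions:
        r = np.hypot(cx, cy)
        ph = np.arctan2(cy, cx)
        a[0] += s
        scale[0] += abs(s)
        for n in range(1, n_max + 1):
            a[n] += s * r**n * np.cos(n * ph) / n
            b[n] += s * r**n * np.sin(n * ph) / n
            scale[n] += abs(s) * r**n / n
    # snap pure-cancellation residues to exact zeros
    a[np.abs(a) < 1e-13 * scale] = 0.0
    b[np.abs(b) < 1e-13 * scale] = 0.0
    return MultipoleResult(a=a, b=b)


def dual_potential(x, y, spec: QuadrupoleSpec, n_max: int = 8):
    """Multipole reconstruction of the dual field phi(r)."""
    coef = multipole_coefficients(spec, n_max)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    r = np.hypot(x, y)
    ph = np.arctan2(y, x)
    out = np.zeros_like(r)
    for n in range(1, n_max + 1):
        out += (coef.a[n] * np.cos(n * ph) + coef.b[n] * np.sin(n * ph)) / r**n
    return out


def _polar(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return np.hypot(x, y), np.arctan2(y, x)


def active_force(x, y, spec: QuadrupoleSpec = QuadrupoleSpec()):
    """Closed-form active force f = div(sigma_active) of the far-field
    quadrupole, valid for r > ell:

        f = 960 alpha6 ell^2 / r^7 * { [-3 cos7phi
              + (ell/r)^2 (3 cos5phi - 14 cos9phi)] e_x
              + [3 sin7phi - (ell/r)^2 (3 sin5phi - 14 sin9phi)] e_y }.

    Returns (fx, fy).
    """
    r, ph = _polar(x, y)
    if np.any(r < spec.ell * (1 - 1e-12)):
        raise ValueError("active_force is valid only outside the cluster (r >= ell)")
    e2 = (spec.ell / r) ** 2
    pre = 960 * spec.alpha6 * spec.ell**2 / r**7
    fx = pre * (-3 * np.cos(7 * ph) + e2 * (3 * np.cos(5 * ph) - 14 * np.cos(9 * ph)))
    fy = pre * (3 * np.sin(7 * ph) - e2 * (3 * np.sin(5 * ph) - 14 * np.sin(9 * ph)))
    return fx, fy


def force_harmonics(spec: QuadrupoleSpec):
    """The active force as complex harmonics: F = fx + i fy =
    sum_m c_m(r) e^{i m phi}; returns {m: callable c_m(r)}."""
    a, e = spec.alpha6, spec.ell
    return {
        -7: lambda r: -2880 * a * e**2 / r**7,
        -5: lambda r: 2880 * a * e**4 / r**9,
        -9: lambda r: -13440 * a * e**4 / r**9,
    }


def flow_nearfield(x, y, spec: QuadrupoleSpec = QuadrupoleSpec()):
    """Compact near-cluster approximation of the quadrupole flow:

        v = (120 alpha6 ell^4 / eta)
            [4 - 6 log(r/ell) - 3 r^2/ell^2] cos(6 phi) r_vec / r^8 .

    For r slightly above ell this is a stagnation (local convergent
    extension) flow: with extensile activity (alpha6 < 0) material moves
    inward along x and outward along y.  Returns (vx, vy); requires r >= ell.
    """
    r, ph = _polar(x, y)
    if np.any(r < spec.ell):
        raise ValueError("flow_nearfield requires r >= ell")
    rho = r / spec.ell
    amp = (120 * spec.alpha6 * spec.ell**4 / spec.eta) * \
        (4 - 6 * np.log(rho) - 3 * rho**2) * np.cos(6 * ph) / r**7
    return amp * np.cos(ph), amp * np.sin(ph)


def _flow_full_harmonics(rho: np.ndarray) -> dict[int, np.ndarray]:
    """Radial profiles C_n(rho) of the closed-form Oseen-annulus flow,
    V = (alpha6 / (eta ell^3)) sum_n C_n(rho) e^{i n phi}, rho = r/ell.

    Derived by reducing the Oseen convolution over the annulus
    rho' in [1, inf) harmonic by harmonic (log expansion of the kernel plus
    trigonometric orthogonality); every coefficient verified against a
    brute-force two-dimensional quadrature of the Oseen integral.
    """
    lr = np.log(rho)
    return {
        -7: -(360 / 7) * (rho**2 - 1) / rho**7 - (60 / 7) / rho**5,
        -5: 72 / rho**5 - 60 / rho**7,
        -9: -(560 / 3) * (rho**2 - 1) / rho**9 - (70 / 3) / rho**7,
        +7: 360 * (1 - rho**-2) / rho**5 - 720 * lr / rho**7,
        +9: -720 * ((rho**2 - 1) / (2 * rho**7) - (rho**4 - 1) / (4 * rho**9)),
        +11: -3360 * ((rho**2 - 1) / (2 * rho**9) - (rho**4 - 1) / (4 * rho**11)),
    }


def flow_full(x, y, spec: QuadrupoleSpec = QuadrupoleSpec()):
    """Closed-form Stokes flow of the quadrupole's active force.

    Evaluates the R -> infinity limit of the Oseen solution over the annulus
    ell < r' < R (the Oseen kernel is divergence-free, so the result is
    exactly incompressible).  The flow is odd under r -> -r, as the force
    is.  Returns (vx, vy); requires r > ell.
    """
    r, ph = _polar(x, y)
    if np.any(r <= spec.ell):
        raise ValueError("flow_full is valid only for r > ell")
    rho = r / spec.ell
    V = np.zeros_like(rho, dtype=complex)
    for n, C in _flow_full_harmonics(rho).items():
        V = V + C * np.exp(1j * n * ph)
    V = V * spec.alpha6 / (spec.eta * spec.ell**3)
    return V.real, V.imag


def radial_cos6_harmonic(r, spec: QuadrupoleSpec = QuadrupoleSpec()):
    """Amplitude A(r) of the ``cos(6 phi) e_r`` component of flow_full,
    defined through the spin-(+7) harmonic of vx + i vy (the only harmonic
    that component feeds).  Closed form:

        A(r) = (alpha6 ell^4 / eta) * 720 (rho^2 - 1 - 2 log rho) / r^7 .
    """
    rho = np.asarray(r, dtype=float) / spec.ell
    return (spec.alpha6 * spec.ell**4 / spec.eta) * 720 * \
        (rho**2 - 1 - 2 * np.log(rho)) / (rho * spec.ell) ** 7


def oseen_point_force(x, y, fx, fy, eta: float, L: float):
    """Velocity of a 2D point force via the Oseen tensor
    G = [ (log(L/r) - 1) 1 + r (x) r / r^2 ] / (4 pi eta)."""
    r2 = np.asarray(x) ** 2 + np.asarray(y) ** 2
    lg = np.log(L / np.sqrt(r2)) - 1.0
    vx = (lg + x * x / r2) * fx + (x * y / r2) * fy
    vy = (x * y / r2) * fx + (lg + y * y / r2) * fy
    return vx / (4 * np.pi * eta), vy / (4 * np.pi * eta)


def oseen_flow_numeric(force, eta: float, ell: float, R_cutoff: float,
                       r_eval, n_radial: int = 4000, n_phi: int = 256,
                       m_max: int = 16):
    """Oseen solution for an arbitrary force density over the annulus
    ell < r' < R_cutoff, evaluated on circles r = r_eval.

    ``force(x, y) -> (fx, fy)`` is sampled on a log-spaced radial grid and a
    uniform angular grid; an FFT gives its complex harmonics c_m(r')
    (F = fx + i fy = sum_m c_m e^{i m phi'}), after which the angular
    integrals of the Oseen kernel (with the constant set to
    L = R_cutoff sqrt(e)) are performed exactly:

    * the isotropic (log) part maps harmonic m to itself with radial weight
      (r_< / r_>)^{|m|} / |m| (plus log(L/r_>) - 1/2 for m = 0);
    * the traceless part maps harmonic m of conj(F) to the output harmonic
      2 - m, fed only by sources with r' < r, weight
      (r'/r)^{|m|} - (r'/r)^{|m|+2} (m < 0; mirrored for m > 2).

    The remaining 1D radial integrals are done by Simpson quadrature in
    log r'.  Returns ``(phis, V)`` with V[i, j] = (vx + i vy)(r_eval[i],
    phis[j]).  The result is divergence-free to quadrature accuracy.
    """
    from scipy.integrate import simpson

    if R_cutoff <= ell:
        raise ValueError("R_cutoff must exceed ell")
    r_eval = np.atleast_1d(np.asarray(r_eval, dtype=float))
    t = np.linspace(np.log(ell), np.log(R_cutoff), n_radial)
    rp = np.exp(t)
    phis_src = np.linspace(0, 2 * np.pi, n_phi, endpoint=False)
    X = rp[:, None] * np.cos(phis_src)[None, :]
    Y = rp[:, None] * np.sin(phis_src)[None, :]
    fx, fy = force(X, Y)
    F = fx + 1j * fy
    cm = np.fft.fft(F, axis=1) / n_phi  # c_m(r'), m = fftfreq order

    ms = np.fft.fftfreq(n_phi, d=1.0 / n_phi).astype(int)
    phis = np.linspace(0, 2 * np.pi, n_phi, endpoint=False)
    V = np.zeros((r_eval.size, n_phi), dtype=complex)
    L = R_cutoff * np.sqrt(np.e)

    for im, m in enumerate(ms):
        if abs(m) > m_max:
            continue
        c = cm[:, im]
        if np.max(np.abs(c)) == 0:
            continue
        for ir, r in enumerate(r_eval):
            inside = rp <= r
            # isotropic part: same output harmonic m
            if m == 0:
                w = 2.0 * np.where(inside, np.log(L / r) - 0.5, np.log(L / rp) - 0.5)
            else:
                rr = np.where(inside, rp / r, r / rp)
                w = rr ** abs(m) / abs(m)
            I1 = simpson(rp**2 * c * w, x=t)
            V[ir] += (I1 / (4 * eta)) * np.exp(1j * m * phis)
            # traceless part: output harmonic 2 - m, from conj(F) harmonic m
            if m <= -1:
                w2 = np.where(inside, (rp / r) ** abs(m) - (rp / r) ** (abs(m) + 2), 0.0)
            elif m >= 3:
                w2 = np.where(~inside, (r / rp) ** (m - 2) - (r / rp) ** m, 0.0)
            elif m == 1:
                w2 = -np.where(inside, rp / r, r / rp)
            else:  # m == 2
                w2 = np.where(inside, 1 - (rp / r) ** 2, 1 - (r / rp) ** 2)
            I2 = simpson(rp**2 * np.conj(c) * w2, x=t)
            V[ir] += (I2 / (4 * eta)) * np.exp(1j * (2 - m) * phis)
    return phis, V
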