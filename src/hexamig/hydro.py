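"""Vorticity--stream-function solver for active hexatic hydrodynamics.

Evolves the complex order parameter ``psi`` and the scalar vorticity
``zeta = dx vy - dy vx`` on a doubly periodic grid:

    D psi / Dt = 4 Gamma6 H(psi) + 3 i zeta psi
                 + (lambda6/2) (dx + i dy)^4 s_u + 2 nu6 s_u^3
    rho D zeta / Dt = eta lap zeta + Im[(dx - i dy)^2 s_sigma] - lap tau

where ``s_u`` is the complex strain-rate representation, ``s_sigma`` the
complex representation of the traceless symmetric part of the elastic +
reactive + active stresses and ``tau`` the antisymmetric stress.  The
velocity is recovered each step from the stream function
(lap chi = -zeta, v = (dy chi, -dx chi)), so incompressibility is exact by
construction.  Time stepping is a predictor--corrector (Heun) Euler scheme
with centred second-order space stencils.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import Grid2D
from .patic_core import MaterialParams, free_energy, molecular_field
from .quadrupole import QuadrupoleSpec, theta_exact

__all__ = [
    "HydroState",
    "DefectRecord",
    "DefectTrajectory",
    "init_quadrupole",
    "init_dipole",
    "thermalize",
    "step",
    "detect_defects_field",
    "track_defects",
    "annihilation_time",
    "run_quadrupole_experiment",
    "run_dipole_experiment",
]


@dataclass
class HydroState:
    grid: Grid2D
    psi: np.ndarray
    zeta: np.ndarray
    time: float = 0.0
    step_count: int = 0
    pinned: np.ndarray | None = None  # mask where psi is held fixed
    meta: dict = field(default_factory=dict)

    def velocity(self) -> tuple[np.ndarray, np.ndarray]:
        chi = self.grid.poisson_periodic(-self.zeta)
        return self.grid.ddy(chi), -self.grid.ddx(chi)

    def copy(self) -> "HydroState":
        return HydroState(self.grid, self.psi.copy(), self.zeta.copy(),
                          self.time, self.step_count,
                          None if self.pinned is None else self.pinned.copy(),
                          dict(self.meta))


@dataclass(frozen=True)
class DefectRecord:
    x: float
    y: float
    charge: float
    time: float = 0.0


@dataclass
class DefectTrajectory:
    charge: float
    times: list
    xs: list
    ys: list
    ended: bool = False  # terminated before the last frame (annihilation)


# ---------------------------------------------------------------------------
# initial conditions

def _random_phase(grid: Grid2D, rng: np.random.Generator) -> np.ndarray:
    """Unit-modulus field with independent uniform phase per node,
    theta in [0, pi/3)."""
    return np.exp(6j * rng.uniform(0, np.pi / 3, grid.shape))


def init_quadrupole(grid: Grid2D, ell: float = 7.0, R_D: float = 28.0,
                    seed: int = 0) -> HydroState:
    """Quadrupole initial condition: |psi| = 1 everywhere, theta equal to
    the exact four-defect angle field inside the disk of radius R_D around
    the grid centre, independent random phase outside.  The disk is pinned
    for the thermalisation stage."""
    if R_D <= ell:
        raise ValueError("R_D must exceed ell")
    if 2 * R_D >= min(grid.nx * grid.dx, grid.ny * grid.dy):
        raise ValueError("pinned disk does not fit in the periodic box")
    x0, y0 = grid.nx * grid.dx / 2, grid.ny * grid.dy / 2
    dx, dy = grid.centered_coords(x0, y0)
    r = np.hypot(dx, dy)
    spec = QuadrupoleSpec(ell=ell)
    # keep cores off grid nodes: exact layout puts them at lattice points,
    # so evaluate displaced by half a spacing
    th = theta_exact(dx + 0.5 * grid.dx, dy + 0.5 * grid.dy, spec)
    rng = np.random.default_rng(seed)
    psi = _random_phase(grid, rng)
    inside = r <= R_D
    psi[inside] = np.exp(6j * th[inside])
    return HydroState(grid, psi, np.zeros(grid.shape), pinned=inside,
                      meta={"ell": ell, "R_D": R_D, "seed": seed,
                            "center": (x0, y0), "kind": "quadrupole"})


def init_dipole(grid: Grid2D, dx_sep: float = 64.0, R_D: float = 5.0,
                seed: int = 0, exterior: str = "field") -> HydroState:
    """+-1/6 dipole on the x-axis at separation dx_sep: theta is the signed
    two-defect angle composition inside a disk of radius R_D around each
    core, and either the same smooth field (``exterior="field"``, default:
    guarantees the protocol's stated end state of exactly two defects) or
    an independent random phase (``exterior="random"``) outside.  The
    initial condition is mirror-symmetric about the x-axis."""
    if dx_sep >= grid.nx * grid.dx - 4 * R_D:
        raise ValueError("separation too large for the periodic box")
    x0, y0 = grid.nx * grid.dx / 2, grid.ny * grid.dy / 2
    dx, dy = grid.centered_coords(x0, y0)
    xp, yp = dx - dx_sep / 2 + 0.5 * grid.dx, dy + 0.5 * grid.dy
    xm, ym = dx + dx_sep / 2 + 0.5 * grid.dx, dy + 0.5 * grid.dy
    th = (np.arctan2(yp, xp) - np.arctan2(ym, xm)) / 6.0
    if exterior == "field":
        psi = np.exp(6j * th)
    elif exterior == "random":
        rng = np.random.default_rng(seed)
        psi = _random_phase(grid, rng)
    else:
        raise ValueError("exterior must be 'field' or 'random'")
    disks = (np.hypot(xp, yp) <= R_D) | (np.hypot(xm, ym) <= R_D)
    psi[disks] = np.exp(6j * th[disks])
    return HydroState(grid, psi, np.zeros(grid.shape), pinned=disks,
                      meta={"dx_sep": dx_sep, "R_D": R_D, "seed": seed,
                            "center": (x0, y0), "kind": "dipole"})


# ---------------------------------------------------------------------------
# dynamics

def _psi_rhs(psi, vx, vy, zeta, params: MaterialParams, grid: Grid2D):
    h = 4.0 * params.Gamma6 * molecular_field(psi, params, grid)
    rhs = h
    if vx is not None:
        adv = vx * grid.ddx(psi) + vy * grid.ddy(psi)
        rhs = rhs - adv + 3j * zeta * psi
        if params.lambda6 != 0.0 or params.nu6 != 0.0:
            uxx = grid.ddx(vx)
            uyy = grid.ddy(vy)
            uxy = 0.5 * (grid.ddx(vy) + grid.ddy(vx))
            s_u = 0.5 * (uxx - uyy) + 1j * uxy
            if params.lambda6 != 0.0:
                rhs = rhs + 0.5 * params.lambda6 * grid.apply_n(grid.dplus, s_u, 4)
            if params.nu6 != 0.0:
                rhs = rhs + 2.0 * params.nu6 * s_u**3
    return rhs


def _zeta_rhs(psi, vx, vy, zeta, params: MaterialParams, grid: Grid2D):
    # curl of the divergence of the non-viscous stresses, in complex form
    hpsi = 4.0 * molecular_field(psi, params, grid)
    px = grid.ddx(psi)
    py = grid.ddy(psi)
    s_el = -(params.L6 / 4.0) * ((px * np.conj(px)).real - (py * np.conj(py)).real
                                 + 2j * (px * np.conj(py)).real)
    s_total = s_el - (params.lambda6 / 8.0) * grid.apply_n(grid.dminus, hpsi, 4)
    if params.alpha6 != 0.0:
        s_total = s_total + (params.alpha6 / 8.0) * grid.apply_n(grid.dminus, psi, 4)
    curl_sym = grid.apply_n(grid.dminus, s_total, 2).imag
    tau = 1.5 * (np.conj(psi) * hpsi).imag
    curl_f = curl_sym - grid.laplacian(tau)
    visc = params.eta * grid.laplacian(zeta)
    adv = vx * grid.ddx(zeta) + vy * grid.ddy(zeta)
    return (visc + curl_f) / params.rho - adv


def step(state: HydroState, params: MaterialParams, dt: float = 0.1,
         pin: bool = False) -> HydroState:
    """One predictor--corrector Euler step of the coupled system."""
    g = state.grid
    psi0, z0 = state.psi, state.zeta
    vx0, vy0 = state.velocity()
    dpsi0 = _psi_rhs(psi0, vx0, vy0, z0, params, g)
    dz0 = _zeta_rhs(psi0, vx0, vy0, z0, params, g)
    psi1 = psi0 + dt * dpsi0
    z1 = z0 + dt * dz0
    st1 = HydroState(g, psi1, z1)
    vx1, vy1 = st1.velocity()
    dpsi1 = _psi_rhs(psi1, vx1, vy1, z1, params, g)
    dz1 = _zeta_rhs(psi1, vx1, vy1, z1, params, g)
    psi = psi0 + 0.5 * dt * (dpsi0 + dpsi1)
    zeta = z0 + 0.5 * dt * (dz0 + dz1)
    if pin and state.pinned is not None:
        psi[state.pinned] = psi0[state.pinned]
    if not np.all(np.isfinite(psi)) or not np.all(np.isfinite(zeta)):
        raise FloatingPointError(
            f"solver produced NaN/inf at step {state.step_count + 1}, "
            f"t={state.time + dt:.2f}; try a smaller dt")
    return HydroState(g, psi, zeta, state.time + dt, state.step_count + 1,
                      state.pinned, state.meta)


def thermalize(state: HydroState, params: MaterialParams, dt: float = 0.1,
               rel_tol: float = 1e-3, max_iter: int = 60000,
               min_iter: int = 50, check_every: int = 10,
               require_clean: bool = True) -> HydroState:
    """Purely relaxational equilibration with the defect region pinned.

    Evolves dpsi/dt = 4 Gamma6 H (no flow, no activity), holding psi fixed
    on ``state.pinned``, until the relative free-energy change per iteration
    drops below ``rel_tol`` (0.1% by default) and, with ``require_clean``,
    until no defects remain outside the pinned region (the protocol's stated
    end state: |psi| near the equilibrium magnitude everywhere except the
    cores, stray pairs from the random exterior annihilated).
    """
    g = state.grid
    psi = state.psi.copy()
    pinned = state.pinned
    clean_mask = None
    if pinned is not None and require_clean:
        from scipy.ndimage import binary_dilation
        clean_mask = ~binary_dilation(pinned, iterations=3)
    f_prev, _ = free_energy(psi, params, g)
    for it in range(1, max_iter + 1):
        rhs = 4.0 * params.Gamma6 * molecular_field(psi, params, g)
        psi_pred = psi + dt * rhs
        rhs1 = 4.0 * params.Gamma6 * molecular_field(psi_pred, params, g)
        psi_new = psi + 0.5 * dt * (rhs + rhs1)
        if pinned is not None:
            psi_new[pinned] = psi[pinned]
        psi = psi_new
        if it % check_every == 0:
            f_now, _ = free_energy(psi, params, g)
            converged = (it >= min_iter
                         and abs(f_now - f_prev) < rel_tol * abs(f_now) * check_every)
            f_prev = f_now
            if converged and clean_mask is not None:
                recs = detect_defects_field(psi, g)
                converged = not any(
                    clean_mask[int(r.y / g.dy), int(r.x / g.dx)] for r in recs)
            if converged:
                st = HydroState(g, psi, np.zeros(g.shape), state.time + it * dt,
                                state.step_count + it, pinned, dict(state.meta))
                st.meta["thermalize_iters"] = it
                return st
    raise RuntimeError(
        f"thermalization did not converge within {max_iter} iterations "
        f"(last F={f_prev:.6g}, rel_tol={rel_tol})")


# ---------------------------------------------------------------------------
# defect detection and tracking

def _wrap(d: np.ndarray) -> np.ndarray:
    """Reduce angle increments to the half-open interval (-pi, pi]."""
    return np.pi - (np.pi - d) % (2 * np.pi)


def detect_defects_field(psi: np.ndarray, grid: Grid2D, t: float = 0.0):
    """Per-plaquette winding of theta = Arg(psi)/6 with increments reduced
    to (-pi/6, pi/6]; nonzero windings are +-1/6, ... defects located at
    plaquette centres (periodic wraparound included)."""
    a6 = np.angle(psi)  # 6 theta
    d_right = _wrap(np.roll(a6, -1, axis=1) - a6)
    d_up = _wrap(np.roll(a6, -1, axis=0) - a6)
    # circulation around plaquette (i,j)-(i,j+1)-(i+1,j+1)-(i+1,j), CCW
    circ = (d_right + np.roll(d_up, -1, axis=1)
            - np.roll(d_right, -1, axis=0) - d_up)
    w = np.rint(circ / (2 * np.pi))
    jj, ii = np.nonzero(w)
    out = []
    for j, i in zip(jj, ii):
        out.append(DefectRecord(x=(i + 0.5) * grid.dx, y=(j + 0.5) * grid.dy,
                                charge=w[j, i] / 6.0, time=t))
    return out


def _pdist(ax, ay, bx, by, grid: Grid2D) -> float:
    lx, ly = grid.nx * grid.dx, grid.ny * grid.dy
    dx = (ax - bx + lx / 2) % lx - lx / 2
    dy = (ay - by + ly / 2) % ly - ly / 2
    return float(np.hypot(dx, dy))


def track_defects(frames, grid: Grid2D, max_jump: float = 6.0):
    """Greedy nearest-neighbour linking of per-frame defect lists into
    trajectories; unmatched defects terminate (death) or start (birth)
    tracks.  Equal-distance ties break deterministically by lowest index.
    """
    tracks: list[DefectTrajectory] = []
    active: list[DefectTrajectory] = []
    for recs in frames:
        unmatched = list(range(len(recs)))
        new_active = []
        # match existing tracks in order
        for tr in active:
            best, best_d = None, max_jump
            for k in unmatched:
                r = recs[k]
                if r.charge != tr.charge:
                    continue
                d = _pdist(tr.xs[-1], tr.ys[-1], r.x, r.y, grid)
                if d < best_d:
                    best, best_d = k, d
            if best is None:
                tr.ended = True
            else:
                r = recs[best]
                unmatched.remove(best)
                tr.times.append(r.time)
                tr.xs.append(r.x)
                tr.ys.append(r.y)
                new_active.append(tr)
        for k in unmatched:
            r = recs[k]
            tr = DefectTrajectory(r.charge, [r.time], [r.x], [r.y])
            tracks.append(tr)
            new_active.append(tr)
        active = new_active
    return tracks


def annihilation_time(trajectories, t0: float = 0.0) -> float:
    """Time of the last pair-death event minus the start time t0."""
    ends = [tr.times[-1] for tr in trajectories if tr.ended]
    if not ends:
        raise ValueError("no annihilation event in the trajectories")
    return max(ends) - t0


# ---------------------------------------------------------------------------
# experiments

def _coarse_phase(psi: np.ndarray, grid: Grid2D, x0: float, y0: float,
                  radius: float) -> complex:
    dx, dy = grid.centered_coords(x0, y0)
    m = np.hypot(dx, dy) <= radius
    return complex(psi[m].mean())


def run_quadrupole_experiment(params: MaterialParams, grid: Grid2D,
                              ell: float = 7.0, R_D: float = 28.0,
                              seed: int = 0, dt: float = 0.1,
                              n_steps: int = 6000, sample_every: int = 25,
                              unbind_sep: float | None = None,
                              thermalized: HydroState | None = None) -> dict:
    """Release a thermalised quadrupole under the full active dynamics and
    classify its fate.

    outcome = "unbinding" when the two +-1/6 dipoles separate beyond
    ``unbind_sep`` (default 3 ell), "annihilation" when no defects remain,
    "undecided" if neither happens within the step budget.  Also reports the
    coarse phase rotation at the cluster centre (mod pi/3) and, for
    unbinding runs, the angle between the two dipoles' displacement
    directions (plus the alternative lab-frame reading).
    """
    if unbind_sep is None:
        unbind_sep = 3.0 * ell
    if thermalized is None:
        st = init_quadrupole(grid, ell=ell, R_D=R_D, seed=seed)
        st = thermalize(st, params, dt=dt)
    else:
        st = thermalized.copy()
    st.pinned = None
    x0, y0 = st.meta["center"]
    phase0 = _coarse_phase(st.psi, grid, x0, y0, 0.45 * ell)
    dip0 = None
    frames = [detect_defects_field(st.psi, grid, st.time)]
    report = {"outcome": "undecided", "alpha6": params.alpha6,
              "ell": ell, "seed": seed}
    t_start = st.time
    for k in range(n_steps):
        st = step(st, params, dt)
        if (k + 1) % sample_every:
            continue
        recs = detect_defects_field(st.psi, grid, st.time)
        frames.append(recs)
        if len(recs) == 0:
            report["outcome"] = "annihilation"
            report["annihilation_time"] = st.time - t_start
            break
        dip = _dipole_centers(recs, grid, x0, y0)
        if dip is not None:
            if dip0 is None:
                dip0 = dip
            sep = _pdist(dip[0][0], dip[0][1], dip[1][0], dip[1][1], grid)
            if sep > unbind_sep:
                report["outcome"] = "unbinding"
                report["dipole_separation"] = sep
                d1 = np.array(dip[0]) - np.array(dip0[0])
                d2 = np.array(dip[1]) - np.array(dip0[1])
                if np.linalg.norm(d1) > 0 and np.linalg.norm(d2) > 0:
                    cosang = np.dot(d1, d2) / (np.linalg.norm(d1) * np.linalg.norm(d2))
                    report["dipole_angle"] = float(np.arccos(np.clip(cosang, -1, 1)))
                    report["dipole_angle_lab"] = float(
                        abs(np.arctan2(d1[1], d1[0])) % np.pi)
                break
    phase1 = _coarse_phase(st.psi, grid, x0, y0, 0.45 * ell)
    dtheta = np.angle(phase1 * np.conj(phase0)) / 6.0
    report["delta_theta"] = float(dtheta)  # in (-pi/6, pi/6]
    report["time"] = st.time - t_start
    report["final_defects"] = len(frames[-1])
    report["frames"] = frames
    report["state"] = st
    return report


def _dipole_centers(recs, grid: Grid2D, x0, y0):
    """Pair each +1/6 with its nearest -1/6; returns the two pair centres
    or None unless there are exactly two of each charge."""
    pos = [r for r in recs if r.charge > 0]
    neg = [r for r in recs if r.charge < 0]
    if len(pos) != 2 or len(neg) != 2:
        return None
    d00 = _pdist(pos[0].x, pos[0].y, neg[0].x, neg[0].y, grid)
    d01 = _pdist(pos[0].x, pos[0].y, neg[1].x, neg[1].y, grid)
    pairs = [(pos[0], neg[0]), (pos[1], neg[1])] if d00 <= d01 else \
        [(pos[0], neg[1]), (pos[1], neg[0])]
    out = []
    for p, n in pairs:
        lx, ly = grid.nx * grid.dx, grid.ny * grid.dy
        ddx = (n.x - p.x + lx / 2) % lx - lx / 2
        ddy = (n.y - p.y + ly / 2) % ly - ly / 2
        out.append((p.x + ddx / 2, p.y + ddy / 2))
    return out


def run_dipole_experiment(params: MaterialParams, grid: Grid2D,
                          dx_sep: float = 64.0, R_D: float = 5.0,
                          seed: int = 0, dt: float = 0.1,
                          n_steps: int = 40000, sample_every: int = 25) -> dict:
    """Thermalise a +-1/6 dipole and follow its annihilation under
    activity; returns trajectories and the annihilation time."""
    st = init_dipole(grid, dx_sep=dx_sep, R_D=R_D, seed=seed)
    st = thermalize(st, params, dt=dt)
    st.pinned = None
    t_start = st.time
    frames = [detect_defects_field(st.psi, grid, st.time)]
    annih = None
    for k in range(n_steps):
        st = step(st, params, dt)
        if (k + 1) % sample_every:
            continue
        recs = detect_defects_field(st.psi, grid, st.time)
        frames.append(recs)
        if len(recs) == 0:
            annih = st.time - t_start
            break
    tracks = track_defects(frames, grid)
    return {"annihilation_time": annih, "frames": frames, "tracks": tracks,
            "state": st, "alpha6": params.alpha6}
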