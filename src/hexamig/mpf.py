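"""Multiphase-field (MPF) model of a confluent, self-propelled monolayer.

Each cell c is a concentration field phi_c(r) on a shared periodic grid.
The free energy density is

    f = (a/4) sum_c phi_c^2 (phi_c - phi0)^2  +  (k_phi/2) sum_c |grad phi_c|^2
      + eps sum_{c<c'} phi_c^2 phi_c'^2  +  k_ad sum_{c<c'} grad phi_c . grad phi_c'
      + sum_c lam (1 - A_c / (pi phi0^2 R_cell^2))^2,   A_c = int phi_c^2 dA,

i.e. a phi^4 wall (surface tension sigma = sqrt(8 k_phi a), width
xi = sqrt(2 k_phi / a)), soft volume exclusion, interfacial adhesion and an
area constraint.  Cells advect at v_c = v0 (cos theta_c, sin theta_c) and
relax by Allen--Cahn dynamics; the polarity angle theta_c performs rotational
diffusion with coefficient D_r (Euler--Maruyama, variance 2 D_r dt, one
independent stream per cell derived from the master seed).

Fields are stored as one (n_cells, ny, nx) array; all per-cell updates are
vectorised over cells.  Defaults are the reference parameter set
a = 0.2, k_phi = 0.2, eps = 0.1, k_ad = 0.005, lam = 600, R_cell = 11.5,
v0 = 0.006, with phi0 = 1, M = 1 and dt = 0.1 as the package's documented
numerical choices (the area-constraint spring 4 lam / (pi phi0^2 R_cell^2)
sets the stability bound for the explicit scheme).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .grid import Grid2D

__all__ = [
    "MPFParams",
    "TissueState",
    "mpf_energy",
    "mpf_force",
    "step_tissue",
    "update_polarity",
    "init_confluent",
    "neighbor_graph",
]


@dataclass(frozen=True)
class MPFParams:
    a_bulk: float = 0.2
    k_phi: float = 0.2
    eps: float = 0.1
    k_ad: float = 0.005
    lam: float = 600.0
    R_cell: float = 11.5
    v0: float = 0.006
    D_r: float = 4e-5
    M: float = 1.0
    phi0: float = 1.0
    dt: float = 0.1

    def __post_init__(self) -> None:
        for name in ("a_bulk", "k_phi", "eps", "lam", "R_cell", "M", "phi0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def sigma(self) -> float:
        """Nominal interfacial tension sqrt(8 k_phi a)."""
        return float(np.sqrt(8 * self.k_phi * self.a_bulk))

    @property
    def xi(self) -> float:
        """Interfacial thickness sqrt(2 k_phi / a)."""
        return float(np.sqrt(2 * self.k_phi / self.a_bulk))

    @property
    def nominal_area(self) -> float:
        return float(np.pi * self.phi0**2 * self.R_cell**2)

    def with_(self, **kw) -> "MPFParams":
        return replace(self, **kw)


@dataclass
class TissueState:
    grid: Grid2D
    phi: np.ndarray          # (n_cells, ny, nx)
    thetas: np.ndarray       # (n_cells,)
    time: float = 0.0
    rng: np.random.Generator | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return self.phi.shape[0]

    def areas(self) -> np.ndarray:
        return (self.phi**2).sum(axis=(1, 2)) * self.grid.dx * self.grid.dy

    def centroids(self) -> np.ndarray:
        """Periodic (circular-mean) centroids weighted by phi^2, (n, 2)."""
        g = self.grid
        w = self.phi**2
        tot = w.sum(axis=(1, 2))
        ax = np.exp(2j * np.pi * np.arange(g.nx) / g.nx)
        ay = np.exp(2j * np.pi * np.arange(g.ny) / g.ny)
        mx = (w.sum(axis=1) * ax).sum(axis=1) / tot
        my = (w.sum(axis=2) * ay).sum(axis=1) / tot
        x = (np.angle(mx) % (2 * np.pi)) / (2 * np.pi) * g.nx * g.dx
        y = (np.angle(my) % (2 * np.pi)) / (2 * np.pi) * g.ny * g.dy
        return np.stack([x, y], axis=1)

    def copy(self) -> "TissueState":
        rng = None
        if self.rng is not None:
            rng = np.random.default_rng()
            rng.bit_generator.state = self.rng.bit_generator.state
        return TissueState(self.grid, self.phi.copy(), self.thetas.copy(),
                           self.time, rng, dict(self.meta))


def _grads(phi: np.ndarray, g: Grid2D):
    gx = (np.roll(phi, -1, axis=2) - np.roll(phi, 1, axis=2)) / (2 * g.dx)
    gy = (np.roll(phi, -1, axis=1) - np.roll(phi, 1, axis=1)) / (2 * g.dy)
    return gx, gy


def _fgrads(phi: np.ndarray, g: Grid2D):
    # forward differences: the discrete adjoint pair of the 5-point Laplacian,
    # used in the energy so that mpf_force is its exact functional gradient
    gx = (np.roll(phi, -1, axis=2) - phi) / g.dx
    gy = (np.roll(phi, -1, axis=1) - phi) / g.dy
    return gx, gy


def _lap(phi: np.ndarray, g: Grid2D):
    return ((np.roll(phi, -1, axis=2) + np.roll(phi, 1, axis=2) - 2 * phi) / g.dx**2
            + (np.roll(phi, -1, axis=1) + np.roll(phi, 1, axis=1) - 2 * phi) / g.dy**2)


def mpf_energy(state: TissueState, params: MPFParams) -> dict:
    """Total free energy and its five contributions.

    Returns {"total", "bulk", "gradient", "exclusion", "adhesion", "area"}.
    """
    p = params
    g = state.grid
    dA = g.dx * g.dy
    phi = state.phi
    bulk = (p.a_bulk / 4) * (phi**2 * (phi - p.phi0) ** 2).sum() * dA
    gx, gy = _fgrads(phi, g)
    grad = (p.k_phi / 2) * (gx**2 + gy**2).sum() * dA
    # pairwise sums via totals: sum_{c<c'} x_c y_c' = ((sum x)^2 - sum x^2)/2
    s2 = (phi**2).sum(axis=0)
    excl = p.eps * 0.5 * ((s2**2 - (phi**4).sum(axis=0)).sum()) * dA
    sgx, sgy = gx.sum(axis=0), gy.sum(axis=0)
    adh = p.k_ad * 0.5 * ((sgx**2 + sgy**2 - (gx**2 + gy**2).sum(axis=0)).sum()) * dA
    areas = state.areas()
    area = (p.lam * (1 - areas / p.nominal_area) ** 2).sum()
    total = bulk + grad + excl + adh + area
    return {"total": float(total), "bulk": float(bulk), "gradient": float(grad),
            "exclusion": float(excl), "adhesion": float(adh), "area": float(area)}


def mpf_force(state: TissueState, params: MPFParams) -> np.ndarray:
    """Functional derivative dF/dphi_c for every cell, shape (n, ny, nx)."""
    p = params
    g = state.grid
    phi = state.phi
    out = (p.a_bulk / 2) * phi * (phi - p.phi0) * (2 * phi - p.phi0)
    lap = _lap(phi, g)
    out -= p.k_phi * lap
    s2 = (phi**2).sum(axis=0)
    out += 2 * p.eps * phi * (s2[None] - phi**2)
    out -= p.k_ad * (lap.sum(axis=0)[None] - lap)
    areas = state.areas()
    out += (-4 * p.lam / p.nominal_area) * (1 - areas / p.nominal_area)[:, None, None] * phi
    return out


def update_polarity(thetas: np.ndarray, rng: np.random.Generator,
                    dt: float, D_r: float) -> np.ndarray:
    """Euler--Maruyama rotational diffusion: theta += sqrt(2 D_r dt) N(0,1).

    Over an ensemble this gives <cos(theta(t) - theta(0))> = exp(-D_r t).
    """
    return thetas + np.sqrt(2 * D_r * dt) * rng.standard_normal(thetas.shape)


def step_tissue(state: TissueState, params: MPFParams,
                n_steps: int = 1) -> TissueState:
    """Advance the tissue by ``n_steps`` predictor--corrector Euler steps.

    Each step advects every phi_c at its own polarity velocity and relaxes
    it by -M dF/dphi_c; polarity angles are then updated by rotational
    diffusion (no-op when D_r = 0; the state's RNG is still consumed
    deterministically)."""
    p = params
    st = state.copy()
    if st.rng is None:
        st.rng = np.random.default_rng(st.meta.get("seed", 0))
    g = st.grid
    for _ in range(n_steps):
        vx = p.v0 * np.cos(st.thetas)[:, None, None]
        vy = p.v0 * np.sin(st.thetas)[:, None, None]

        def rhs(stt):
            gx, gy = _grads(stt.phi, g)
            return -vx * gx - vy * gy - p.M * mpf_force(stt, p)

        k1 = rhs(st)
        pred = TissueState(g, st.phi + p.dt * k1, st.thetas)
        k2 = rhs(pred)
        st.phi = st.phi + 0.5 * p.dt * (k1 + k2)
        if p.D_r > 0:
            st.thetas = update_polarity(st.thetas, st.rng, p.dt, p.D_r)
        st.time += p.dt
        if not np.all(np.isfinite(st.phi)):
            bad = np.nonzero(~np.isfinite(st.phi).all(axis=(1, 2)))[0]
            raise FloatingPointError(
                f"MPF solver produced NaN/inf for cells {bad.tolist()} at "
                f"t={st.time:.1f}")
    return st


def init_confluent(n_cells: int, params: MPFParams, grid: Grid2D,
                   seed: int = 0, relax_steps: int = 200) -> TissueState:
    """Seed ``n_cells`` cells on a jittered hexagonal-ish lattice, initialise
    each phi_c as a smoothed disk indicator, and passively relax (v0 = 0) to
    a confluent packing.  Fully reproducible from (seed, parameters)."""
    if n_cells < 1:
        raise ValueError("need at least one cell")
    p = params
    lx, ly = grid.nx * grid.dx, grid.ny * grid.dy
    if n_cells * p.nominal_area > 1.35 * lx * ly:
        raise ValueError("requested packing exceeds the box capacity")
    rng = np.random.default_rng(seed)
    # near-uniform seeds: hexagonal rows scaled to the box, plus jitter
    ncol = max(1, int(round(np.sqrt(n_cells * lx / ly))))
    nrow = int(np.ceil(n_cells / ncol))
    pts = []
    for j in range(nrow):
        for i in range(ncol):
            if len(pts) >= n_cells:
                break
            x = (i + 0.5 + 0.25 * (j % 2)) * lx / ncol
            y = (j + 0.5) * ly / nrow
            pts.append((x, y))
    pts = np.asarray(pts) + rng.uniform(-0.05, 0.05, (n_cells, 2)) * [lx / ncol, ly / nrow]
    phi = np.empty((n_cells, grid.ny, grid.nx))
    r0 = min(p.R_cell, 0.55 * min(lx / ncol, ly / nrow))
    for c, (x0, y0) in enumerate(pts):
        dx, dy = grid.centered_coords(x0, y0)
        d = np.hypot(dx, dy)
        phi[c] = p.phi0 / (1 + np.exp((d - r0) / p.xi))
    thetas = rng.uniform(0, 2 * np.pi, n_cells)
    st = TissueState(grid, phi, thetas, rng=rng,
                     meta={"seed": seed, "n_cells": n_cells})
    if relax_steps:
        st = step_tissue(st, p.with_(v0=0.0, D_r=0.0), relax_steps)
    return st


def segmentation_labels(state: TissueState, params: MPFParams) -> np.ndarray:
    """Per-pixel owner cell: argmax_c phi_c, with -1 where all phi are
    below phi0/2 nowhere near any cell (empty background)."""
    lab = state.phi.argmax(axis=0)
    empty = state.phi.max(axis=0) < 0.05 * params.phi0
    lab = lab.astype(int)
    lab[empty] = -1
    return lab


def neighbor_graph(state: TissueState, params: MPFParams,
                   min_interface: int = 3):
    """Undirected cell-adjacency graph.

    Two cells are adjacent when their thresholded supports (phi > phi0/2),
    each dilated by one pixel, overlap in at least ``min_interface`` pixels.
    Returns a networkx Graph on the cell indices (symmetric, no self edges).
    Temporal persistence filtering is applied downstream on the adjacency
    time series (see tissue analysis).
    """
    import networkx as nx
    from scipy.ndimage import binary_dilation

    th = params.phi0 / 2
    masks = state.phi > th
    struct = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
    dil = np.stack([_periodic_dilate(m, struct, binary_dilation) for m in masks])
    G = nx.Graph()
    G.add_nodes_from(range(state.n_cells))
    for c in range(state.n_cells):
        for c2 in range(c + 1, state.n_cells):
            overlap = int(np.count_nonzero(dil[c] & dil[c2]))
            if overlap >= min_interface:
                G.add_edge(c, c2, interface=overlap)
    return G


def _periodic_dilate(mask, struct, binary_dilation):
    pad = np.pad(mask, 1, mode="wrap")
    return binary_dilation(pad, structure=struct)[1:-1, 1:-1]
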