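"""Synthetic fixtures: planted defect lattices, honeycomb tilings and
scripted T1 sequences with known ground truth."""

from __future__ import annotations

import numpy as np

from .analysis import PolygonCell
from .grid import Grid2D

__all__ = ["make_defect_field", "make_honeycomb", "make_t1_script"]


def make_defect_field(grid: Grid2D, charges_positions, p: int = 6) -> np.ndarray:
    """Complex lattice field psi = prod_k e^{i p s_k atan2(y - y_k, x - x_k)}
    with planted disclinations.  The total charge must vanish on the torus
    (otherwise the field cannot be smooth away from the cores)."""
    total = sum(s for s, _ in charges_positions)
    if abs(total) > 1e-12:
        raise ValueError(f"net charge {total} is not admissible on a torus")
    x, y = grid.coords()
    psi = np.ones(grid.shape, dtype=complex)
    for s, (x0, y0) in charges_positions:
        psi *= np.exp(1j * p * s * np.arctan2(y - y0, x - x0))
    return psi


def make_honeycomb(n_rows: int, n_cols: int, jitter: float = 0.0,
                   seed: int = 0, a: float = 1.0):
    """Periodic honeycomb tiling: ``n_rows x n_cols`` hexagonal cells with
    centre spacing set by the hexagon circumradius ``a``.

    Every interior vertex is threefold coordinated; with ``jitter = 0``
    every cell is a perfect regular hexagon (|gamma6| = 1, equal phases).
    ``jitter`` displaces each vertex by a uniform offset in
    [-jitter, jitter]^2 (consistently for the cells sharing it).
    Returns (cells, box) with box = (lx, ly).
    """
    if jitter < 0:
        raise ValueError("jitter must be non-negative")
    rng = np.random.default_rng(seed)
    w = np.sqrt(3.0) * a       # horizontal centre spacing
    h = 1.5 * a                # vertical centre spacing
    lx, ly = n_cols * w, n_rows * h
    # shared vertex displacements, keyed by rounded vertex coordinate
    disp: dict[tuple, np.ndarray] = {}

    def jolt(vx, vy):
        # quantised periodic key so shared vertices hash identically despite
        # floating-point wrap
        key = (int(round((vx % lx) * 1e4)) % int(round(lx * 1e4)),
               int(round((vy % ly) * 1e4)) % int(round(ly * 1e4)))
        if key not in disp:
            disp[key] = rng.uniform(-jitter, jitter, 2) if jitter else np.zeros(2)
        return disp[key]

    cells = []
    cid = 0
    for row in range(n_rows):
        for col in range(n_cols):
            cx = (col + 0.5 * (row % 2)) * w
            cy = row * h
            verts = []
            for k in range(6):
                ang = np.pi / 6 + k * np.pi / 3
                vx = cx + a * np.cos(ang)
                vy = cy + a * np.sin(ang)
                d = jolt(vx, vy)
                verts.append((vx - cx + d[0], vy - cy + d[1]))
            cells.append(PolygonCell(cell_id=cid, centroid=(cx % lx, cy % ly),
                                     vertices=np.asarray(verts)))
            cid += 1
    return cells, (lx, ly)


def _square_cells(positions, box):
    out = []
    for cid, (cx, cy, verts) in enumerate(positions):
        out.append(PolygonCell(cell_id=cid, centroid=(cx, cy),
                               vertices=np.asarray(verts) - [cx, cy]))
    return out


def make_t1_script(kind: str, T: int, n_frames: int | None = None,
                   t_event: int = 2):
    """Scripted four-cell neighbour exchange with known labels.

    Cells 0 (left) and 1 (right) initially share an edge; at frame
    ``t_event`` the junction flips so 2 (bottom) and 3 (top) become
    neighbours (the 5-7-5-7 intermediate).  ``kind="cycle"`` reverts the
    flip after ``T`` frames; ``kind="intercalation"`` keeps it to the end.

    Returns dict with keys ``adjacency`` (list of edge sets),
    ``neighbors`` (list of dict cell -> neighbour set), ``polygons``
    (per-frame list of PolygonCell for the four-cell patch), ``times``
    and ``truth``.
    """
    if kind not in ("cycle", "intercalation"):
        raise ValueError("kind must be 'cycle' or 'intercalation'")
    if n_frames is None:
        n_frames = t_event + T + 6 if kind == "cycle" else t_event + 4 * T + 6
    base = {frozenset((0, 2)), frozenset((0, 3)), frozenset((1, 2)),
            frozenset((1, 3))}
    edge_a = frozenset((0, 1))   # vertical junction: left-right neighbours
    edge_b = frozenset((2, 3))   # horizontal junction: bottom-top neighbours
    adjacency = []
    for k in range(n_frames):
        flipped = k >= t_event and (kind == "intercalation" or k < t_event + T)
        adjacency.append(base | ({edge_b} if flipped else {edge_a}))
    # frames of polygons: four cells around the junction, with the central
    # edge shrinking to a fourfold vertex and reopening orthogonally
    polygons = []
    L = 2.0
    for k in range(n_frames):
        flipped = k >= t_event and (kind == "intercalation" or k < t_event + T)
        e = 0.6 if not flipped else -0.6   # half-length of the inner junction
        # inner vertices on the x-axis (unflipped) or y-axis (flipped)
        if e > 0:
            v1, v2 = (-e, 0.0), (e, 0.0)
        else:
            v1, v2 = (0.0, e), (0.0, -e)
        left = [(-2 * L, -L), (-2 * L, L), (-L, 1.4 * L), v1, (-L, -1.4 * L)]
        right = [(2 * L, -L), (2 * L, L), (L, 1.4 * L), v2, (L, -1.4 * L)]
        bottom = [(-L, -1.4 * L), v1, v2, (L, -1.4 * L), (0, -2.2 * L)]
        top = [(-L, 1.4 * L), v1, v2, (L, 1.4 * L), (0, 2.2 * L)]
        if e > 0:
            left = [(-2 * L, -L), (-2 * L, L), (-L, 1.4 * L), v1, (-L, -1.4 * L)]
            right = [(2 * L, -L), (2 * L, L), (L, 1.4 * L), v2, (L, -1.4 * L)]
        frame = []
        for cid, (cx, cy, vs) in enumerate([
                (-1.3 * L, 0.0, left), (1.3 * L, 0.0, right),
                (0.0, -1.3 * L, bottom), (0.0, 1.3 * L, top)]):
            vs = np.asarray(vs, dtype=float)
            frame.append(PolygonCell(cell_id=cid, centroid=(cx, cy),
                                     vertices=vs - [cx, cy]))
        polygons.append(frame)
    nbrs = []
    for adj in adjacency:
        d = {c: set() for c in range(4)}
        for e_ in adj:
            a, b = tuple(e_)
            d[a].add(b)
            d[b].add(a)
        nbrs.append(d)
    truth = dict(kind=kind, t_event=t_event,
                 period=T if kind == "cycle" else None)
    return dict(adjacency=adjacency, neighbors=nbrs, polygons=polygons,
                times=list(range(n_frames)), truth=truth)
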