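"""From per-cell fields or polygons to hexatic order, defects and T1 events.

Pipeline: threshold the cell fields into an occupancy map, repair dropped
interface pixels, extract junction vertices, polygonise each cell, compute
the p-fold shape function

    gamma_p = sum_v |r_v|^p e^{i p phi_v} / sum_v |r_v|^p,

coarse-grain gamma_6 over disks of radius R = 1.5 R_cell sampled on a square
lattice of spacing R_cell, and read topological defects off the winding
number of Arg(Gamma6)/6 around each lattice plaquette.  Neighbour-exchange
(T1) events are detected from the adjacency time series and classified into
reverting cycles and permanent intercalations, from which the temporal
statistics and defect-distance/mobility correlations are assembled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import Grid2D

__all__ = [
    "PolygonCell",
    "ShapeField",
    "T1Event",
    "threshold_density",
    "extract_vertices",
    "polygonize",
    "shape_function",
    "coarse_grain",
    "winding_defects",
    "longitudinal_stress",
    "detect_T1_events",
    "event_time_statistics",
    "msd_defect_density",
    "t1_defect_distance_distribution",
]


@dataclass
class PolygonCell:
    """Ordered-vertex polygon of one cell; vertices are stored relative to
    the centroid, counterclockwise by polar angle."""

    cell_id: int
    centroid: np.ndarray          # (2,)
    vertices: np.ndarray          # (V, 2), relative to centroid

    def __post_init__(self):
        self.centroid = np.asarray(self.centroid, dtype=float)
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[0] < 3:
            raise ValueError("polygon needs at least 3 vertices")
        order = np.argsort(np.arctan2(v[:, 1], v[:, 0]))
        self.vertices = v[order]

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]


@dataclass
class ShapeField:
    """Coarse-grained hexatic shape order on a square sampling lattice."""

    gamma: dict                  # cell_id -> complex gamma_6
    lattice: np.ndarray          # (ny, nx) complex Gamma6
    valid: np.ndarray            # (ny, nx) bool: N_disk >= 1
    spacing: float
    origin: tuple = (0.0, 0.0)


@dataclass(frozen=True)
class T1Event:
    time: float
    cells: tuple                  # 4 involved cell ids (lost pair + gained pair)
    lost: tuple
    gained: tuple
    kind: str = "unresolved"      # "cycle" | "intercalation" | "unresolved"
    period: float | None = None   # revert time for cycles
    flagged: bool = False         # overlapping concurrent event on shared cells


# ---------------------------------------------------------------------------
# segmentation

def threshold_density(cell_fields: np.ndarray, phi_th: float,
                      max_repair: int = 50) -> np.ndarray:
    """Occupancy count Phi: how many cells exceed ``phi_th`` per pixel.

    Interface pixels where every field dips below the threshold (Phi = 0)
    are repaired iteratively: each such pixel receives one count for every
    cell whose thresholded support touches its 4-neighbourhood; repetition
    stops when two consecutive sweeps produce no change.  The repaired map
    has Phi >= 1 across the tissue interior: 1 inside cells, 2 on edges,
    >= 3 on junction vertices.
    """
    from scipy.ndimage import binary_dilation

    masks = cell_fields >= phi_th
    phi_map = masks.sum(axis=0).astype(int)
    struct = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)

    def dil(m):
        return binary_dilation(np.pad(m, 1, mode="wrap"), structure=struct)[1:-1, 1:-1]

    grown = masks.copy()
    for _ in range(max_repair):
        zeros = phi_map == 0
        if not zeros.any():
            return phi_map
        touched = np.stack([dil(m) for m in grown])
        counts = touched.sum(axis=0)
        # only true interface gaps are repaired: pixels reachable from at
        # least two cells; exterior vacuum around an isolated cell stays 0
        fill = zeros & (counts >= 2)
        new = np.where(fill, counts, phi_map)
        if np.array_equal(new, phi_map):
            return phi_map
        phi_map = new
        grown = grown | (touched & fill[None])
    raise RuntimeError("occupancy repair did not converge")


def extract_vertices(phi_map: np.ndarray, cell_fields: np.ndarray | None = None,
                     phi_th: float | None = None):
    """Junction vertices: centroids of 8-connected clusters of pixels with
    Phi > 2 (periodic wraparound respected).

    Returns a list of (x, y) vertex coordinates and, when ``cell_fields`` is
    given, a mapping vertex index -> set of incident cell ids (cells whose
    dilated thresholded support covers the cluster).
    """
    from scipy.ndimage import binary_dilation, label

    ny, nx = phi_map.shape
    mask = phi_map > 2
    # periodic labelling: label on a wrapped pad, then merge via the seam
    lab, n = label(mask, structure=np.ones((3, 3), dtype=bool))
    if n == 0:
        return [], {}
    # merge clusters across the periodic seam
    parent = list(range(n + 1))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    for j in range(ny):
        for dj in (-1, 0, 1):
            a, b = lab[j, nx - 1], lab[(j + dj) % ny, 0]
            if a and b:
                union(a, b)
    for i in range(nx):
        for di in (-1, 0, 1):
            a, b = lab[ny - 1, i], lab[0, (i + di) % nx]
            if a and b:
                union(a, b)
    roots = {}
    verts = []
    members: dict[int, list] = {}
    jj, ii = np.nonzero(mask)
    for j, i in zip(jj, ii):
        r = find(lab[j, i])
        members.setdefault(r, []).append((i, j))
    for r, pix in members.items():
        pix = np.asarray(pix, dtype=float)
        # periodic centroid via circular mean
        cx = np.angle(np.exp(2j * np.pi * pix[:, 0] / nx).mean()) % (2 * np.pi)
        cy = np.angle(np.exp(2j * np.pi * pix[:, 1] / ny).mean()) % (2 * np.pi)
        roots[r] = len(verts)
        verts.append((cx / (2 * np.pi) * nx, cy / (2 * np.pi) * ny))
    incidence: dict[int, set] = {k: set() for k in range(len(verts))}
    if cell_fields is not None:
        th = phi_th if phi_th is not None else 0.5 * cell_fields.max()
        struct = np.ones((3, 3), dtype=bool)
        from scipy.ndimage import binary_dilation as bd
        for c, f in enumerate(cell_fields):
            sup = bd(np.pad(f >= th, 1, mode="wrap"), structure=struct)[1:-1, 1:-1]
            sup = bd(np.pad(sup, 1, mode="wrap"), structure=struct)[1:-1, 1:-1]
            for r, pix in members.items():
                if any(sup[int(j), int(i)] for i, j in pix):
                    incidence[roots[r]].add(c)
    return verts, incidence


def polygonize(cell_fields: np.ndarray, phi_th: float, grid: Grid2D,
               centroids: np.ndarray | None = None):
    """Full segmentation: occupancy, vertices, and per-cell polygons.

    Cells with fewer than 3 incident vertices are skipped (boundary or
    degenerate cases).  Returns a list of PolygonCell.
    """
    phi_map = threshold_density(cell_fields, phi_th)
    verts, incidence = extract_vertices(phi_map, cell_fields, phi_th)
    per_cell: dict[int, list] = {}
    for vi, cells in incidence.items():
        for c in cells:
            per_cell.setdefault(c, []).append(verts[vi])
    if centroids is None:
        w = cell_fields**2
        centroids = []
        for c in range(cell_fields.shape[0]):
            jj, ii = np.nonzero(w[c] > 0.25 * w[c].max())
            centroids.append((ii.mean(), jj.mean()))
        centroids = np.asarray(centroids, dtype=float)
    out = []
    lx, ly = grid.nx * grid.dx, grid.ny * grid.dy
    for c, vlist in sorted(per_cell.items()):
        if len(vlist) < 3:
            continue
        v = np.asarray(vlist, dtype=float) - centroids[c]
        v[:, 0] = (v[:, 0] + lx / 2) % lx - lx / 2
        v[:, 1] = (v[:, 1] + ly / 2) % ly - ly / 2
        out.append(PolygonCell(cell_id=c, centroid=centroids[c], vertices=v))
    return out


# ---------------------------------------------------------------------------
# shape order

def shape_function(polygon: PolygonCell, p: int = 6) -> complex:
    """p-fold shape function gamma_p of one polygon.

    Weighted by |r_v|^p so that long-armed vertices dominate;
    Arg(gamma_p)/p is the cell's p-fold orientation and |gamma_p| <= 1 its
    coherence (1 for a regular p-gon with p | V symmetry).
    """
    if p < 2:
        raise ValueError("p must be >= 2")
    r = np.hypot(polygon.vertices[:, 0], polygon.vertices[:, 1])
    if np.all(r < 1e-12):
        raise ValueError("degenerate polygon: all vertices at the centroid")
    ph = np.arctan2(polygon.vertices[:, 1], polygon.vertices[:, 0])
    w = r**p
    return complex((w * np.exp(1j * p * ph)).sum() / w.sum())


def coarse_grain(cells, R: float, spacing: float,
                 box: tuple, p: int = 6) -> ShapeField:
    """Disk-average the per-cell shape function onto a square lattice.

    Gamma_p(r) = mean of gamma_p over cells whose centroid lies within the
    (periodic) disk of radius R centred at r; lattice points with an empty
    disk are marked invalid.
    """
    lx, ly = box
    nx = max(1, int(round(lx / spacing)))
    ny = max(1, int(round(ly / spacing)))
    cells = list(cells)
    if not cells:
        return ShapeField(gamma={}, lattice=np.zeros((ny, nx), complex),
                          valid=np.zeros((ny, nx), bool), spacing=spacing)
    cxs = np.asarray([c.centroid for c in cells], dtype=float)
    gam = np.asarray([shape_function(c, p) for c in cells])
    lattice = np.zeros((ny, nx), dtype=complex)
    valid = np.zeros((ny, nx), dtype=bool)
    xs = (np.arange(nx) + 0.5) * spacing
    ys = (np.arange(ny) + 0.5) * spacing
    for j, y in enumerate(ys):
        dy = (cxs[:, 1] - y + ly / 2) % ly - ly / 2
        for i, x in enumerate(xs):
            dx = (cxs[:, 0] - x + lx / 2) % lx - lx / 2
            m = dx * dx + dy * dy <= R * R
            if m.any():
                lattice[j, i] = gam[m].mean()
                valid[j, i] = True
    return ShapeField(gamma={c.cell_id: g for c, g in zip(cells, gam)},
                      lattice=lattice, valid=valid, spacing=spacing)


def _wrap_half(d):
    return np.pi - (np.pi - d) % (2 * np.pi)


def winding_defects(shape_field: ShapeField, p: int = 6):
    """Topological defects of the coarse-grained field: the winding of
    theta = Arg(Gamma_p)/p around each lattice plaquette, with increments
    reduced to (-pi/p, pi/p].  Returns a list of (x, y, charge) with
    positions at plaquette centres in physical units."""
    ap = np.angle(shape_field.lattice)  # p * theta
    d_right = _wrap_half(np.roll(ap, -1, axis=1) - ap)
    d_up = _wrap_half(np.roll(ap, -1, axis=0) - ap)
    circ = (d_right + np.roll(d_up, -1, axis=1)
            - np.roll(d_right, -1, axis=0) - d_up)
    ok = (shape_field.valid & np.roll(shape_field.valid, -1, axis=1)
          & np.roll(shape_field.valid, -1, axis=0)
          & np.roll(np.roll(shape_field.valid, -1, axis=0), -1, axis=1))
    w = np.rint(circ / (2 * np.pi))
    w[~ok] = 0
    jj, ii = np.nonzero(w)
    s = shape_field.spacing
    return [((i + 1.0) * s, (j + 1.0) * s, w[j, i] / p) for j, i in zip(jj, ii)]


def longitudinal_stress(cell_fields: np.ndarray, orientations: dict,
                        k_phi: float, grid: Grid2D, p: int = 6):
    """Longitudinal p-atic stress map: per pixel,

        sigma_par = -k_phi sum_c (grad phi_c . n_{c,p})^p,

    the rank-p concentration-gradient tensor of each cell contracted with
    n_{c,p}^{(x) p}, where n_{c,p} is the cell's p-fold orientation axis
    (Arg(gamma_p)/p).  Negative values signal extensile stress.  Returns
    (map, tissue mean over occupied pixels)."""
    out = np.zeros(grid.shape)
    for c, f in enumerate(cell_fields):
        if c not in orientations:
            continue
        th = orientations[c]
        nxv, nyv = np.cos(th), np.sin(th)
        gx = grid.ddx(f)
        gy = grid.ddy(f)
        out += -k_phi * (gx * nxv + gy * nyv) ** p
    occ = cell_fields.max(axis=0) > 0.25
    mean = float(out[occ].mean()) if occ.any() else 0.0
    return out, mean


# ---------------------------------------------------------------------------
# T1 events

def persist_adjacency(series, n_persist: int = 2):
    """Edge sets that have been present for ``n_persist`` consecutive
    frames — suppresses single-frame pixel flicker."""
    out = []
    for k in range(len(series)):
        if k + 1 < n_persist:
            out.append(set(series[k]))
            continue
        inter = set(series[k])
        for back in range(1, n_persist):
            inter &= set(series[k - back])
        out.append(inter)
    return out


def detect_T1_events(adjacency_series, times=None, neighbor_sets=None,
                     horizon_factor: float = 4.0):
    """Classify neighbour exchanges from an adjacency time series.

    A T1 is a frame-to-frame transition that loses an edge (A, B) and gains
    an edge (C, D) with C, D common neighbours of A and B at the loss frame.
    An event whose lost edge reappears later (with the gained edge lost) is
    a ``cycle`` with period T; an event not reverted within
    ``horizon_factor`` times the median observed cycle period (or by the end
    of the series when no cycle is seen) is an ``intercalation``.
    Overlapping concurrent events sharing cells are both recorded, flagged.
    """
    series = [set(frozenset(e) for e in s) for s in adjacency_series]
    if times is None:
        times = list(range(len(series)))
    events = []
    for k in range(1, len(series)):
        lost = series[k - 1] - series[k]
        gained = series[k] - series[k - 1]
        if not lost or not gained:
            continue
        nbrs = neighbor_sets[k - 1] if neighbor_sets is not None else None
        used_cells = set()
        for le in lost:
            a, b = tuple(le)
            for ge in gained:
                c, d = tuple(ge)
                quartet = {a, b, c, d}
                if len(quartet) != 4:
                    continue
                if nbrs is not None:
                    if not ({c, d} <= (nbrs[a] & nbrs[b])):
                        continue
                flag = bool(quartet & used_cells)
                used_cells |= quartet
                events.append(dict(k=k, time=times[k], lost=(a, b),
                                   gained=(c, d), flagged=flag))
                break
    # resolve cycles: the lost edge returns while the gained edge is absent
    out = []
    cycle_periods = []
    for ev in events:
        le, ge = frozenset(ev["lost"]), frozenset(ev["gained"])
        kind, period = "unresolved", None
        for k2 in range(ev["k"] + 1, len(series)):
            if le in series[k2] and ge not in series[k2]:
                kind, period = "cycle", times[k2] - ev["time"]
                cycle_periods.append(period)
                break
        out.append((ev, kind, period))
    med = float(np.median(cycle_periods)) if cycle_periods else None
    events_final = []
    t_end = times[-1]
    for ev, kind, period in out:
        if kind == "unresolved":
            horizon = (horizon_factor * med) if med is not None else 0.0
            if t_end - ev["time"] >= horizon:
                kind = "intercalation"
        events_final.append(T1Event(time=ev["time"],
                                    cells=tuple(sorted(set(ev["lost"]) | set(ev["gained"]))),
                                    lost=ev["lost"], gained=ev["gained"],
                                    kind=kind, period=period,
                                    flagged=ev["flagged"]))
    return events_final


def intercalation_intervals(events) -> list:
    """Per-cell time intervals between consecutive intercalation events."""
    percell: dict[int, list] = {}
    for ev in events:
        if ev.kind != "intercalation":
            continue
        for c in ev.cells:
            percell.setdefault(c, []).append(ev.time)
    out = []
    for ts in percell.values():
        ts = sorted(ts)
        out.extend(np.diff(ts).tolist())
    return out


def event_time_statistics(cycle_periods, interc_intervals, by_key=None):
    """Summary statistics and the two-sided two-sample t-test between the
    cycle-period and intercalation-interval populations."""
    from scipy import stats

    def summ(x):
        x = np.asarray(x, dtype=float)
        if x.size == 0:
            return dict(n=0, mean=np.nan, q1=np.nan, q3=np.nan)
        return dict(n=int(x.size), mean=float(x.mean()),
                    q1=float(np.percentile(x, 25)),
                    q3=float(np.percentile(x, 75)))

    res = {"cycle": summ(cycle_periods), "intercalation": summ(interc_intervals)}
    if len(cycle_periods) >= 2 and len(interc_intervals) >= 2:
        t, pval = stats.ttest_ind(cycle_periods, interc_intervals)
        res["t_stat"], res["p_value"] = float(t), float(pval)
    else:
        res["t_stat"] = res["p_value"] = float("nan")
    return res


# ---------------------------------------------------------------------------
# mobility / defect correlations

def msd_defect_density(centroid_frames, defect_frames, dl: float,
                       box: tuple, window: int):
    """Per-subregion normalised mean square displacement vs defect density.

    The box is tiled with square subregions of side ``dl``; for every
    window of ``window`` consecutive frames, each subregion row reports the
    mean over its cells (assigned by position at the window start) of
    sum_t |r(t) - r(t-1)|^2 / dl^2, together with the mean defect density
    in the subregion over the window.  Empty subregions are omitted.
    """
    lx, ly = box
    nsx, nsy = max(1, int(lx / dl)), max(1, int(ly / dl))
    frames = np.asarray(centroid_frames)  # (T, n, 2)
    T = frames.shape[0]
    rows = []
    for t0 in range(0, T - window, window):
        seg = frames[t0:t0 + window + 1]
        d = seg[1:] - seg[:-1]
        d[:, :, 0] = (d[:, :, 0] + lx / 2) % lx - lx / 2
        d[:, :, 1] = (d[:, :, 1] + ly / 2) % ly - ly / 2
        msd_cell = (d**2).sum(axis=2).sum(axis=0) / dl**2
        sx = np.minimum((frames[t0, :, 0] % lx / dl).astype(int), nsx - 1)
        sy = np.minimum((frames[t0, :, 1] % ly / dl).astype(int), nsy - 1)
        dens = np.zeros((nsy, nsx))
        for t in range(t0, t0 + window + 1):
            for (dx_, dy_, _q) in defect_frames[t]:
                dens[min(int(dy_ % ly / dl), nsy - 1),
                     min(int(dx_ % lx / dl), nsx - 1)] += 1
        dens /= (window + 1) * dl**2
        for j in range(nsy):
            for i in range(nsx):
                m = (sx == i) & (sy == j)
                if m.any():
                    rows.append(dict(t0=t0, sub_x=i, sub_y=j,
                                     msd=float(msd_cell[m].mean()),
                                     defect_density=float(dens[j, i]),
                                     n_cells=int(m.sum())))
    return pd.DataFrame(rows)


def t1_defect_distance_distribution(event_positions, defect_frames,
                                    frame_of_event, box: tuple,
                                    rng: np.random.Generator,
                                    cell_positions=None, n_baseline: int = 200):
    """Signed x-offset from each T1 site (and from random baseline cells)
    to the nearest same-frame defect.

    Returns (t1_dx, baseline_dx) arrays.  The projection axis is x; the
    distribution over many events is symmetric with approximately zero mean.
    """
    lx, ly = box

    def nearest_dx(x, y, defects):
        if not defects:
            return None
        dxs = [( (dx_ - x + lx / 2) % lx - lx / 2, (dy_ - y + ly / 2) % ly - ly / 2)
               for (dx_, dy_, _q) in defects]
        k = int(np.argmin([ddx * ddx + ddy * ddy for ddx, ddy in dxs]))
        return dxs[k][0]

    t1_dx = []
    for (x, y), fr in zip(event_positions, frame_of_event):
        v = nearest_dx(x, y, defect_frames[fr])
        if v is not None:
            t1_dx.append(v)
    base_dx = []
    for _ in range(n_baseline):
        fr = int(rng.integers(0, len(defect_frames)))
        if cell_positions is not None and len(cell_positions[fr]):
            k = int(rng.integers(0, len(cell_positions[fr])))
            x, y = cell_positions[fr][k]
        else:
            x, y = rng.uniform(0, lx), rng.uniform(0, ly)
        v = nearest_dx(x, y, defect_frames[fr])
        if v is not None:
            base_dx.append(v)
    return np.asarray(t1_dx), np.asarray(base_dx)
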