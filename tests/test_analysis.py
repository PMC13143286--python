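"""Segmentation, shape order, winding defects, stresses and T1 statistics."""

import numpy as np
import pytest

from hexamig.analysis import (PolygonCell, ShapeField, coarse_grain,
                              detect_T1_events, event_time_statistics,
                              extract_vertices, intercalation_intervals,
                              longitudinal_stress, msd_defect_density,
                              polygonize, shape_function, persist_adjacency,
                              t1_defect_distance_distribution,
                              threshold_density, winding_defects)
from hexamig.fixtures import make_defect_field, make_honeycomb, make_t1_script
from hexamig.grid import Grid2D


def _regular_polygon(n, radius=1.0, phase=0.0):
    ang = phase + 2 * np.pi * np.arange(n) / n
    return PolygonCell(0, (0.0, 0.0),
                       np.stack([radius * np.cos(ang), radius * np.sin(ang)], 1))


class TestShapeFunction:
    @pytest.mark.parametrize("n,expected", [(6, 1.0), (4, 0.0), (5, 0.0)])
    def test_regular_polygons(self, n, expected):
        """gamma6 is 1 for a regular hexagon and cancels exactly for the
        square (alternating -+i terms) and pentagon (fifth roots of unity)."""
        g6 = shape_function(_regular_polygon(n, radius=2.3), 6)
        assert abs(g6) == pytest.approx(expected, abs=1e-12)
        if n == 6:
            assert g6.real == pytest.approx(1.0)

    def test_rotation_equivariance_scale_invariance(self, rng):
        verts = rng.standard_normal((7, 2)) * 3
        cell = PolygonCell(0, (0, 0), verts)
        for p in (2, 6):
            g0 = shape_function(cell, p)
            delta = 0.77
            c, s = np.cos(delta), np.sin(delta)
            R = np.array([[c, -s], [s, c]])
            rot = PolygonCell(0, (0, 0), verts @ R.T)
            assert shape_function(rot, p) == pytest.approx(
                g0 * np.exp(1j * p * delta), abs=1e-12)
            scaled = PolygonCell(0, (0, 0), 3.7 * verts)
            assert shape_function(scaled, p) == pytest.approx(g0, abs=1e-12)

    def test_magnitude_bounded(self, rng):
        for _ in range(20):
            cell = PolygonCell(0, (0, 0), rng.standard_normal((6, 2)))
            assert abs(shape_function(cell, 6)) <= 1 + 1e-12

    def test_degenerate_polygon_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            shape_function(PolygonCell(0, (0, 0), np.zeros((4, 2)) + 1e-15), 6)


class TestCoarseGrain:
    def test_constant_field(self):
        cells, box = make_honeycomb(4, 4, a=3.0)
        sf = coarse_grain(cells, 1.5 * 3.0, 3.0, box)
        g0 = shape_function(cells[0], 6)
        assert sf.valid.all()
        assert np.allclose(sf.lattice, g0)

    def test_single_cell_disk(self):
        cell = PolygonCell(3, (5.0, 5.0), _regular_polygon(6, 2.0).vertices)
        sf = coarse_grain([cell], R=20.0, spacing=5.0, box=(10.0, 10.0))
        assert np.allclose(sf.lattice, shape_function(cell, 6))

    def test_average_bounded_by_max(self, rng):
        cells, box = make_honeycomb(4, 4, jitter=0.4, seed=2, a=3.0)
        sf = coarse_grain(cells, 4.5, 3.0, box)
        gmax = max(abs(v) for v in sf.gamma.values())
        assert np.abs(sf.lattice[sf.valid]).max() <= gmax + 1e-12


class TestWindingDefects:
    def test_planted_charge_quantum(self):
        """A planted +-1/6 pair on the sampling lattice is recovered with
        charges exactly +-1/6 and positions within one lattice cell."""
        g = Grid2D(24, 24)
        pos = [(1 / 6, (11.6, 11.6)), (-1 / 6, (5.6, 5.6))]
        psi = make_defect_field(g, pos)
        sf = ShapeField(gamma={}, lattice=psi, valid=np.ones(g.shape, bool),
                        spacing=1.0)
        found = winding_defects(sf)
        assert sorted(c for _, _, c in found) == pytest.approx([-1 / 6, 1 / 6])
        for s, (x0, y0) in pos:
            d = min(np.hypot(x - x0, y - y0) for x, y, c in found
                    if np.sign(c) == np.sign(s))
            assert d <= np.sqrt(2)

    def test_uniform_phase_clean(self):
        sf = ShapeField({}, np.exp(0.4j) * np.ones((8, 8)),
                        np.ones((8, 8), bool), 1.0)
        assert winding_defects(sf) == []

    def test_total_winding_zero_on_torus(self, rng):
        g = Grid2D(16, 16)
        psi = make_defect_field(g, [(1 / 6, (4.3, 4.3)), (1 / 6, (12.3, 4.3)),
                                    (-1 / 6, (4.3, 12.3)), (-1 / 6, (12.3, 12.3))])
        sf = ShapeField({}, psi, np.ones(g.shape, bool), 1.0)
        assert sum(c for _, _, c in winding_defects(sf)) == pytest.approx(0.0)


class TestSegmentation:
    @staticmethod
    def _smooth_honeycomb_fields(nrow=2, ncol=2, a=8.0, overlap=1.1,
                                 width=0.5):
        """Smoothed indicator cells of a periodic honeycomb tiling.  Each
        hexagon is expanded by ``overlap`` so neighbouring supports share a
        thin band above threshold, as confluent phase-field cells do."""
        cells, (lx, ly) = make_honeycomb(nrow, ncol, a=a)
        nx, ny = int(round(lx)), int(round(ly))
        g = Grid2D(nx, ny, lx / nx, ly / ny)
        x, y = g.coords()
        fields = []
        for c in cells:
            dx = (x - c.centroid[0] + lx / 2) % lx - lx / 2
            dy = (y - c.centroid[1] + ly / 2) % ly - ly / 2
            ang = np.arctan2(dy, dx)
            # exact polar boundary of the regular hexagon (apothem form)
            rel = (ang - np.pi / 6) % (np.pi / 3) - np.pi / 6
            r_edge = a * np.cos(np.pi / 6) / np.cos(rel) + overlap
            d = np.hypot(dx, dy) - r_edge
            fields.append(1.0 / (1 + np.exp(d / width)))
        return np.stack(fields), cells, g

    def test_occupancy_levels_single_disk(self):
        g = Grid2D(32, 32)
        dx, dy = g.centered_coords(16, 16)
        f = 1.0 / (1 + np.exp((np.hypot(dx, dy) - 8) / 0.5))
        phi_map = threshold_density(f[None], 0.5)
        assert set(np.unique(phi_map)) == {0, 1}
        assert phi_map[16, 16] == 1
        assert phi_map[0, 0] == 0   # vacuum not repaired

    def test_two_halfplane_cells_interface_band(self):
        g = Grid2D(32, 16)
        x, _ = g.coords()
        a = 1.0 / (1 + np.exp((x - 15.0) / 0.7))
        b = 1.0 / (1 + np.exp(-(x - 16.0) / 0.7)) + 1.0 / (1 + np.exp((x - 0.5) / 0.7))
        phi_map = threshold_density(np.stack([a, np.minimum(b, 1.0)]), 0.5)
        assert phi_map.min() >= 1
        band = (phi_map >= 2).sum(axis=1)
        assert np.all(band >= 1) and np.all(band <= 4)

    def test_honeycomb_junctions_found(self):
        """Threefold vertices of a smoothed honeycomb carry occupancy >= 3
        and are recovered within one pixel of the exact junctions."""
        fields, cells, g = self._smooth_honeycomb_fields()
        phi_map = threshold_density(fields, 0.5)
        assert phi_map.max() >= 3
        verts, incidence = extract_vertices(phi_map, fields, 0.5)
        assert len(verts) >= 6
        # every true junction has a detected vertex within ~1.5 px
        lx, ly = g.nx * g.dx, g.ny * g.dy
        true_j = set()
        for c in cells:
            for v in c.vertices:
                true_j.add((round((c.centroid[0] + v[0]) % lx, 2),
                            round((c.centroid[1] + v[1]) % ly, 2)))
        hits = 0
        for tx, ty in true_j:
            dmin = min(np.hypot((vx - tx + lx / 2) % lx - lx / 2,
                                (vy - ty + ly / 2) % ly - ly / 2)
                       for vx, vy in verts)
            hits += dmin <= 1.6
        assert hits / len(true_j) > 0.9

    def test_polygonize_interior_cells_six_vertices(self):
        # an even row count is needed for the staggered tiling to close
        # periodically
        fields, cells, g = self._smooth_honeycomb_fields(2, 3, a=10.0)
        cents = np.asarray([c.centroid for c in cells])
        polys = polygonize(fields, 0.5, g, centroids=cents)
        counts = [p.n_vertices for p in polys]
        assert len(polys) == len(cells)
        assert counts == [6] * len(cells)


class TestLongitudinalStress:
    def test_uniform_field_zero(self):
        g = Grid2D(16, 16)
        m, mean = longitudinal_stress(np.full((1, 16, 16), 0.7), {0: 0.3},
                                      0.2, g, p=2)
        assert np.abs(m).max() == 0.0

    def test_kink_interface_negative_when_aligned(self):
        """n parallel to the concentration gradient gives strictly negative
        longitudinal nematic stress -k |grad phi|^2 on the interface, and
        rotating n by pi/2 moves the interface to the angular node."""
        g = Grid2D(32, 16)
        x, _ = g.coords()
        f = 1.0 / (1 + np.exp((x - 16.0) / 1.5))
        m_par, mean_par = longitudinal_stress(f[None], {0: 0.0}, 0.2, g, p=2)
        band = slice(None), slice(12, 20)
        assert (m_par[band] < 0).all()
        gx = g.ddx(f)
        assert np.allclose(m_par, -0.2 * gx**2, atol=1e-12)
        m_perp, _ = longitudinal_stress(f[None], {0: np.pi / 2}, 0.2, g, p=2)
        assert np.abs(m_perp).max() < 1e-12


class TestT1Events:
    def test_cycle_script(self):
        sc = make_t1_script("cycle", T=5)
        evs = detect_T1_events(sc["adjacency"], sc["times"], sc["neighbors"])
        cycles = [e for e in evs if e.kind == "cycle"]
        assert len(cycles) == 1
        assert cycles[0].time == sc["truth"]["t_event"]
        assert cycles[0].period == 5

    def test_intercalation_script(self):
        sc = make_t1_script("intercalation", T=5)
        evs = detect_T1_events(sc["adjacency"], sc["times"], sc["neighbors"])
        assert [e.kind for e in evs] == ["intercalation"]
        assert evs[0].lost in ((0, 1), (1, 0))

    def test_no_change_no_events(self):
        adj = [{frozenset((0, 1))}] * 5
        assert detect_T1_events(adj) == []

    def test_persistence_filter_drops_flicker(self):
        base = {frozenset((0, 1))}
        flick = {frozenset((0, 1)), frozenset((2, 3))}
        series = [base, flick, base, flick, base]
        persisted = persist_adjacency(series, 2)
        assert all(s == base for s in persisted[1:])

    def test_intervals_per_cell(self):
        from hexamig.analysis import T1Event

        evs = [T1Event(time=t, cells=(0, 1, 2, 3), lost=(0, 1),
                       gained=(2, 3), kind="intercalation")
               for t in (2, 20, 50)]
        evs.append(T1Event(time=30, cells=(4, 5, 6, 7), lost=(4, 5),
                           gained=(6, 7), kind="cycle", period=3))
        iv = intercalation_intervals(evs)
        assert sorted(set(iv)) == [18, 30]
        assert len(iv) == 8  # four cells, two consecutive gaps each


class TestEventStatistics:
    def test_identical_populations(self):
        r = event_time_statistics([3.0, 4.0, 5.0], [3.0, 4.0, 5.0])
        assert r["p_value"] == pytest.approx(1.0)
        assert r["cycle"]["mean"] == r["intercalation"]["mean"]

    def test_disjoint_populations_significant(self):
        r = event_time_statistics([1.0, 1.1, 0.9, 1.05] * 5,
                                  [9.0, 9.3, 8.8, 9.1] * 5)
        assert r["p_value"] < 1e-3
        assert r["cycle"]["q3"] < r["intercalation"]["q1"]

    def test_quartiles_reported(self):
        r = event_time_statistics(list(range(1, 101)), [1.0, 2.0])
        assert r["cycle"]["q1"] == pytest.approx(25.75)
        assert r["cycle"]["q3"] == pytest.approx(75.25)


class TestMobilityCorrelations:
    def test_stationary_cells_zero_msd(self):
        frames = np.tile(np.array([[5.0, 5.0], [15.0, 15.0]]), (6, 1, 1))
        defects = [[(8.0, 8.0, 1 / 6)]] * 6
        df = msd_defect_density(frames, defects, dl=10.0, box=(20.0, 20.0),
                                window=5)
        assert (df["msd"] == 0).all()

    def test_ballistic_cell_closed_form(self):
        """A cell moving at speed v with frame spacing tau accumulates
        (n_steps) (v tau)^2 / dl^2 over the window."""
        v, tau, n = 0.4, 1.0, 8
        xs = 2.0 + v * tau * np.arange(n + 1)
        frames = np.stack([np.stack([xs, np.full(n + 1, 3.0)], 1)])
        frames = frames.transpose(1, 0, 2)  # (T, 1, 2)
        defects = [[] for _ in range(n + 1)]
        df = msd_defect_density(frames, defects, dl=5.0, box=(40.0, 10.0),
                                window=n)
        assert len(df) == 1
        assert df["msd"].iloc[0] == pytest.approx(n * (v * tau) ** 2 / 25.0)

    def test_empty_subregion_omitted(self):
        frames = np.tile(np.array([[2.0, 2.0]]), (4, 1, 1))
        df = msd_defect_density(frames, [[]] * 4, dl=5.0, box=(10.0, 10.0),
                                window=3)
        assert set(zip(df["sub_x"], df["sub_y"])) == {(0, 0)}


class TestDefectDistance:
    def test_colocated_defects_spike_at_zero(self, rng):
        events = [(3.0, 3.0), (7.0, 7.0)]
        frames = [[(3.0, 3.0, 1 / 6), (7.0, 7.0, -1 / 6)]] * 2
        t1_dx, base = t1_defect_distance_distribution(
            events, frames, [0, 1], (10.0, 10.0), rng)
        assert np.abs(t1_dx).max() == 0.0

    def test_uniform_baseline_symmetric(self, rng):
        frames = [[(rng.uniform(0, 50), rng.uniform(0, 50), 1 / 6)
                   for _ in range(8)] for _ in range(20)]
        _, base = t1_defect_distance_distribution(
            [], frames, [], (50.0, 50.0), rng, n_baseline=4000)
        assert abs(base.mean()) < 3 * base.std() / np.sqrt(base.size)
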