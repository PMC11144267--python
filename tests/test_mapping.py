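"""Ray-traced cylindrical maps: tracer correctness, map identities,
helix axes and contact masks."""

import numpy as np
import pytest

from dmportrait import (Structure, StraightAxis, VoxelGrid, trace_map,
                        integrate_profile, helix_axis,
                        helix_map_with_contacts, make_helix)
from dmportrait.geometry import PoreAxis


def _brute_trace(coords, radii, o, d, t_max):
    oc = coords - o
    b = oc @ d
    disc = b * b - (np.einsum("ij,ij->i", oc, oc) - radii ** 2)
    ts = np.full(len(coords), np.inf)
    ok = disc >= 0
    sq = np.sqrt(disc[ok])
    t_in, t_out = b[ok] - sq, b[ok] + sq
    ts[ok] = np.where(t_in >= 0, t_in,
                      np.where(t_out >= 0, t_out, np.inf))
    a = int(np.argmin(ts))
    return (a, ts[a]) if ts[a] <= t_max else (-1, np.inf)


class TestVoxelTracer:
    def test_matches_brute_force_on_random_rays(self, rng):
        """>= 1000 random rays against random sphere systems hit the
        same atom at the same distance as an all-spheres scan."""
        for trial in range(4):
            n = rng.integers(10, 40)
            coords = rng.uniform(-5, 5, (n, 3))
            radii = rng.uniform(0.8, 2.0, n)
            grid = VoxelGrid(coords, radii, voxel_size=2.0)
            for _ in range(300):
                o = rng.uniform(-8, 8, 3)
                d = rng.normal(size=3)
                d /= np.linalg.norm(d)
                a, t = grid.trace(o, d, 30.0)
                ba, bt = _brute_trace(coords, radii, o, d, 30.0)
                assert a == ba
                if a >= 0:
                    assert t == pytest.approx(bt, abs=1e-9)

    def test_result_independent_of_voxel_size(self, rng):
        coords = rng.uniform(-5, 5, (25, 3))
        radii = rng.uniform(0.8, 2.0, 25)
        g1 = VoxelGrid(coords, radii, voxel_size=1.5)
        g2 = VoxelGrid(coords, radii, voxel_size=4.0)
        for _ in range(200):
            o = rng.uniform(-8, 8, 3)
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            a1, t1 = g1.trace(o, d, 30.0)
            a2, t2 = g2.trace(o, d, 30.0)
            assert a1 == a2
            if a1 >= 0:
                assert t1 == pytest.approx(t2, abs=1e-9)

    def test_tangent_ray_counts_as_hit(self):
        grid = VoxelGrid(np.array([[0.0, 2.0, 0.0]]), np.array([2.0]))
        a, t = grid.trace(np.array([-5.0, 0.0, 0.0]),
                          np.array([1.0, 0.0, 0.0]), 20.0)
        assert a == 0
        assert t == pytest.approx(5.0, abs=1e-9)


class TestTraceMap:
    def test_single_sphere_hit_at_its_radius(self):
        s = Structure(np.zeros((1, 3)), ["C"], ["CB"], ["ALA"], [1],
                      ["A"])
        s.vdw_radius[:] = 2.0
        s.hydro_const[:] = 1.0
        axis = StraightAxis([0, 0, 0], [0, 0, 1])
        m = trace_map(s, axis, z_range=(-1.5, 1.5), z_step=0.5,
                      angle_step=10.0)
        hit = ~m.miss
        assert hit.all()
        d = np.linalg.norm(m.hit_points[hit], axis=1)
        assert np.allclose(d, 2.0, atol=1e-9)

    def test_c4_map_is_90_degree_periodic(self, pore23, pore23_axis):
        m = trace_map(pore23, pore23_axis, z_range=(-6, 6), z_step=1.0,
                      angle_step=2.0)
        q = len(m.angle_grid) // 4
        rolled = np.roll(m.values, q, axis=1)
        hit = ~m.miss
        assert (hit == np.roll(hit, q, axis=1)).all()
        assert np.nanmax(np.abs(m.values - rolled)[hit]) < 1e-9

    def test_profile_total_is_self_plus_induced(self, pore23,
                                                pore23_axis):
        m = trace_map(pore23, pore23_axis, z_range=(-6, 6), z_step=1.0,
                      angle_step=6.0)
        prof = integrate_profile(m)
        ok = ~prof.undefined
        assert np.allclose(prof.total[ok],
                           prof.self_part[ok] + prof.induced_part[ok])

    def test_angular_integration_invariant_to_angle_origin(
            self, pore23, pore23_axis):
        """Rotating a C4 structure by a whole number of angular steps
        relabels the rays, leaving the integrated profile unchanged."""
        m1 = trace_map(pore23, pore23_axis, z_range=(-4, 4), z_step=1.0,
                       angle_step=6.0)
        rot = pore23.copy()
        th = np.radians(5 * 6.0)
        c, s_ = np.cos(th), np.sin(th)
        r = np.array([[c, -s_, 0], [s_, c, 0], [0, 0, 1.0]])
        rot.coords = pore23.coords @ r.T
        m2 = trace_map(rot, pore23_axis, z_range=(-4, 4), z_step=1.0,
                       angle_step=6.0)
        p1, p2 = integrate_profile(m1), integrate_profile(m2)
        assert np.allclose(p1.total, p2.total, atol=1e-6,
                           equal_nan=True)

    def test_hydrophobic_belt_positive_total_mhp(self, pore23,
                                                 pore23_axis):
        """The Ile-ring band of the hydrophobic-faced pore shows
        positive angle-integrated total MHP."""
        ca = pore23.is_protein & (pore23.res_id == 13) \
            & (pore23.atom_name == "CA")
        zg = float(pore23.coords[ca, 2].mean())
        m = trace_map(pore23, pore23_axis, z_range=(zg - 2, zg + 2),
                      z_step=0.5, angle_step=6.0)
        prof = integrate_profile(m)
        assert np.nanmean(prof.total) > 0

    def test_row_without_atoms_flagged_miss(self):
        s = Structure(np.array([[3.0, 0, 0]]), ["C"], ["CB"], ["ALA"],
                      [1], ["A"])
        s.vdw_radius[:] = 1.5
        s.hydro_const[:] = 1.0
        axis = StraightAxis([0, 0, 0], [0, 0, 1])
        m = trace_map(s, axis, z_range=(-30, 0), z_step=30.0,
                      angle_step=30.0)
        assert m.miss[0].all() and not m.miss[1].all()
        assert integrate_profile(m).undefined[0]


class TestHelixAxis:
    def test_ideal_helix_axis_geometry(self):
        """Ca atoms advance uniformly along the axis (1.5 A rise) and
        stay at a constant radial distance from it."""
        h = make_helix(["ALA"] * 18)
        ca = h.coords[h.atom_name == "CA"]
        center, d = helix_axis(ca)
        t = (ca - center) @ d
        radial = np.linalg.norm(ca - center - t[:, None] * d, axis=1)
        # Ca stay near the canonical 2.3 A helix radius, with modest
        # scatter (the gyration axis tilts slightly off the screw axis
        # for a non-integer number of turns), advancing ~1.5 A/residue
        assert 2.0 < radial.mean() < 2.6
        assert radial.std() < 0.25
        assert np.diff(t).mean() == pytest.approx(1.55, abs=0.1)
        assert (np.diff(t) > 1.2).all() and (np.diff(t) < 1.9).all()

    def test_equivariance_under_rotation(self, rng):
        from scipy.spatial.transform import Rotation
        h = make_helix(["ALA"] * 10)
        ca = h.coords[h.atom_name == "CA"]
        _, d = helix_axis(ca)
        r = Rotation.random(random_state=3).as_matrix()
        _, d2 = helix_axis(ca @ r.T)
        assert min(np.linalg.norm(d2 - r @ d),
                   np.linalg.norm(d2 + r @ d)) < 1e-9

    def test_too_few_ca_rejected(self):
        with pytest.raises(ValueError):
            helix_axis(np.zeros((3, 3)))

    def test_degenerate_tensor_rejected(self):
        square = np.array([[1, 1, 0], [1, -1, 0], [-1, 1, 0],
                           [-1, -1, 0.0]])
        with pytest.raises(ValueError, match="degenerate"):
            helix_axis(square)


class TestHelixContacts:
    def _two_chain(self, extra_pos):
        h = make_helix(["LEU"] * 10, chain_id="A")
        n = h.n_atoms
        coords = np.vstack([h.coords, np.atleast_2d(extra_pos)])
        k = len(np.atleast_2d(extra_pos))
        s = Structure(coords, list(h.element) + ["C"] * k,
                      list(h.atom_name) + ["CB"] * k,
                      list(h.res_name) + ["ALA"] * k,
                      list(h.res_id) + list(range(1, k + 1)),
                      list(h.chain_id) + ["B"] * k)
        from dmportrait import assign_radii, assign_hydrophobicity
        assign_radii(s)
        assign_hydrophobicity(s)
        return s

    def test_far_neighbors_give_empty_mask(self):
        s = self._two_chain([[60.0, 0, 0]])
        m, mask = helix_map_with_contacts(s, (1, 10), (1, 5),
                                          angle_step=15.0)
        assert not mask.mask.any()

    def test_neighbor_within_seven_angstrom_marks_points(self):
        h = make_helix(["LEU"] * 10, chain_id="A")
        # place the neighbour 6.9 A from a known surface region
        top = h.coords[h.atom_name == "CA"].mean(axis=0)
        s = self._two_chain(top + np.array([10.0, 0.0, 0.0]))
        m, mask = helix_map_with_contacts(s, (1, 10), (1, 5),
                                          angle_step=15.0)
        pts = m.hit_points[~m.miss]
        d = np.linalg.norm(pts - (top + np.array([10.0, 0.0, 0.0])),
                           axis=1)
        assert (d < 7.0).any()
        assert mask.mask[~m.miss].sum() == (d < 7.0).sum()

    def test_empty_neighbor_selection_warns_all_false(self):
        s = self._two_chain([[60.0, 0, 0]])
        with pytest.warns(UserWarning, match="empty neighbour"):
            _, mask = helix_map_with_contacts(s, (1, 10), (900, 901),
                                              angle_step=15.0)
        assert not mask.mask.any()

    def test_helix_map_is_self_mhp_only(self):
        s = self._two_chain([[9.0, 0, 0]])
        m, _ = helix_map_with_contacts(s, (1, 10), (1, 5),
                                       angle_step=15.0)
        # induced part must be identically zero: contributors are the
        # helix's own subunit
        hit = ~m.miss
        assert np.allclose(m.induced_part[hit], 0.0)
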