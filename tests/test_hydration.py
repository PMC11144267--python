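"""Surface point clouds, ESA profiles, densities and permeation."""

import numpy as np
import pytest

from dmportrait import (Structure, FrameSeries, connolly_points,
                        exposed_subset, esa_profile, delta_esa,
                        density_profiles, count_permeation,
                        make_c4_pore, make_hydrated_frames, PoreSpec,
                        StraightAxis)


def _sphere(radius=2.0, element="C", center=(0, 0, 0)):
    s = Structure(np.array([center], dtype=float), [element], ["CB"],
                  ["ALA"], [1], ["A"])
    s.vdw_radius[:] = radius
    s.hydro_const[:] = 1.0 if element == "C" else -1.0
    return s


class TestConnollyPoints:
    def test_isolated_sphere_area_within_two_percent(self):
        cloud = connolly_points(_sphere(2.0), compute_mhp=False)
        assert cloud.total_area == pytest.approx(4 * np.pi * 4,
                                                 rel=0.02)

    def test_density_doubling_doubles_points_not_area(self):
        c1 = connolly_points(_sphere(2.0), density=5.0,
                             compute_mhp=False)
        c2 = connolly_points(_sphere(2.0), density=10.0,
                             compute_mhp=False)
        assert len(c2.points) == pytest.approx(2 * len(c1.points),
                                               rel=0.02)
        assert c2.total_area == pytest.approx(c1.total_area, rel=0.02)

    def test_coincident_duplicate_spheres_keep_single_area(self):
        s = Structure(np.zeros((2, 3)), ["C", "C"], ["CB", "CB"],
                      ["ALA", "ALA"], [1, 2], ["A", "A"])
        s.vdw_radius[:] = 2.0
        s.hydro_const[:] = 1.0
        cloud = connolly_points(s, compute_mhp=False)
        assert cloud.total_area == pytest.approx(4 * np.pi * 4,
                                                 rel=0.02)

    def test_area_invariant_under_rigid_motion(self, pore10):
        c1 = connolly_points(pore10, density=2.0, compute_mhp=False)
        moved = pore10.copy()
        th = 0.7
        r = np.array([[np.cos(th), -np.sin(th), 0],
                      [np.sin(th), np.cos(th), 0], [0, 0, 1.0]])
        moved.coords = pore10.coords @ r.T + np.array([5.0, 1.0, -2.0])
        c2 = connolly_points(moved, density=2.0, compute_mhp=False)
        # the sample lattice does not rotate with the body, so the
        # rejection boundary shifts by up to a point spacing
        assert c2.total_area == pytest.approx(c1.total_area, rel=0.01)

    def test_zero_atoms_rejected(self, pore10):
        with pytest.raises(ValueError):
            connolly_points(pore10, atom_mask=np.zeros(pore10.n_atoms,
                                                       dtype=bool))


class TestExposedSubset:
    def test_no_waters_gives_empty_valid_subset(self):
        cloud = connolly_points(_sphere(), compute_mhp=False)
        sub = exposed_subset(cloud, np.empty((0, 3)))
        assert sub.total_area == 0.0

    def test_water_exactly_on_a_point_is_retained(self):
        cloud = connolly_points(_sphere(), compute_mhp=False)
        sub = exposed_subset(cloud, cloud.points[:1])
        assert len(sub.points) >= 1

    def test_flooded_surface_saturates_to_total_area(self, rng):
        """Waters everywhere within reach recover the full area."""
        cloud = connolly_points(_sphere(2.0), compute_mhp=False)
        waters = cloud.points * (1.0 + 0.5 / 2.0)   # 1 A off-surface
        sub = exposed_subset(cloud, waters)
        assert sub.total_area == pytest.approx(cloud.total_area,
                                               rel=0.02)

    def test_exposed_is_a_pointwise_subset(self, rng):
        cloud = connolly_points(_sphere(2.0), compute_mhp=False)
        waters = rng.uniform(-3, 3, (30, 3))
        sub = exposed_subset(cloud, waters)
        assert sub.total_area <= cloud.total_area + 1e-9
        assert len(sub.points) <= len(cloud.points)


@pytest.fixture(scope="module")
def wet_series():
    pore = make_c4_pore(PoreSpec(helix_length=14, lumen_radius=2.9,
                                 gate_index=7))
    return make_hydrated_frames(pore, n_frames=3, water_density=0.3,
                                water_radius=6.0, seed=11)


class TestESAProfile:

    def test_static_frame_repeated_equals_single_frame(self, wet_series):
        one = FrameSeries(wet_series.topology, wet_series.coords[:1])
        rep = FrameSeries(wet_series.topology,
                          np.repeat(wet_series.coords[:1], 4, axis=0))
        p1 = esa_profile(one, region=(-6, 6), density=2.0)
        p4 = esa_profile(rep, region=(-6, 6), density=2.0)
        assert np.allclose(p1.esa_total, p4.esa_total)
        assert np.allclose(p1.esa_hydrophobic, p4.esa_hydrophobic)

    def test_histogram_conserves_total_exposed_area(self, wet_series):
        p = esa_profile(wet_series, region=(-6, 6), density=2.0)
        assert p.esa_by_mhp.sum() == pytest.approx(p.esa_total.sum(),
                                                   abs=1e-9)
        assert (p.esa_hydrophobic <= p.esa_total + 1e-12).all()
        # saturation bound: exposed never exceeds the region's area
        assert p.integrated_total <= p.region_area + 1e-9

    def test_all_negative_mhp_means_zero_hydrophobic_esa(self):
        s = _sphere(2.0, element="N")   # negative constant everywhere
        s.hydro_const[:] = -0.5
        frames = FrameSeries(
            Structure(np.vstack([s.coords, [[0, 0, 2.5]]]),
                      ["N", "O"], ["CB", "O"], ["ALA", "HOH"], [1, 2],
                      ["A", "W"], category=["protein", "water"]),
            np.repeat(np.vstack([s.coords,
                                 [[0, 0, 2.5]]])[None], 2, axis=0))
        frames.topology.vdw_radius[:] = [2.0, 1.52]
        frames.topology.hydro_const[:] = [-0.5, 0.0]
        p = esa_profile(frames, region=(-2.5, 2.5), density=3.0)
        assert p.integrated_total > 0
        assert p.integrated_hydrophobic == 0.0

    def test_dry_band_suppresses_esa(self):
        pore = make_c4_pore(PoreSpec(helix_length=14, lumen_radius=2.9,
                                     gate_index=7))
        ser = make_hydrated_frames(pore, n_frames=2, water_density=0.3,
                                   water_radius=6.0, dry_zband=(-4, 4),
                                   seed=7)
        p = esa_profile(ser, region=(-8, 8), density=2.0)
        zc = p.z_centers
        inner = (zc > -2.5) & (zc < 2.5)   # > 1.4 A inside the band
        assert p.esa_total[inner].sum() == 0.0
        assert p.esa_total[~inner].sum() > 0


class TestDeltaESA:
    def test_identical_replicas_give_zero_delta_and_sd(self):
        d = delta_esa([(100.0, 40.0), (100.0, 40.0)],
                      [(100.0, 40.0), (100.0, 40.0)])
        assert d.delta_total == 0.0 and d.sd_total == 0.0
        assert d.delta_hydrophobic == 0.0 and d.sd_hydrophobic == 0.0

    def test_extra_exposed_sphere_of_known_area(self):
        """Two states differing by one fully wetted sphere change the
        exposed area by that sphere's analytic area."""
        base = _sphere(2.0)
        extra = _sphere(1.5, center=(10.0, 0, 0))
        def wet_area(s):
            cloud = connolly_points(s, compute_mhp=False)
            # waters on every surface point: fully saturated
            return exposed_subset(cloud, cloud.points).total_area
        a = wet_area(base)
        merged = Structure(np.vstack([base.coords, extra.coords]),
                           ["C", "C"], ["CB", "CB"], ["ALA", "ALA"],
                           [1, 2], ["A", "A"])
        merged.vdw_radius[:] = [2.0, 1.5]
        merged.hydro_const[:] = 1.0
        b = wet_area(merged)
        d = delta_esa([(a, a), (a, a)], [(b, b), (b, b)])
        assert d.delta_total == pytest.approx(4 * np.pi * 1.5 ** 2,
                                              rel=0.02)

    def test_sign_convention_b_minus_a(self):
        d = delta_esa([(1.0, 0.5), (1.0, 0.5)],
                      [(3.0, 1.0), (3.0, 1.0)], "closed", "open")
        assert d.delta_total == pytest.approx(2.0)
        assert d.state_a == "closed" and d.state_b == "open"

    def test_single_replica_rejected(self):
        with pytest.raises(ValueError, match="replica"):
            delta_esa([(1.0, 1.0)], [(2.0, 2.0), (2.0, 2.0)])


class TestDensity:
    def _series_with_particles(self, particle_coords, category="water"):
        n = len(particle_coords)
        el = "O" if category == "water" else "NA"
        topo = Structure(np.asarray(particle_coords, dtype=float),
                         [el] * n, [el] * n,
                         ["HOH" if category == "water" else "NA"] * n,
                         range(1, n + 1), ["W"] * n,
                         category=[category] * n)
        coords = np.repeat(np.asarray(particle_coords,
                                      dtype=float)[None], 5, axis=0)
        return FrameSeries(topo, coords)

    def test_absent_species_rejected(self):
        ser = self._series_with_particles([[0, 0, 0]], "water")
        with pytest.raises(ValueError, match="absent"):
            density_profiles(ser, "ion")

    def test_single_immobile_water_in_one_voxel(self):
        ser = self._series_with_particles([[0.2, 0.3, 0.4]])
        d = density_profiles(ser, "water")
        assert np.count_nonzero(d.density) == 1
        assert d.mean_count == pytest.approx(1.0, abs=1e-6)
        assert d.axial_counts.sum() == pytest.approx(1.0)

    def test_ions_outside_the_pore_cylinder_leave_zero_profile(self):
        ser = self._series_with_particles([[50.0, 0, 0]], "ion")
        axis = StraightAxis([0, 0, 0], [0, 0, 1])
        d = density_profiles(ser, "ion", axis, cylinder_radius=8.0)
        assert d.axial_counts.sum() == 0.0

    def test_grid_integral_equals_mean_particle_count(self, rng):
        pts = rng.uniform(-5, 5, (40, 3))
        ser = FrameSeries(
            self._series_with_particles(pts).topology,
            rng.uniform(-5, 5, (6, 40, 3)))
        d = density_profiles(ser, "water")
        assert d.mean_count == pytest.approx(40.0, rel=1e-6)

    def test_uniform_particles_give_flat_axial_profile(self, rng):
        from scipy.stats import chisquare
        pts = rng.uniform(-10, 10, (2000, 3)) * np.array([0.2, 0.2, 1])
        ser = FrameSeries(self._series_with_particles(pts).topology,
                          pts[None])
        d = density_profiles(ser, "water", z_bin=2.0)
        counts = d.axial_counts[1:-1]   # edge bins are partial
        stat, p = chisquare(counts)
        assert p > 1e-3


class TestPermeation:
    def _series(self, traces):
        """traces: (n_frames, n_particles) z histories."""
        traces = np.asarray(traces, dtype=float)
        nf, np_ = traces.shape
        coords = np.zeros((nf, np_, 3))
        coords[:, :, 2] = traces
        topo = Structure(coords[0], ["NA"] * np_, ["NA"] * np_,
                         ["NA"] * np_, range(1, np_ + 1), ["I"] * np_,
                         category=["ion"] * np_)
        return FrameSeries(topo, coords)

    def test_monotone_traversal_counts_once(self):
        ser = self._series(np.linspace(-10, 10, 15)[:, None])
        pc = count_permeation(ser, "ion", (-4, 4))
        assert pc.total == 1 and pc.upward == 1

    def test_oscillation_inside_does_not_count(self):
        z = np.concatenate([np.linspace(-10, 0, 5),
                            np.linspace(0, -10, 5),
                            np.linspace(-10, 3, 5),
                            np.linspace(3, -10, 5)])
        pc = count_permeation(self._series(z[:, None]), "ion", (-4, 4))
        assert pc.total == 0

    def test_reversed_trajectory_flips_direction(self):
        z = np.linspace(-10, 10, 15)[:, None]
        fwd = count_permeation(self._series(z), "ion", (-4, 4))
        rev = count_permeation(self._series(z[::-1]), "ion", (-4, 4))
        assert fwd.total == rev.total == 1
        assert fwd.upward == 1 and rev.downward == 1

    def test_hysteresis_buffer_suppresses_boundary_noise(self):
        # touches the far boundary but never clears the 2 A buffer
        z = np.array([-10, -3, 4.5, -3, -10])[:, None]
        pc = count_permeation(self._series(z), "ion", (-4, 4))
        assert pc.total == 0

    def test_walked_ion_in_synthetic_frames(self):
        pore = make_c4_pore(PoreSpec(helix_length=14, lumen_radius=2.0,
                                     gate_index=7))
        ser = make_hydrated_frames(pore, n_frames=12, water_density=0.01,
                                   ion_count=1, ion_walk=(-12, 12),
                                   seed=2)
        pc = count_permeation(ser, "ion", (-4, 4))
        assert pc.total == 1
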