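"""Shape metrics, purity, virial stress, binned profiles, local strain."""

import numpy as np
import pytest
from scipy.spatial import Delaunay

import semcell as sc
from semcell.analysis import (DegenerateGeometryError, EmptySelectionError,
                              alpha_shape_outline, fit_ellipsoid,
                              normalize_range)
from semcell.model import ParticleSystem
from semcell.potentials import build_interaction_neighbor_list

from conftest import random_morse_system


def fib_sphere(n, radii=(1.0, 1.0, 1.0), seed=None):
    """Quasi-uniform points on an ellipsoid surface."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    theta = np.pi * (1 + 5**0.5) * k
    pts = np.column_stack([np.sin(phi) * np.cos(theta),
                           np.sin(phi) * np.sin(theta), np.cos(phi)])
    return pts * np.asarray(radii)


class TestShapeIndex:
    def test_square_corners(self):
        idx, area, per = sc.shape_index(np.array(
            [[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float))
        assert idx == pytest.approx(np.pi / 4, rel=1e-12)
        assert area == pytest.approx(1.0) and per == pytest.approx(4.0)

    def test_circle_limit(self):
        t = np.linspace(0, 2 * np.pi, 256, endpoint=False)
        idx, _, _ = sc.shape_index(np.column_stack([np.cos(t), np.sin(t)]))
        assert idx == pytest.approx(1.0, abs=1e-3)

    def test_equilateral_triangle(self):
        verts = np.array([[np.cos(a), np.sin(a)]
                          for a in (np.pi / 2, np.pi / 2 + 2 * np.pi / 3,
                                    np.pi / 2 + 4 * np.pi / 3)])
        idx, _, _ = sc.shape_index(verts)
        assert idx == pytest.approx(np.pi * np.sqrt(3) / 9, rel=1e-12)

    def test_similarity_invariance(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(-1, 1, (40, 2))
        idx0, _, _ = sc.shape_index(pts)
        ang = 1.1
        rot = np.array([[np.cos(ang), -np.sin(ang)],
                        [np.sin(ang), np.cos(ang)]])
        moved = 3.7 * pts @ rot.T + np.array([12.0, -4.0])
        idx1, _, _ = sc.shape_index(moved)
        assert idx1 == pytest.approx(idx0, abs=1e-9)

    def test_collinear_raises(self):
        pts = np.column_stack([np.arange(5.0), np.arange(5.0)])
        with pytest.raises(DegenerateGeometryError):
            sc.shape_index(pts)

    def test_alpha_shape_never_exceeds_hull_index(self):
        rng = np.random.default_rng(3)
        # a crescent: alpha shape hugs it, the hull bridges the bay
        t = rng.uniform(0, np.pi, 250)
        r = rng.uniform(1.5, 2.0, 250)
        pts = np.column_stack([r * np.cos(t), r * np.sin(t)])
        hull_idx, hull_a, _ = sc.shape_index(pts)
        alpha_idx, alpha_a, _ = sc.shape_index(pts, method="alpha_shape")
        assert alpha_idx <= hull_idx + 1e-12
        assert alpha_a <= hull_a + 1e-12

    def test_alpha_shape_is_single_polygon(self):
        pts = fib_sphere(120)[:, :2]
        poly = alpha_shape_outline(pts)
        assert poly.geom_type == "Polygon"
        assert poly.area > 0


class TestEllipticity:
    def test_sphere_is_zero(self):
        assert sc.ellipticity(fib_sphere(200)) == pytest.approx(0.0,
                                                                abs=1e-9)

    @pytest.mark.parametrize("radii,expected", [
        ((2.0, 1.0, 1.0), 0.5),
        ((4.0, 2.0, 1.0), 0.625),
    ])
    def test_reference_ellipsoids(self, radii, expected):
        pts = fib_sphere(300, radii)
        assert sc.ellipticity(pts) == pytest.approx(expected, abs=1e-6)

    def test_rotation_and_permutation_invariance(self):
        pts = fib_sphere(300, (3.0, 1.5, 1.0))
        f0 = sc.ellipticity(pts)
        rng = np.random.default_rng(1)
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        assert sc.ellipticity(pts @ q.T + 5.0) == pytest.approx(f0, abs=1e-9)
        assert sc.ellipticity(pts[rng.permutation(len(pts))]) == \
            pytest.approx(f0, abs=1e-12)

    def test_fit_recovers_center_and_radii(self):
        pts = fib_sphere(400, (3.0, 2.0, 1.0)) + np.array([1.0, -2.0, 0.5])
        center, radii, _ = fit_ellipsoid(pts)
        np.testing.assert_allclose(center, [1.0, -2.0, 0.5], atol=1e-9)
        np.testing.assert_allclose(radii, [3.0, 2.0, 1.0], rtol=1e-9)

    def test_degenerate_cloud_raises(self):
        flat = np.column_stack([np.random.default_rng(0).uniform(0, 1, (20, 2)),
                                np.zeros(20)])
        with pytest.raises(DegenerateGeometryError):
            sc.ellipticity(flat)


class TestPurity:
    def build(self, cyt, nuc):
        pos = np.vstack([cyt, nuc])
        kinds = np.array([1] * len(cyt) + [2] * len(nuc))
        return ParticleSystem(pos, kinds, np.ones(len(pos), bool),
                              np.zeros(len(pos), np.int64))

    def test_disjoint_is_zero(self):
        nuc = fib_sphere(20) * 1.0
        cyt = fib_sphere(50) * 1.0 + np.array([10.0, 0, 0])
        assert sc.nuclear_purity(self.build(cyt, nuc)) == 0.0

    def test_all_inside_is_hundred(self):
        nuc = fib_sphere(30) * 5.0
        cyt = np.random.default_rng(0).uniform(-1, 1, (40, 3))
        assert sc.nuclear_purity(self.build(cyt, nuc)) == 100.0

    def test_matches_delaunay_membership_oracle(self):
        rng = np.random.default_rng(4)
        nuc = rng.uniform(-2, 2, (40, 3))
        cyt = rng.uniform(-4, 4, (160, 3))
        system = self.build(cyt, nuc)
        got = sc.nuclear_purity(system)
        inside = Delaunay(nuc).find_simplex(cyt) >= 0
        # find_simplex includes boundary points; interior counting may
        # differ only on the measure-zero boundary
        assert got == pytest.approx(100.0 * inside.mean(), abs=1e-9)

    def test_mixed_denominator(self):
        nuc = fib_sphere(30) * 5.0
        cyt = np.random.default_rng(0).uniform(-1, 1, (40, 3))
        system = self.build(cyt, nuc)
        assert sc.nuclear_purity(system, denominator="mixed") == \
            pytest.approx(100.0 * 40 / 70)

    def test_too_few_nuclear_particles(self):
        system = self.build(np.zeros((5, 3)), fib_sphere(3))
        with pytest.raises(DegenerateGeometryError):
            sc.nuclear_purity(system)


class TestProjectedArea:
    def test_disc_area(self):
        t = np.linspace(0, 2 * np.pi, 400, endpoint=False)
        r = 3.0
        ring = np.column_stack([r * np.cos(t), r * np.sin(t), np.zeros(400)])
        system = ParticleSystem(ring, np.ones(400, np.int64),
                                np.ones(400, bool), np.zeros(400, np.int64))
        assert sc.projected_area(system) == pytest.approx(np.pi * r**2,
                                                          rel=2e-2)

    def test_triangle_and_empty_slab(self):
        tri = np.array([[0, 0, 0], [2, 0, 0], [0, 2, 0]], dtype=float)
        system = ParticleSystem(tri, np.ones(3, np.int64), np.ones(3, bool),
                                np.zeros(3, np.int64))
        assert sc.projected_area(system) == pytest.approx(2.0)
        with pytest.raises(EmptySelectionError):
            sc.projected_area(system, z_max=-1.0)


class TestStress:
    def test_isolated_pair_at_minimum_is_stress_free(self, test_params,
                                                     test_table):
        p = test_params
        pair = random_morse_system(2, p)
        pair.positions[:] = [[0, 0, 0], [p.deq, 0, 0]]
        nl = build_interaction_neighbor_list(pair.positions, pair.kinds,
                                             test_table)
        field = sc.per_particle_stress(pair, test_table, nl)
        np.testing.assert_allclose(field.tensor, 0, atol=1e-9 * p.u0)

    def test_compressed_pair_sign_and_magnitude(self, test_params,
                                                test_table):
        """A Morse pair at 0.8 deq is compressed: σm < 0 on both members,
        with magnitude r·F/6 per particle."""
        p = test_params
        d = 0.8 * p.deq
        pair = random_morse_system(2, p)
        pair.positions[:] = [[0, 0, 0], [d, 0, 0]]
        nl = build_interaction_neighbor_list(pair.positions, pair.kinds,
                                             test_table)
        field = sc.per_particle_stress(pair, test_table, nl)
        _, fmag = test_table.get(1, 1).energy_force(np.array([d]))
        assert fmag[0] > 0   # repulsive
        expected = -d * fmag[0] / 6.0
        assert field.sigma_m[0] == pytest.approx(expected, rel=1e-12)
        assert field.sigma_m[1] == pytest.approx(expected, rel=1e-12)
        assert np.all(field.sigma_m < 0)

    def test_global_virial_matches_double_loop(self, test_params,
                                               test_table):
        system = random_morse_system(60, test_params, seed=6)
        nl = build_interaction_neighbor_list(system.positions, system.kinds,
                                             test_table)
        total = sc.per_particle_stress(system, test_table, nl).tensor.sum(
            axis=0)
        oracle = np.zeros((3, 3))
        for i in range(60):
            for j in range(i + 1, 60):
                rij = system.positions[i] - system.positions[j]
                d = float(np.linalg.norm(rij))
                _, fmag = test_table.get(1, 1).energy_force(np.array([d]))
                fvec = fmag[0] / d * rij
                oracle += -np.outer(rij, fvec)
        np.testing.assert_allclose(total, oracle, rtol=1e-9,
                                   atol=1e-9 * np.abs(oracle).max())


class TestBinProfile:
    def test_constant_values(self):
        pos = np.random.default_rng(0).uniform(0, 10, 100)
        centers, means = sc.bin_profile(np.full(100, 2.5), pos, nbins=7)
        filled = ~np.isnan(means)
        np.testing.assert_allclose(means[filled], 2.5)

    def test_linear_field_tracks_bin_centers(self):
        pos = np.linspace(0, 10, 2000)
        centers, means = sc.bin_profile(pos.copy(), pos, nbins=10)
        np.testing.assert_allclose(means, centers, atol=0.01)

    def test_single_bin_is_global_mean(self):
        v = np.array([1.0, 2.0, 6.0])
        _, means = sc.bin_profile(v, np.array([0.0, 1.0, 2.0]), nbins=1)
        assert means[0] == pytest.approx(3.0)

    def test_empty_bins_are_nan(self):
        pos = np.array([0.0, 0.1, 9.9, 10.0])
        _, means = sc.bin_profile(np.ones(4), pos, nbins=5)
        assert np.isnan(means[1:4]).all()

    def test_normalization_band(self):
        v = np.linspace(-10, 10, 1001)
        out = normalize_range(v, 5, 95)
        assert out.min() == pytest.approx(-1) and out.max() == \
            pytest.approx(1)


class TestLocalShearStrain:
    def grid(self):
        g = np.linspace(0, 4, 5)
        X, Y, Z = np.meshgrid(g, g, g, indexing="ij")
        return np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def test_identity_and_rotation_are_strain_free(self):
        ref = self.grid()
        zero = sc.local_shear_strain(ref, ref, neighbor_radius=1.5)
        np.testing.assert_allclose(zero, 0, atol=1e-12)
        ang = 0.7
        rot = np.array([[np.cos(ang), -np.sin(ang), 0],
                        [np.sin(ang), np.cos(ang), 0], [0, 0, 1]])
        rotated = sc.local_shear_strain(ref, ref @ rot.T,
                                        neighbor_radius=1.5)
        np.testing.assert_allclose(rotated, 0, atol=1e-9)

    def test_affine_simple_shear_uniform(self):
        """γ = 0.1 simple shear: every particle carries the closed-form
        von Mises invariant of that deformation gradient."""
        gamma = 0.1
        ref = self.grid()
        F = np.eye(3)
        F[0, 1] = gamma
        cur = ref @ F.T
        strain = sc.local_shear_strain(ref, cur, neighbor_radius=1.5)
        E = 0.5 * (F.T @ F - np.eye(3))
        expected = np.sqrt(E[0, 1]**2 + E[0, 2]**2 + E[1, 2]**2
                           + ((E[0, 0] - E[1, 1])**2
                              + (E[1, 1] - E[2, 2])**2
                              + (E[0, 0] - E[2, 2])**2) / 6.0)
        np.testing.assert_allclose(strain, expected, rtol=1e-9)

    def test_underdetermined_marked_nan(self):
        ref = np.array([[0, 0, 0], [10, 0, 0], [20, 0, 0]], dtype=float)
        out = sc.local_shear_strain(ref, ref, neighbor_radius=1.0)
        assert np.isnan(out).all()
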