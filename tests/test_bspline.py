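"""Cubic B-spline FFD: basis identities, evaluation oracles, warping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import spinereg as sr
from spinereg.exceptions import DomainError


def random_transform(seed=3, shape=(7, 8), spacing=(10.0, 12.0),
                     origin=(-10.0, -12.0), scale=2.0):
    rng = np.random.default_rng(seed)
    phi = rng.normal(0, scale, shape + (len(shape),))
    return sr.BSplineTransform(phi, spacing, origin)


def interior_points(transform, n, seed=7, margin=0.5):
    lo, hi = transform.domain_bounds
    rng = np.random.default_rng(seed)
    return rng.uniform(lo + margin, hi - margin, size=(n, transform.ndim))


class TestBasis:
    def test_values_at_zero(self):
        assert sr.basis(0, 0.0) == pytest.approx(1 / 6)
        assert sr.basis(1, 0.0) == pytest.approx(2 / 3)
        assert sr.basis(2, 0.0) == pytest.approx(1 / 6)
        assert sr.basis(3, 0.0) == 0.0

    @given(st.floats(min_value=0.0, max_value=1.0, exclude_max=True))
    @settings(deadline=None)
    def test_partition_of_unity(self, n):
        assert sum(sr.basis(l, n) for l in range(4)) == pytest.approx(
            1.0, abs=1e-12)

    @given(st.floats(min_value=1e-6, max_value=1 - 1e-6))
    @settings(deadline=None)
    def test_kernel_symmetry(self, n):
        assert sr.basis(3, n) == pytest.approx(sr.basis(0, 1 - n), abs=1e-12)

    def test_invalid_index(self):
        with pytest.raises(ValueError):
            sr.basis(4, 0.5)

    @pytest.mark.parametrize("l", range(4))
    def test_derivatives_match_finite_differences(self, l):
        n = np.linspace(0.05, 0.95, 19)
        h = 1e-6
        d1 = (sr.basis(l, n + h) - sr.basis(l, n - h)) / (2 * h)
        np.testing.assert_allclose(sr.basis_d1(l, n), d1, atol=1e-8)
        d2 = (sr.basis_d1(l, n + h) - sr.basis_d1(l, n - h)) / (2 * h)
        np.testing.assert_allclose(sr.basis_d2(l, n), d2, atol=1e-8)


class TestLocalCoordinates:
    def test_point_on_control_point(self):
        t = random_transform()
        lc = t.to_local(np.array([10.0, 12.0]))  # exactly 2 spacings in
        np.testing.assert_allclose(lc.frac, 0.0, atol=1e-12)

    def test_cell_midpoint(self):
        t = random_transform()  # spacing (10, 12), origin (-10, -12)
        lc = t.to_local(np.array([-5.0, 0.0]))
        assert lc.frac[0] == pytest.approx(0.5)  # midpoint along axis 0
        assert lc.frac[1] == pytest.approx(0.0, abs=1e-12)  # on a node

    def test_reconstruction_identity(self):
        t = random_transform()
        pts = interior_points(t, 1000)
        cell, frac = t._local(pts)
        rebuilt = np.asarray(t.grid_origin) + \
            (cell + frac) * np.asarray(t.grid_spacing)
        np.testing.assert_allclose(rebuilt, pts, atol=1e-9)

    def test_out_of_domain_raises(self):
        t = random_transform()
        lo, _ = t.domain_bounds
        with pytest.raises(DomainError):
            t.to_local(lo - 1.0)


class TestTransformPoint:
    def test_identity(self, phantom2d):
        vol, _, _ = phantom2d
        t = sr.BSplineTransform.identity_for_domain(vol, 16.0)
        pts = vol.grid_points()
        np.testing.assert_array_equal(t.transform_points(pts), pts)

    def test_uniform_lattice_is_exact_translation(self):
        t = random_transform()
        t.phi[...] = np.array([1.25, -0.75])
        pts = interior_points(t, 500)
        np.testing.assert_allclose(t.transform_points(pts),
                                   pts + [1.25, -0.75], atol=1e-12)

    def test_single_control_point_vs_literal_sum(self):
        """Tensor-product displacement equals a brute-force 16-term sum."""
        t = sr.BSplineTransform(np.zeros((7, 8, 2)), (10.0, 12.0),
                                (-10.0, -12.0))
        t.phi[3, 4] = (1.5, -2.0)
        for p in interior_points(t, 25, seed=11):
            lc = t.to_local(p)
            disp = np.zeros(2)
            for l in range(4):
                for a in range(4):
                    w = sr.basis(l, lc.frac[0]) * sr.basis(a, lc.frac[1])
                    disp += w * t.phi[lc.cell[0] + l, lc.cell[1] + a]
            np.testing.assert_allclose(t.transform_point(p), p + disp,
                                       atol=1e-12)

    def test_locality_of_one_control_point(self):
        """Perturbing one control point only moves points in its support."""
        t0 = random_transform(scale=0.0)
        t1 = random_transform(scale=0.0)
        t1.phi[3, 4] = (5.0, 5.0)
        pts = interior_points(t1, 2000, seed=2)
        moved = np.linalg.norm(
            t1.transform_points(pts) - t0.transform_points(pts), axis=1) > 1e-14
        cell, _ = t1._local(pts)
        # support: cells whose 4x4 stencil includes index (3, 4)
        in_support = ((cell[:, 0] >= 0) & (cell[:, 0] + 3 >= 3)
                      & (cell[:, 0] <= 3)
                      & (cell[:, 1] + 3 >= 4) & (cell[:, 1] <= 4))
        assert not np.any(moved & ~in_support)

    def test_matches_simpleitk(self):
        """Independent oracle: SimpleITK's cubic B-spline transform."""
        sitk = pytest.importorskip("SimpleITK")
        t = random_transform()
        imgs = []
        for comp in (1, 0):  # sitk wants x-displacements first
            im = sitk.GetImageFromArray(
                np.ascontiguousarray(t.phi[:, :, comp]))
            im.SetSpacing((t.grid_spacing[1], t.grid_spacing[0]))
            # sitk's coefficient grid sits one spacing before ours
            im.SetOrigin((t.grid_origin[1] - t.grid_spacing[1],
                          t.grid_origin[0] - t.grid_spacing[0]))
            imgs.append(im)
        oracle = sitk.BSplineTransform(imgs, 3)
        for p in interior_points(t, 100, seed=5):
            q_ref = oracle.TransformPoint((p[1], p[0]))
            q = t.transform_point(p)
            np.testing.assert_allclose([q[1], q[0]], q_ref, atol=1e-9)


class TestSecondDerivatives:
    def test_identity_and_translation_have_zero_curvature(self):
        t = random_transform(scale=0.0)
        pts = interior_points(t, 100)
        np.testing.assert_array_equal(t.second_derivatives(pts), 0.0)
        t.phi[...] = (3.0, -4.0)
        np.testing.assert_allclose(t.second_derivatives(pts), 0.0, atol=1e-12)

    def test_matches_central_differences(self):
        t = random_transform(seed=9)
        pts = interior_points(t, 50, seed=13, margin=2.0)
        H = t.hessian(pts)
        h = 1e-3 * np.asarray(t.grid_spacing)
        scale = np.abs(H).max()
        for i in range(2):
            for j in range(2):
                ei = np.zeros(2)
                ej = np.zeros(2)
                ei[i] = h[i]
                ej[j] = h[j]
                fd = (t.transform_points(pts + ei + ej)
                      - t.transform_points(pts + ei - ej)
                      - t.transform_points(pts - ei + ej)
                      + t.transform_points(pts - ei - ej)) / (4 * h[i] * h[j])
                assert np.abs(fd - H[:, :, i, j]).max() / scale < 1e-3

    def test_six_component_layout_2d(self):
        t = random_transform(seed=9)
        pts = interior_points(t, 10)
        d2 = t.second_derivatives(pts)
        assert d2.shape == (10, 2, 6)
        # z-components vanish for 2D transforms
        np.testing.assert_array_equal(d2[:, :, 2], 0.0)
        np.testing.assert_array_equal(d2[:, :, 4], 0.0)
        np.testing.assert_array_equal(d2[:, :, 5], 0.0)


class TestWarp:
    def test_identity_warp_is_exact(self, phantom2d):
        vol, _, _ = phantom2d
        t = sr.BSplineTransform.identity_for_domain(vol, 16.0)
        np.testing.assert_array_equal(t.warp_image(vol).data, vol.data)

    def test_integer_voxel_translation(self, phantom2d):
        vol, _, _ = phantom2d
        t = sr.BSplineTransform.identity_for_domain(vol, 16.0)
        t.phi[...] = (0.0, 1.0)  # one voxel along x (spacing 1 mm)
        warped = t.warp_image(vol)
        np.testing.assert_array_equal(warped.data[:, :-1], vol.data[:, 1:])
        np.testing.assert_array_equal(warped.data[:, -1], 0.0)

    def test_warp_then_inverse_warp_small_error(self, phantom2d):
        """Numerical-inverse round trip on a smoothed phantom."""
        from scipy import ndimage
        vol, _, _ = phantom2d
        smooth = vol.copy_with(ndimage.gaussian_filter(vol.data, 2.0))
        cfg = sr.PhantomConfig(seed=0)
        t = sr.random_deformation(cfg, 1.5)
        warped = t.warp_image(smooth)
        pts = vol.grid_points()
        q = pts.copy()
        for _ in range(100):  # fixed-point inverse of a small deformation
            q = pts - t.displacement(q)
        coords = ((q - np.asarray(vol.origin))
                  / np.asarray(vol.spacing)).T
        back = ndimage.map_coordinates(warped.data, coords, order=1,
                                       cval=0.0).reshape(vol.shape)
        interior = np.zeros(vol.shape, bool)
        interior[4:-4, 4:-4] = True
        mae = np.abs(back - smooth.data)[interior].mean()
        assert mae / np.ptp(smooth.data) < 0.02

    def test_unknown_interpolation(self, phantom2d):
        vol, _, _ = phantom2d
        t = sr.BSplineTransform.identity_for_domain(vol, 16.0)
        with pytest.raises(ValueError):
            t.warp_image(vol, interpolation="cubic")


class Test3D:
    def test_full_3d_path(self):
        """Phantom, warp, Hessian and bending energy in three dimensions."""
        cfg = sr.PhantomConfig(shape=(40, 32, 32), seed=0)
        vol, mask, lms = sr.generate_phantom(cfg)
        t = sr.random_deformation(cfg, 2.0)
        warped = t.warp_image(vol)
        assert warped.shape == vol.shape
        assert t.warp_mask(mask).shape == mask.shape
        pts = vol.grid_points(stride=8)
        H = t.hessian(pts[:20])
        assert H.shape == (20, 3, 3, 3)
        # analytic vs finite differences on one mixed pair
        h = 1e-3 * np.asarray(t.grid_spacing)
        ei = np.array([h[0], 0, 0])
        ej = np.array([0, 0, h[2]])
        p = pts[:20]
        fd = (t.transform_points(p + ei + ej) - t.transform_points(p + ei - ej)
              - t.transform_points(p - ei + ej)
              + t.transform_points(p - ei - ej)) / (4 * h[0] * h[2])
        assert np.abs(fd - H[:, :, 0, 2]).max() / np.abs(H).max() < 1e-3
        assert sr.bending_energy(t, vol, stride=8) > 0


class TestSerialization:
    @pytest.mark.parametrize("ext", ["yaml", "json"])
    def test_round_trip_exact(self, tmp_path, ext):
        t = random_transform(seed=21)
        path = tmp_path / f"t.{ext}"
        t.save(path)
        back = sr.BSplineTransform.load(path)
        np.testing.assert_array_equal(back.phi, t.phi)
        assert back.grid_spacing == t.grid_spacing
        assert back.grid_origin == t.grid_origin

    def test_3d_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        t = sr.BSplineTransform(rng.normal(size=(5, 5, 5, 3)),
                                (8.0, 8.0, 8.0), (-8.0, -8.0, -8.0))
        path = tmp_path / "t.json"
        t.save(path)
        np.testing.assert_array_equal(sr.BSplineTransform.load(path).phi,
                                      t.phi)
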