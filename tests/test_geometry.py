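"""Forward/backward spherical projection, center grids and local scale."""

import numpy as np
import pytest
from scipy.ndimage import binary_dilation
from skimage.metrics import structural_similarity as ssim

from sphereseg.geometry import (
    ProjectionCenter,
    ProjectionGeometry,
    backward_project,
    forward_project,
    local_scale_map,
    make_center_grid,
    polar_angle,
    _spherical_sample_coords,
)
from sphereseg.images import PlanarImage

from conftest import disk_mask, smooth_image


class TestForwardProject:
    def test_constant_image_stays_constant(self, default_geometry, image_center):
        img = PlanarImage(np.full((192, 192), 2.5))
        sph = forward_project(img, default_geometry, image_center)
        # values are either the constant or blends with the fill value
        assert sph.pixels.max() <= 2.5 + 1e-9
        center_patch = sph.pixels[96:160, 96:160]
        np.testing.assert_allclose(center_patch, 2.5)

    def test_bright_pixel_at_center_maps_to_pole(self, default_geometry, image_center):
        img = np.zeros((192, 192))
        img[95, 95] = 1.0  # projection center pixel (95.5, 95.5) is between
        img[95, 96] = img[96, 95] = img[96, 96] = 1.0  # the four brightest
        sph = forward_project(PlanarImage(img), default_geometry, image_center)
        r, c = np.unravel_index(np.argmax(sph.pixels), sph.pixels.shape)
        assert abs(r - 127.5) < 2 and abs(c - 127.5) < 2

    def test_center_outside_image_rejected(self, default_geometry):
        img = PlanarImage(np.zeros((192, 192)))
        with pytest.raises(ValueError, match="outside"):
            forward_project(img, default_geometry, ProjectionCenter(-1.0, 50.0))

    def test_non_finite_pixels_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            PlanarImage(np.full((4, 4), np.nan))

    def test_wrong_image_size_rejected(self, default_geometry, image_center):
        with pytest.raises(ValueError, match="planar_grid_size"):
            forward_project(PlanarImage(np.zeros((64, 64))), default_geometry, image_center)

    def test_channel_independence(self, default_geometry, image_center):
        a = smooth_image(1).pixels
        b = smooth_image(2).pixels
        both = forward_project(
            PlanarImage(np.stack([a, b], axis=-1)), default_geometry, image_center
        )
        one = forward_project(PlanarImage(a), default_geometry, image_center)
        two = forward_project(PlanarImage(b), default_geometry, image_center)
        np.testing.assert_array_equal(both.pixels[..., 0], one.pixels)
        np.testing.assert_array_equal(both.pixels[..., 1], two.pixels)

    def test_center_covariance_under_translation(self, default_geometry, image_center):
        """Projecting about an off-center O equals projecting the
        correspondingly translated image about the image center."""
        img = np.zeros((192, 192))
        img[80:110, 85:115] = smooth_image(3, n=30).pixels  # interior support
        off = ProjectionCenter(image_center.row + 5, image_center.col - 7)
        a = forward_project(PlanarImage(img), default_geometry, off)
        shifted = np.roll(img, (-5, 7), axis=(0, 1))
        b = forward_project(PlanarImage(shifted), default_geometry, image_center)
        np.testing.assert_allclose(a.pixels, b.pixels, atol=1e-9)


class TestRoundTrip:
    def test_smooth_round_trip_ssim(self, default_geometry, image_center):
        for seed in range(5):
            img = smooth_image(seed)
            back = backward_project(forward_project(img, default_geometry, image_center))
            assert ssim(img.pixels, back.pixels, data_range=1.0) >= 0.95

    def test_constant_round_trip(self, default_geometry, image_center):
        img = PlanarImage(np.full((192, 192), 1.7))
        back = backward_project(forward_project(img, default_geometry, image_center))
        # exact away from the fill-value border band at the planar corners
        np.testing.assert_allclose(back.pixels[16:-16, 16:-16], 1.7, atol=1e-9)

    def test_binary_disk_round_trip_nearest(self):
        geom = ProjectionGeometry(planar_grid_size=96, spherical_grid_size=128)
        mask = disk_mask(96)
        center = ProjectionCenter(47.5, 47.5)
        img = PlanarImage(mask.pixels.astype(float))
        sph = forward_project(img, geom, center, order=0)
        back = backward_project(sph, order=0)
        out = back.pixels > 0.5
        diff = out ^ mask.astype_bool()
        m = mask.astype_bool()
        band = binary_dilation(m) & binary_dilation(~m)  # <=1 px from the contour
        assert not (diff & ~band).any()


class TestMagnification:
    def test_known_magnification_ratio(self, default_geometry):
        """dtheta/drho ratio between rho=0 and rho=0.5 is 3.78 for d=0.3."""
        eps = 1e-6
        d0 = (polar_angle(eps, default_geometry) - polar_angle(0.0, default_geometry)) / eps
        d5 = (
            polar_angle(0.5 + eps, default_geometry)
            - polar_angle(0.5 - eps, default_geometry)
        ) / (2 * eps)
        assert d0 / d5 == pytest.approx(3.7778, rel=1e-3)

    def test_local_scale_argmax_at_center(self, default_geometry):
        center = ProjectionCenter(60.0, 120.0)
        m = local_scale_map(default_geometry, center).pixels
        r, c = np.unravel_index(np.argmax(m), m.shape)
        assert (r, c) == (60, 120)

    def test_local_scale_radially_symmetric(self, default_geometry, image_center):
        m = local_scale_map(default_geometry, image_center).pixels
        np.testing.assert_allclose(m, m[::-1, :], rtol=1e-12)
        np.testing.assert_allclose(m, m[:, ::-1], rtol=1e-12)
        np.testing.assert_allclose(m, m.T, rtol=1e-12)

    def test_monotone_decay_along_rays(self, default_geometry, image_center):
        m = local_scale_map(default_geometry, image_center).pixels
        row = m[95, 95:]  # ray from center to the right
        assert np.all(np.diff(row) <= 1e-12)
        diag = np.diagonal(m)[95:]
        assert np.all(np.diff(diag) <= 1e-12)

    def test_jacobian_matches_finite_differences(self, default_geometry, image_center):
        """Analytic |J| equals the finite-difference Jacobian of the
        implemented planar->spherical coordinate map within 2%."""
        rows, cols = _spherical_sample_coords(default_geometry, image_center)
        dri, drj = np.gradient(rows)
        dci, dcj = np.gradient(cols)
        fd_jac = np.abs(dri * dcj - drj * dci)
        analytic = local_scale_map(default_geometry, image_center).pixels
        rng = np.random.default_rng(0)
        idx = rng.integers(10, 182, size=(50, 2))
        for r, c in idx:
            assert fd_jac[r, c] == pytest.approx(analytic[r, c], rel=0.02)


class TestCenterGrid:
    def test_single_center_is_image_center(self):
        cs = make_center_grid(192, 1)
        assert cs.count == 1
        assert (cs[0].row, cs[0].col) == (95.5, 95.5)

    def test_121_lattice_symmetric_about_center(self):
        cs = make_center_grid(192, 121, 0.5)
        assert cs.count == 121
        rows = np.array([c.row for c in cs])
        cols = np.array([c.col for c in cs])
        assert rows.mean() == pytest.approx(95.5)
        assert cols.mean() == pytest.approx(95.5)
        assert len(set(np.round(rows, 9))) == 11

    def test_3x3_lattice_coordinates(self):
        cs = make_center_grid(192, 9, 0.5)
        half_span = 0.5 * 191 / 2.0  # 47.75
        expected = [95.5 - half_span, 95.5, 95.5 + half_span]
        got_rows = sorted({c.row for c in cs})
        got_cols = sorted({c.col for c in cs})
        np.testing.assert_allclose(got_rows, expected)
        np.testing.assert_allclose(got_cols, expected)
        assert cs.count == 9

    def test_non_square_count_suggests_nearest(self):
        with pytest.raises(ValueError, match="121"):
            make_center_grid(192, 120)


class TestGeometryValidation:
    def test_plane_must_sit_inside_sphere(self):
        with pytest.raises(ValueError, match="smaller than sphere_radius"):
            ProjectionGeometry(plane_distance=1.5, sphere_radius=1.0)

    def test_positive_lengths_required(self):
        with pytest.raises(ValueError):
            ProjectionGeometry(plane_half_width=-0.5)

    def test_default_design(self, default_geometry):
        g = default_geometry
        assert (g.plane_half_width, g.sphere_radius, g.plane_distance) == (0.5, 1.0, 0.3)
        assert (g.spherical_grid_size, g.planar_grid_size) == (256, 192)
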