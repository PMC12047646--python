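"""Acquisition geometry: defaults, truncation arithmetic, ray parameterization."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from truncbct.geometry import (
    GeometryError,
    Ray,
    build_geometry,
    detector_u,
    kept_column_range,
    ray_for_pixel,
    scaled_geometry,
    source_position,
    truncation_fraction,
)


class TestBuildGeometry:
    def test_defaults_match_clinical_system(self):
        g = build_geometry()
        assert g.sdd == 898.0
        assert g.sad == 650.0
        assert g.n_views == 300
        assert g.angular_range == 360.0
        assert g.pixel_pitch == 0.388
        assert (g.det_cols_full, g.det_rows) == (1024, 768)

    def test_magnification(self):
        assert build_geometry().magnification == pytest.approx(898 / 650, abs=1e-12)
        assert build_geometry().magnification == pytest.approx(1.3815, abs=5e-4)

    def test_full_detector_is_untuncated_identity(self):
        g = build_geometry(truncated_cols=1024)
        assert not g.is_truncated
        assert kept_column_range(g) == (0, 1024)

    @pytest.mark.parametrize("bad", [
        dict(sad_mm=-1.0), dict(sdd_mm=100.0, sad_mm=650.0),
        dict(truncated_cols=2000), dict(truncated_cols=0),
        dict(pixel_pitch_mm=0.0),
    ])
    def test_invalid_configuration_rejected(self, bad):
        with pytest.raises(GeometryError):
            build_geometry(bad)

    def test_serialized_key_names_accepted(self):
        g = build_geometry({"sad_mm": 600.0, "sdd_mm": 900.0, "angular_range_deg": 360.0})
        assert g.sad == 600.0 and g.sdd == 900.0


class TestTruncationFraction:
    @pytest.mark.parametrize("m,expected", [
        (596, 428 / 1024), (1024, 0.0), (536, 488 / 1024), (512, 0.5),
    ])
    def test_values(self, m, expected):
        g = build_geometry(truncated_cols=m)
        assert truncation_fraction(g) == pytest.approx(expected, abs=1e-12)

    @given(st.integers(min_value=513, max_value=1023))
    def test_monotone_decreasing_in_kept_columns(self, m):
        g1 = build_geometry(truncated_cols=m)
        g2 = build_geometry(truncated_cols=m + 1)
        assert truncation_fraction(g1) > truncation_fraction(g2)


class TestRays:
    def test_central_ray_passes_through_rotation_axis(self):
        g = build_geometry()
        # central column lies between indices 511 and 512; use geometry math
        ray = ray_for_pixel(g, 0.0, g.det_rows // 2, 511)
        s, d = ray.source, ray.detector_point
        # perpendicular distance of the axis (origin) from the ray, in-plane
        v = (d - s)[:2]
        dist = abs(s[0] * v[1] - s[1] * v[0]) / np.linalg.norm(v)
        assert dist < 0.5 * g.pixel_pitch  # within half a pixel of the axis

    def test_central_pixel_ray_length_equals_sdd(self):
        g = build_geometry(det_cols_full=1023, det_rows=767)  # odd: exact center
        ray = ray_for_pixel(g, 33.0, 383, 511)
        assert ray.length == pytest.approx(g.sdd, rel=1e-12)

    def test_conjugate_rays_coincide_in_central_plane(self):
        g = build_geometry()
        row = g.det_rows // 2
        for col in (200, 400, 700, 900):
            u = float(detector_u(g, col))
            gamma = np.degrees(np.arctan(u / g.sdd))
            r1 = ray_for_pixel(g, 0.0, row, col)
            # conjugate: view + 180 - 2 gamma, mirrored column
            col_conj = int(round(g.det_cols_full - 1 - col))
            r2 = ray_for_pixel(g, 180.0 - 2 * gamma, row, col_conj)
            # both rays describe the same line: endpoints mutually colinear
            p, q = r1.source[:2], r1.detector_point[:2]
            for point in (r2.source[:2], r2.detector_point[:2]):
                cross = (q - p)[0] * (point - p)[1] - (q - p)[1] * (point - p)[0]
                assert abs(cross) / np.linalg.norm(q - p) < 1.0  # mm

    def test_out_of_bounds_pixel_raises(self):
        g = build_geometry()
        with pytest.raises(IndexError):
            ray_for_pixel(g, 0.0, g.det_rows, 0)

    def test_sample_fractions_strictly_increasing(self):
        g = build_geometry()
        ray = ray_for_pixel(g, 10.0, 5, 5, n_samples=32,
                            rng=np.random.default_rng(0))
        assert np.all(np.diff(ray.sample_fractions) > 0)
        assert ray.sample_points.shape == (32, 3)
        # t_i = s + alpha_i (d - s)
        recon = ray.source + ray.sample_fractions[:, None] * (
            ray.detector_point - ray.source)
        np.testing.assert_allclose(ray.sample_points, recon)

    def test_bad_fractions_rejected(self):
        with pytest.raises(GeometryError):
            Ray(source=np.zeros(3), detector_point=np.ones(3),
                sample_fractions=np.array([0.5, 0.4]))


class TestPixelRoundTrip:
    def test_ray_back_to_pixel(self):
        from truncbct.geometry import detector_frame
        g = build_geometry()
        rng = np.random.default_rng(1)
        for _ in range(20):
            row = int(rng.integers(0, g.det_rows))
            col = int(rng.integers(0, g.det_cols_full))
            ang = float(rng.uniform(0, 360))
            ray = ray_for_pixel(g, ang, row, col)
            center, e_u, e_v = detector_frame(g, ang)
            rel = ray.detector_point - center
            col_back = rel @ e_u / g.pixel_pitch + (g.det_cols_full - 1) / 2
            row_back = rel @ e_v / g.pixel_pitch + (g.det_rows - 1) / 2
            assert round(col_back) == col and round(row_back) == row


class TestScaledGeometry:
    def test_preserves_physical_extent(self):
        g = build_geometry(truncated_cols=596)
        s = scaled_geometry(g, 4)
        assert s.det_cols_full * s.pixel_pitch == pytest.approx(
            g.det_cols_full * g.pixel_pitch)
        assert s.truncated_cols == 149
        assert s.fov_radius == pytest.approx(g.fov_radius)

    def test_truncation_must_keep_central_column(self):
        g = build_geometry(truncated_cols=500)  # kept block excludes the axis
        with pytest.raises(GeometryError):
            kept_column_range(g)
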