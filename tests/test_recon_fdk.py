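"""Fan-beam FBP / FDK with redundancy weighting, and the shading-artifact score."""

import numpy as np
import pytest

from truncbct.geometry import detector_u
from truncbct.projector import forward_project, truncate_sinogram
from truncbct.recon_fdk import (
    ReconError,
    artifact_score,
    fdk_reconstruct,
    redundancy_weights,
)

from conftest import DISK_MU, DISK_RADIUS_MM, GRID_N, VOX_MM, antialiased_disk


def interior_mask(n=GRID_N, vox=VOX_MM, r=0.8 * DISK_RADIUS_MM, cx=6.0, cy=-4.0):
    yy, xx = np.indices((n, n))
    return np.hypot((yy - (n - 1) / 2) * vox - cy, (xx - (n - 1) / 2) * vox - cx) < r


@pytest.fixture(scope="module")
def reference_fdk(disk_sinogram):
    return fdk_reconstruct(disk_sinogram, grid_shape=GRID_N, voxel_size_mm=VOX_MM)


class TestRedundancyWeights:
    def test_partition_of_unity_in_overlap_band(self, geom):
        g = geom.with_truncation(149)
        w = redundancy_weights(g)[0]
        u = detector_u(g, np.arange(g.det_cols_full))
        d = abs(u[g.det_cols_full - 149])
        band = np.abs(u) <= d
        cols = np.nonzero(band)[0]
        for c in cols:
            # conjugate column: mirrored u (uniform grid -> mirrored index)
            c_conj = g.det_cols_full - 1 - c
            if band[c_conj]:
                assert w[c] + w[c_conj] == pytest.approx(1.0, abs=1e-12)

    def test_axis_column_weight_half(self, geom):
        g = geom.with_truncation(149)
        w = redundancy_weights(g)[0]
        u = detector_u(g, np.arange(g.det_cols_full))
        w_axis = np.interp(0.0, u, w)
        assert w_axis == pytest.approx(0.5, abs=1e-6)

    def test_weights_bounded_and_zero_on_missing(self, geom):
        g = geom.with_truncation(134)
        w = redundancy_weights(g)
        assert np.all((w >= 0) & (w <= 1))
        lo = g.det_cols_full - 134
        assert np.all(w[:, :lo] == 0)

    def test_zero_overlap_falls_back_to_step(self, geom):
        g = geom.with_truncation(geom.det_cols_full // 2)
        with pytest.warns(UserWarning):
            w = redundancy_weights(g)[0]
        kept = w[geom.det_cols_full // 2:]
        assert set(np.round(kept, 6)) <= {0.0, 0.5, 1.0}

    def test_complete_detector_constant_half(self, geom):
        w = redundancy_weights(geom)
        assert np.all(w == 0.5)


class TestFdkReconstruct:
    def test_uniform_disk_interior_recovered(self, geom):
        from truncbct.projector import forward_project
        vol = antialiased_disk(GRID_N, VOX_MM, DISK_RADIUS_MM, DISK_MU)
        sino = forward_project(vol, geom, VOX_MM)
        rec = fdk_reconstruct(sino, grid_shape=GRID_N, voxel_size_mm=VOX_MM)
        vals = rec.values[interior_mask(cx=0.0, cy=0.0)]
        assert vals.mean() == pytest.approx(DISK_MU, rel=0.02)

    def test_zero_sinogram_gives_zero_volume(self, disk_sinogram):
        import dataclasses
        zero = dataclasses.replace(disk_sinogram, data=np.zeros_like(disk_sinogram.data))
        rec = fdk_reconstruct(zero, grid_shape=64, voxel_size_mm=VOX_MM)
        assert np.allclose(rec.values, 0)

    def test_linearity(self, disk_sinogram, reference_fdk):
        import dataclasses
        doubled = dataclasses.replace(disk_sinogram, data=2 * disk_sinogram.data)
        rec2 = fdk_reconstruct(doubled, grid_shape=GRID_N, voxel_size_mm=VOX_MM)
        np.testing.assert_allclose(rec2.values, 2 * reference_fdk.values, atol=1e-10)

    def test_truncated_without_weights_refused(self, disk_sinogram):
        trunc = truncate_sinogram(disk_sinogram, 149)
        with pytest.raises(ReconError):
            fdk_reconstruct(trunc, grid_shape=64)

    def test_weight_conventions_agree_on_complete_data(self, disk_sinogram, geom,
                                                       reference_fdk):
        w = redundancy_weights(geom)  # constant 1/2
        rec = fdk_reconstruct(disk_sinogram, weights=w, grid_shape=GRID_N,
                              voxel_size_mm=VOX_MM)
        rms = np.sqrt(np.mean((rec.values - reference_fdk.values) ** 2))
        assert rms <= 0.005 * DISK_MU

    def test_fdkw_matches_complete_fdk_at_640_equivalent(self, disk_sinogram,
                                                         reference_fdk):
        trunc = truncate_sinogram(disk_sinogram, 160)  # 640-equivalent
        w = redundancy_weights(trunc.geometry)
        rec = fdk_reconstruct(trunc, weights=w, grid_shape=GRID_N, voxel_size_mm=VOX_MM)
        inside = interior_mask()
        rms = np.sqrt(np.mean((rec.values - reference_fdk.values)[inside] ** 2))
        assert rms <= 0.02 * DISK_MU


class TestConeBeam3D:
    def test_fdk_recovers_ellipsoid_interior(self):
        """Reduced-grid cone-beam round trip: project a uniform ellipsoid and
        recover its interior attenuation with 3-D FDK."""
        from truncbct.geometry import build_geometry
        g = build_geometry(det_cols_full=96, det_rows=64, pixel_pitch=4.0,
                           n_views=90)
        n = 48
        zz, yy, xx = np.indices((n, n, n))
        c = (n - 1) / 2
        vox = 4.0
        ell = ((xx - c) / 18) ** 2 + ((yy - c) / 18) ** 2 + ((zz - c) / 10) ** 2 <= 1
        vol = 0.2 * ell.astype(float)
        sino = forward_project(vol, g, vox)
        rec = fdk_reconstruct(sino, grid_shape=(n, n, n), voxel_size_mm=vox)
        core = ((xx - c) / 12) ** 2 + ((yy - c) / 12) ** 2 + ((zz - c) / 5) ** 2 <= 1
        assert rec.values[core].mean() == pytest.approx(0.2, rel=0.05)


class TestArtifactScore:
    def test_identity_is_zero(self, reference_fdk):
        assert artifact_score(reference_fdk, reference_fdk) == 0.0

    def test_centered_disk_bias_scores_its_amplitude(self, reference_fdk):
        ref = reference_fdk.values
        interior = ref > 0.5 * np.percentile(ref, 99)
        bias = 0.10 * ref[interior].mean()
        n = ref.shape[0]
        yy, xx = np.indices(ref.shape)
        disk = np.hypot(yy - (n - 1) / 2, xx - (n - 1) / 2) < n / 8
        biased = ref + bias * disk
        score = artifact_score(biased, ref, VOX_MM)
        assert score == pytest.approx(0.10, abs=0.015)

    def test_grid_mismatch_rejected(self, reference_fdk):
        with pytest.raises(ReconError):
            artifact_score(np.zeros((10, 10)), reference_fdk.values, VOX_MM)

    def test_fixed_transition_severity_grows_with_truncation(self, disk_sinogram,
                                                             geom, reference_fdk):
        """The knee: with the weighting transition fixed at the widest studied
        overlap, shading worsens monotonically as the detector narrows."""
        u = detector_u(geom, np.arange(geom.det_cols_full))
        W = abs(u[geom.det_cols_full - 149])  # design overlap (596-equivalent)
        scores = []
        for m in (149, 143, 137, 134):
            trunc = truncate_sinogram(disk_sinogram, m)
            w = redundancy_weights(trunc.geometry, transition_half_width_mm=W)
            rec = fdk_reconstruct(trunc, weights=w, grid_shape=GRID_N,
                                  voxel_size_mm=VOX_MM)
            scores.append(artifact_score(rec, reference_fdk, VOX_MM))
        assert all(a < b for a, b in zip(scores, scores[1:]))
        assert scores[0] < 0.05 < scores[-1]
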