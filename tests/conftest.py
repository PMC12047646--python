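"""Shared fixtures: scaled geometry, analytic disk phantoms, reusable sinograms.

Expensive objects (forward projections, trained attenuation fields) are
session-scoped so the suite pays for them once.
"""

import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from truncbct.geometry import build_geometry, scaled_geometry
from truncbct.projector import forward_project
from truncbct.spectrum_materials import default_material_table, make_spectrum

settings.register_profile(
    "suite", deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    derandomize=True,
)
settings.load_profile("suite")

# attenuation of the adipose-like disk used throughout (cm^-1)
DISK_MU = 0.2318
DISK_RADIUS_MM = 50.0
VOX_MM = 1.8
GRID_N = 128


def antialiased_disk(n, vox, r_mm, mu, ss=4, cx_mm=0.0, cy_mm=0.0):
    """Grayscale rasterized disk (supersampled partial-volume edges)."""
    c = (n - 1) / 2
    yy, xx = np.meshgrid(np.arange(n * ss), np.arange(n * ss), indexing="ij")
    inside = (((xx + 0.5) / ss - 0.5 - c - cx_mm / vox) ** 2
              + ((yy + 0.5) / ss - 0.5 - c - cy_mm / vox) ** 2) <= (r_mm / vox) ** 2
    return mu * inside.reshape(n, ss, n, ss).mean(axis=(1, 3))


@pytest.fixture(scope="session")
def geom():
    """Desk-scale fan-beam geometry: 4x-binned detector, 150 views."""
    g = scaled_geometry(build_geometry(), 4)
    return build_geometry(
        det_cols_full=g.det_cols_full, det_rows=g.det_rows,
        pixel_pitch=g.pixel_pitch, n_views=150,
    )


@pytest.fixture(scope="session")
def material_table():
    return default_material_table()


@pytest.fixture(scope="session")
def spectrum49():
    return make_spectrum(49.0, 1.39)


@pytest.fixture(scope="session")
def disk_volume():
    """Off-center adipose disk with an embedded low-contrast insert."""
    return (antialiased_disk(GRID_N, VOX_MM, DISK_RADIUS_MM, DISK_MU, cx_mm=6, cy_mm=-4)
            + antialiased_disk(GRID_N, VOX_MM, 18.0, 0.06, cx_mm=-10, cy_mm=8))


@pytest.fixture(scope="session")
def disk_sinogram(disk_volume, geom):
    return forward_project(disk_volume, geom, VOX_MM)


@pytest.fixture(scope="session")
def trained_disk_field(disk_sinogram):
    """Field trained on the truncated (536-equivalent) noise-free disk sinogram."""
    from truncbct.projector import truncate_sinogram
    from truncbct.recon_afn import AFNConfig, train_field

    trunc = truncate_sinogram(disk_sinogram, 134)
    fld = train_field(trunc, AFNConfig.small(steps=1200, rng_seed=7))
    return fld, trunc
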