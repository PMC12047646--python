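"""Forward model: ray-driven line integrals, counting noise, truncation emulation.

The primary test surface is the 2-D fan-beam path (a single central detector
row); the full 3-D cone-beam path is supported at reduced grids.  Volumes are
attenuation grids in cm^-1 centered on the isocenter; line integrals are
dimensionless (mu * path length).

The forward projector samples the volume with bi/trilinear interpolation at a
fixed step along each ray (default: half the voxel size, Joseph-style); the
backprojector used by the iterative reconstructions is its exact adjoint.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numba
import numpy as np

from .geometry import SystemGeometry, detector_u, detector_v, kept_column_range
from .spectrum_materials import Spectrum

__all__ = [
    "Sinogram",
    "forward_project",
    "back_project",
    "apply_counting_noise",
    "counts_to_line_integrals",
    "truncate_sinogram",
    "conjugate_resample",
]

MM_TO_CM = 0.1


class ProjectorError(ValueError):
    pass


@dataclass
class Sinogram:
    """View x row x column projection data with geometry handle and validity mask.

    ``domain`` is ``"line_integral"`` (dimensionless) or ``"counts"`` (photons).
    """

    data: np.ndarray  # (n_views, n_rows, n_cols)
    geometry: SystemGeometry
    validity_mask: np.ndarray  # bool, same shape
    domain: Literal["line_integral", "counts"] = "line_integral"
    i0: float | None = None  # photons/pixel used when domain == "counts"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim == 2:  # fan-beam convenience: insert a singleton row
            self.data = self.data[:, None, :]
        if self.validity_mask is None:
            self.validity_mask = np.ones(self.data.shape, dtype=bool)
        self.validity_mask = np.asarray(self.validity_mask, dtype=bool)
        if self.validity_mask.shape != self.data.shape:
            raise ProjectorError("validity_mask shape differs from data shape")
        if not np.all(np.isfinite(self.data)):
            raise ProjectorError("sinogram data must be finite")
        if self.domain == "counts" and np.any(self.data < 0):
            raise ProjectorError("counts must be non-negative")

    @property
    def n_views(self) -> int:
        return self.data.shape[0]

    @property
    def n_rows(self) -> int:
        return self.data.shape[1]

    @property
    def n_cols(self) -> int:
        return self.data.shape[2]

    def plane(self) -> np.ndarray:
        """The central-row (view x column) array — the fan-beam working plane."""
        return self.data[:, self.n_rows // 2, :]


# ---------------------------------------------------------------------------
# numba kernels (2-D fan beam)
# ---------------------------------------------------------------------------


@numba.njit(cache=True, fastmath=True)
def _ray_box_range(sx, sy, dx, dy, half_mm):
    """Parametric [t0, t1] (mm along unit direction) where the ray meets the box."""
    t0, t1 = 0.0, 1.0e30
    for axis in range(2):
        s = sx if axis == 0 else sy
        d = dx if axis == 0 else dy
        if abs(d) < 1e-12:
            if abs(s) > half_mm:
                return 1.0, 0.0
        else:
            ta = (-half_mm - s) / d
            tb = (half_mm - s) / d
            if ta > tb:
                ta, tb = tb, ta
            if ta > t0:
                t0 = ta
            if tb < t1:
                t1 = tb
    return t0, t1


@numba.njit(cache=True, fastmath=True)
def _bilinear(vol, fy, fx):
    ny, nx = vol.shape
    if fx < 0.0 or fy < 0.0 or fx > nx - 1.0 or fy > ny - 1.0:
        return 0.0
    ix = int(fx)
    iy = int(fy)
    if ix >= nx - 1:
        ix = nx - 2
    if iy >= ny - 1:
        iy = ny - 2
    wx = fx - ix
    wy = fy - iy
    return (
        vol[iy, ix] * (1 - wy) * (1 - wx)
        + vol[iy, ix + 1] * (1 - wy) * wx
        + vol[iy + 1, ix] * wy * (1 - wx)
        + vol[iy + 1, ix + 1] * wy * wx
    )


@numba.njit(cache=True, fastmath=True)
def _forward_fan_kernel(vol, vox, sad, sdd, angles, u_mm, step, out):
    ny, nx = vol.shape
    half = 0.5 * max(nx, ny) * vox
    cy = (ny - 1) / 2.0
    cx = (nx - 1) / 2.0
    for iv in range(angles.shape[0]):
        th = angles[iv]
        cth = np.cos(th)
        sth = np.sin(th)
        sx = sad * cth
        sy = sad * sth
        for ic in range(u_mm.shape[0]):
            u = u_mm[ic]
            # detector point
            px = sx - sdd * cth - u * sth
            py = sy - sdd * sth + u * cth
            dx = px - sx
            dy = py - sy
            norm = np.sqrt(dx * dx + dy * dy)
            dx /= norm
            dy /= norm
            t0, t1 = _ray_box_range(sx, sy, dx, dy, half)
            if t1 <= t0:
                out[iv, ic] = 0.0
                continue
            n_steps = int((t1 - t0) / step) + 1
            acc = 0.0
            for k in range(n_steps):
                t = t0 + (k + 0.5) * step
                if t > t1:
                    break
                x = sx + t * dx
                y = sy + t * dy
                acc += _bilinear(vol, cy + y / vox, cx + x / vox)
            out[iv, ic] = acc * step * 0.1


@numba.njit(cache=True, fastmath=True)
def _back_fan_kernel(sino, vox, sad, sdd, angles, u_mm, step, vol):
    """Exact adjoint of _forward_fan_kernel (scatter with the same weights)."""
    ny, nx = vol.shape
    half = 0.5 * max(nx, ny) * vox
    cy = (ny - 1) / 2.0
    cx = (nx - 1) / 2.0
    for iv in range(angles.shape[0]):
        th = angles[iv]
        cth = np.cos(th)
        sth = np.sin(th)
        sx = sad * cth
        sy = sad * sth
        for ic in range(u_mm.shape[0]):
            val = sino[iv, ic] * step * 0.1
            if val == 0.0:
                continue
            u = u_mm[ic]
            px = sx - sdd * cth - u * sth
            py = sy - sdd * sth + u * cth
            dx = px - sx
            dy = py - sy
            norm = np.sqrt(dx * dx + dy * dy)
            dx /= norm
            dy /= norm
            t0, t1 = _ray_box_range(sx, sy, dx, dy, half)
            if t1 <= t0:
                continue
            n_steps = int((t1 - t0) / step) + 1
            for k in range(n_steps):
                t = t0 + (k + 0.5) * step
                if t > t1:
                    break
                x = sx + t * dx
                y = sy + t * dy
                fx = cx + x / vox
                fy = cy + y / vox
                if fx < 0.0 or fy < 0.0 or fx > nx - 1.0 or fy > ny - 1.0:
                    continue
                ix = int(fx)
                iy = int(fy)
                if ix >= nx - 1:
                    ix = nx - 2
                if iy >= ny - 1:
                    iy = ny - 2
                wx = fx - ix
                wy = fy - iy
                vol[iy, ix] += val * (1 - wy) * (1 - wx)
                vol[iy, ix + 1] += val * (1 - wy) * wx
                vol[iy + 1, ix] += val * wy * (1 - wx)
                vol[iy + 1, ix + 1] += val * wy * wx


@numba.njit(cache=True, fastmath=True)
def _trilinear(vol, fz, fy, fx):
    nz, ny, nx = vol.shape
    if fx < 0.0 or fy < 0.0 or fz < 0.0 or fx > nx - 1.0 or fy > ny - 1.0 or fz > nz - 1.0:
        return 0.0
    ix = min(int(fx), nx - 2)
    iy = min(int(fy), ny - 2)
    iz = min(int(fz), nz - 2)
    wx = fx - ix
    wy = fy - iy
    wz = fz - iz
    c00 = vol[iz, iy, ix] * (1 - wx) + vol[iz, iy, ix + 1] * wx
    c01 = vol[iz, iy + 1, ix] * (1 - wx) + vol[iz, iy + 1, ix + 1] * wx
    c10 = vol[iz + 1, iy, ix] * (1 - wx) + vol[iz + 1, iy, ix + 1] * wx
    c11 = vol[iz + 1, iy + 1, ix] * (1 - wx) + vol[iz + 1, iy + 1, ix + 1] * wx
    return (c00 * (1 - wy) + c01 * wy) * (1 - wz) + (c10 * (1 - wy) + c11 * wy) * wz


@numba.njit(cache=True, fastmath=True)
def _forward_cone_kernel(vol, vox, sad, sdd, angles, u_mm, v_mm, step, out):
    nz, ny, nx = vol.shape
    half = 0.5 * max(nx, ny) * vox
    half_z = 0.5 * nz * vox
    cz = (nz - 1) / 2.0
    cy = (ny - 1) / 2.0
    cx = (nx - 1) / 2.0
    for iv in range(angles.shape[0]):
        th = angles[iv]
        cth = np.cos(th)
        sth = np.sin(th)
        sx = sad * cth
        sy = sad * sth
        for ir in range(v_mm.shape[0]):
            v = v_mm[ir]
            for ic in range(u_mm.shape[0]):
                u = u_mm[ic]
                px = sx - sdd * cth - u * sth
                py = sy - sdd * sth + u * cth
                pz = v
                dx = px - sx
                dy = py - sy
                dz = pz
                norm = np.sqrt(dx * dx + dy * dy + dz * dz)
                dx /= norm
                dy /= norm
                dz /= norm
                t0, t1 = _ray_box_range(sx, sy, dx, dy, half)
                if abs(dz) > 1e-12:
                    ta = (-half_z) / dz
                    tb = half_z / dz
                    if ta > tb:
                        ta, tb = tb, ta
                    if ta > t0:
                        t0 = ta
                    if tb < t1:
                        t1 = tb
                if t1 <= t0:
                    out[iv, ir, ic] = 0.0
                    continue
                n_steps = int((t1 - t0) / step) + 1
                acc = 0.0
                for k in range(n_steps):
                    t = t0 + (k + 0.5) * step
                    if t > t1:
                        break
                    x = sx + t * dx
                    y = sy + t * dy
                    z = t * dz
                    acc += _trilinear(vol, cz + z / vox, cy + y / vox, cx + x / vox)
                out[iv, ir, ic] = acc * step * 0.1


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def forward_project(
    volume: np.ndarray,
    geom: SystemGeometry,
    voxel_size_mm: float,
    step_mm: float | None = None,
) -> Sinogram:
    """Line integrals of an attenuation volume (cm^-1) over all views.

    2-D input (ny, nx) produces a single-row fan-beam sinogram; 3-D input
    (nz, ny, nx) produces the full cone-beam sinogram.  The volume must fit
    inside the scan field of view of the complete detector.
    """
    volume = np.ascontiguousarray(volume, dtype=np.float64)
    half_extent = 0.5 * max(volume.shape[-2:]) * voxel_size_mm
    if half_extent > geom.sad:
        raise ProjectorError("volume extends past the source orbit")
    step = step_mm if step_mm is not None else 0.5 * voxel_size_mm
    angles = np.deg2rad(geom.view_angles_deg)
    u_mm = detector_u(geom, np.arange(geom.det_cols_full)).astype(np.float64)
    if volume.ndim == 2:
        out = np.zeros((geom.n_views, geom.det_cols_full))
        _forward_fan_kernel(volume, voxel_size_mm, geom.sad, geom.sdd, angles, u_mm, step, out)
        data = out[:, None, :]
    elif volume.ndim == 3:
        v_mm = detector_v(geom, np.arange(geom.det_rows)).astype(np.float64)
        data = np.zeros((geom.n_views, geom.det_rows, geom.det_cols_full))
        _forward_cone_kernel(
            volume, voxel_size_mm, geom.sad, geom.sdd, angles, u_mm, v_mm, step, data
        )
    else:
        raise ProjectorError("volume must be 2-D or 3-D")
    return Sinogram(data=data, geometry=geom, validity_mask=np.ones(data.shape, bool))


def back_project(
    sino_plane: np.ndarray,
    geom: SystemGeometry,
    grid_shape: tuple,
    voxel_size_mm: float,
    step_mm: float | None = None,
) -> np.ndarray:
    """Exact adjoint of the 2-D fan-beam forward projector (not filtered)."""
    step = step_mm if step_mm is not None else 0.5 * voxel_size_mm
    angles = np.deg2rad(geom.view_angles_deg)
    u_mm = detector_u(geom, np.arange(geom.det_cols_full)).astype(np.float64)
    vol = np.zeros(grid_shape)
    _back_fan_kernel(
        np.ascontiguousarray(sino_plane, dtype=np.float64),
        voxel_size_mm, geom.sad, geom.sdd, angles, u_mm, step, vol,
    )
    return vol


def apply_counting_noise(
    sino: Sinogram,
    i0: float,
    rng_seed: int = 0,
    spectrum: Spectrum | None = None,
    noiseless: bool = False,
) -> Sinogram:
    """Poisson counting noise: counts ~ Poisson(i0 * exp(-p)) per acquired pixel.

    The default mode treats the line integrals as monoenergetic at the
    spectrum's effective energy (``spectrum`` is accepted for interface parity
    and future polyenergetic use; it does not change the monoenergetic noise
    model).  ``noiseless=True`` returns the exact expectations, so the
    round trip through :func:`counts_to_line_integrals` is the identity.
    """
    if sino.domain != "line_integral":
        raise ProjectorError("counting noise applies to line-integral sinograms")
    if i0 is None or i0 <= 0:
        raise ProjectorError("i0 must be positive")
    expected = i0 * np.exp(-sino.data)
    if noiseless:
        counts = expected
    else:
        rng = np.random.default_rng(rng_seed)
        counts = rng.poisson(expected).astype(np.float64)
    counts[~sino.validity_mask] = 0.0
    return Sinogram(
        data=counts, geometry=sino.geometry, validity_mask=sino.validity_mask.copy(),
        domain="counts", i0=i0,
    )


def counts_to_line_integrals(sino: Sinogram) -> Sinogram:
    """Log-convert a counts sinogram back to line integrals: p = -ln(counts / i0)."""
    if sino.domain != "counts":
        return sino
    if sino.i0 is None:
        raise ProjectorError("counts sinogram lacks its i0")
    counts = np.maximum(sino.data, 0.5)  # guard empty pixels
    p = -np.log(counts / sino.i0)
    p[~sino.validity_mask] = 0.0
    return Sinogram(
        data=p, geometry=sino.geometry, validity_mask=sino.validity_mask.copy(),
        domain="line_integral",
    )


def truncate_sinogram(
    sino: Sinogram, m: int, side: str | None = None, keep_data: bool = False
) -> Sinogram:
    """Emulate the truncated detector: keep ``m`` contiguous fan-direction columns.

    Removed pixels are flagged invalid (and zeroed unless ``keep_data``, which
    retains them for oracle comparisons).  The cone-angle extent is unchanged.
    """
    geom = sino.geometry.with_truncation(m, side)
    lo, hi = kept_column_range(geom)  # raises if central column excluded
    mask = np.zeros(sino.data.shape, dtype=bool)
    mask[:, :, lo:hi] = sino.validity_mask[:, :, lo:hi]
    data = sino.data.copy()
    if not keep_data:
        data[~mask] = 0.0
    return Sinogram(data=data, geometry=geom, validity_mask=mask,
                    domain=sino.domain, i0=sino.i0)


def conjugate_resample(sino: Sinogram) -> np.ndarray:
    """Central-row conjugate-ray values: for each (view, col), the interpolated
    value of the opposed ray sampling the same line.

    In this package's convention (counter-clockwise views, detector u along
    (-sin theta, cos theta)) the ray at (theta, fan angle gamma) coincides
    with the ray at (theta + 180 deg - 2 gamma, -gamma); for a flat detector
    u = sdd * tan(gamma) and the conjugate column is at -u.  Bilinear
    interpolation in (view, u), periodic in view.  Useful for redundancy
    checks and inpainting oracles.
    """
    geom = sino.geometry
    plane = sino.plane()
    n_views, n_cols = plane.shape
    u = detector_u(geom, np.arange(n_cols))
    gamma = np.arctan(u / geom.sdd)
    dtheta = 2 * np.pi / n_views

    view_f = (np.arange(n_views)[:, None] + (np.pi - 2 * gamma)[None, :] / dtheta) % n_views
    col_f = np.interp(-u, u, np.arange(n_cols))  # conjugate column (u is uniform)

    v0 = np.floor(view_f).astype(int) % n_views
    v1 = (v0 + 1) % n_views
    wv = view_f - np.floor(view_f)
    c0 = np.clip(np.floor(col_f).astype(int), 0, n_cols - 2)
    wc = np.clip(col_f - c0, 0.0, 1.0)
    c0 = np.broadcast_to(c0, plane.shape)
    wc = np.broadcast_to(wc, plane.shape)

    def gather(vi, ci):
        return plane[vi, ci]

    out = (
        gather(v0, c0) * (1 - wv) * (1 - wc)
        + gather(v0, c0 + 1) * (1 - wv) * wc
        + gather(v1, c0) * wv * (1 - wc)
        + gather(v1, c0 + 1) * wv * wc
    )
    return out
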