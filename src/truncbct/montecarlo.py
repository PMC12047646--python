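"""Analog voxel Monte Carlo photon transport for breast-CT dose and scatter.

Photons are sampled from the fluence spectrum at a square focal spot, aimed
uniformly at the (possibly collimated) detector area, and tracked through the
labeled voxel grid by Amanatides-Woo traversal with sampled optical depth.
Interactions: photoelectric absorption (local energy deposition), Compton
scattering (Klein-Nishina free-electron kinematics, recoil deposited locally),
and Rayleigh scattering (Thomson angular law, direction change only).  No
electron transport and no fluorescence: below 50 keV in low-Z tissue both are
sub-voxel / negligible.  Photons reaching the detector plane are tallied as
energy fluence, split into primary (no interactions) and scatter (>= 1).

Collimating the beam to the kept detector columns emulates the narrower beam
of an offset-detector system: the emitted photon number scales with the
illuminated area, so the tube output per unit beam area — and therefore the
free-in-air kerma at the isocenter — is the same in every arm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numba
import numpy as np

from .geometry import SystemGeometry, kept_column_range
from .spectrum_materials import MaterialTable, Spectrum

__all__ = [
    "MCConfig",
    "DoseScatterTally",
    "transport",
    "dgn_ct",
    "mgd",
    "spr_profile",
]

DEFAULT_MATERIALS = ("air", "skin", "adipose", "fibroglandular", "calcification")


class MCError(RuntimeError):
    pass


class DoseUndefinedError(ZeroDivisionError):
    """Raised when the phantom has no fibroglandular voxels (DgN divides by n_g m_g)."""


@dataclass
class MCConfig:
    n_photons: int = 1_000_000        # full-beam-equivalent budget over all projections
    n_projections: int = 30           # equiangular over 360 deg (12 deg apart)
    rng_seed: int = 0
    tally_bin: int = 4                # detector tally binning factor
    photoelectric: bool = True
    compton: bool = True
    rayleigh: bool = True

    def __post_init__(self) -> None:
        if self.n_photons < 1 or self.n_projections < 1:
            raise ValueError("photon and projection counts must be >= 1")


@dataclass
class DoseScatterTally:
    """Per-material deposited energy plus detector primary/scatter images."""

    deposited_kev: dict               # material name -> keV
    primary: np.ndarray               # (n_proj, t_rows, t_cols) energy fluence, keV
    scatter: np.ndarray
    emitted_kev: float
    escaped_kev: float
    n_emitted: int
    voxel_size_mm: float
    voxel_counts: dict                # material name -> voxels
    fluence_iso_per_cm2: float        # photons / cm^2 at the isocenter, free in air
    geometry: SystemGeometry | None = None
    config: MCConfig | None = None

    @property
    def total_deposited_kev(self) -> float:
        return float(sum(self.deposited_kev.values()))

    def energy_balance_error(self) -> float:
        """|emitted - deposited - escaped| / emitted (analog transport: ~0)."""
        return abs(self.emitted_kev - self.total_deposited_kev - self.escaped_kev) / max(
            self.emitted_kev, 1e-300
        )


# ---------------------------------------------------------------------------
# numba samplers
# ---------------------------------------------------------------------------


@numba.njit(cache=True)
def _sample_kn(k):
    """Kahn's rejection sampling of the Klein-Nishina distribution.

    k = E / m_e c^2.  Returns the scattered-photon cosine and E'/E.
    """
    while True:
        r1 = np.random.random()
        r2 = np.random.random()
        r3 = np.random.random()
        if r1 <= (1.0 + 2.0 * k) / (9.0 + 2.0 * k):
            x = 1.0 + 2.0 * k * r2
            if r3 <= 4.0 * (1.0 / x - 1.0 / (x * x)):
                ratio = 1.0 / x
                break
        else:
            x = (1.0 + 2.0 * k) / (1.0 + 2.0 * k * r2)
            ct = 1.0 - (x - 1.0) / k
            if r3 <= 0.5 * (ct * ct + 1.0 / x):
                ratio = 1.0 / x
                break
    cos_t = 1.0 - (1.0 / ratio - 1.0) / k
    return cos_t, ratio


@numba.njit(cache=True)
def _sample_thomson():
    """cos(theta) from the Thomson / coherent angular law (1 + cos^2)."""
    while True:
        ct = 2.0 * np.random.random() - 1.0
        if np.random.random() <= 0.5 * (1.0 + ct * ct):
            return ct


@numba.njit(cache=True)
def _rotate(dx, dy, dz, cos_t, phi):
    """Unit direction at polar angle acos(cos_t), azimuth phi, about (dx,dy,dz)."""
    sin_t = np.sqrt(max(0.0, 1.0 - cos_t * cos_t))
    cp = np.cos(phi)
    sp = np.sin(phi)
    if abs(dz) < 0.99:
        ux, uy, uz = -dy, dx, 0.0
    else:
        ux, uy, uz = 1.0, 0.0, 0.0
    n = np.sqrt(ux * ux + uy * uy + uz * uz)
    ux, uy, uz = ux / n, uy / n, uz / n
    vx = dy * uz - dz * uy
    vy = dz * ux - dx * uz
    vz = dx * uy - dy * ux
    nx = sin_t * (cp * ux + sp * vx) + cos_t * dx
    ny = sin_t * (cp * uy + sp * vy) + cos_t * dy
    nz = sin_t * (cp * uz + sp * vz) + cos_t * dz
    n = np.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / n, ny / n, nz / n


@numba.njit(cache=True)
def _transport_kernel(
    labels, vox, ox, oy, oz,
    mu_tot, p_pe, p_comp,            # (n_mat, nE): linear mu (1/mm), partial probabilities
    e_min, e_step,
    spec_cum, e_centers,
    n_per_view, angles,
    sad, sdd, pitch, det_cols, det_rows, kept_lo, kept_hi, focal,
    tally_bin, seed,
    use_pe, use_comp, use_ray,
    deposited, primary, scatter,
):
    np.random.seed(seed)
    nz, ny, nx = labels.shape
    nE = e_centers.shape[0]
    emitted = 0.0
    escaped = 0.0
    half_w = 0.5 * det_cols * pitch
    half_h = 0.5 * det_rows * pitch
    u_lo = kept_lo * pitch - half_w
    u_hi = kept_hi * pitch - half_w
    t_cols = det_cols // tally_bin
    t_rows = det_rows // tally_bin
    big = 1.0e30

    for iv in range(angles.shape[0]):
        th = angles[iv]
        cth = np.cos(th)
        sth = np.sin(th)
        s0x = sad * cth
        s0y = sad * sth
        ebx = -cth
        eby = -sth                    # beam axis (source -> isocenter)
        eux = -sth
        euy = cth                     # detector u axis
        dcx = s0x + sdd * ebx
        dcy = s0y + sdd * eby
        for _ in range(n_per_view):
            r = np.random.random()
            ie = 0
            while ie < nE - 1 and spec_cum[ie] < r:
                ie += 1
            e_kev = e_centers[ie]
            emitted += e_kev
            fu = (np.random.random() - 0.5) * focal
            fz = (np.random.random() - 0.5) * focal
            px = s0x + fu * eux
            py = s0y + fu * euy
            pz = fz
            du = u_lo + np.random.random() * (u_hi - u_lo)
            dv = (np.random.random() - 0.5) * 2.0 * half_h
            tx = dcx + du * eux
            ty = dcy + du * euy
            dx = tx - px
            dy = ty - py
            dz = dv - pz
            dn = np.sqrt(dx * dx + dy * dy + dz * dz)
            dx /= dn
            dy /= dn
            dz /= dn

            n_inter = 0
            alive = True
            while alive:
                # ray/grid bounding-box intersection
                t0 = 0.0
                t1 = big
                ok = True
                for ax in range(3):
                    if ax == 0:
                        p = px - ox
                        d = dx
                        ext = nx * vox
                    elif ax == 1:
                        p = py - oy
                        d = dy
                        ext = ny * vox
                    else:
                        p = pz - oz
                        d = dz
                        ext = nz * vox
                    if abs(d) < 1e-12:
                        if p < 0.0 or p > ext:
                            ok = False
                            break
                    else:
                        ta = (0.0 - p) / d
                        tb = (ext - p) / d
                        if ta > tb:
                            ta, tb = tb, ta
                        if ta > t0:
                            t0 = ta
                        if tb < t1:
                            t1 = tb
                if (not ok) or t1 <= t0:
                    # no (further) grid crossing: free flight to the detector plane
                    denom = dx * ebx + dy * eby
                    if denom > 1e-12:
                        tdet = ((dcx - px) * ebx + (dcy - py) * eby) / denom
                        if tdet > 0.0:
                            hx = px + tdet * dx - dcx
                            hy = py + tdet * dy - dcy
                            hz = pz + tdet * dz
                            uu = hx * eux + hy * euy
                            if -half_w <= uu < half_w and -half_h <= hz < half_h:
                                ic = int((uu + half_w) / pitch) // tally_bin
                                ir = int((hz + half_h) / pitch) // tally_bin
                                if 0 <= ic < t_cols and 0 <= ir < t_rows:
                                    if n_inter == 0:
                                        primary[iv, ir, ic] += e_kev
                                    else:
                                        scatter[iv, ir, ic] += e_kev
                    escaped += e_kev
                    alive = False
                    break

                # walk the grid with a sampled optical depth
                eps = 1e-9 * vox
                t = t0 + eps
                x = px + t * dx - ox
                y = py + t * dy - oy
                z = pz + t * dz - oz
                ix = min(max(int(x / vox), 0), nx - 1)
                iy = min(max(int(y / vox), 0), ny - 1)
                iz = min(max(int(z / vox), 0), nz - 1)
                stepx = 1 if dx > 0 else -1
                stepy = 1 if dy > 0 else -1
                stepz = 1 if dz > 0 else -1
                tmaxx = big if dx == 0.0 else ((ix + (stepx > 0)) * vox - x) / dx + t
                tmaxy = big if dy == 0.0 else ((iy + (stepy > 0)) * vox - y) / dy + t
                tmaxz = big if dz == 0.0 else ((iz + (stepz > 0)) * vox - z) / dz + t
                tdx = big if dx == 0.0 else abs(vox / dx)
                tdy = big if dy == 0.0 else abs(vox / dy)
                tdz = big if dz == 0.0 else abs(vox / dz)

                fe = (e_kev - e_min) / e_step
                je = min(max(int(fe), 0), nE - 2)
                we = fe - je

                tau = -np.log(np.random.random())
                acc = 0.0
                interacted = False
                while t < t1:
                    tnext = tmaxx
                    if tmaxy < tnext:
                        tnext = tmaxy
                    if tmaxz < tnext:
                        tnext = tmaxz
                    if tnext > t1:
                        tnext = t1
                    mat = labels[iz, iy, ix]
                    mu = mu_tot[mat, je] * (1.0 - we) + mu_tot[mat, je + 1] * we
                    seg = tnext - t
                    if mu > 0.0 and acc + mu * seg >= tau:
                        t_int = t + (tau - acc) / mu
                        # move to the interaction point (old direction!)
                        px += t_int * dx
                        py += t_int * dy
                        pz += t_int * dz
                        ppe = p_pe[mat, je] * (1.0 - we) + p_pe[mat, je + 1] * we
                        pco = p_comp[mat, je] * (1.0 - we) + p_comp[mat, je + 1] * we
                        r2 = np.random.random()
                        if use_pe and r2 < ppe:
                            deposited[mat] += e_kev
                            alive = False
                        elif use_comp and r2 < ppe + pco:
                            kk = e_kev / 510.99895
                            cos_t, ratio = _sample_kn(kk)
                            e_new = e_kev * ratio
                            deposited[mat] += e_kev - e_new
                            e_kev = e_new
                            phi = 2.0 * np.pi * np.random.random()
                            dx, dy, dz = _rotate(dx, dy, dz, cos_t, phi)
                            n_inter += 1
                            if e_kev < e_min:
                                deposited[mat] += e_kev
                                alive = False
                        elif use_ray:
                            cos_t = _sample_thomson()
                            phi = 2.0 * np.pi * np.random.random()
                            dx, dy, dz = _rotate(dx, dy, dz, cos_t, phi)
                            n_inter += 1
                        else:
                            # interaction channel disabled: absorb to keep balance
                            deposited[mat] += e_kev
                            alive = False
                        interacted = True
                        break
                    acc += mu * seg
                    t = tnext
                    if tnext == tmaxx:
                        ix += stepx
                        tmaxx += tdx
                        if ix < 0 or ix >= nx:
                            break
                    elif tnext == tmaxy:
                        iy += stepy
                        tmaxy += tdy
                        if iy < 0 or iy >= ny:
                            break
                    else:
                        iz += stepz
                        tmaxz += tdz
                        if iz < 0 or iz >= nz:
                            break
                if not interacted and alive:
                    # crossed the grid: advance past it and let the bbox test
                    # route the photon to the detector on the next pass
                    px += (t1 + eps) * dx
                    py += (t1 + eps) * dy
                    pz += (t1 + eps) * dz
    return emitted, escaped


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def _material_arrays(table: MaterialTable, materials, energies):
    """Linear attenuation (1/mm) and interaction-type probabilities per material."""
    n_mat = len(materials)
    nE = len(energies)
    mu_tot = np.zeros((n_mat, nE))
    p_pe = np.zeros((n_mat, nE))
    p_comp = np.zeros((n_mat, nE))
    for i, name in enumerate(materials):
        rho = table.density(name)
        pe = table.mu_rho(name, energies, "pe") * rho
        co = table.mu_rho(name, energies, "incoherent") * rho
        ry = table.mu_rho(name, energies, "coherent") * rho
        tot = pe + co + ry
        mu_tot[i] = tot * 0.1  # cm^-1 -> mm^-1
        with np.errstate(invalid="ignore", divide="ignore"):
            p_pe[i] = np.where(tot > 0, pe / tot, 0.0)
            p_comp[i] = np.where(tot > 0, co / tot, 0.0)
    return mu_tot, p_pe, p_comp


def transport(
    labels: np.ndarray,
    voxel_size_mm: float,
    spectrum: Spectrum,
    geom: SystemGeometry,
    cfg: MCConfig | None = None,
    materials: tuple = DEFAULT_MATERIALS,
    table: MaterialTable | None = None,
) -> DoseScatterTally:
    """Run the analog transport; deterministic for a given ``cfg.rng_seed``.

    ``labels`` is a (nz, ny, nx) integer grid indexing into ``materials``;
    the grid is centered on the isocenter.  The emitted photon number is
    ``cfg.n_photons`` scaled by the illuminated detector fraction (constant
    tube output per beam area across collimations).
    """
    from .spectrum_materials import default_material_table

    cfg = cfg or MCConfig()
    table = table or default_material_table()
    labels = np.ascontiguousarray(labels, dtype=np.uint8)
    if labels.max() >= len(materials):
        raise MCError("label grid references materials beyond the material list")

    energies = np.asarray(spectrum.energies_kev, dtype=float)
    fl = np.asarray(spectrum.fluence, dtype=float)
    if fl.sum() <= 0:
        raise MCError("spectrum has no fluence")
    mu_tot, p_pe, p_comp = _material_arrays(table, materials, energies)
    spec_cum = np.cumsum(fl) / fl.sum()

    kept_lo, kept_hi = kept_column_range(geom)
    kept_frac = (kept_hi - kept_lo) / geom.det_cols_full
    n_emit = max(1, int(round(cfg.n_photons * kept_frac)))
    n_per_view = max(1, n_emit // cfg.n_projections)
    angles = np.deg2rad(np.arange(cfg.n_projections) * 360.0 / cfg.n_projections)

    nz, ny, nx = labels.shape
    ox = -0.5 * nx * voxel_size_mm
    oy = -0.5 * ny * voxel_size_mm
    oz = -0.5 * nz * voxel_size_mm

    t_rows = geom.det_rows // cfg.tally_bin
    t_cols = geom.det_cols_full // cfg.tally_bin
    deposited = np.zeros(len(materials))
    primary = np.zeros((cfg.n_projections, t_rows, t_cols))
    scatter = np.zeros((cfg.n_projections, t_rows, t_cols))

    emitted, escaped = _transport_kernel(
        labels, voxel_size_mm, ox, oy, oz,
        mu_tot, p_pe, p_comp,
        energies[0], energies[1] - energies[0] if len(energies) > 1 else 1.0,
        spec_cum, energies,
        n_per_view, angles,
        geom.sad, geom.sdd, geom.pixel_pitch,
        geom.det_cols_full, geom.det_rows, kept_lo, kept_hi, geom.focal_spot,
        cfg.tally_bin, cfg.rng_seed % (2**31),
        cfg.photoelectric, cfg.compton, cfg.rayleigh,
        deposited, primary, scatter,
    )

    tally = DoseScatterTally(
        deposited_kev={m: float(deposited[i]) for i, m in enumerate(materials)},
        primary=primary,
        scatter=scatter,
        emitted_kev=float(emitted),
        escaped_kev=float(escaped),
        n_emitted=n_per_view * cfg.n_projections,
        voxel_size_mm=voxel_size_mm,
        voxel_counts={
            m: int(np.count_nonzero(labels == i)) for i, m in enumerate(materials)
        },
        fluence_iso_per_cm2=_isocenter_fluence(geom, cfg, n_per_view),
        geometry=geom,
        config=cfg,
    )
    if tally.energy_balance_error() > 1e-3:
        raise MCError(
            f"energy bookkeeping violated: {tally.energy_balance_error():.2e} relative"
        )
    return tally


def _isocenter_fluence(geom: SystemGeometry, cfg: MCConfig, n_per_view: int) -> float:
    """Free-in-air photon fluence (photons/cm^2) at the isocenter, all views.

    Photons are aimed uniformly at the illuminated detector area, so the
    planar density at the detector is n / A_kept; the pencil through the
    isocenter is magnified by (sdd/sad)^2.  The emitted number scales with the
    kept area, so this is the same for every collimation.
    """
    kept_lo, kept_hi = kept_column_range(geom)
    area_mm2 = (kept_hi - kept_lo) * geom.pixel_pitch * geom.det_rows * geom.pixel_pitch
    density_mm2 = n_per_view / area_mm2
    return float(density_mm2 * geom.magnification**2 * 100.0 * cfg.n_projections)


KEV_TO_J = 1.602177e-16


def dgn_ct(
    tally: DoseScatterTally,
    spectrum: Spectrum,
    glandular_material: str = "fibroglandular",
    table: MaterialTable | None = None,
) -> float:
    """Normalized glandular dose coefficient DgN^CT (mGy per mGy air kerma).

    Mean glandular dose per unit free-in-air kerma at the isocenter:
    E_dep,g / (n_g m_g) over sum_E Phi(E) Theta_k(E), with Phi the simulated
    per-exposure fluence at the isocenter.
    """
    from .spectrum_materials import default_material_table

    table = table or default_material_table()
    n_g = tally.voxel_counts.get(glandular_material, 0)
    if n_g == 0:
        raise DoseUndefinedError(
            "no fibroglandular voxels: DgN^CT divides by n_g * m_g"
        )
    rho = table.density(glandular_material)  # g/cm^3
    m_g = rho * (tally.voxel_size_mm * 0.1) ** 3  # per-voxel mass, g
    e_dep_j = tally.deposited_kev[glandular_material] * KEV_TO_J
    dose_mgy = e_dep_j / (n_g * m_g * 1e-3) * 1e3  # J/kg -> Gy -> mGy
    kerma_factors = table.kerma_factors(spectrum.energies_kev)
    frac = spectrum.fluence / np.sum(spectrum.fluence)
    k_air_mgy = float(tally.fluence_iso_per_cm2 * np.sum(frac * kerma_factors))
    return dose_mgy / k_air_mgy


def mgd(tally: DoseScatterTally, spectrum: Spectrum, scan_air_kerma_mgy: float,
        **kw) -> float:
    """Mean glandular dose (mGy) for a scan delivering the given isocenter air kerma."""
    return dgn_ct(tally, spectrum, **kw) * scan_air_kerma_mgy


def spr_profile(
    tally: DoseScatterTally, roi_rows: tuple[int, int] | None = None
) -> tuple[np.ndarray, float]:
    """Horizontal scatter-to-primary profile and its maximum.

    Scatter and primary detector images are averaged over all projection views
    and the ROI rows (tally-grid indices, half-open); SPR(col) =
    scatter / primary where primary is nonzero, NaN on excluded columns.
    """
    prim = tally.primary.mean(axis=0)
    scat = tally.scatter.mean(axis=0)
    if roi_rows is not None:
        prim = prim[roi_rows[0]: roi_rows[1]]
        scat = scat[roi_rows[0]: roi_rows[1]]
    p = prim.mean(axis=0)
    s = scat.mean(axis=0)
    if not np.any(p > 0):
        raise MCError("all-zero primary image: SPR undefined")
    with np.errstate(invalid="ignore", divide="ignore"):
        profile = np.where(p > 0, s / p, np.nan)
    return profile, float(np.nanmax(profile))
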