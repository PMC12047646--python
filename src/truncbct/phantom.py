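"""Synthetic pendant-breast phantoms and material segmentation.

The generator emulates the statistical structure of a clinical breast-CT
cohort: a semi-ellipsoidal pendant breast (circular chest-wall cross section
of the requested diameter, extending one chest-to-nipple length along the
rotation axis), a thin skin shell, an adipose interior, and fibroglandular
tissue laid down as a thresholded smoothed Gaussian random field whose
threshold is solved by bisection so the fibroglandular weight fraction of the
interior tissue matches the request.  Spherical calcifications (0.2-1.0 mm)
can be embedded in the interior.

Label alphabet (integer codes): 0 air, 1 skin, 2 adipose, 3 fibroglandular,
4 calcification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .spectrum_materials import MaterialTable, default_material_table

__all__ = [
    "LABELS",
    "BreastPhantom",
    "CohortSpec",
    "generate_phantom",
    "segment_volume",
    "phantom_to_mu",
    "SegmentationResult",
]

LABELS = {"air": 0, "skin": 1, "adipose": 2, "fibroglandular": 3, "calcification": 4}
LABEL_NAMES = {v: k for k, v in LABELS.items()}

# Cohort statistics the generator defaults reproduce (cm / cm / weight fraction).
COHORT_CHEST_WALL_DIAMETER_CM = (12.26, 2.68)
COHORT_CHEST_TO_NIPPLE_CM = (10.4, 2.75)
COHORT_FIBROGLANDULAR_FRACTION = (0.20, 0.16)


class PhantomError(ValueError):
    pass


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one synthetic breast; defaults are the cohort means."""

    chest_wall_diameter_cm: float = COHORT_CHEST_WALL_DIAMETER_CM[0]
    chest_to_nipple_cm: float = COHORT_CHEST_TO_NIPPLE_CM[0]
    fibroglandular_fraction: float = COHORT_FIBROGLANDULAR_FRACTION[0]
    skin_thickness_mm: float = 1.5
    n_calcifications: int = 4
    calc_diameter_range_mm: tuple = (0.2, 1.0)
    voxel_size_mm: float = 1.0
    blob_correlation_mm: float = 15.0

    def sampled(self, rng: np.random.Generator) -> "CohortSpec":
        """Draw one subject from the cohort distributions, truncated to physical
        bounds.  The fibroglandular fraction is floored at 5% so that every
        subject carries a fibroglandular region measurable by the ROI protocol
        (clinical breasts retain dense tissue near the chest wall)."""
        d = max(6.0, rng.normal(*COHORT_CHEST_WALL_DIAMETER_CM))
        l = max(4.0, rng.normal(*COHORT_CHEST_TO_NIPPLE_CM))
        f = float(np.clip(rng.normal(*COHORT_FIBROGLANDULAR_FRACTION), 0.05, 0.95))
        return CohortSpec(
            chest_wall_diameter_cm=d, chest_to_nipple_cm=l, fibroglandular_fraction=f,
            skin_thickness_mm=self.skin_thickness_mm,
            n_calcifications=self.n_calcifications,
            calc_diameter_range_mm=self.calc_diameter_range_mm,
            voxel_size_mm=self.voxel_size_mm,
            blob_correlation_mm=self.blob_correlation_mm,
        )


@dataclass(frozen=True)
class BreastPhantom:
    """Labeled voxel grid (z, y, x ordering; z along the rotation axis)."""

    label_grid: np.ndarray
    voxel_size: float
    chest_wall_diameter: float  # cm
    chest_to_nipple: float      # cm
    fibroglandular_weight_fraction: float  # achieved, from the grid
    calcification_list: tuple = ()
    rng_seed: int = 0

    def voxel_counts(self) -> dict:
        counts = np.bincount(self.label_grid.ravel(), minlength=5)
        return {name: int(counts[code]) for name, code in LABELS.items()}

    def central_slice(self) -> np.ndarray:
        """2-D label slice through the chest-wall end (largest cross section)."""
        return self.label_grid[0]


def _weight_fraction(labels: np.ndarray, table: MaterialTable) -> float:
    """Fibroglandular weight fraction of the interior tissue (skin excluded)."""
    n_g = np.count_nonzero(labels == LABELS["fibroglandular"])
    n_a = np.count_nonzero(labels == LABELS["adipose"])
    m_g = n_g * table.density("fibroglandular")
    m_a = n_a * table.density("adipose")
    return m_g / (m_g + m_a) if (m_g + m_a) > 0 else 0.0


def generate_phantom(
    spec: CohortSpec | None = None,
    rng_seed: int = 0,
    table: MaterialTable | None = None,
) -> BreastPhantom:
    """Generate one voxelized pendant breast; deterministic given ``rng_seed``."""
    spec = spec or CohortSpec()
    table = table or default_material_table()
    if not (0.0 <= spec.fibroglandular_fraction <= 1.0):
        raise PhantomError("fibroglandular fraction must be in [0, 1]")
    if spec.chest_wall_diameter_cm <= 0 or spec.chest_to_nipple_cm <= 0:
        raise PhantomError("breast dimensions must be positive")

    vox = spec.voxel_size_mm
    r_mm = spec.chest_wall_diameter_cm * 10.0 / 2.0
    l_mm = spec.chest_to_nipple_cm * 10.0
    margin = 2 * vox
    nx = int(np.ceil(2 * (r_mm + margin) / vox))
    nz = int(np.ceil((l_mm + margin) / vox))
    rng = np.random.default_rng(rng_seed)

    x = (np.arange(nx) - (nx - 1) / 2.0) * vox
    z = (np.arange(nz) + 0.5) * vox
    zz, yy, xx = np.meshgrid(z, x, x, indexing="ij")

    # semi-ellipsoid: circular cross-section radius r at z=0 shrinking to 0 at z=l
    body = (xx / r_mm) ** 2 + (yy / r_mm) ** 2 + (zz / l_mm) ** 2 <= 1.0
    # skin = outer shell of the body, by Euclidean depth; never thinner than
    # one voxel so the shell stays closed on coarse grids
    depth = ndimage.distance_transform_edt(body, sampling=vox)
    interior = body & (depth > max(spec.skin_thickness_mm, vox))

    labels = np.zeros((nz, nx, nx), dtype=np.uint8)
    labels[body] = LABELS["skin"]
    labels[interior] = LABELS["adipose"]

    f_target = spec.fibroglandular_fraction
    if f_target > 0 and np.any(interior):
        noise = rng.standard_normal(labels.shape)
        sigma_vox = spec.blob_correlation_mm / vox / 2.0
        texture = ndimage.gaussian_filter(noise, sigma=sigma_vox)
        vals = texture[interior]
        # bisection on the threshold so the *weight* fraction hits the target
        lo, hi = float(vals.min()) - 1e-9, float(vals.max()) + 1e-9
        rho_g = table.density("fibroglandular")
        rho_a = table.density("adipose")
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            n_g = np.count_nonzero(vals > mid)
            n_a = vals.size - n_g
            f = n_g * rho_g / (n_g * rho_g + n_a * rho_a) if vals.size else 0.0
            if f > f_target:
                lo = mid
            else:
                hi = mid
        glandular = interior & (texture > 0.5 * (lo + hi))
        labels[glandular] = LABELS["fibroglandular"]

    calcs = []
    if spec.n_calcifications > 0 and np.any(interior):
        idx = np.argwhere(interior)
        for _ in range(spec.n_calcifications):
            center = idx[rng.integers(len(idx))]
            dia = rng.uniform(*spec.calc_diameter_range_mm)
            cz, cy, cx = center
            rad_vox = dia / 2.0 / vox
            span = int(np.ceil(rad_vox)) + 1
            zs = slice(max(cz - span, 0), cz + span + 1)
            ys = slice(max(cy - span, 0), cy + span + 1)
            xs = slice(max(cx - span, 0), cx + span + 1)
            sub = np.indices(labels[zs, ys, xs].shape).astype(float)
            dist = np.sqrt(
                (sub[0] + zs.start - cz) ** 2
                + (sub[1] + ys.start - cy) ** 2
                + (sub[2] + xs.start - cx) ** 2
            )
            ball = (dist <= max(rad_vox, 0.5)) & (labels[zs, ys, xs] >= LABELS["adipose"])
            labels[zs, ys, xs][ball] = LABELS["calcification"]
            calcs.append(((int(cz), int(cy), int(cx)), float(dia)))

    achieved = _weight_fraction(labels, table)
    return BreastPhantom(
        label_grid=labels,
        voxel_size=vox,
        chest_wall_diameter=spec.chest_wall_diameter_cm,
        chest_to_nipple=spec.chest_to_nipple_cm,
        fibroglandular_weight_fraction=achieved,
        calcification_list=tuple(calcs),
        rng_seed=rng_seed,
    )


def phantom_to_mu(
    phantom: BreastPhantom | np.ndarray,
    energy_kev: float,
    table: MaterialTable | None = None,
) -> np.ndarray:
    """Per-voxel linear attenuation (cm^-1) of a label grid at one energy."""
    table = table or default_material_table()
    labels = phantom.label_grid if isinstance(phantom, BreastPhantom) else phantom
    unknown = set(np.unique(labels)) - set(LABEL_NAMES)
    if unknown:
        raise PhantomError(f"unknown material labels {sorted(unknown)}")
    lut = np.zeros(max(LABEL_NAMES) + 1)
    for code, name in LABEL_NAMES.items():
        lut[code] = table.mu(name, energy_kev)
    return lut[labels]


@dataclass(frozen=True)
class SegmentationResult:
    label_grid: np.ndarray
    counts: dict = field(default_factory=dict)


def segment_volume(
    recon: np.ndarray,
    thresholds: tuple | None = None,
    energy_kev: float = 30.0,
    table: MaterialTable | None = None,
    skin_thickness_mm: float = 1.5,
    voxel_size_mm: float = 1.0,
) -> SegmentationResult:
    """Threshold a reconstructed attenuation volume into the four tissue classes.

    ``thresholds = (air_adipose, adipose_fibroglandular)`` in cm^-1; defaults
    are the midpoints of the material attenuations at ``energy_kev``.  Skin is
    assigned morphologically as the outer shell (``skin_thickness_mm`` deep,
    by Euclidean distance to the air boundary) of the non-air mask — a
    stand-in for the model-based segmentation used on clinical
    reconstructions.  Voxels above an attenuation of twice the fibroglandular
    value are labeled calcification.
    """
    recon = np.asarray(recon, dtype=float)
    if not np.all(np.isfinite(recon)):
        raise PhantomError("reconstruction contains non-finite values")
    table = table or default_material_table()
    mu_a = table.mu("adipose", energy_kev)
    mu_g = table.mu("fibroglandular", energy_kev)
    if thresholds is None:
        thresholds = (0.5 * mu_a, 0.5 * (mu_a + mu_g))
    t_air, t_fg = thresholds
    if not t_air < t_fg:
        raise PhantomError("thresholds must be strictly increasing")

    labels = np.zeros(recon.shape, dtype=np.uint8)
    tissue = recon >= t_air
    labels[tissue & (recon < t_fg)] = LABELS["adipose"]
    labels[tissue & (recon >= t_fg)] = LABELS["fibroglandular"]
    labels[recon >= 2.0 * mu_g] = LABELS["calcification"]

    if skin_thickness_mm > 0 and np.any(tissue):
        depth = ndimage.distance_transform_edt(tissue, sampling=voxel_size_mm)
        shell = tissue & (depth <= max(skin_thickness_mm, voxel_size_mm))
        labels[shell] = LABELS["skin"]

    counts = np.bincount(labels.ravel(), minlength=5)
    return SegmentationResult(
        label_grid=labels,
        counts={name: int(counts[code]) for name, code in LABELS.items()},
    )
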