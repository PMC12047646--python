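"""Quantitative image quality: ROI statistics, SDNR, calcification FWHM.

SDNR between fibroglandular (G) and adipose (A) ROIs:

    SDNR = |mean_G - mean_A| / sqrt((var_G + var_A) / 2)

FWHM of a calcification profile is measured along two orthogonal in-plane
axes (mediolateral and superior-inferior) with the background estimated from
the outer quarter of the profile tails and the half-maximum crossings located
by linear interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "ROIStats",
    "sdnr",
    "fwhm",
    "place_roi",
    "evaluate_case",
]


class MetricError(ValueError):
    pass


@dataclass(frozen=True)
class ROIStats:
    tissue: str
    corner: tuple          # (row, col) of the ROI's upper-left pixel
    size: int              # ROI edge, pixels
    mean: float            # cm^-1
    variance: float        # cm^-2
    in_class_fraction: float = 1.0


def sdnr(glandular: ROIStats | float, adipose: ROIStats | float,
         var_g: float | None = None, var_a: float | None = None) -> float:
    """Signal-difference-to-noise ratio between the two tissue ROIs.

    Accepts either two :class:`ROIStats` or four scalars
    ``sdnr(mean_g, mean_a, var_g, var_a)``.
    """
    if isinstance(glandular, ROIStats):
        mg, vg = glandular.mean, glandular.variance
        ma, va = adipose.mean, adipose.variance
    else:
        mg, ma, vg, va = glandular, adipose, var_g, var_a
    denom = 0.5 * (vg + va)
    if denom <= 0:
        raise MetricError("both ROI variances are zero: SDNR undefined")
    return abs(mg - ma) / np.sqrt(denom)


def fwhm(profile: np.ndarray, pixel_size_mm: float = 1.0) -> float:
    """Full width at half maximum of a 1-D peak, in mm.

    Background = mean of the outer 25% tails; half-max = background +
    (peak - background)/2; crossings by linear interpolation.
    """
    p = np.asarray(profile, dtype=float)
    if p.ndim != 1 or p.size < 3:
        raise MetricError("profile must be 1-D with at least 3 samples")
    n_tail = max(1, p.size // 8)  # outer 25% total: 12.5% each side
    background = 0.5 * (p[:n_tail].mean() + p[-n_tail:].mean())
    ipk = int(np.argmax(p))
    peak = p[ipk]
    if peak <= background or ipk == 0 or ipk == p.size - 1:
        raise MetricError("profile has no interior maximum above background")
    half = background + 0.5 * (peak - background)

    def cross(idx_range):
        prev = None
        for i in idx_range:
            if prev is not None and (p[prev] - half) * (p[i] - half) <= 0:
                # linear interpolation between prev and i
                if p[i] == p[prev]:
                    return i
                return prev + (half - p[prev]) / (p[i] - p[prev]) * (i - prev)
            prev = i
        return None

    left = cross(range(ipk, -1, -1))
    right = cross(range(ipk, p.size))
    if left is None or right is None:
        raise MetricError("profile never crosses half maximum on both sides")
    return float(abs(right - left)) * pixel_size_mm


def place_roi(
    mask: np.ndarray,
    size: int = 32,
    min_fraction: float = 0.9,
    rng_seed: int = 0,
) -> tuple[int, int, float]:
    """Upper-left corner of a ``size x size`` ROI inside a tissue mask.

    Chooses the window with the highest in-class fraction (>= min_fraction),
    breaking ties by distance to the mask centroid (then by a seeded draw).
    Raises when no window reaches the minimum fraction.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape[0] < size or mask.shape[1] < size:
        raise MetricError("mask smaller than requested ROI")
    frac = ndimage.uniform_filter(mask.astype(float), size=size, mode="constant")
    # valid window centers (uniform_filter is centered)
    half = size // 2
    valid = np.zeros_like(frac, dtype=bool)
    valid[half: mask.shape[0] - (size - half) + 1,
          half: mask.shape[1] - (size - half) + 1] = True
    frac = np.where(valid, frac, 0.0)
    best = frac.max()
    if best < min_fraction:
        raise MetricError(
            f"no {size}x{size} ROI reaches {min_fraction:.0%} in-class (best {best:.0%})"
        )
    cands = np.argwhere(frac >= min(best, min_fraction) - 1e-12)
    cy, cx = ndimage.center_of_mass(mask)
    d2 = (cands[:, 0] - cy) ** 2 + (cands[:, 1] - cx) ** 2
    # highest fraction first, then nearest the centroid, then seeded tie-break
    key = frac[cands[:, 0], cands[:, 1]]
    order = np.lexsort((np.random.default_rng(rng_seed).random(len(cands)), d2, -key))
    r, c = cands[order[0]]
    return int(r - half), int(c - half), float(frac[r, c])


def roi_stats(image: np.ndarray, mask: np.ndarray, tissue: str,
              size: int = 32, rng_seed: int = 0) -> ROIStats:
    r, c, frac = place_roi(mask, size=size, rng_seed=rng_seed)
    patch = np.asarray(image, dtype=float)[r: r + size, c: c + size]
    return ROIStats(tissue=tissue, corner=(r, c), size=size,
                    mean=float(patch.mean()), variance=float(patch.var(ddof=1)),
                    in_class_fraction=frac)


def calcification_fwhm(
    image: np.ndarray,
    center_rc: tuple,
    pixel_size_mm: float,
    half_len: int = 8,
) -> tuple[float, float]:
    """FWHM (mm) along the two in-plane axes through a calcification.

    Rows = superior-inferior surrogate, columns = mediolateral surrogate in
    the axial slice convention used here.  The declared center is refined to
    the local maximum within +/-1 pixel.
    """
    img = np.asarray(image, dtype=float)
    r0, c0 = int(center_rc[0]), int(center_rc[1])
    sub = img[max(r0 - 1, 0): r0 + 2, max(c0 - 1, 0): c0 + 2]
    dr, dc = np.unravel_index(np.argmax(sub), sub.shape)
    r0 = max(r0 - 1, 0) + dr
    c0 = max(c0 - 1, 0) + dc
    rows = img[max(r0 - half_len, 0): r0 + half_len + 1, c0]
    cols = img[r0, max(c0 - half_len, 0): c0 + half_len + 1]
    return fwhm(cols, pixel_size_mm), fwhm(rows, pixel_size_mm)


def evaluate_case(
    recon_values: np.ndarray,
    truth_labels: np.ndarray,
    pixel_size_mm: float,
    calc_centers: tuple = (),
    roi_size: int = 32,
    erosion: int = 0,
    rng_seed: int = 0,
    labels: dict | None = None,
) -> dict:
    """One flat metrics record for a reconstructed slice against its truth labels.

    ROIs are auto-placed inside the eroded adipose and fibroglandular masks;
    FWHM is measured for every listed calcification center.  Deterministic.
    """
    from .phantom import LABELS

    labels = labels or LABELS
    img = np.asarray(recon_values, dtype=float)
    if img.shape != truth_labels.shape:
        raise MetricError("recon and truth shapes differ")
    rec: dict = {"roi_size": roi_size, "pixel_size_mm": pixel_size_mm}
    stats = {}
    for tissue in ("adipose", "fibroglandular"):
        mask = truth_labels == labels[tissue]
        if erosion > 0:
            mask = ndimage.binary_erosion(mask, iterations=erosion)
        stats[tissue] = roi_stats(img, mask, tissue, size=roi_size, rng_seed=rng_seed)
        rec[f"mean_{tissue}"] = stats[tissue].mean
        rec[f"var_{tissue}"] = stats[tissue].variance
    rec["sdnr"] = sdnr(stats["fibroglandular"], stats["adipose"])
    fw_ml, fw_si = [], []
    for center in calc_centers:
        try:
            ml, si = calcification_fwhm(img, center, pixel_size_mm)
        except MetricError:
            continue
        fw_ml.append(ml)
        fw_si.append(si)
    rec["fwhm_ml_mm"] = float(np.mean(fw_ml)) if fw_ml else np.nan
    rec["fwhm_si_mm"] = float(np.mean(fw_si)) if fw_si else np.nan
    rec["n_calcifications"] = len(fw_ml)
    return rec
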