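"""Cone-beam acquisition geometry for an offset/truncated flat-panel detector.

Conventions
-----------
Right-handed world frame with the axis of rotation along ``z``. The x-ray
source rotates in the x-y plane, counter-clockwise, with the view angle
measured from ``+x``.  At view angle 0 the source sits at ``(sad, 0, 0)``
and the flat detector is centered on the line through the source and the
rotation axis, at distance ``sdd`` from the source.

Detector indices are 0-based. The column (fan-angle) axis ``u`` increases
with column index; the detector is laterally centered when complete, so the
projected rotation axis falls between columns ``(det_cols_full - 1) / 2``.
Truncation removes a contiguous block of columns from one side (default:
``left``, i.e. low column indices), so the kept block is
``[det_cols_full - truncated_cols, det_cols_full)`` and always contains the
central column.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

__all__ = [
    "SystemGeometry",
    "Ray",
    "build_geometry",
    "ray_for_pixel",
    "truncation_fraction",
    "kept_column_range",
    "detector_u",
    "detector_v",
    "source_position",
    "scaled_geometry",
]

TruncationSide = Literal["left", "right"]


class GeometryError(ValueError):
    """Invalid acquisition-geometry configuration."""


@dataclass(frozen=True)
class SystemGeometry:
    """Circular-trajectory cone-beam system with a flat, possibly truncated detector.

    Lengths in mm, angles in degrees.  Defaults reproduce the clinical-prototype
    breast-CT system emulated throughout this package: 300 views over 360 deg,
    898 mm source-detector and 650 mm source-axis distance, 0.388 mm pixels on
    a 1024 x 768 panel.
    """

    sad: float = 650.0
    sdd: float = 898.0
    n_views: int = 300
    angular_range: float = 360.0
    det_cols_full: int = 1024
    det_rows: int = 768
    pixel_pitch: float = 0.388
    truncated_cols: int = 1024
    truncation_side: TruncationSide = "left"
    focal_spot: float = 0.3

    def __post_init__(self) -> None:
        if self.sad <= 0 or self.sdd <= 0 or self.pixel_pitch <= 0:
            raise GeometryError("lengths must be positive")
        if self.sdd <= self.sad:
            raise GeometryError("sdd must exceed sad (magnification > 1)")
        if self.n_views < 1 or self.det_cols_full < 1 or self.det_rows < 1:
            raise GeometryError("counts must be positive integers")
        if not (0 < self.truncated_cols <= self.det_cols_full):
            raise GeometryError(
                f"truncated_cols must be in (0, {self.det_cols_full}], got {self.truncated_cols}"
            )
        if self.truncation_side not in ("left", "right"):
            raise GeometryError(f"unknown truncation_side {self.truncation_side!r}")

    @property
    def magnification(self) -> float:
        return self.sdd / self.sad

    @property
    def is_truncated(self) -> bool:
        return self.truncated_cols < self.det_cols_full

    @property
    def view_angles_deg(self) -> np.ndarray:
        """View angles, end-point excluded (a full scan does not repeat 0 deg)."""
        return np.arange(self.n_views) * (self.angular_range / self.n_views)

    @property
    def fov_radius(self) -> float:
        """Radius (mm) of the field of view at the isocenter for the complete detector."""
        half_width = 0.5 * self.det_cols_full * self.pixel_pitch
        return half_width * self.sad / np.hypot(self.sdd, half_width)

    def with_truncation(self, m: int, side: TruncationSide | None = None) -> "SystemGeometry":
        return replace(
            self, truncated_cols=m, truncation_side=side or self.truncation_side
        )


@dataclass(frozen=True)
class Ray:
    """A source-to-detector-pixel ray with ordered fractional sample positions."""

    source: np.ndarray
    detector_point: np.ndarray
    sample_fractions: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        a = np.asarray(self.sample_fractions, dtype=float)
        if a.size and (np.any(np.diff(a) <= 0) or a[0] <= 0 or a[-1] >= 1):
            raise GeometryError("sample_fractions must be strictly increasing in (0, 1)")

    @property
    def sample_points(self) -> np.ndarray:
        d = self.detector_point - self.source
        return self.source[None, :] + self.sample_fractions[:, None] * d[None, :]

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.detector_point - self.source))


def build_geometry(config: dict | None = None, **kwargs) -> SystemGeometry:
    """Build a validated :class:`SystemGeometry` from config keys.

    Accepts either the serialized key names (``sad_mm``, ``sdd_mm``,
    ``angular_range_deg``, ``pixel_pitch_mm`` ...) or the dataclass field names.
    """
    params: dict = {}
    merged = dict(config or {})
    merged.update(kwargs)
    aliases = {
        "sad_mm": "sad",
        "sdd_mm": "sdd",
        "angular_range_deg": "angular_range",
        "pixel_pitch_mm": "pixel_pitch",
        "focal_spot_mm": "focal_spot",
    }
    for key, value in merged.items():
        params[aliases.get(key, key)] = value
    if "truncated_cols" not in params and "det_cols_full" in params:
        params["truncated_cols"] = params["det_cols_full"]
    return SystemGeometry(**params)


def geometry_to_config(geom: SystemGeometry) -> dict:
    """Serialize geometry with the stable external key names."""
    return {
        "sad_mm": geom.sad,
        "sdd_mm": geom.sdd,
        "n_views": geom.n_views,
        "angular_range_deg": geom.angular_range,
        "det_cols_full": geom.det_cols_full,
        "det_rows": geom.det_rows,
        "pixel_pitch_mm": geom.pixel_pitch,
        "truncated_cols": geom.truncated_cols,
        "truncation_side": geom.truncation_side,
        "focal_spot_mm": geom.focal_spot,
    }


def kept_column_range(geom: SystemGeometry) -> tuple[int, int]:
    """Half-open ``[lo, hi)`` index range of acquired detector columns.

    Raises if the kept block would exclude the central column (the projected
    rotation axis), which no offset-detector scheme permits.
    """
    m, full = geom.truncated_cols, geom.det_cols_full
    if geom.truncation_side == "left":
        lo, hi = full - m, full
    else:
        lo, hi = 0, m
    center = (full - 1) / 2.0
    if not (lo - 0.5 <= center <= hi - 0.5):
        raise GeometryError(
            f"kept columns [{lo}, {hi}) exclude the central column {center:.1f}"
        )
    return lo, hi


def detector_u(geom: SystemGeometry, col) -> np.ndarray:
    """Signed fan-direction detector coordinate (mm) of column center(s)."""
    return (np.asarray(col, dtype=float) - (geom.det_cols_full - 1) / 2.0) * geom.pixel_pitch


def detector_v(geom: SystemGeometry, row) -> np.ndarray:
    """Signed cone-direction detector coordinate (mm) of row center(s)."""
    return (np.asarray(row, dtype=float) - (geom.det_rows - 1) / 2.0) * geom.pixel_pitch


def source_position(geom: SystemGeometry, view_angle_deg: float) -> np.ndarray:
    th = np.deg2rad(view_angle_deg)
    return np.array([geom.sad * np.cos(th), geom.sad * np.sin(th), 0.0])


def detector_frame(geom: SystemGeometry, view_angle_deg: float):
    """Return (detector center, u-axis unit vector, v-axis unit vector) in world mm."""
    th = np.deg2rad(view_angle_deg)
    e_beam = np.array([-np.cos(th), -np.sin(th), 0.0])  # source -> isocenter
    e_u = np.array([-np.sin(th), np.cos(th), 0.0])
    e_v = np.array([0.0, 0.0, 1.0])
    center = source_position(geom, view_angle_deg) + geom.sdd * e_beam
    return center, e_u, e_v


def pixel_position(geom: SystemGeometry, view_angle_deg: float, row, col) -> np.ndarray:
    center, e_u, e_v = detector_frame(geom, view_angle_deg)
    u = detector_u(geom, col)
    v = detector_v(geom, row)
    return center + np.multiply.outer(u, e_u) + np.multiply.outer(v, e_v)


def ray_for_pixel(
    geom: SystemGeometry,
    view_angle: float,
    row: int,
    col: int,
    n_samples: int = 0,
    rng: np.random.Generator | None = None,
) -> Ray:
    """Ray from the source at ``view_angle`` (deg) to the center of pixel (row, col).

    With ``n_samples > 0``, stratified sample fractions are attached (jittered
    when an ``rng`` is given, midpoints otherwise).
    """
    if not (0 <= row < geom.det_rows and 0 <= col < geom.det_cols_full):
        raise IndexError(f"pixel ({row}, {col}) outside detector bounds")
    s = source_position(geom, view_angle)
    d = pixel_position(geom, view_angle, row, col)
    fractions = np.empty(0)
    if n_samples > 0:
        edges = np.linspace(0.0, 1.0, n_samples + 1)
        if rng is None:
            fractions = 0.5 * (edges[:-1] + edges[1:])
        else:
            fractions = edges[:-1] + rng.random(n_samples) / n_samples
    return Ray(source=s, detector_point=np.asarray(d, dtype=float), sample_fractions=fractions)


def truncation_fraction(geom: SystemGeometry) -> float:
    """Fraction of the full detector area removed by the truncation."""
    return (geom.det_cols_full - geom.truncated_cols) / geom.det_cols_full


def scaled_geometry(geom: SystemGeometry, factor: int) -> SystemGeometry:
    """Bin the detector by an integer factor, preserving all physical extents.

    Used for desk-scale studies: column/row counts divide by ``factor``, the
    pixel pitch multiplies by it, and the truncation width scales to the
    nearest equivalent column count.
    """
    if factor < 1 or geom.det_cols_full % factor or geom.det_rows % factor:
        raise GeometryError("factor must divide both detector dimensions")
    return replace(
        geom,
        det_cols_full=geom.det_cols_full // factor,
        det_rows=geom.det_rows // factor,
        pixel_pitch=geom.pixel_pitch * factor,
        truncated_cols=max(1, int(round(geom.truncated_cols / factor))),
    )
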