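"""TV-regularized statistical iterative reconstruction (FRIST-style).

Each main iteration performs one ordered-subsets SART pass over all views
(data fidelity) followed by a fixed number of safeguarded gradient-descent
steps on the isotropic total variation with a diminishing step size — the
ASD-POCS family.  The number of TV steps per main iteration follows a
breast-size schedule: 10 for large and medium breasts, 15 for small ones
(chest-wall diameter tertiles).

Works on the 2-D fan-beam path (single-row sinograms).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .projector import Sinogram, back_project, forward_project
from .recon_fdk import ReconVolume, fdk_reconstruct, redundancy_weights

__all__ = [
    "TVConfig",
    "tv_norm",
    "frist_reconstruct",
    "classify_breast_size",
    "TV_STEPS_BY_SIZE",
]

# TV steps per main iteration, keyed by breast-size class.
TV_STEPS_BY_SIZE = {"large": 10, "medium": 10, "small": 15}

# chest-wall diameter cuts (cm) for the size classes
SIZE_CUTS_CM = (11.0, 14.0)


class ConvergenceError(RuntimeError):
    def __init__(self, message: str, residual_log=None):
        super().__init__(message)
        self.residual_log = residual_log


@dataclass
class TVConfig:
    n_main_iterations: int = 20
    n_tv_steps: int | None = None        # explicit override of the schedule
    size_class: str = "medium"           # resolves n_tv_steps when not overridden
    tv_step_ratio: float = 0.2           # first TV step as a fraction of the SART update norm
    tv_step_decay: float = 0.97          # per-main-iteration step shrink
    sart_relaxation: float = 0.8
    n_subsets: int = 10
    init: str = "fdkw"                   # or "zeros"
    rng_seed: int = 0
    nonnegativity: bool = True

    def __post_init__(self) -> None:
        if self.n_main_iterations < 0 or self.n_subsets < 1:
            raise ValueError("iteration counts must be non-negative / positive")
        if self.size_class not in TV_STEPS_BY_SIZE:
            raise ValueError(f"unknown size class {self.size_class!r}")
        if self.init not in ("fdkw", "zeros"):
            raise ValueError("init must be 'fdkw' or 'zeros'")

    @property
    def tv_steps(self) -> int:
        return self.n_tv_steps if self.n_tv_steps is not None else TV_STEPS_BY_SIZE[self.size_class]


def classify_breast_size(chest_wall_diameter_cm: float,
                         cuts_cm: tuple = SIZE_CUTS_CM) -> str:
    """Tertile size class from chest-wall diameter: <11 cm small, 11-14 medium, >14 large."""
    lo, hi = cuts_cm
    if chest_wall_diameter_cm < lo:
        return "small"
    if chest_wall_diameter_cm <= hi:
        return "medium"
    return "large"


def tv_norm(volume: np.ndarray) -> float:
    """Isotropic discrete total variation: sum of Euclidean norms of forward differences."""
    v = np.asarray(volume, dtype=float)
    sq = np.zeros_like(v)
    for axis in range(v.ndim):
        d = np.diff(v, axis=axis)
        pad = [(0, 1) if ax == axis else (0, 0) for ax in range(v.ndim)]
        sq += np.pad(d, pad) ** 2
    return float(np.sum(np.sqrt(sq)))


def _tv_gradient(v: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Gradient of the smoothed isotropic TV (2-D)."""
    dy = np.diff(v, axis=0, append=v[-1:, :])
    dx = np.diff(v, axis=1, append=v[:, -1:])
    mag = np.sqrt(dx**2 + dy**2 + eps)
    px = dx / mag
    py = dy / mag
    div = np.zeros_like(v)
    div += px - np.roll(px, 1, axis=1)
    div += py - np.roll(py, 1, axis=0)
    div[:, 0] = px[:, 0] + py[:, 0] - np.roll(py, 1, axis=0)[:, 0]
    div[0, :] = px[0, :] + py[0, :] - np.roll(px, 1, axis=1)[0, :]
    div[0, 0] = px[0, 0] + py[0, 0]
    return -div


def _masked_plane(sino: Sinogram) -> tuple[np.ndarray, np.ndarray]:
    row = sino.n_rows // 2
    return np.where(sino.validity_mask[:, row, :], sino.data[:, row, :], 0.0), (
        sino.validity_mask[:, row, :]
    )


def frist_reconstruct(
    sino: Sinogram,
    cfg: TVConfig | None = None,
    grid_shape: int | tuple = 160,
    voxel_size_mm: float | None = None,
    weights: np.ndarray | None = None,
) -> ReconVolume:
    """OS-SART data-fidelity passes interleaved with safeguarded TV descent.

    Initialized from FDK-W (redundancy-weighted FBP) by default.  Returns the
    volume with a per-main-iteration data-residual log in ``params``; raises
    :class:`ConvergenceError` if the residual grows five main iterations in a
    row.
    """
    cfg = cfg or TVConfig()
    geom = sino.geometry
    if sino.domain != "line_integral":
        raise ValueError("frist_reconstruct needs line-integral input")
    if isinstance(grid_shape, int):
        grid_shape = (grid_shape, grid_shape)
    if voxel_size_mm is None:
        voxel_size_mm = 2.0 * geom.fov_radius / max(grid_shape)

    data, mask = _masked_plane(sino)
    maskf = mask.astype(float)

    if cfg.init == "fdkw":
        w = weights
        if w is None:
            w = redundancy_weights(geom)
        x = fdk_reconstruct(sino, weights=w, grid_shape=grid_shape,
                            voxel_size_mm=voxel_size_mm).values.copy()
        if cfg.nonnegativity:
            np.clip(x, 0.0, None, out=x)
    else:
        x = np.zeros(grid_shape)

    # SART normalizations: row sums (projection of ones) and column sums
    # (backprojection of ones on acquired pixels), per subset.
    ones_vol = np.ones(grid_shape)
    row_sum = forward_project(ones_vol, geom, voxel_size_mm).plane()
    rng = np.random.default_rng(cfg.rng_seed)
    subsets = [np.arange(s, geom.n_views, cfg.n_subsets) for s in range(cfg.n_subsets)]

    def subset_sino(arr, views):
        out = np.zeros_like(arr)
        out[views] = arr[views]
        return out

    col_sums = []
    for views in subsets:
        col_sums.append(back_project(subset_sino(maskf, views), geom, grid_shape, voxel_size_mm))

    def residual_norm(xv):
        proj = forward_project(xv, geom, voxel_size_mm).plane()
        return float(np.linalg.norm((proj - data) * maskf))

    residual_log = [residual_norm(x)]
    grow_streak = 0
    order = np.arange(cfg.n_subsets)

    for it in range(cfg.n_main_iterations):
        x_pre = x.copy()
        rng.shuffle(order)
        for si in order:
            views = subsets[si]
            proj = forward_project(x, geom, voxel_size_mm).plane()
            resid = (data - proj) * maskf
            resid_n = np.divide(resid, row_sum, out=np.zeros_like(resid),
                                where=row_sum > 1e-9)
            upd = back_project(subset_sino(resid_n, views), geom, grid_shape, voxel_size_mm)
            upd = np.divide(upd, col_sums[si], out=np.zeros_like(upd),
                            where=col_sums[si] > 1e-9)
            x += cfg.sart_relaxation * upd
            if cfg.nonnegativity:
                np.clip(x, 0.0, None, out=x)
        # TV descent step length tied to the size of this iteration's SART
        # change (ASD-POCS convention), with a geometric decay across mains.
        dp = float(np.linalg.norm(x - x_pre))
        step = cfg.tv_step_ratio * dp * cfg.tv_step_decay**it
        # safeguarded descent: a step that would raise the TV is halved/skipped
        for _ in range(cfg.tv_steps):
            g = _tv_gradient(x)
            gn = np.linalg.norm(g)
            if gn < 1e-12 or step <= 0:
                break
            tv_before = tv_norm(x)
            trial_step = step
            for _ in range(8):
                x_trial = x - trial_step * g / gn
                if cfg.nonnegativity:
                    np.clip(x_trial, 0.0, None, out=x_trial)
                if tv_norm(x_trial) <= tv_before:
                    x = x_trial
                    break
                trial_step *= 0.5
        r = residual_norm(x)
        residual_log.append(r)
        grow_streak = grow_streak + 1 if r > residual_log[-2] else 0
        if grow_streak >= 5:
            raise ConvergenceError(
                f"data residual grew {grow_streak} consecutive main iterations",
                residual_log=residual_log,
            )

    return ReconVolume(
        values=x, voxel_size=voxel_size_mm, algorithm="frist",
        params={
            "m": geom.truncated_cols,
            "main_iterations": cfg.n_main_iterations,
            "tv_steps": cfg.tv_steps,
            "size_class": cfg.size_class,
            "residual_log": residual_log,
        },
    )
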