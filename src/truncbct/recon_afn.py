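"""Self-supervised attenuation field network (AFN) for sinogram inpainting.

A per-scan coordinate network h_Theta maps a world position (mm) to a
non-negative attenuation coefficient (cm^-1).  A projection is rendered as a
Riemann sum of field samples along the source->pixel ray,

    p_hat(d) = sum_i h_Theta(t_i) |t_{i+1} - t_i| ,

and the network is trained by minimizing the squared error between rendered
and acquired projections over the acquired detector pixels only.  The trained
field then renders the unacquired pixels; the inpainted and acquired data are
spliced (with a short linear feather across the boundary) into a complete
hybrid sinogram that is reconstructed by plain FDK — no redundancy weighting
is needed because the hybrid data are complete.

The network is a Fourier-feature multilayer perceptron implemented directly
in numpy (hand-written backprop, Adam), deterministic for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import SystemGeometry, detector_u
from .projector import Sinogram, counts_to_line_integrals
from .recon_fdk import ReconVolume, fdk_reconstruct

__all__ = [
    "AFNConfig",
    "AttenuationField",
    "render_projection",
    "train_field",
    "inpaint_and_splice",
    "afn_reconstruct",
]

MM_TO_CM = 0.1


class TrainingError(RuntimeError):
    def __init__(self, message: str, field=None):
        super().__init__(message)
        self.field = field


@dataclass
class AFNConfig:
    """Architecture and optimization settings for the attenuation field.

    Defaults are sized for full-resolution 2-D work; :meth:`small` returns the
    desk-scale preset used by the study pipeline and the test suite.
    """

    n_freqs: int = 96
    freq_scale: float = 25.0
    hidden_layers: int = 4
    hidden_units: int = 128
    n_samples_per_ray: int = 192
    batch_rays: int = 4096
    steps: int = 2000
    learning_rate: float = 1e-3
    lr_decay: str = "none"  # or "cosine" / "staged"
    rng_seed: int = 0
    feather_px: int = 8

    @classmethod
    def small(cls, steps: int = 1600, rng_seed: int = 0) -> "AFNConfig":
        return cls(
            n_freqs=48, freq_scale=25.0, hidden_layers=3, hidden_units=48,
            n_samples_per_ray=64, batch_rays=512, steps=steps,
            learning_rate=2e-3, rng_seed=rng_seed,
        )


def _softplus(x):
    # numerically safe softplus without the logaddexp broadcast overhead
    return np.where(x > 15.0, x, np.log1p(np.exp(np.minimum(x, 15.0))))


@dataclass
class AttenuationField:
    """Fourier-feature MLP representation of the attenuation map (cm^-1)."""

    config: AFNConfig
    fov_radius_mm: float
    dim: int
    fourier: np.ndarray            # (n_freqs, dim)
    weights: list = field(default_factory=list)   # [(W, b), ...]
    loss_history: list = field(default_factory=list)
    rng_seed: int = 0

    @classmethod
    def initialize(cls, config: AFNConfig, fov_radius_mm: float, dim: int = 2
                   ) -> "AttenuationField":
        rng = np.random.default_rng(config.rng_seed)
        # multi-scale Fourier bank: three octave bands up to freq_scale, so the
        # field captures the smooth interior and the sharp object boundary at once
        bands = np.array([config.freq_scale / 8, config.freq_scale / 2.5,
                          config.freq_scale])
        scales = np.repeat(bands, config.n_freqs // 3 + 1)[: config.n_freqs]
        B = (rng.normal(0.0, 1.0, size=(config.n_freqs, dim)) * scales[:, None]
             ).astype(np.float32)
        sizes = [2 * config.n_freqs] + [config.hidden_units] * config.hidden_layers + [1]
        weights = []
        for n_in, n_out in zip(sizes[:-1], sizes[1:]):
            W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_out, n_in)).astype(np.float32)
            b = np.zeros(n_out, dtype=np.float32)
            weights.append((W, b))
        return cls(config=config, fov_radius_mm=fov_radius_mm, dim=dim,
                   fourier=B, weights=weights, rng_seed=config.rng_seed)

    def _features(self, pts_mm: np.ndarray) -> np.ndarray:
        z = (pts_mm.astype(np.float32) / np.float32(self.fov_radius_mm)) @ self.fourier.T
        return np.concatenate([np.sin(z), np.cos(z)], axis=-1)

    def _forward(self, pts_mm: np.ndarray, cache: bool = False):
        """Forward pass (float32).  With ``cache`` also returns activations and
        pre-activations for backprop."""
        a = self._features(pts_mm)
        acts = [a]
        pre = []
        for i, (W, b) in enumerate(self.weights):
            z = a @ W.T + b
            if i < len(self.weights) - 1:
                a = np.maximum(z, 0.0, out=z if not cache else None)
                if cache:
                    pre.append(z)
                    acts.append(a)
            else:
                out = _softplus(z[:, 0].astype(np.float64))
                if cache:
                    pre.append(z)
        return (out, acts, pre) if cache else out

    def __call__(self, pts_mm: np.ndarray) -> np.ndarray:
        """Field values (cm^-1) at world points, shape (..., dim)."""
        pts = np.asarray(pts_mm, dtype=np.float32)
        flat = pts.reshape(-1, self.dim)
        out = np.empty(flat.shape[0])
        for i in range(0, flat.shape[0], 1 << 18):
            out[i: i + (1 << 18)] = self._forward(flat[i: i + (1 << 18)])
        return out.reshape(pts.shape[:-1])

    def _backward(self, dL_dout, acts, pre):
        """Gradients w.r.t. all weights given dL/d(field value) and the
        forward cache (single forward pass per step)."""
        grads = [None] * len(self.weights)
        # softplus' = sigmoid
        delta = (dL_dout * _sigmoid(pre[-1][:, 0].astype(np.float64))).astype(np.float32)[:, None]
        h_last = acts[-1]
        grads[-1] = (delta.T @ h_last, delta.sum(axis=0))
        dh = delta @ self.weights[-1][0]
        for i in range(len(self.weights) - 2, -1, -1):
            dz = dh * (pre[i] > 0)
            grads[i] = (dz.T @ acts[i], dz.sum(axis=0))
            if i > 0:
                dh = dz @ self.weights[i][0]
        return grads


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


# ---------------------------------------------------------------------------
# ray sampling / rendering
# ---------------------------------------------------------------------------


def _clip_to_fov(src, dst, fov_radius):
    """Parametric [t0, t1] in (0,1) where segments src->dst cross the FOV disk.

    src, dst: (N, dim) with the disk in the first two coordinates.
    Returns (t0, t1, hit).
    """
    d = dst[:, :2] - src[:, :2]
    a = np.sum(d * d, axis=1)
    b = 2 * np.sum(src[:, :2] * d, axis=1)
    c = np.sum(src[:, :2] ** 2, axis=1) - fov_radius**2
    disc = b * b - 4 * a * c
    hit = disc > 0
    sq = np.sqrt(np.maximum(disc, 0.0))
    t0 = np.clip((-b - sq) / (2 * a), 0.0, 1.0)
    t1 = np.clip((-b + sq) / (2 * a), 0.0, 1.0)
    hit &= t1 > t0
    return t0, t1, hit


def _render_batch(fld: AttenuationField, src, dst, rng=None, n_samples=None,
                  want_cache: bool = False):
    """Riemann-sum line integrals for a batch of rays (src, dst in world mm).

    Stratified sample fractions, jittered when an rng is given.  Returns the
    dimensionless line integrals (mu in cm^-1 times path in mm times 0.1), the
    per-sample path length, the miss flags, and optionally the forward cache
    for backprop.
    """
    n = n_samples or fld.config.n_samples_per_ray
    t0, t1, hit = _clip_to_fov(src, dst, fld.fov_radius_mm)
    nr = src.shape[0]
    base = (np.arange(n, dtype=np.float32) / n)[None, :]
    if rng is not None:
        frac = base + rng.random((nr, n), dtype=np.float32) / n
    else:
        frac = base + np.float32(0.5 / n)
    t = t0[:, None].astype(np.float32) + frac * (t1 - t0)[:, None].astype(np.float32)
    pts = src[:, None, :].astype(np.float32) + t[..., None] * (
        (dst - src)[:, None, :].astype(np.float32)
    )
    ray_len = np.linalg.norm(dst - src, axis=1)
    seg = (t1 - t0) * ray_len / n * MM_TO_CM  # per-sample path length, cm
    seg = np.where(hit, seg, 0.0)
    fw = fld._forward(pts.reshape(-1, fld.dim), cache=want_cache)
    if want_cache:
        vals, acts, pre = fw
    else:
        vals, acts, pre = fw, None, None
    integrals = vals.reshape(nr, n).sum(axis=1) * seg
    return integrals, seg, hit, (acts, pre)


def render_projection(fld: AttenuationField, ray) -> tuple[float, bool]:
    """Line integral of the field along one ray; flag False if it misses the FOV.

    When the ray carries explicit sample fractions they are honored (the
    Riemann sum uses the stated points and segment lengths); otherwise the
    field's configured stratified sampling is used.
    """
    src = np.asarray(ray.source, dtype=float)[: fld.dim][None, :]
    dst = np.asarray(ray.detector_point, dtype=float)[: fld.dim][None, :]
    if getattr(ray, "sample_fractions", None) is not None and len(ray.sample_fractions):
        fr = np.asarray(ray.sample_fractions)
        pts = src + fr[:, None] * (dst - src)
        vals = fld(pts)
        dl = np.diff(fr) * np.linalg.norm(dst - src) * MM_TO_CM
        return float(np.sum(vals[:-1] * dl)), True
    integ, _, hit, _ = _render_batch(fld, src, dst)
    return float(integ[0]), bool(hit[0])


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def estimate_support_radius(sino: Sinogram, threshold: float = 0.05,
                            margin: float = 1.08) -> float:
    """Object support radius (mm) from the acquired data.

    Every tangent line of the object appears on the acquired detector side at
    some view of a full scan, so the largest ray impact parameter carrying
    signal bounds the support.  Falls back to the geometric FOV radius for
    empty sinograms.
    """
    geom = sino.geometry
    plane = sino.data[:, 0, :]
    mask = sino.validity_mask[:, 0, :]
    u_iso = detector_u(geom, np.arange(geom.det_cols_full)) * geom.sad / geom.sdd
    impact = geom.sad * np.abs(u_iso) / np.sqrt(geom.sad**2 + u_iso**2)
    has_signal = ((plane > threshold) & mask).any(axis=0)
    if not has_signal.any():
        return geom.fov_radius
    return float(min(impact[has_signal].max() * margin, geom.fov_radius))


def _ray_endpoints(geom: SystemGeometry, views, cols, dim: int):
    """World-space (source, pixel) endpoints for central-row detector pixels."""
    th = np.deg2rad(geom.view_angles_deg[views])
    src = np.stack([geom.sad * np.cos(th), geom.sad * np.sin(th)], axis=1)
    u = detector_u(geom, cols)
    e_u = np.stack([-np.sin(th), np.cos(th)], axis=1)
    center = src - geom.sdd * np.stack([np.cos(th), np.sin(th)], axis=1)
    dst = center + u[:, None] * e_u
    if dim == 3:
        src = np.pad(src, ((0, 0), (0, 1)))
        dst = np.pad(dst, ((0, 0), (0, 1)))
    return src, dst


def train_field(
    sino: Sinogram,
    cfg: AFNConfig | None = None,
    fov_radius_mm: float | None = None,
) -> AttenuationField:
    """Fit the attenuation field to the acquired (mask-true) rays.

    Counts sinograms are log-converted first; training minimizes the mean
    squared projection error over random ray batches with Adam.  Deterministic
    for a given ``cfg.rng_seed``.
    """
    cfg = cfg or AFNConfig()
    sino = counts_to_line_integrals(sino)
    geom = sino.geometry
    if sino.n_rows != 1:
        raise TrainingError("2-D fan-beam training expects a single-row sinogram")
    plane = sino.data[:, 0, :]
    mask = sino.validity_mask[:, 0, :]
    views, cols = np.nonzero(mask)
    targets = plane[views, cols]
    # normalize coordinates to the object support, not the full FOV: the
    # Fourier features then spend their bandwidth on the object
    fov = fov_radius_mm or estimate_support_radius(sino)
    fld = AttenuationField.initialize(cfg, fov, dim=2)
    src_all, dst_all = _ray_endpoints(geom, views, cols, dim=2)

    rng = np.random.default_rng(cfg.rng_seed + 1)
    adam_m = [(np.zeros_like(W), np.zeros_like(b)) for W, b in fld.weights]
    adam_v = [(np.zeros_like(W), np.zeros_like(b)) for W, b in fld.weights]
    beta1, beta2, eps = 0.9, 0.999, 1e-8

    n_rays = len(targets)
    n = cfg.n_samples_per_ray
    for step in range(cfg.steps):
        idx = rng.integers(0, n_rays, size=min(cfg.batch_rays, n_rays))
        src, dst, y = src_all[idx], dst_all[idx], targets[idx]
        integ, seg, hit, (acts, pre) = _render_batch(fld, src, dst, rng=rng,
                                                     want_cache=True)
        resid = integ - y
        loss = float(np.mean(resid**2))
        fld.loss_history.append(loss)
        if not np.isfinite(loss):
            raise TrainingError(f"non-finite loss at step {step}", field=fld)
        # dL/d(field value at sample s of ray r) = 2 resid_r seg_r / n_batch
        dL_dout = np.repeat(2.0 * resid * seg / len(idx), n)
        grads = fld._backward(dL_dout, acts, pre)
        if cfg.lr_decay == "cosine":
            lr = cfg.learning_rate * 0.5 * (1 + np.cos(np.pi * step / cfg.steps))
        elif cfg.lr_decay == "staged":
            lr = cfg.learning_rate * (0.1 if step >= int(0.75 * cfg.steps) else 1.0)
        else:
            lr = cfg.learning_rate
        t = step + 1
        for i, ((gW, gb), (W, b)) in enumerate(zip(grads, fld.weights)):
            mW, mb = adam_m[i]
            vW, vb = adam_v[i]
            mW = beta1 * mW + (1 - beta1) * gW
            mb = beta1 * mb + (1 - beta1) * gb
            vW = beta2 * vW + (1 - beta2) * gW**2
            vb = beta2 * vb + (1 - beta2) * gb**2
            adam_m[i] = (mW, mb)
            adam_v[i] = (vW, vb)
            mW_h = mW / (1 - beta1**t)
            mb_h = mb / (1 - beta1**t)
            vW_h = vW / (1 - beta2**t)
            vb_h = vb / (1 - beta2**t)
            fld.weights[i] = (
                (W - lr * mW_h / (np.sqrt(vW_h) + eps)).astype(np.float32),
                (b - lr * mb_h / (np.sqrt(vb_h) + eps)).astype(np.float32),
            )
    return fld


def smoothed_loss(fld: AttenuationField, window: int = 25) -> np.ndarray:
    """Monotone-smoothed training loss: running-mean then running-min envelope."""
    h = np.asarray(fld.loss_history, dtype=float)
    if h.size == 0:
        return h
    kernel = np.ones(min(window, h.size)) / min(window, h.size)
    sm = np.convolve(h, kernel, mode="valid")
    return np.minimum.accumulate(sm)


# ---------------------------------------------------------------------------
# inpainting / reconstruction
# ---------------------------------------------------------------------------


def inpaint_and_splice(
    fld: AttenuationField,
    sino: Sinogram,
    feather: int | None = None,
) -> Sinogram:
    """Render the unacquired pixels and splice with the acquired data.

    A linear cross-fade over ``feather`` columns on the acquired side of each
    boundary suppresses the seam; acquired pixels outside the feather band are
    returned bit-identical.  The output mask is all-true (complete hybrid).
    """
    sino = counts_to_line_integrals(sino)
    feather = fld.config.feather_px if feather is None else feather
    if feather < 0:
        raise ValueError("feather must be >= 0")
    plane = sino.data[:, 0, :].copy()
    mask = sino.validity_mask[:, 0, :]
    if mask.all():
        return Sinogram(data=sino.data.copy(), geometry=sino.geometry,
                        validity_mask=np.ones_like(sino.validity_mask), domain="line_integral")

    geom = sino.geometry
    # pixels to render: all missing, plus the acquired feather band
    missing_v, missing_c = np.nonzero(~mask)
    # feather band: acquired pixels within `feather` columns of a missing pixel
    band = np.zeros_like(mask)
    if feather > 0:
        miss_cols = ~mask
        for k in range(1, feather + 1):
            band |= np.roll(miss_cols, k, axis=1) | np.roll(miss_cols, -k, axis=1)
        band &= mask
    band_v, band_c = np.nonzero(band)

    def render(views, cols):
        src, dst = _ray_endpoints(geom, views, cols, dim=2)
        out = np.empty(len(views))
        chunk = 1 << 15
        for i in range(0, len(views), chunk):
            integ, _, _, _ = _render_batch(fld, src[i:i + chunk], dst[i:i + chunk])
            out[i:i + chunk] = integ
        return out

    plane[missing_v, missing_c] = render(missing_v, missing_c)
    if len(band_v):
        rendered_band = render(band_v, band_c)
        # distance (in columns) of each band pixel to the nearest missing pixel
        dist = np.full(mask.shape[1], np.inf)
        miss_any = (~mask).any(axis=0)
        cols_idx = np.arange(mask.shape[1])
        miss_idx = cols_idx[miss_any]
        if len(miss_idx):
            dist = np.min(np.abs(cols_idx[:, None] - miss_idx[None, :]), axis=1)
        alpha = np.clip(dist[band_c] / (feather + 1.0), 0.0, 1.0)
        plane[band_v, band_c] = (
            alpha * plane[band_v, band_c] + (1 - alpha) * rendered_band
        )

    data = plane[:, None, :]
    return Sinogram(data=data, geometry=geom,
                    validity_mask=np.ones_like(data, dtype=bool),
                    domain="line_integral")


def afn_reconstruct(
    sino: Sinogram,
    cfg: AFNConfig | None = None,
    grid_shape: int | tuple = 160,
    voxel_size_mm: float | None = None,
    fld: AttenuationField | None = None,
) -> ReconVolume:
    """Train -> inpaint/splice -> plain FDK of the complete hybrid sinogram."""
    cfg = cfg or AFNConfig()
    if fld is None:
        fld = train_field(sino, cfg)
    hybrid = inpaint_and_splice(fld, sino)
    rec = fdk_reconstruct(hybrid, grid_shape=grid_shape, voxel_size_mm=voxel_size_mm)
    return replace(rec, algorithm="afn", params={
        "m": sino.geometry.truncated_cols,
        "steps": cfg.steps,
        "final_loss": fld.loss_history[-1] if fld.loss_history else None,
    })
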