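"""Desk-scale study orchestration: phantom cohort -> truncation sweep ->
reconstructions -> image-quality metrics -> Monte Carlo dose and scatter.

The imaging arm runs 2-D fan-beam on a 4x-binned detector (256 columns of
1.552 mm); truncation widths are quoted in full-resolution detector units
(1024, 596, ... 512) and scaled internally.  The FDK-W arm uses a redundancy
weighting whose smooth transition width is fixed at the overlap of the widest
studied truncation (the design point of a fielded weighting scheme), which is
what makes its artifact onset observable; AFN needs no weighting and is
evaluated at the truncations of interest.  The Monte Carlo arm uses 2 mm
voxel phantoms in the clinical layout (chest wall at the top edge of the cone
field of view) and reports mean glandular dose and the maximum of the
horizontal scatter-to-primary profile per collimation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import build_geometry, detector_u, scaled_geometry, SystemGeometry
from .phantom import CohortSpec, LABELS, generate_phantom
from .projector import (
    Sinogram, apply_counting_noise, counts_to_line_integrals, forward_project,
    truncate_sinogram,
)
from .recon_fdk import artifact_score, fdk_reconstruct, redundancy_weights
from .recon_tv import TVConfig, classify_breast_size, frist_reconstruct
from .recon_afn import AFNConfig, afn_reconstruct
from .spectrum_materials import make_spectrum, mean_energy, default_material_table
from . import montecarlo as mc
from . import metrics as mt

__all__ = ["StudyConfig", "run_study", "embed_for_mc", "clinical_roi_rows"]


TRUNCATION_LIST = (1024, 596, 584, 572, 560, 548, 536, 524, 512)


@dataclass
class StudyConfig:
    """Configuration of one synthetic study; defaults are the desk-scale run."""

    n_phantoms: int = 5
    base_seed: int = 0
    truncations: tuple = TRUNCATION_LIST     # full-resolution units, descending, 1024 first
    algorithms: tuple = ("fdkw", "frist", "afn")
    detector_scale: int = 4
    n_views: int = 300
    imaging_voxel_mm: float = 1.4
    grid_n: int = 160
    i0: float = 3.0e4                        # photons/pixel entering the detector
    quant_m: int = 596                       # truncation for the quantitative arm
    afn_m: tuple = (596, 536)                # truncations where AFN is evaluated
    afn_steps: int = 1200
    frist_main_iterations: int = 10
    artifact_threshold: float = 0.05
    roi_size_px: int = 6                     # ~8.5 mm at the imaging voxel
    mc_photons: int = 30_000_000
    mc_collimations: tuple = (1024, 596, 536)
    mc_voxel_mm: float = 2.0
    mc_grid_n: int = 128
    mc_tally_bin: int = 8
    scan_air_kerma_mgy: float = 10.0
    run_imaging: bool = True
    run_mc: bool = True
    outdir: str | None = None

    def __post_init__(self) -> None:
        if list(self.truncations) != sorted(self.truncations, reverse=True):
            raise ValueError("truncation list must be sorted descending")
        if self.truncations[0] != 1024:
            raise ValueError("the complete detector (1024) must head the truncation list")


def _scaled_m(m: int, scale: int) -> int:
    return max(1, int(round(m / scale)))


def embed_for_mc(label_grid: np.ndarray, geom: SystemGeometry, grid_n: int,
                 voxel_mm: float) -> np.ndarray:
    """Center a pendant-breast label grid in the clinical layout.

    The chest wall (slice 0 of the phantom) is placed at the top edge of the
    cone field of view, the breast hanging downward along -z, centered in x-y.
    """
    nz, ny, nx = label_grid.shape
    out = np.zeros((grid_n, grid_n, grid_n), dtype=np.uint8)
    half_h_iso = 0.5 * geom.det_rows * geom.pixel_pitch * geom.sad / geom.sdd
    k_top = int(min((half_h_iso + 0.5 * grid_n * voxel_mm) / voxel_mm, grid_n))
    k_lo = max(k_top - nz, 0)
    y0 = (grid_n - ny) // 2
    x0 = (grid_n - nx) // 2
    out[k_lo:k_top, y0:y0 + ny, x0:x0 + nx] = label_grid[::-1][-(k_top - k_lo):]
    return out


def clinical_roi_rows(geom: SystemGeometry, tally_bin: int,
                      rows_from_chest_wall=(101, 200)) -> tuple[int, int]:
    """Detector tally-row range for an ROI quoted in full-resolution rows
    counted from the chest-wall (top) edge of the panel."""
    top, bottom = rows_from_chest_wall
    lo = (geom.det_rows - bottom) // tally_bin
    hi = (geom.det_rows - top) // tally_bin + 1
    return max(lo, 0), min(hi, geom.det_rows // tally_bin)


def make_imaging_slice(subject: CohortSpec, rng_seed: int, grid_n: int,
                       n_calcs: int = 3):
    """2-D label slice near the chest wall with seeded calcification pixels.

    Returns (labels2d, calc_centers) embedded in a grid_n x grid_n frame.
    """
    phantom = generate_phantom(replace(subject, n_calcifications=0), rng_seed=rng_seed)
    # among the chest-wall-adjacent slices, take the one richest in
    # fibroglandular tissue so the ROI protocol has something to measure
    candidates = range(1, min(7, phantom.label_grid.shape[0]))
    sl_idx = max(candidates,
                 key=lambda k: int((phantom.label_grid[k] == LABELS["fibroglandular"]).sum()))
    sl = phantom.label_grid[sl_idx].copy()
    ny, nx = sl.shape
    frame = np.zeros((grid_n, grid_n), dtype=np.uint8)
    y0 = (grid_n - ny) // 2
    x0 = (grid_n - nx) // 2
    frame[y0:y0 + ny, x0:x0 + nx] = sl
    rng = np.random.default_rng(rng_seed + 7919)
    interior = np.argwhere(frame >= LABELS["adipose"])
    centers = []
    if len(interior):
        for _ in range(n_calcs):
            r, c = interior[rng.integers(len(interior))]
            frame[r, c] = LABELS["calcification"]
            centers.append((int(r), int(c)))
    return frame, tuple(centers), phantom


def _labels_to_mu_2d(labels2d: np.ndarray, energy_kev: float) -> np.ndarray:
    table = default_material_table()
    lut = np.zeros(5)
    for name, code in LABELS.items():
        lut[code] = table.mu(name, energy_kev)
    return lut[labels2d]


def run_study(cfg: StudyConfig | None = None) -> dict:
    """Run the full synthetic study; deterministic for a given config.

    Returns a dict with ``records`` (tidy per-case metric DataFrame),
    ``artifact`` (per-case, per-algorithm, per-m artifact scores),
    ``artifact_onset`` (narrowest artifact-free m per algorithm),
    ``mc`` (per-case MGD / max-SPR vs collimation with percent reductions),
    and ``failures``.  Writes CSV/JSON into ``cfg.outdir`` when set.
    """
    cfg = cfg or StudyConfig()
    spectrum = make_spectrum(49.0, 1.39)
    e_eff = mean_energy(spectrum)
    geom_full = build_geometry(n_views=cfg.n_views)
    geom = scaled_geometry(geom_full, cfg.detector_scale)
    scale = cfg.detector_scale
    # fixed Wang transition width: overlap of the widest studied truncation
    widest_m = max([m for m in cfg.truncations if m < 1024], default=596)
    lo_col = geom.det_cols_full - _scaled_m(widest_m, scale)
    transition_w = float(abs(detector_u(geom, lo_col)))

    records: list[dict] = []
    art_rows: list[dict] = []
    mc_rows: list[dict] = []
    failures: list[dict] = []

    cohort_rng = np.random.default_rng(cfg.base_seed + 424243)
    subjects = [CohortSpec(voxel_size_mm=cfg.imaging_voxel_mm).sampled(cohort_rng)
                for _ in range(cfg.n_phantoms)]

    for case in range(cfg.n_phantoms):
        seed = cfg.base_seed + 1000 * (case + 1)
        subject = subjects[case]
        if cfg.run_imaging:
            try:
                _imaging_arm(cfg, case, seed, subject, geom, e_eff, transition_w,
                             records, art_rows)
            except Exception as exc:  # record and continue with remaining cells
                failures.append({"case": case, "stage": "imaging", "error": repr(exc)})
        if cfg.run_mc:
            try:
                _mc_arm(cfg, case, seed, subject, geom_full, spectrum, mc_rows)
            except Exception as exc:
                failures.append({"case": case, "stage": "mc", "error": repr(exc)})

    art = pd.DataFrame(art_rows)
    onset = {}
    if len(art):
        for algo, grp in art.groupby("algorithm"):
            onset[algo] = _artifact_onset(grp, cfg.artifact_threshold)

    mc_df = pd.DataFrame(mc_rows)
    if len(mc_df):
        ref = mc_df[mc_df.m == cfg.mc_collimations[0]].set_index("case")
        mc_df["mgd_reduction_pct"] = mc_df.apply(
            lambda r: 100.0 * (1 - r.mgd_mgy / ref.loc[r.case, "mgd_mgy"]), axis=1)
        mc_df["spr_reduction_pct"] = mc_df.apply(
            lambda r: 100.0 * (1 - r.max_spr / ref.loc[r.case, "max_spr"]), axis=1)

    report = {
        "records": pd.DataFrame(records),
        "artifact": art,
        "artifact_onset": onset,
        "mc": mc_df,
        "failures": failures,
        "config": asdict(cfg),
    }
    if cfg.outdir:
        out = Path(cfg.outdir)
        out.mkdir(parents=True, exist_ok=True)
        report["records"].to_csv(out / "metrics.csv", index=False)
        art.to_csv(out / "artifact_scores.csv", index=False)
        mc_df.to_csv(out / "mc_dose_spr.csv", index=False)
        with open(out / "summary.json", "w") as fh:
            json.dump({"artifact_onset": onset, "failures": failures,
                       "config": asdict(cfg)}, fh, indent=2, default=str)
        with open(out / "summary.md", "w") as fh:
            fh.write("# Study summary\n\n## Artifact-free detector widths\n\n")
            for algo, m in sorted(onset.items()):
                fh.write(f"- {algo}: m = {m}\n")
            if len(mc_df):
                fh.write("\n## Dose and scatter vs collimation (per case)\n\n")
                cols = ["case", "m", "mgd_mgy", "max_spr",
                        "mgd_reduction_pct", "spr_reduction_pct"]
                fh.write(mc_df[cols].round(4).to_markdown(index=False))
                fh.write("\n")
            if failures:
                fh.write(f"\n## Failures\n\n{len(failures)} stage failure(s); "
                         "see summary.json.\n")
    return report


def _artifact_onset(grp: pd.DataFrame, threshold: float):
    """Narrowest m that is artifact-free with every wider m also artifact-free."""
    onset = None
    for m in sorted(grp.m.unique(), reverse=True):
        score = grp[grp.m == m].score.max()
        if score <= threshold:
            onset = int(m)
        else:
            break
    return onset


def _imaging_arm(cfg, case, seed, subject, geom, e_eff, transition_w,
                 records, art_rows):
    labels2d, calc_centers, phantom = make_imaging_slice(subject, seed, cfg.grid_n)
    mu2d = _labels_to_mu_2d(labels2d, e_eff)
    clean = forward_project(mu2d, geom, cfg.imaging_voxel_mm)
    noisy = apply_counting_noise(clean, i0=cfg.i0, rng_seed=seed + 1)
    sino = counts_to_line_integrals(noisy)
    vox = cfg.imaging_voxel_mm
    size_class = classify_breast_size(subject.chest_wall_diameter_cm)

    reference = fdk_reconstruct(sino, grid_shape=cfg.grid_n, voxel_size_mm=vox)

    def add_metrics(rec, algo, m):
        try:
            row = mt.evaluate_case(rec.values, labels2d, vox, calc_centers,
                                   roi_size=cfg.roi_size_px, rng_seed=seed)
        except mt.MetricError as exc:
            records.append({"case": case, "algorithm": algo, "m": m,
                            "size_class": size_class, "error": repr(exc)})
            return
        row.update({"case": case, "algorithm": algo, "m": m,
                    "size_class": size_class})
        records.append(row)

    add_metrics(reference, "fdk", 1024)

    scale = cfg.detector_scale
    quant_ms = _scaled_m(cfg.quant_m, scale)

    for m in cfg.truncations:
        if m == 1024 or "fdkw" not in cfg.algorithms:
            continue
        ms = _scaled_m(m, scale)
        trunc = truncate_sinogram(sino, ms)
        w = redundancy_weights(trunc.geometry, transition_half_width_mm=transition_w)
        rec = fdk_reconstruct(trunc, weights=w, grid_shape=cfg.grid_n, voxel_size_mm=vox)
        score = artifact_score(rec, reference, vox)
        art_rows.append({"case": case, "algorithm": "fdkw", "m": m, "score": score})
        if ms == quant_ms:
            add_metrics(rec, "fdkw", m)

    if "frist" in cfg.algorithms:
        trunc = truncate_sinogram(sino, quant_ms)
        w = redundancy_weights(trunc.geometry)  # adaptive band for the initializer
        tv_cfg = TVConfig(n_main_iterations=cfg.frist_main_iterations,
                          size_class=size_class, rng_seed=seed)
        rec = frist_reconstruct(trunc, tv_cfg, grid_shape=cfg.grid_n,
                                voxel_size_mm=vox, weights=w)
        art_rows.append({"case": case, "algorithm": "frist", "m": cfg.quant_m,
                         "score": artifact_score(rec, reference, vox)})
        add_metrics(rec, "frist", cfg.quant_m)

    if "afn" in cfg.algorithms:
        for m in cfg.afn_m:
            ms = _scaled_m(m, scale)
            trunc = truncate_sinogram(sino, ms)
            afn_cfg = AFNConfig.small(steps=cfg.afn_steps, rng_seed=seed)
            rec = afn_reconstruct(trunc, afn_cfg, grid_shape=cfg.grid_n,
                                  voxel_size_mm=vox)
            score = artifact_score(rec, reference, vox)
            art_rows.append({"case": case, "algorithm": "afn", "m": m, "score": score})
            add_metrics(rec, "afn", m)


def _mc_arm(cfg, case, seed, subject, geom_full, spectrum, mc_rows):
    subject_mc = replace(subject, voxel_size_mm=cfg.mc_voxel_mm, n_calcifications=0)
    phantom = generate_phantom(subject_mc, rng_seed=seed)
    vol = embed_for_mc(phantom.label_grid, geom_full, cfg.mc_grid_n, cfg.mc_voxel_mm)
    roi_rows = clinical_roi_rows(geom_full, cfg.mc_tally_bin)
    for m in cfg.mc_collimations:
        g = geom_full.with_truncation(m)
        mc_cfg = mc.MCConfig(n_photons=cfg.mc_photons, n_projections=30,
                             rng_seed=seed + m, tally_bin=cfg.mc_tally_bin)
        tally = mc.transport(vol, cfg.mc_voxel_mm, spectrum, g, mc_cfg)
        _, max_spr = mc.spr_profile(tally, roi_rows)
        mgd_mgy = mc.mgd(tally, spectrum, cfg.scan_air_kerma_mgy)
        mc_rows.append({
            "case": case, "m": m, "max_spr": max_spr, "mgd_mgy": mgd_mgy,
            "dgn_ct": mc.dgn_ct(tally, spectrum),
            "deposited_kev": tally.total_deposited_kev,
        })
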