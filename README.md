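# truncbct

Desk-scale study of **offset/truncated-detector cone-beam breast CT**: how far
can the flat-panel detector be narrowed along the fan-angle direction — cutting
both radiation dose and scattered radiation — before each reconstruction
algorithm breaks down, and what does that truncation buy in mean glandular dose
(MGD) and scatter-to-primary ratio (SPR)?

The package is written for medical-physics researchers who want a fully
synthetic, reproducible re-run of this question: every input (breast phantoms,
x-ray spectrum, material cross sections, noise) is generated in code, and every
stage is a tested library function.

## What is inside

* **Geometry** — circular-trajectory cone-beam system (300 views / 360°,
  SDD 898 mm, SAD 650 mm, 1024 × 768 panel at 0.388 mm pitch) with a
  contiguous-column truncation scheme `m ∈ {1024, 596, 584, …, 512}` that
  always retains the projected rotation axis.
* **Phantoms** — semi-ellipsoidal pendant breasts matching a clinical cohort
  (chest-wall diameter 12.26 ± 2.68 cm, chest-to-nipple 10.4 ± 2.75 cm,
  fibroglandular weight fraction 0.20 ± 0.16), with skin shell, Gaussian-field
  fibroglandular texture, and spherical calcifications.
* **Spectrum & materials** — 49 kV tungsten-anode model hardened to a first
  HVL of 1.39 mm Al; photoelectric/Compton/Rayleigh cross sections for breast
  tissues, air, aluminum, and calcification on a 1 keV grid.
* **Forward model** — ray-driven fan-/cone-beam line integrals with a matched
  adjoint and Poisson counting noise.
* **Reconstruction** —
  * `FDK-W`: fan-beam FBP / FDK with Wang-style sin² redundancy weighting,
    `w(u) = sin²(π (u + W) / 4W)` across the overlap band so conjugate rays
    satisfy `w(u) + w(−u) = 1`;
  * `FRIST`-style iterative: ordered-subsets SART fidelity passes interleaved
    with safeguarded total-variation descent (10 TV steps per iteration for
    large/medium breasts, 15 for small);
  * `AFN`: a per-scan self-supervised attenuation field — a coordinate network
    `h_Θ(t)` trained by `argmin_Θ Σ_d ‖p̂(d) − p(d)‖²` over the acquired rays,
    where `p̂(d) = Σ_i h_Θ(t_i)|t_{i+1} − t_i|`, then used to inpaint the
    unacquired sinogram half before plain FDK.
* **Monte Carlo** — analog voxel photon transport (Klein–Nishina Compton,
  Thomson-law Rayleigh, local photoelectric absorption) tallying per-tissue
  deposited energy and primary/scatter detector images; the normalized
  glandular dose coefficient is
  `DgN^CT = E_g,dep / (n_g · m_g · Σ_E Φ(E) Θ_k(E))`.
* **Metrics** — ROI mean/variance, `SDNR = |μ̄_G − μ̄_A| / √(½(σ²_G + σ²_A))`,
  and calcification FWHM along two orthogonal axes.
* **Pipeline** — `run_study` orchestrates phantom cohort → truncation sweep →
  three reconstructions → metrics → MC dose/scatter, and reports artifact-onset
  widths and percent dose/SPR reductions.

## Worked example

```python
import numpy as np
from truncbct import (build_geometry, make_spectrum, hvl, mean_energy,
                      truncation_fraction, generate_phantom, CohortSpec,
                      MCConfig, transport, dgn_ct, spr_profile)
from truncbct.pipeline import embed_for_mc, clinical_roi_rows

geom = build_geometry()                  # 300 views, 898/650 mm, 1024x768 @ 0.388 mm
spectrum = make_spectrum(49.0, 1.39)     # 49 kV W-anode matched to 1.39 mm Al HVL
print(f"first HVL      : {hvl(spectrum):.3f} mm Al")
print(f"mean energy    : {mean_energy(spectrum):.1f} keV")
print(f"truncated area : {100*truncation_fraction(geom.with_truncation(596)):.1f}% at m=596")

phantom = generate_phantom(CohortSpec(voxel_size_mm=2.0), rng_seed=7)
volume = embed_for_mc(phantom.label_grid, geom, 128, 2.0)
for m in (1024, 596, 536):
    cfg = MCConfig(n_photons=10_000_000, n_projections=30, rng_seed=7, tally_bin=8)
    tally = transport(volume, 2.0, spectrum, geom.with_truncation(m), cfg)
    _, max_spr = spr_profile(tally, clinical_roi_rows(geom, 8))
    print(f"m={m:4d}: DgN^CT = {dgn_ct(tally, spectrum):.3f} mGy/mGy, max SPR = {max_spr:.3f}")
```

Output (a few minutes on one core):

```
first HVL      : 1.390 mm Al
mean energy    : 29.6 keV
truncated area : 41.8% at m=596
m=1024: DgN^CT = 0.386 mGy/mGy, max SPR = 0.193
m= 596: DgN^CT = 0.287 mGy/mGy, max SPR = 0.164
m= 536: DgN^CT = 0.219 mGy/mGy, max SPR = 0.119
```

Reading it: the spectrum solver reproduces the requested beam hardness; the
widest artifact-free FDK-W detector (m = 596) discards 41.8% of the panel; and
narrowing the beam from the complete panel to 536 columns cuts the glandular
dose coefficient by ~43% and the peak scatter-to-primary ratio by ~38% on this
phantom, while the 596-column panel gives intermediate values — the dose and
scatter move together, which is the point of the truncated-detector design.

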