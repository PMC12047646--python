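# Methods

This note records the models, defaults, and numerical choices behind
`truncbct`, in the spirit of a methods appendix: what each stage assumes, which
knobs matter, and what the synthetic experiments can and cannot show.

## System geometry

A circular-trajectory cone-beam system: source–axis distance 650 mm,
source–detector distance 898 mm, flat panel of 1024 × 768 pixels at 0.388 mm
(2×2-binned), 300 views over 360°. World frame: rotation axis = z, source in
the x–y plane, counter-clockwise views from +x; detector u-axis along
(−sin θ, cos θ). Truncation removes a contiguous block of fan-direction
columns from one side (default: low indices), so the kept block
`[1024 − m, 1024)` always contains the projected rotation axis plus an overlap
band of half-width `d = (m − 512.5) · pitch`. Conjugate rays obey
(θ, γ) ↔ (θ + 180° − 2γ, −γ) in this convention.

Desk scale: the imaging arm bins the detector 4× (256 columns of 1.552 mm) and
works in the central fan plane (2-D); truncation widths are quoted in
full-resolution units and scaled. Cone-beam (3-D) projection and FDK are
implemented and tested at reduced grids but the study pipeline is fan-beam:
every algorithmic question investigated here (redundancy weighting, TV
regularization, sinogram inpainting) has a faithful fan-beam analog.

## Breast phantoms (synthetic-data stage)

Pendant semi-ellipsoid: circular chest-wall cross section of the subject's
diameter, tapering over one chest-to-nipple length. Cohort draws use
N(12.26, 2.68²) cm diameter, N(10.4, 2.75²) cm length, and a fibroglandular
weight fraction from N(0.20, 0.16²) clipped to [0.05, 0.95] — the 5% floor
guarantees every subject carries a fibroglandular region large enough for the
ROI protocol, as clinical breasts do near the chest wall.

* Skin: Euclidean-distance shell of thickness max(1.5 mm, one voxel) — the
  floor keeps the shell closed on the 2 mm Monte Carlo grids.
* Fibroglandular tissue: a Gaussian random field smoothed to a 15 mm
  correlation length (the scale of dense-tissue clusters), thresholded by
  bisection until the *weight* fraction of the interior (densities: adipose
  0.93, fibroglandular 1.04, skin 1.09 g/cm³) matches the request within
  machine precision; the generated grid lands within ±0.02 of the request.
* Calcifications: spheres of 0.2–1.0 mm placed in interior tissue. At the
  imaging-arm resolution (1.4 mm) they are single-pixel impulses, which is
  what the FWHM comparison needs (parity across algorithms, not absolute
  sizes).

What the generator does **not** emulate: ductal anatomy, biomechanical shape
variation, partial-volume skin gradients, positioning error. Passing tests
demonstrate algorithmic behavior (noise, redundancy, inpainting, transport),
not anatomical realism.

## Spectrum and materials

The tube model is a Kramers continuum at 49 kV on a 1 keV grid (5–49 keV),
hardened by an aluminum thickness solved by bisection so the computed first
half-value layer equals 1.39 mm Al within 0.01 mm (the system's nominal value;
the printed 1.4 mm figure is the same quantity at coarser precision). Photons
below 5 keV are dropped — negligible after ~1.4 mm-Al-equivalent filtration.

Cross sections are generated per element and mixed by weight fraction
(compositions shipped as CSV): Klein–Nishina incoherent scattering per
electron, a photoelectric power law `Z^4.15 / E^3.1` calibrated to the
standard aluminum anchor (26.23 cm²/g total at 10 keV), and a coherent power
law `Z^2.5 / E^1.9` calibrated to water at 10 keV. Accuracy is roughly ±10%
against standard tabulations over 5–50 keV for low-Z materials — adequate
here because every consumer is either self-consistent (HVL solver,
Beer–Lambert checks) or comparative (dose/SPR ratios across collimations).
The air mass energy-absorption coefficient is photoelectric plus incoherent
times the Klein–Nishina mean energy-transfer fraction; fluence-to-air-kerma
factors follow as `Θ_k(E) = E · (μ_en/ρ)_air`.

## Forward model

Ray-driven line integrals with bilinear (2-D) / trilinear (3-D) interpolation
at a step of half the voxel size; the fan-beam backprojector is the exact
adjoint (needed by the iterative reconstruction). Counting noise is Poisson
with `i0 = 3 × 10⁴` photons/pixel by default — chosen so the reference
reconstruction's flat-ROI noise sits at the few-×10⁻³ cm⁻¹ level typical of
breast-CT images. The imaging arm is monoenergetic at the spectrum's mean
energy (29.6 keV): beam hardening is out of scope for the reconstruction
questions, and the polyenergetic physics lives in the Monte Carlo arm.

## FDK-W and the artifact-onset mechanism

Fan-beam FBP with cosine pre-weighting, ramp × Hann filtering (2× zero
padding, cutoff at Nyquist) and distance-weighted backprojection; a complete
full-scan detector uses the constant redundancy weight ½. For truncated
detectors the Wang-style weight rises as sin²(π(u+W)/4W) across the
transition band |u| ≤ W, which satisfies w(u) + w(−u) = 1 *exactly* for any W
because the two arguments are complementary.

The transition half-width W is a genuine design parameter. With W adapted to
each truncation's overlap, ideal noise-free fan-beam data reconstruct
essentially exactly at every width down to m = 512 — there is no failure to
observe. Fielded weighting schemes, however, are commissioned for one detector
offset; the study pipeline therefore fixes W at the overlap of the widest
studied truncation (m = 596 equivalent, ≈32 mm). When the acquired overlap is
narrower than W, the missing part of the transition band has no conjugate
partner with compensating weight (pairs there sum to <1), and a centered
shading artifact appears and deepens as m shrinks — scores on the default
phantoms: ~10⁻⁴ at 596-eq, ~0.02 at 584-eq, ~0.1 at 572-eq, >1 at 536-eq.
This reproduces the clinical observation that redundancy-weighted FDK is
usable down to m = 596 and fails below.

The **artifact score** is the maximum deviation of the azimuthally averaged
radial profile (about the FOV center, where offset-detector shading lives)
from the reference reconstruction's profile, normalized by the reference
interior mean. Radial bins at and beyond the object edge (reference profile
below half its interior mean) are excluded: edge sharpness is measured by the
FWHM metrics, and including the edge would let a ~1-pixel boundary blur
masquerade as shading. The pipeline calls a reconstruction artifact-free when
the score is ≤ 0.05, a threshold calibrated so complete-data FDK on an
independent noisy realization scores well below 0.01.

## FRIST-style iterative reconstruction

Each main iteration = one ordered-subsets SART pass (10 subsets, relaxation
0.8) followed by TV gradient descent. Defaults: 20 main iterations in the
API, 8–10 in the study pipeline (converged for these sizes); TV steps per
iteration follow the breast-size schedule (10 large/medium, 15 small; tertile
cuts at 11 and 14 cm chest-wall diameter). The TV stage uses a safeguarded
step — a step that would raise the TV is halved up to 8 times, then skipped —
so the denoising block never increases total variation; the step length is a
fixed ratio (0.2) of that iteration's SART change with a 0.97 geometric decay
(ASD-POCS convention). Divergence (data residual growing five consecutive
main iterations) raises an error carrying the residual log. The update
equations are this package's own concrete realization; behavior is pinned by
properties (residual monotonicity, TV monotonicity, variance reduction at
matched means), not by equation-level fidelity to any particular published
implementation.

## Attenuation field network

The field h_Θ maps world coordinates (normalized by an object-support radius
estimated from the acquired data: the largest ray impact parameter carrying
signal, +8%) through a multi-scale Fourier feature bank — three octave bands
up to `freq_scale` (default 25 rad per support radius), 48–96 frequencies —
into a ReLU MLP with a softplus output enforcing non-negative attenuation.
Training minimizes the mean squared difference between rendered and acquired
line integrals over random ray batches (Adam, lr 2 × 10⁻³, batch 512 rays ×
64 stratified-jittered samples at desk scale; 1200–1600 steps). Rendering is
the left-endpoint Riemann sum of field samples times segment lengths, rays
clipped to the support disk. Everything is float32 numpy with hand-written
backprop; a fixed seed reproduces training bit-for-bit.

Inpainting renders the mask-false pixels; splicing cross-fades linearly over
an 8-pixel feather band on the acquired side of the boundary and leaves all
other acquired pixels bit-identical. The hybrid sinogram is complete, so the
final reconstruction is plain FDK with the full-scan ½ weight — no redundancy
weighting, which is why the field approach has no fixed-transition failure
mode. On the desk-scale phantoms the inpainted pixels agree with their
acquired conjugates to ~2% median and reconstructions stay artifact-free down
to m = 536-equivalent (and usually 512-equivalent); per the study protocol the
pipeline evaluates it at 596- and 536-equivalent widths.

## Monte Carlo dose and scatter

Analog transport on the labeled voxel grid (2 mm default), exact
Amanatides–Woo traversal with sampled optical depth — no majorant tracking,
so high-attenuation calcification voxels cost nothing extra. Photoelectric
events absorb locally; Compton uses Kahn's Klein–Nishina sampling with the
recoil deposited locally (electron ranges are sub-voxel below 49 keV);
Rayleigh redirects with the Thomson angular law (form factors omitted — this
overweights large-angle coherent scatter slightly but coherent is a small
fraction of interactions here). No fluorescence (low-Z tissues). Energy
bookkeeping (emitted = deposited + escaped) is exact to float rounding and
enforced at 10⁻³ relative.

Photons are emitted from a 0.3 mm square focal spot toward points sampled
uniformly over the *illuminated* detector area; the emitted number scales
with that area, so tube output per unit beam area — and the free-in-air kerma
at the isocenter, computed analytically from the planar emission density and
the magnification — is identical across collimations. `DgN^CT` divides the
fibroglandular dose by that kerma; MGD multiplies `DgN^CT` by a configurable
scan air kerma (default 10 mGy — a plausible diagnostic CBBCT technique; the
absolute MGD scale is not a claim, the reductions across collimations are).

Phantoms are placed in the clinical layout — chest wall at the top edge of
the cone field of view, breast hanging down — so the SPR region of interest
(full-resolution detector rows 101–200 from the chest-wall edge, averaged
over all views) falls in the breast shadow near the chest wall. The SPR
profile is scatter over primary energy fluence per detector column on a
binned tally grid (default 8× binning). The profile maximum is a ratio of
sparse tallies in the breast shadow and needs real statistics — the largest
cohort subjects require 3 × 10⁷ full-beam-equivalent photons per collimation
before the collimation ordering resolves reliably, which is the study
default (dose-only quantities are stable from 10⁶, with a run-to-run
coefficient of variation around 0.3%).

## Problem sizes used by the tests and the study

Imaging arm: 160² grid at 1.4 mm, 300 views, 256-column detector; iterative
reconstruction 8–10 main iterations; field network 1200–1600 steps. Monte
Carlo: 128³ grid at 2 mm; 10⁶ photons × 10 repeats for the repeatability
check, 10⁵ per arm for the half-beam bound, 3 × 10⁷ per collimation for
dose/SPR sweeps. The default study runs 5 phantoms; the test suite exercises
a 2-phantom configuration with the field network at the 536-equivalent width.

## Known limitations

* The imaging arm is 2-D and monoenergetic; cone-angle redundancy violations,
  beam hardening, and scatter contamination of the projections — all present
  in clinical data — are not part of the reconstruction experiments.
* Cross sections are model fits (±10%), not library tabulations; absolute
  dose coefficients inherit that uncertainty, ratios largely cancel it.
* The fixed-transition FDK-W failure mechanism is one concrete realization of
  how fielded weighting schemes break under deepening truncation; clinical
  failure mixes several causes.
* The half-beam dose-reduction bound (≤50%) holds in expectation; single
  Monte Carlo estimates straddle it within their standard error, and the
  test accounts for that explicitly.
* The field network is a compact CPU-sized coordinate MLP; its residual edge
  blur (~1 pixel) is visible in FWHM comparisons at desk scale, while
  clinical-scale variants of such networks train far larger models.
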