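# Methods

This package implements voxel-wise uncertainty estimation for deep-learning
CBCT-to-synthetic-CT (sCT) translation and the propagation of that image
uncertainty to dose, on synthetic paired phantoms with a built-in proxy dose
engine. This note documents the model, its assumptions, the tunable
parameters, what the phantom generator does and does not emulate, and the
numerical choices.

## Image translation and aleatoric uncertainty

The generator `G` maps a normalized CBCT volume to two output channels: the
translated image and the per-voxel natural log of an aleatoric noise scale
`sigma_data(x)` (normalized units). Assuming a Laplacian noise model for the
CBCT/CT discrepancy, training minimises the masked negative log-likelihood

    L_unc = (1/N) sum_i [ |CT_i - G(CBCT)_i| / sigma_i + log sigma_i ],

with the distribution's additive constant dropped, plus an L1 reconstruction
term (weight `w_rec = 1`) and an optional least-squares adversarial term
(weight `w_adv = 0` by default; the published full loss weighting for the
original clinical backbone is not public, so the supervised defaults are
declared here as this package's own configuration). The per-voxel optimum of
`L_unc` over `sigma` is `sigma* = |residual|`, so the scale channel learns
the local magnitude of the irreducible error. `sigma` is floored at `1e-4`
(normalized; 0.1 HU) inside the loss for `1/sigma` stability.

The backbone is a compact numpy U-Net (default width 16, two pooling levels,
3x3 kernels, ReLU, average pooling, nearest-neighbour upsampling) with
hand-written backpropagation and Adam, trained on 2D axial slices (batch 1);
a 3D mode exists for small volumes. Two deliberate architectural choices:

* **Residual output.** The image channel is predicted as `CBCT + correction`.
  Input and target share the HU scale, so the identity is the right
  inductive bias; it also keeps the aleatoric channel honest — the lazy
  solution leaves the injected noise in the residual rather than
  oversmoothing the prediction.
* **Slice-mean context channel.** The input has a second channel: the
  volume's mean along the slice axis. Voxel-scale tissue heterogeneity and
  noise average away in this projection while slice-constant artifact fields
  (cupping, streaks, global offset) survive at full strength, giving the
  decoder a clean view of what to subtract. Without it, a slice-wise model
  cannot estimate a 20-40 HU artifact field under ~100 HU voxel-wise tissue
  texture, and the aleatoric scale in low-noise regions absorbs the
  unremoved artifacts.

Optimisation: Adam, base learning rate 1e-3 decayed linearly to 20% over
training (the clinical reference configuration used 2e-4 for a much larger
adversarial backbone trained for 200 epochs; this small supervised network
trains faster and the decayed schedule lets the scale channel settle to the
local residual magnitude), gradient clipping at global norm 5, batch size 1,
40 epochs, and random flip/right-angle-rotation augmentation of training
slices (which multiplies the diversity of streak angles seen in training),
seeded end to end. Training is deterministic on one device.

The loss is restricted to the external body mask by default (`loss_region`);
the acceptance pipeline trains with `loss_region="all"` so that the scale
channel is supervised on the background too, which the two-region recovery
analysis evaluates.

## Epistemic uncertainty and calibration

Epistemic uncertainty uses MC dropout: dropout (rate 0.3) is injected at
inference only, in the decoder's dropout sites, and T = 50 stochastic passes
are drawn. The model variance is the voxelwise population variance over the
passes — divisor T, exactly as the estimator is defined, not T-1. The per-pass
aleatoric maps are averaged into a single `sigma_data` map (lowest-variance
unbiased reduction; which pass's map to use is otherwise arbitrary).

Total uncertainty combines quadratically, `sigma_tot = sqrt(sigma_data^2 +
sigma_model^2)`; maps are exposed in standard-deviation units (HU after
scaling by 1000) with the squared identity preserved as an invariant.

Calibration is a single pooled ordinary-least-squares fit of observed
absolute error `|CT - sCT|` on predicted `sigma_tot` over training cases
(voxels subsampled to at most 1e6 pairs, seeded), applied at inference as
`max(slope * sigma + intercept, floor)`. Being a global affine map, it
cannot change the Pearson correlation between uncertainty and error; it
aligns the scale, which is what the held-out regression slope checks.

## Plausible sCTs and dose propagation

Error scenarios are generated by perturbing each MCD sample once with
independent per-voxel Laplacian noise at scale `sigma_data` (interpreted as
the Laplace scale parameter b, consistent with the loss; a flag reinterprets
it as a standard deviation). The K = T = 50 perturbed volumes are
denormalized and clipped to [-1000, 3000] HU. Away from the clip bounds the
member variance is Var_MCD + 2 sigma_data^2.

The dose engine is a declared toy replacement for a treatment-planning
system: relative density `rho = clip(1 + HU/1000, 0, 3)`, radiological depth
along each beam (exact cumulative sum for axis-aligned beams; trilinear ray
marching, step 1 mm, for oblique ones — the two quadratures differ by up to
half a voxel of water-equivalent depth at the ray entry), per-beam dose =
linear build-up ramp (10 mm) x exponential falloff (0.005/mm) inside a
cylindrical aperture (22 mm) around the PTV centroid axis, two opposed
lateral beams by default. The plan is scaled once so the PTV median dose on
the planning CT equals the 60 Gy prescription; the frozen scale is reused
for every ensemble member of the case. The engine sits behind a small
interface so a real dose export could be substituted.

Dose ensemble statistics use the same population divisor as the MCD
variance. Bounds are `[max(D - 3 sigma_dose, 0), D + 3 sigma_dose]` around
the nominal sCT dose (+/-3 sigma covers 99.7% under normality; the lower
bound is clamped because dose is non-negative). DVHs are cumulative
(fraction of structure volume receiving at least each dose level, default
bin 0.01 Gy); a structure's DVH band is the three curves on shared edges,
and "the CT DVH is covered" is defined as lying inside [lower, upper] at
>= 98% of bin edges (tolerance 1e-6).

Gamma analysis is 3D, 1%/1 mm local with a 10% lower dose threshold by
default: per reference voxel, the minimum over evaluated positions within
3 x DTA (sub-voxel step DTA/10, trilinear interpolation) of
`sqrt((dose diff / dd_abs)^2 + (distance / DTA)^2)`. Offsets are visited
nearest-first with exact pruning (an offset is skipped only when its distance
term alone exceeds the current minimum), so the result equals a dense
exhaustive search; positions outside the grid are excluded. Voxels below the
threshold carry the sentinel value -1 in the gamma map.

The subset-convergence analysis draws n of the 50 member doses without
replacement (seeded), compares the subset's voxelwise dose-sigma map with the
full-ensemble map by mean absolute difference over the body, and averages
over repeats; reported in cGy.

## The phantom generator

Each sample is a body ellipsoid (~40 HU) on a -1000 HU background with an
embedded bone ellipsoid (~700 HU), an air cavity, a PTV sphere and two
lateral organs at risk, on a 64x64x32 grid at 2 mm spacing by default
(configurable up to clinical sizes; desk-scale sizes keep the full pipeline
in minutes). The CBCT is the CT plus a radial cupping field (40 HU), six
random-angle Gaussian-profile streaks (30 HU), a +20 HU global offset, and
per-voxel Laplacian noise with a tissue-linked scale map — body 50 HU, bone
and background 10 HU by default — clipped to [-1000, 3000] HU after
corruption, so extreme draws are censored exactly as a clinical HU range
would. Cohorts jitter anatomy and artifact amplitudes per sample; an OOD flag
scales artifact amplitudes and noise by 1.8x to emulate an unseen centre.

Soft tissue and bone carry white Gaussian HU heterogeneity (sd 100 HU).
This is the one deliberately stylised ingredient: with a piecewise-constant
target, a denoising network drives the residual to zero and the aleatoric
channel would correctly learn "no irreducible error" — recovering the
injected noise scale requires voxel-scale anatomical content that is not
inferable from a voxel's neighbourhood, which is the role registration
residuals and day-to-day anatomical change play in real CBCT/CT pairs. With
texture sd 100 and the default scales, the information-theoretic floor of
the residual is ~0.92 b in the body and ~1.1 b in bone, both inside the 30%
recovery band.

What the generator does not emulate: projection-domain physics (scatter,
beam hardening), spatially correlated noise, registration error as a
deformation (it is modelled statistically via the texture), fixation
devices, and oblique orientations. Consequences: passing tests show the
estimator recovers a known per-voxel noise scale and propagates it to dose
consistently; they do not show robustness to correlated artifacts or
real-scanner noise spectra.

## Study conditions and problem sizes

The acceptance pipeline trains on 8 phantoms and holds 2 out (the clinical
reference cohort is 54/5/26; sizes here are scaled down to keep the full
pipeline at desk scale, as are the 40 training epochs), then runs T = 50 MCD
passes, K = 50 plausible members, and 50 member doses per case — the ensemble
sizes the method itself prescribes. Background aleatoric scale is not
recoverable by construction (the background is exactly constant, so a
converged model predicts it perfectly and its residual scale honestly tends
to zero); recovery is therefore evaluated in the two textured regions (body
and bone).

## Known limitations

* The backbone is a small numpy CNN, not the published adversarial
  architecture; conclusions about the uncertainty machinery transfer, those
  about achievable image quality do not.
* In small low-noise regions the recovered scale overestimates the injected
  b: interface voxels carry genuine partial-volume error across the
  soft-tissue/bone boundary, and unremoved streak/shading error adds a few
  HU. sigma_data tracks its true target — the residual |CT - sCT| scale — to
  ~15%; that residual itself bottoms out above b in bone at this model
  scale. The body-region scale and the full-grid correlation with the true
  scale map (~0.97) recover cleanly.
* Pearson correlations between uncertainty and error on phantoms are
  substantially lower than clinical values: with a two-level noise field the
  error map's dynamic range inside the body is narrow, so the correlation is
  dominated by single-draw |Laplace| variability rather than anatomy-driven
  error structure.
* The proxy engine's dose is exponential-attenuation only (no lateral
  scatter, no heterogeneity-corrected kernels); gamma pass rates between CT
  and sCT doses are informative relative to each other, not clinically.
* Fisher's Z treats voxels as independent; spatial autocorrelation is
  ignored, as in the evaluation protocol this mirrors.
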