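# Methods

This note records the models, conventions and numerical choices behind
`orthosr`, and what the phantom-based tests do and do not demonstrate.

## Geometry and DICOM conventions

Volumes are stored as `(i, j, k)` arrays where `i` runs along the
in-plane row direction (increasing DICOM column), `j` along the
in-plane column direction, and `k` along the slice normal. Patient
coordinates are LPS; the world point of voxel `(i, j, k)` is
`origin + D · (spacing ∘ (i, j, k))` with `D` the orthonormal matrix of
direction cosines and `origin` the *center* of voxel `(0,0,0)`. This
matches the semantics of ImagePositionPatient /
ImageOrientationPatient / PixelSpacing, so a canonical axial volume is
indexed `(x, y, z)` and a canonical coronal volume `(x, −z, y)`.

Reading a series sorts slices by the projection of
ImagePositionPatient onto the slice normal, so file order is
irrelevant. Series are rejected (not repaired) on mixed series UIDs,
inconsistent orientation, inter-slice intervals spreading more than
10⁻² mm, or a non-uniform rescale slope; silent mixing of any of these
would corrupt geometry or intensities undetectably. Intensities are
Hounsfield units (`slope·stored + intercept`); writing stores rounded
HU with slope 1 / intercept −1024 in signed 16-bit, and errors on
values outside that range. Round-trips are exact in stored integers
and reproduce geometry to better than 10⁻⁶ mm.

Series admission mirrors the clinical collection rules: thin axial
thickness in [1, 1.25] mm with interval in [0.7, 1.25] mm and no wider
than the thickness; both thick series 5 mm thickness and 5 mm
interval; and the two thick planes right orthogonal. Orthogonality is
a pure predicate on absolute cosine residuals with default tolerance
10⁻³ (no tolerance is published; 10⁻³ rejects a 5° gantry tilt by
three orders of magnitude while admitting numerically perturbed
canonical headers). Intervals are computed from slice positions; the
SliceThickness tag provides the slab width.

## Fusion

The LR volume is built directly on the thin-axial grid: each target
voxel center is mapped to patient space, then to continuous indices of
each thick source, sampled by trilinear interpolation, and averaged
where both sources cover the point. Trilinear interpolation is the
standard choice and is exact on affine intensity fields, which gives
the test suite a closed-form oracle; the implementation
(`scipy.ndimage.map_coordinates`, order 1) is additionally checked
voxel-by-voxel against an independent pure-python loop. Averaging is
done in HU with equal weights and no intensity harmonisation between
the series. Voxels covered by a single source keep that value; voxels
covered by neither are filled with −1000 HU (air) and flagged in a
coverage mask, so downstream metrics can restrict to covered regions
if desired. A non-orthogonal pair is rejected outright, mirroring the
admission rule.

## Architectures

All four networks are 1:1: the fused LR volume already has the target
resolution, so the interpolation / upsampling stages of the original
designs are replaced by the identity.

| | structure | loss | notes |
|---|---|---|---|
| SRCNN | conv 9-5-5, 64→32 filters | MSE | plain feed-forward |
| VDSR | 20 conv layers, 64×3×3 | MSE | global skip; global-norm gradient clip 1.0 |
| SRResNet | 16 residual blocks (conv-BN-PReLU-conv-BN), long skip | MSE | head/tail 9×9 convs |
| EDSR | 32 residual blocks (conv-ReLU-conv), no normalization, residual scaling 0.1, long skip | L1 | |

Open choices resolved here: filter width defaults to 64 everywhere
(the EDSR-baseline width; block counts are fixed but width is
configurable, and desk-scale runs use width 8 without changing any
structure). The VDSR clipping constant is not published; a global-norm
bound of 1.0 is used. The 1:1 modification makes an input-to-output
skip natural for all residual designs, so VDSR, SRResNet and EDSR are
implemented as `y = x + f(x)`; zeroing the final convolution makes
them exactly the identity. Their final convolutions are initialised
with 10×-reduced He weights so training starts near the identity map —
the standard small-residual initialisation for residual SR networks —
which matters at desk scale where only dozens of steps are taken.
Optimisation is Adam at the published initial learning rates with no
schedule.

The engine behind the networks is a minimal numpy implementation
(im2col convolution with BLAS matmuls, explicit backprop, float64).
Its gradients are verified against central finite differences in the
test suite; training is bit-reproducible given the seed in
single-threaded execution.

## Training and inference protocol

HU intensities are normalised from the fixed window [−1024, 3071] to
[0, 1]; the window is recorded on the trained model and network
outputs are de-normalised and clipped back to it. Each epoch draws
`batches_per_epoch` batches of `batch_size` random patch pairs from
the configured plane (patches 96×96 at full scale; slices smaller than
the patch are reflect-padded), cut at identical HR/LR locations with
uniform offsets. HR targets for coronal/sagittal training are taken
directly from the restacked thin-axial volume, not resampled. After
each epoch the model is scored by full-volume inference on the
held-out evaluation cases and the checkpoint with the best evaluation
PSNR is returned. No patch rejection is applied — air-only patches are
admitted. Inference is fully convolutional on whole slices along any
requested plane; using a plane other than the training plane is a
supported experiment and warns rather than errors.

The published schedules (e.g. EDSR: 16 × 7500 × 20 = 2.4 M patches)
are shipped as `TrainConfig.published(...)` but are GPU-scale. The
desk-scale profile used in tests and the pipeline default keeps every
structural setting (block counts, losses, clipping, patch mechanics)
and shrinks the schedule to 32×32 patches, batch 8, ~50–320 steps,
learning rate 10⁻³ (a short schedule needs larger steps), width 8,
with phantoms of 48×48×40 voxels at 1 mm and a 3/1/1
train/eval/test split.

## Phantom generator

Each case is an ellipsoidal soft-tissue body (40 HU) in −1000 HU air,
containing two lung ellipsoids (−800 HU) with random bright tubular
vessels (0 HU, radius 1–2 mm) and ground-glass-like nodules (−400 HU,
radius 2–4 mm), plus Gaussian noise (σ = 15 HU) confined to the body
so ambient air is exactly blank, as it nearly is clinically. Anatomy
scales with the grid so lungs never touch the volume border. The
thick series are derived by pure boxcar means of 5 consecutive 1 mm
slices along the respective patient axis (slice thickness = interval,
i.e. contiguous slabs with no slice-profile tails), with the coronal
result re-gridded so its third axis is anterior–posterior and its
world coordinates consistent with the source.

What the phantom does *not* emulate: scanner physics (beam hardening,
reconstruction kernels — the clinical series mix smooth and sharp
kernels), anatomical texture, breathing/registration error between
series, and field-of-view differences. Tests passing on phantoms
therefore demonstrate the correctness of the machinery and the
*direction* of the findings (fusion beats the axial stack alone; short
SR training beats LR; ROI ordering), not clinical effect sizes: the
published per-case PSNR/SSIM magnitudes are properties of the private
22-case clinical test set and are out of scope here.

## Metrics and ROIs

PSNR uses a fixed data range of 4095 HU (the normalisation window
width) rather than per-image ranges, for comparability across cases;
zero-MSE comparisons are reported as a 100 dB sentinel. SSIM is the
Gaussian-weighted formulation (11×11 window, σ = 1.5, K₁ = 0.01,
K₂ = 0.03, no sample-covariance correction), delegated to
scikit-image and verified against a direct per-window implementation
of the formula.

ROI boxes are one 3-D bounding box per case, derived from the HR
volume only: body = largest connected component above −500 HU with
holes filled; lungs = components below −320 HU inside the body,
excluding border-touching components, keeping the two largest. The
thresholds follow common chest-CT practice. Scores are computed per
axial slice inside the box and averaged over slices (the per-slice
convention matches slice-wise processing of DICOM series; a per-volume
alternative would differ only in weighting). Nesting
lung ⊆ body ⊆ whole holds by construction.

A note on the ROI-ordering property (whole ≥ body ≥ lung): it is
driven by the fraction of near-zero-error ambient air in each box. For
PSNR it holds under any body-confined error. For SSIM the property
test uses a body-confined *blur* as the error model — resolution loss
concentrated on structure, which is what thick-slice averaging
produces — because spatially uniform additive noise damages flat soft
tissue more than structured lung tissue in the SSIM sense and drives
the body/lung comparison into a tie.

## Paired statistics

The one-sided Wilcoxon signed-rank test ("x exceeds y") drops zero
differences, assigns midranks to tied magnitudes, and computes the
exact null distribution of the rank sum by convolution for up to 25
non-zero differences (midranks are half-integers, so doubling them
makes the distribution integer-supported). Beyond that a tie-corrected
normal approximation with continuity correction is used. With 22 test
cases and all differences positive the exact p is 1/2²² ≈ 2.38 × 10⁻⁷,
the floor visible throughout pairwise comparison tables. scipy's
implementation is used as an independent cross-check in tie-free cases
but not as the implementation, since its exact method does not admit
ties.

Comparison families: plane mode compares all C(13,2) = 78 unordered
pairs of {LR} ∪ {4 models × 3 planes}; ROI mode compares only the
5·C(3,2) + 3·C(5,2) = 45 pairs of {5 methods × 3 ROIs} sharing a
method or an ROI (cross-method cross-ROI cells are marked absent, not
zero). Thresholds are α/n with α = 0.05: 6.41 × 10⁻⁴ and 1.11 × 10⁻³.

## Known limitations

- Only right-orthogonal axial/coronal pairs are fused; arbitrary-angle
  registration is out of scope.
- The numpy engine is single-threaded and float64 — correct and
  reproducible, but orders of magnitude slower than a GPU framework;
  the published multi-hour schedules are configuration only.
- DICOM support is single-frame CT with uncompressed transfer
  syntaxes; enhanced multi-frame CT is not parsed.
- Phantom realism is deliberately minimal (see above); conclusions
  about clinical magnitudes cannot be drawn from it.
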