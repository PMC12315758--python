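# Methods

This note documents the models, numerical choices, and limitations of
`mridenoise` at the level a maintainer needs to reason about results.

## Noise model

Magnitude MRI noise is Rician: with true intensity A ≥ 0 and per-channel
Gaussian sd σ, the observed magnitude has density
p(M) = (M/σ²)·exp(−(M²+A²)/(2σ²))·I₀(AM/σ²).  `rice_pdf` evaluates this
through the exponentially scaled Bessel function `i0e`, i.e.
(M/σ²)·exp(−(M−A)²/(2σ²))·i0e(AM/σ²), which is stable for arbitrarily
large AM/σ² (the unscaled I₀ overflows near A/σ ≈ 30).  `add_rician` draws
two independent Gaussian fields and takes the magnitude voxelwise; outputs
are clipped to [0, 1] so noisy volumes remain valid unit-scale volumes
(the clip only affects voxels whose magnitude would exceed 1, i.e. bright
tissue under heavy noise; background and mid-intensity statistics, which
the distributional tests rely on, are untouched).

Sigma is always a fraction of the unit intensity range of conformed images:
"9%" means σ = 0.09.  Three named regimes drive training:

| regime        | base σ range | field      |
|---------------|--------------|------------|
| `standard`    | [0, 0.09]    | variable   |
| `refine_low`  | [0, 0.04]    | stationary |
| `refine_high` | [0.04, 0.09] | stationary |

The spatially **variable field** multiplies the base σ by a factor that is
3 at the volume center and 1 at the outermost voxels.  The source states
only those two anchors plus "cubic interpolation"; the concrete geometry
here is a 3×3×3 control lattice (center 3, all 26 boundary controls 1)
expanded with tricubic spline interpolation and clamped to [1, 3].  The
lower clamp removes spline undershoot near the corners; the upper clamp
pins the design ceiling of 27% at base 9% exactly.  On odd-sized grids the
center voxel sits on the lattice center, so the pointwise maximum is
exactly 3× the base; on even grids it falls marginally below.

The lower bounds of `standard` and `refine_low` are inclusive zeros:
exposure to clean inputs during training is what teaches the network to
leave noise-free images unchanged, and the test suite checks that a model
trained at σ = 0 drifts less on clean inputs than on noisy ones.

## Conforming

`conform` normalizes a volume to the form every other stage assumes:
reorient to RAS, resample to a cubic grid of edge max(H, W, D) with
isotropic voxels of size min(v₁, v₂, v₃), rescale intensities to [0, 1].
Resampling is per-axis linear with the half-pixel-center convention
(src = (dst + 0.5)·(v_out/v_in) − 0.5); the scale factor is the voxel-size
ratio, never recomputed from grid sizes, and out-of-field samples are air
(0).  No bias-field correction is performed.

The intensity map is a clipped-histogram 8-bit rescale: a 1000-bin
histogram determines the smallest bin edge above which at most 1/1000 of
the voxels lie; values above that ceiling are clipped and [min, ceiling]
maps linearly to [0, 255] (then /255).  Two refinements matter in practice:

- The bin-edge search is **iterated** — the histogram is rebuilt over the
  clipped range until the ceiling stabilizes (≤ 8 passes).  A single pass
  cannot separate the bulk from one extreme outlier (the ceiling would
  land at max/1000); iteration recovers the bulk dynamic range while still
  cropping at most the stated fraction.
- Volumes already tagged `unit_0_1` **skip the histogram rescale** (the
  linear cast is then the identity).  A histogram re-crop of already
  conformed data is not idempotent in general — after clipping, at most
  0.1% of voxels sit at the ceiling, so a second pass would cut into the
  bulk — and gating on the intensity tag is what makes `conform` a fixed
  point (idempotent to < 1e-6, interpolation round-off only).
- A constant-valued volume maps to all zeros (documented degenerate case
  instead of a division by zero).

Coordinates are 0-based voxel indices in (sagittal, coronal, axial) order
after RAS reorientation.  Working precision is float32 throughout; files
may be stored at higher precision.

## Network

`Fondue` is a nested UNet++-style encoder–decoder over seven resolution
rows with a constant filter count N_filt (default 64; tests and toy runs
use 4–16).  A CBU is conv–PReLU, conv–PReLU, elementwise maxout of the two
stages, conv–PReLU (all 3×3, padding 1; optional conv→BN→PReLU ordering
when batch normalization is enabled; PReLU has one learnable slope per
channel).  The input CBU maps the 7-channel slab to N_filt; output CBUs
append a 1×1 collapse to one channel.

Row 0 operates at native resolution.  The VINN step rescales features to
the internal resolution R_i = 1.0 mm by the factor F = R_o/R_i (bilinear,
half-pixel convention, no corner alignment; the factor is used directly,
not recomputed from the target shape).  Rows 2–6 are reached by 2×2/stride-2
max pooling whose argmax indices feed the matching unpooling.  Internal
feature maps are zero-padded to the next multiple of 32 after the VINN
rescale (pooling depth 5) and cropped back before upsampling, so any slab
H, W ≥ 16 passes through without shape error.

Nested blocks exist for rows i = 1..5, columns j = 1..6−i: the stated
encoder range i={2..5} cannot by itself feed the six top-row heads, so the
grid is completed the only way the head count allows.  Each nested block
maxouts the unpooled block from (i+1, j−1) with all same-row predecessors
(i, 0..j−1).  Row-0 columns j = 1..6 maxout the VINN-upscaled (1, j−1)
block with all row-0 predecessors and emit candidate Y_j through their 1×1
collapse.  The final residual is Y = Σλ_N·Y_N / Σλ_N with trainable
scalars λ_N initialized at 1.0 and unconstrained (the normalization
absorbs scale; a numerically zero Σλ raises instead of dividing).  λ_N
participate in weight decay like any other parameter.

With `filter_doubling` (the LT++ configuration) rows 0–1 keep N_filt and
each pooled row doubles it.  Where a skip's channel count then differs
from its row, fusion falls back to channel concatenation (the maxout
competition requires equal widths); unpool indices are tiled across the
doubled channels.

Comparators: `UNetVINN` (plain five-level U-Net, 32→512 filter doubling,
VINN normalization, concatenating skips, residual output) and `MCDnCNN`
(17 stacked conv–BN–ReLU layers, 64 filters, residual output).  All three
share the residual contract: zeroing the output heads makes the network an
exact identity.

### Compute backend

All tensor computation runs on a small reverse-mode autograd engine on
numpy: conv2d is im2col + GEMM with hand-written backward, pooling uses a
reshape/argmax formulation, bilinear resizing is a pair of dense 1D
interpolation matrices (exact transpose in the backward pass).  Everything
is deterministic — two runs with the same seed are bit-identical, which the
checkpoint and inference tests assert.  The `autocast` policy emulates
mixed precision by casting GEMM operands to float16 while keeping float32
master parameters; the contract tested is that shapes never change and the
toy-run loss moves by < 10%.

## Training

- One-cycle policy with max_lr = 0.01, pct_start = 0.075, div_factor = 10,
  final_div_factor = 100; both the ramp and the anneal are cosine (the
  anneal shape is stated, the ramp shape is a package choice).
- AdamW with β₁ = 0.9, β₂ = 0.99, decoupled weight decay 1e-4.  Momentum
  cycling maps onto β₁: 0.95 at the rate extremes, 0.85 at the peak,
  moving inversely to the learning rate.
- Refinement stages (B1/B2) use a fixed 1e-6 learning rate, start from a
  first-stage checkpoint, and train on the frozen first stage's output.
- Noise is re-drawn each epoch with a per-sample seed derived from
  (global seed, epoch, volume index), so realizations are fresh but
  reproducible.
- Training uses axial slabs only; view aggregation is inference-only.
- Gradients are accumulated sample by sample within a batch, which lets
  the inner-scale offset differ per sample as intended; the optimizer
  steps once per batch.
- Loss is computed on the denoised middle slice against its clean
  counterpart.  Variant defaults: feature loss (L1 on deep features) for A,
  LPIPS-style (L2 on deep features) for B/LT/LT++/B1/B2 and the
  comparators; MAE/MSE are available for cheap toy runs.
- A non-finite loss aborts immediately with the step, learning rate, and
  sigma in the message.

## Augmentation

Horizontal flips with probability 0.5 (the probability is unstated in the
source; 0.5 is the package default), rotations uniform in ±5°, bilinear
with zero fill (background is air after conforming), applied identically
to input slab and clean target.  Rotations are in-plane only — slabs are
2.5D and through-plane context must stay aligned.  The inSA offset is
Gaussian (mean 0, sd 0.1) added to F, redrawn if the factor would fall
below 0.05; it is sampled per training sample, not per batch.

## Metrics

MAE, MSE, PSNR (10·log₁₀(MAXI²/MSE), +inf sentinel at zero error), SSIM,
MS-SSIM, deep-feature losses, Dice/IOU, and paired t-tests with
Benjamini–Hochberg FDR for method comparison.  Numerical conventions:

- SSIM uses an 11×11 Gaussian window (σ = 1.5), population (weighted)
  statistics, and averages over fully valid window positions only.
- MS-SSIM uses M = 2 dyadic scales by default; the standard five-scale
  exponents are renormalized to the first M so the index stays ≤ 1 and
  comparable across M.  c₃ = c₂/2 collapses structure·contrast into the
  familiar second SSIM factor.  Negative contrast-structure means are
  clamped at 0 before exponentiation.
- The deep-feature backbone is a deterministic seeded-random two-stage
  conv stack (He-initialized, ReLU); grayscale inputs are replicated to
  three channels.  By default losses read the first stage (l = {1}), and
  the per-layer mean is averaged across selected layers.  Published
  pretrained classifier weights are an opt-in origin that raises a clear
  error when unavailable; the seeded extractor is the default everywhere
  so no download is ever needed.  The learned linear calibration of the
  published perceptual metric is not reproduced.
- Metrics operate on the conformed [0, 1] scale with MAXI = 1 unless the
  caller passes 8-bit data.
- Zero-variance paired differences are reported as p = 1 / "ns" rather
  than propagating a NaN t-statistic.

## Phantoms

`make_phantom` renders nested ellipsoids on an air background: scalp
(0.35), a thin bright cortical shell (0.85), white matter (0.55), and dark
ventricles (0.12), each with smooth low-frequency texture, plus an optional
smooth multiplicative bias field.  The thin bright shell is deliberate:
over-smoothing by a denoiser erodes it visibly in SSIM and feature terms.
The registry provides a 32³ fast-test phantom, a ten-volume 64³ training
set, and a 96³ anisotropic (1.0×1.0×1.2 mm) phantom for conform tests.

What the phantoms do *not* emulate: k-space acquisition, point-spread
functions, partial-volume mixtures, motion/ghosting, spatially correlated
or coil-map noise, and real anatomical variability.  Passing tests
therefore demonstrate the correctness of the pipeline's mechanics and the
denoiser's behavior under the stated noise model — not clinical-grade
performance on scanner data.

## Problem sizes

The suite's end-to-end toy run trains a 16-filter network on ten 64³
phantoms for 320 optimizer steps (batch 2, 8 axial slices per volume per
epoch, 8 epochs) — a scale chosen so the whole suite runs in minutes on one
CPU — and checks a ≥ 3 dB PSNR gain on a held-out phantom at σ = 5% plus a
< 0.5 dB drift on a clean phantom.  The drift criterion is expressed as an
amplitude ratio: 20·log₁₀(1 + MAE/mean(clean)) in dB.  These are the
package's own bars for its toy scale, not published performance numbers;
full-scale training (50 epochs over multi-site datasets) is days of GPU
work and out of scope here, as is loading the originally released weights.

## Known limitations

- The numpy backend is single-node and CPU-bound; it is meant for tests,
  toy studies, and reference semantics, not production-scale training.
- `add_rician` clips at 1.0, slightly truncating the magnitude
  distribution of very bright voxels under heavy noise.
- The histogram rescale resolves the clipping ceiling only to bin-edge
  granularity (1/1000 of the current range per pass).
- MS-SSIM at M > 2 on small images fails fast rather than padding.
- Checkpoints are npz archives specific to this package; no compatibility
  with other serialization formats is promised.
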