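# mridenoise

Resolution-invariant denoising of structural brain MRI with a nested
competitive U-Net.

Structural T1-weighted MRI carries Rician-distributed noise: both quadrature
channels of the scanner are contaminated with zero-mean Gaussian noise of
standard deviation σ, so a voxel with true intensity *A* is observed as the
magnitude *M* = √((A+n₁)² + n₂²) with density

    p(M) = (M/σ²) · exp(−(M² + A²)/(2σ²)) · I₀(AM/σ²),

Rayleigh in the air background and near-Gaussian at high SNR.  Higher
spatial resolution raises the noise floor, which hurts segmentation and
morphometry — and classical patch-based denoisers are slow, while most CNN
denoisers must be retrained per voxel size.  This package is for
neuroimaging researchers who want a fast, voxel-size-invariant CNN denoiser
that can be exercised end to end on synthetic phantoms, with every stage —
preprocessing, noise simulation, training, inference, evaluation —
available as a tested library plus CLI.

## The model

A stack of **seven consecutive slices** (a 2.5D slab) is fed to a nested
encoder–decoder that predicts six candidate maps Y₁…Y₆ of the *residual
noise* of the middle slice.  The final residual is their weighted average
with trainable scalars λ_N,

    Y = (Σ_N λ_N Y_N) / (Σ_N λ_N),

and the denoised slice is the noisy middle slice minus Y.  Architectural
ingredients:

- **CBU blocks**: 3×3 convolutions with PReLU (optional batch norm) and an
  internal elementwise **maxout** competition, so the filter count stays
  constant through the whole network.
- **Latent resolution normalization (VINN)**: feature maps are rescaled
  bilinearly by F = R_o/R_i between the native voxel size R_o and a fixed
  internal resolution R_i = 1.0 mm, which makes one set of weights work at
  any voxel size; during training F is jittered by a zero-mean Gaussian
  offset (inner-scale augmentation, sd 0.1).
- **Nested topology**: seven resolution rows (native, internal, five
  pooled), max-pooling with argmax index passing to the matching unpooling,
  and dense same-row maxout fusion; each of the six top-row columns emits
  one candidate head.
- **Three-plane view aggregation** at inference: the volume is denoised
  independently along axial, coronal, and sagittal planes with the same
  weights and the three results are averaged voxelwise.

Training uses the one-cycle "super-convergence" schedule (max_lr 0.01,
pct_start 0.075, div_factor 10, final_div_factor 100, cosine phases),
AdamW (β₁ = 0.9, β₂ = 0.99), and simulated Rician noise with base
σ ∈ [0, 9%] of the unit intensity range under a spatially variable field
(×3 in the volume center, ×1 at the edges, so at most 27%).  Comparator
architectures (a VINN U-Net with 32→512 filter doubling and a 17-layer
multi-channel DnCNN) share the same slab interface.  All compute runs on a
small numpy reverse-mode autograd backend — no GPU or deep-learning
framework is required.

## Worked example

Train a small 8-filter network on four 48³ synthetic head phantoms and
denoise a held-out phantom contaminated with 5% stationary Rician noise:

```python
import numpy as np
from mridenoise import (NetworkConfig, build_fondue, conform, psnr, ssim,
                        default_head_spec, make_phantom, add_rician, SigmaField)
from mridenoise.training import TrainConfig, train
from mridenoise.phantom import training_phantoms
from mridenoise.inference import denoise_volume

volumes = training_phantoms(n=4, side=48, seed=0)
net = build_fondue(NetworkConfig(n_filt=8, seed=0))
config = TrainConfig(variant="LT", loss="mae", epochs=4, batch_size=2,
                     seed=0, slices_per_volume=6, max_steps=200)
result = train(net, volumes, config)
print(result.epoch_losses().to_string(float_format="%.5f"))

clean = conform(make_phantom(default_head_spec(shape=(48,)*3, seed=99)))
noisy = add_rician(clean, SigmaField.stationary(clean.shape, 0.05), seed=7)
denoised = denoise_volume(net, noisy)
mid = clean.side // 2
print(f"PSNR noisy    : {psnr(noisy.data, clean.data):.2f} dB")
print(f"PSNR denoised : {psnr(denoised.data, clean.data):.2f} dB")
print(f"SSIM noisy    : {ssim(noisy.data[:, :, mid], clean.data[:, :, mid]):.4f}")
print(f"SSIM denoised : {ssim(denoised.data[:, :, mid], clean.data[:, :, mid]):.4f}")
print("lambda weights:", np.round([float(l.data) for l in net.lambdas], 3))
```

Output (a few minutes on one CPU):

```
epoch
0   0.41372
1   0.04582
2   0.03869
3   0.03859
PSNR noisy    : 23.89 dB
PSNR denoised : 26.96 dB
SSIM noisy    : 0.7828
SSIM denoised : 0.7963
lambda weights: [1.023 1.036 1.036 1.021 0.978 1.009]
```

The training loss settles within a few epochs; the denoiser gains about
3 dB PSNR over the noisy input at this toy scale (larger networks and
longer runs gain more — the test suite trains a 16-filter network to a
≥ 3 dB gain at 64³), SSIM improves, and the six candidate weights λ_N stay
near their 1.0 initialization with all heads contributing.

The same pipeline is scriptable from the shell:

```
mridenoise phantom  --out phantom.nii.gz --shape 64 --seed 0
mridenoise simulate --in phantom.nii.gz --out noisy.nii.gz --sigma 0.09 --variable
mridenoise train    --out model.npz --n-filt 16 --epochs 8
mridenoise denoise  --in noisy.nii.gz --out denoised.nii.gz --weights model.npz
mridenoise metrics  --ref phantom.nii.gz --test denoised.nii.gz
```

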