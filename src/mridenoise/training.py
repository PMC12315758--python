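"""Training harness: one-cycle schedule, AdamW, variants, checkpointing.

Training follows the super-convergence recipe: a one-cycle learning-rate
policy (cosine ramp from max_lr/div_factor up to max_lr over the first
pct_start fraction of steps, cosine anneal down to the initial rate divided
by final_div_factor), AdamW with beta1 = 0.9 and beta2 = 0.99, momentum
cycling mapped onto beta1 (0.95 at the rate extremes, 0.85 at the peak),
and an optional mixed-precision mode.

Per sample the pipeline is: conform -> draw a base sigma from the noise
regime -> add Rician noise -> extract axial slabs -> flip/rotate/inSA
augmentation -> forward -> loss on the denoised middle slice vs its clean
counterpart -> backprop.  The candidate weights lambda_N train jointly with
the convolutions.  Refinement variants (B1/B2) first denoise each noisy
volume with a frozen first-stage network and train on its output.
Gradients are accumulated over the batch sample by sample, which lets the
inner-scale offset differ per sample as intended.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import nn
from .nn import autograd as ag
from .nn.autograd import Tensor
from .augment import AugmentConfig, augment_pair, sample_insa_offset
from .io import conform
from .metrics import FeatureExtractor, feature_loss_t, lpips_like_t
from .model import (Fondue, NetworkConfig, SlabBatch, denoise_slab,
                    load_checkpoint, save_checkpoint)
from .noise import REGIMES, NoiseRegime, add_rician, sample_training_sigma, \
    sigma_field_for
from .volume import ConformedVolume, Volume

__all__ = ["OneCycleSchedule", "TrainConfig", "TrainResult",
           "one_cycle_lr", "train", "VARIANT_DEFAULTS"]


@dataclass(frozen=True)
class OneCycleSchedule:
    max_lr: float = 0.01
    pct_start: float = 0.075
    div_factor: float = 10.0
    final_div_factor: float = 100.0

    @property
    def initial_lr(self) -> float:
        return self.max_lr / self.div_factor

    @property
    def final_lr(self) -> float:
        return self.initial_lr / self.final_div_factor


def one_cycle_lr(step: int, total_steps: int,
                 schedule: OneCycleSchedule = OneCycleSchedule()) -> float:
    """Learning rate at ``step`` of a cosine one-cycle policy."""
    if total_steps < 2:
        raise ValueError("total_steps must be >= 2")
    if not 0 <= step < total_steps:
        raise ValueError(f"step {step} outside [0, {total_steps})")
    n_up = schedule.pct_start * total_steps
    lo, hi, fin = schedule.initial_lr, schedule.max_lr, schedule.final_lr
    if step <= n_up and n_up > 0:
        t = step / n_up
        return lo + (hi - lo) * 0.5 * (1.0 - math.cos(math.pi * t))
    t = (step - n_up) / (total_steps - 1 - n_up)
    return fin + (hi - fin) * 0.5 * (1.0 + math.cos(math.pi * min(t, 1.0)))


def _cycled_beta1(step: int, total_steps: int, schedule: OneCycleSchedule,
                  b1_max: float = 0.95, b1_min: float = 0.85) -> float:
    """Momentum cycling: beta1 moves opposite to the learning rate."""
    lr = one_cycle_lr(step, total_steps, schedule)
    lo, hi = schedule.final_lr, schedule.max_lr
    frac = (lr - lo) / (hi - lo)
    return b1_max - (b1_max - b1_min) * frac


#: per-variant defaults: loss function, batch-norm, architecture extras
VARIANT_DEFAULTS: Dict[str, dict] = {
    "A": {"loss": "feature_loss_l1", "use_batchnorm": False},
    "B": {"loss": "lpips_like", "use_batchnorm": False},
    "LT": {"loss": "lpips_like", "use_batchnorm": False},
    "LT_PP": {"loss": "lpips_like", "use_batchnorm": False,
              "filter_doubling": True},
    "B1": {"loss": "lpips_like", "refinement": True, "regime": "refine_low",
           "fixed_lr": 1e-6},
    "B2": {"loss": "lpips_like", "refinement": True, "regime": "refine_high",
           "fixed_lr": 1e-6},
    "unet_vinn": {"loss": "lpips_like"},
    "mcdncnn": {"loss": "lpips_like"},
}


@dataclass
class TrainConfig:
    variant: str = "LT"
    loss: Optional[str] = None          # mae | mse | feature_loss_l1 | lpips_like
    epochs: int = 2
    batch_size: int = 2
    regime: str = "standard"
    schedule: OneCycleSchedule = field(default_factory=OneCycleSchedule)
    fixed_lr: Optional[float] = None    # overrides the one-cycle schedule
    betas: tuple = (0.9, 0.99)
    weight_decay: float = 1e-4
    mixed_precision: bool = False
    seed: int = 0
    slices_per_volume: Optional[int] = 8
    max_steps: Optional[int] = None
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    checkpoint_dir: Optional[str] = None
    first_stage: Optional[str] = None   # checkpoint path for B1/B2

    def __post_init__(self):
        if self.variant not in VARIANT_DEFAULTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        defaults = VARIANT_DEFAULTS[self.variant]
        if self.loss is None:
            self.loss = defaults["loss"]
        if defaults.get("refinement"):
            if self.first_stage is None:
                raise ValueError(
                    f"variant {self.variant} requires a first-stage checkpoint")
            self.regime = defaults["regime"]
            if self.fixed_lr is None:
                self.fixed_lr = defaults["fixed_lr"]
        if self.regime not in REGIMES:
            raise ValueError(f"unknown noise regime {self.regime!r}")


@dataclass
class TrainResult:
    network: nn.Module
    trace: pd.DataFrame
    checkpoint_path: Optional[str] = None

    def epoch_losses(self) -> pd.Series:
        return self.trace.groupby("epoch")["loss"].mean()


def _loss_factory(config: TrainConfig) -> Callable[[Tensor, np.ndarray], Tensor]:
    if config.loss == "mae":
        return lambda pred, tgt: ag.mean(ag.tabs(ag.sub(pred, Tensor(tgt))))
    if config.loss == "mse":
        return lambda pred, tgt: ag.mean(ag.square(ag.sub(pred, Tensor(tgt))))
    extractor = FeatureExtractor(seed=config.seed, n_filt=16)
    if config.loss == "feature_loss_l1":
        return lambda pred, tgt: feature_loss_t(pred, tgt[None, None], extractor)
    if config.loss == "lpips_like":
        return lambda pred, tgt: lpips_like_t(pred, tgt[None, None], extractor)
    raise ValueError(f"unknown loss {config.loss!r}")


def _sample_seed(seed: int, epoch: int, index: int) -> int:
    ss = np.random.SeedSequence([seed, epoch, index])
    return int(ss.generate_state(1)[0] % (2 ** 31 - 1))


def _axial_slab(data: np.ndarray, k: int, channels: int = 7) -> np.ndarray:
    half = channels // 2
    idx = np.clip(np.arange(k - half, k + half + 1), 0, data.shape[2] - 1)
    return np.ascontiguousarray(np.moveaxis(data[:, :, idx], 2, 0))


def train(model: nn.Module, data_source: Sequence[Volume],
          config: TrainConfig) -> TrainResult:
    """Train a denoising network on clean volumes with simulated noise."""
    regime = REGIMES[config.regime]
    loss_fn = _loss_factory(config)
    rng = np.random.default_rng(config.seed)
    stage1 = None
    if config.first_stage is not None:
        stage1, _ = load_checkpoint(config.first_stage)
        stage1.eval()

    volumes = [v if isinstance(v, ConformedVolume) else conform(v)
               for v in data_source]
    side = volumes[0].side
    spv = config.slices_per_volume or side
    steps_per_epoch = max(1, (len(volumes) * spv) // config.batch_size)
    total_steps = config.epochs * steps_per_epoch
    if config.max_steps is not None:
        total_steps = min(total_steps, config.max_steps)
    total_steps = max(total_steps, 2)  # the one-cycle policy needs >= 2

    opt = nn.AdamW(model.parameters(), lr=config.schedule.initial_lr,
                   betas=config.betas, weight_decay=config.weight_decay)
    trace_rows: List[dict] = []
    step = 0
    draw_index = 0
    checkpoint_path = None
    model.train()

    for epoch in range(config.epochs):
        if step >= total_steps:
            break
        samples: List[tuple] = []  # (noisy volume data, clean volume data, k)
        for vi, clean in enumerate(volumes):
            s = _sample_seed(config.seed, epoch, vi)
            base_sigma = sample_training_sigma(regime, s)
            fld = sigma_field_for(regime, clean.shape, base_sigma)
            noisy = add_rician(clean, fld, seed=s + 1)
            if stage1 is not None:
                from .inference import denoise_plane
                noisy = denoise_plane(stage1, noisy, "axial")
            ks = rng.choice(side, size=min(spv, side), replace=False)
            samples.extend((noisy.data, clean.data, int(k), base_sigma)
                           for k in ks)
        order = rng.permutation(len(samples))

        batch: List[tuple] = []
        for oi in order:
            batch.append(samples[oi])
            if len(batch) < config.batch_size:
                continue
            lr = (config.fixed_lr if config.fixed_lr is not None
                  else one_cycle_lr(step, total_steps, config.schedule))
            opt.lr = lr
            if config.fixed_lr is None:
                opt.betas = (_cycled_beta1(step, total_steps, config.schedule),
                             config.betas[1])
            opt.zero_grad()
            batch_loss = 0.0
            mean_sigma = float(np.mean([b[3] for b in batch]))
            for noisy_data, clean_data, k, _sig in batch:
                slab_np = _axial_slab(noisy_data, k)
                clean_slice = clean_data[:, :, k]
                slab_np, clean_slice = augment_pair(
                    slab_np, clean_slice, config.augment, draw_index)
                mu = sample_insa_offset(config.augment, draw_index)
                draw_index += 1
                slab = SlabBatch(slab_np[None], plane="axial",
                                 native_res=volumes[0].iso_voxel)
                with ag.autocast(config.mixed_precision):
                    pred = denoise_slab(model, slab, insa_offset=mu)
                    loss = ag.mul(loss_fn(pred, clean_slice),
                                  1.0 / len(batch))
                if not np.isfinite(loss.data):
                    raise RuntimeError(
                        f"non-finite loss at step {step} (epoch {epoch}, "
                        f"lr {lr:.3g}, sigma {_sig:.4f})")
                loss.backward()
                batch_loss += float(loss.data)
            opt.step()
            trace_rows.append({"step": step, "epoch": epoch, "lr": lr,
                               "sigma": mean_sigma, "loss": batch_loss})
            step += 1
            batch = []
            if step >= total_steps:
                break
        if config.checkpoint_dir:
            os.makedirs(config.checkpoint_dir, exist_ok=True)
            checkpoint_path = os.path.join(
                config.checkpoint_dir, f"epoch_{epoch:03d}.npz")
            save_checkpoint(checkpoint_path, model,
                            extra={"epoch": epoch, "step": step,
                                   "variant": config.variant})

    model.eval()
    trace = pd.DataFrame(trace_rows)
    return TrainResult(network=model, trace=trace,
                       checkpoint_path=checkpoint_path)
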