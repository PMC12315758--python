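"""Training-time augmentation: flips, small rotations, inner-scale offsets.

Geometric transforms are sampled once per training sample and applied
identically to the noisy input slab and its clean target, so input and
target stay voxel-aligned.  Inner-scale augmentation (inSA) perturbs the
latent VINN rescale factor F by a zero-mean Gaussian offset, exposing the
network to a continuum of effective voxel sizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy import ndimage

__all__ = ["AugmentConfig", "sample_insa_offset", "sample_geometry",
           "augment_pair"]


@dataclass(frozen=True)
class AugmentConfig:
    flip_prob: float = 0.5
    rot_max_deg: float = 5.0
    insa_std: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.flip_prob <= 1:
            raise ValueError("flip_prob must be in [0, 1]")
        if self.rot_max_deg < 0 or self.insa_std < 0:
            raise ValueError("rot_max_deg and insa_std must be >= 0")


def _rng(config: AugmentConfig, draw_index: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, int(draw_index), stream])


def sample_insa_offset(config: AugmentConfig, draw_index: int,
                       min_factor: float = 0.05) -> float:
    """Gaussian inSA offset (mean 0, sd ``insa_std``) for the scale factor.

    Draws that would push the rescale factor at or below ``min_factor`` are
    redrawn, so the latent rescale never degenerates.
    """
    if config.insa_std == 0:
        return 0.0
    rng = _rng(config, draw_index, 0)
    for _ in range(100):
        mu = float(rng.normal(0.0, config.insa_std))
        if 1.0 + mu > min_factor:
            return mu
    raise RuntimeError("inSA offset redraw limit exceeded")


def sample_geometry(config: AugmentConfig, draw_index: int) -> Tuple[bool, float]:
    """Draw (flip decision, rotation angle in degrees) for one sample."""
    rng = _rng(config, draw_index, 1)
    flip = bool(rng.random() < config.flip_prob)
    angle = float(rng.uniform(-config.rot_max_deg, config.rot_max_deg))
    return flip, angle


def _transform_slices(stack: np.ndarray, flip: bool, angle: float) -> np.ndarray:
    """Apply flip + in-plane rotation to a (C, H, W) stack."""
    out = stack
    if flip:
        out = out[:, :, ::-1]
    if angle != 0.0:
        out = ndimage.rotate(out, angle, axes=(1, 2), reshape=False,
                             order=1, mode="constant", cval=0.0)
    return np.ascontiguousarray(out, dtype=np.float32)


def augment_pair(noisy: np.ndarray, clean: np.ndarray, config: AugmentConfig,
                 draw_index: int) -> Tuple[np.ndarray, np.ndarray]:
    """Apply one identical geometric transform to input slab and target.

    ``noisy`` is a (C, H, W) slab, ``clean`` the matching (H, W) target
    slice.  Rotation is bilinear with zero (air) fill.
    """
    noisy = np.asarray(noisy, dtype=np.float32)
    clean = np.asarray(clean, dtype=np.float32)
    if noisy.shape[-2:] != clean.shape[-2:]:
        raise ValueError("noisy slab and clean slice disagree in shape")
    flip, angle = sample_geometry(config, draw_index)
    out_noisy = _transform_slices(noisy, flip, angle)
    out_clean = _transform_slices(clean[None], flip, angle)[0]
    return out_noisy, out_clean
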