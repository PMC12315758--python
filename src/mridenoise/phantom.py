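"""Synthetic multi-tissue head phantoms for tests and toy training.

A phantom is a nest of ellipsoids on a zero (air) background: an outer
scalp-like shell, a thin bright cortical shell whose high-frequency edges
make over-smoothing by a denoiser visible, a mid-intensity white-matter
core, and dark ventricle-like cavities.  Each tissue carries smooth
low-frequency texture, and an optional smooth multiplicative bias field
emulates coil inhomogeneity.  Everything is deterministic given the seed.

These phantoms emulate the geometry and intensity statistics needed to
exercise the pipeline; they are not an MR physics simulation (no k-space,
no point-spread function, no motion).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .io import conform
from .noise import NoiseRegime, add_rician, sample_training_sigma, sigma_field_for
from .volume import ConformedVolume, Volume

__all__ = ["Tissue", "PhantomSpec", "make_phantom", "make_pair",
           "default_head_spec", "fast_test_phantom", "training_phantoms",
           "anisotropic_phantom"]


@dataclass(frozen=True)
class Tissue:
    """One ellipsoid layer: semi-axes as fractions of the half-grid, and
    center offsets as fractions of the grid, plus intensity statistics."""

    semi_axes: Tuple[float, float, float]
    intensity: float
    texture: float = 0.0
    center: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if not 0.0 <= self.intensity <= 1.0:
            raise ValueError("tissue intensity must be in [0, 1]")
        if any(a <= 0 for a in self.semi_axes):
            raise ValueError("semi-axes must be positive")


@dataclass(frozen=True)
class PhantomSpec:
    shape: Tuple[int, int, int] = (64, 64, 64)
    voxel_size: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    tissues: Tuple[Tissue, ...] = ()
    bias_field: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if any(s < 8 for s in self.shape):
            raise ValueError("phantom grid must be at least 8 per axis")
        for t in self.tissues:
            for a, c in zip(t.semi_axes, t.center):
                if a + abs(c) > 1.0 + 1e-9:
                    raise ValueError(
                        f"ellipsoid (axes {t.semi_axes}, center {t.center}) "
                        "exceeds the grid")


def default_head_spec(shape=(64, 64, 64), voxel_size=(1.0, 1.0, 1.0),
                      seed: int = 0, bias_field: float = 0.05) -> PhantomSpec:
    """Nested head-like layering: scalp, bright cortex shell, WM, ventricles."""
    tissues = (
        Tissue((0.92, 0.88, 0.90), 0.35, texture=0.03),           # scalp/skull
        Tissue((0.80, 0.76, 0.78), 0.85, texture=0.04),           # cortex shell
        Tissue((0.70, 0.66, 0.68), 0.55, texture=0.04),           # white matter
        Tissue((0.22, 0.18, 0.26), 0.12, texture=0.02,
               center=(0.05, 0.0, 0.0)),                          # ventricles
    )
    return PhantomSpec(shape=tuple(shape), voxel_size=tuple(voxel_size),
                       tissues=tissues, bias_field=bias_field, seed=seed)


def _ellipsoid_mask(shape, tissue: Tissue) -> np.ndarray:
    grids = np.meshgrid(*[np.linspace(-1.0, 1.0, s) for s in shape],
                        indexing="ij")
    q = sum(((g - c) / a) ** 2
            for g, a, c in zip(grids, tissue.semi_axes, tissue.center))
    return q <= 1.0


def _smooth_noise(rng: np.random.Generator, shape, sigma_frac: float = 0.08):
    field = rng.standard_normal(shape)
    field = ndimage.gaussian_filter(field, [max(1.0, sigma_frac * s)
                                            for s in shape])
    field /= max(np.abs(field).max(), 1e-12)
    return field


def make_phantom(spec: PhantomSpec) -> Volume:
    """Render a phantom volume with intensities in [0, 1] (unit scale)."""
    rng = np.random.default_rng(spec.seed)
    data = np.zeros(spec.shape, dtype=np.float64)
    for tissue in spec.tissues:
        mask = _ellipsoid_mask(spec.shape, tissue)
        level = tissue.intensity
        if tissue.texture > 0:
            level = level + tissue.texture * _smooth_noise(rng, spec.shape)
        data = np.where(mask, level, data)
    if spec.bias_field > 0:
        bias = 1.0 + spec.bias_field * _smooth_noise(rng, spec.shape,
                                                     sigma_frac=0.25)
        data = data * bias
    data = np.clip(data, 0.0, 1.0).astype(np.float32)
    return Volume(data=data, voxel_size=spec.voxel_size,
                  orientation=("R", "A", "S"), intensity_scale="unit_0_1")


def tissue_fractions(spec: PhantomSpec) -> List[float]:
    """Voxel-count fraction of each tissue layer (outermost first)."""
    masks = [_ellipsoid_mask(spec.shape, t) for t in spec.tissues]
    n = float(np.prod(spec.shape))
    fracs = []
    for i, m in enumerate(masks):
        inner = np.zeros_like(m)
        for m2 in masks[i + 1:]:
            inner |= m2
        fracs.append(float((m & ~inner).sum()) / n)
    return fracs


def make_pair(spec: PhantomSpec, regime: NoiseRegime,
              seed: int) -> Tuple[ConformedVolume, ConformedVolume]:
    """A (noisy, clean) training pair in conformed space.

    The clean member is the conformed phantom (it stands in for a noise-free
    surrogate); the noisy member adds Rician noise with a base sigma drawn
    from the regime and the regime's field kind.
    """
    clean = conform(make_phantom(spec))
    base_sigma = sample_training_sigma(regime, seed)
    field = sigma_field_for(regime, clean.shape, base_sigma)
    noisy_vol = add_rician(clean, field, seed=seed + 1)
    noisy = ConformedVolume(data=noisy_vol.data, voxel_size=clean.voxel_size,
                            orientation=clean.orientation,
                            intensity_scale="unit_0_1", side=clean.side,
                            iso_voxel=clean.iso_voxel)
    return noisy, clean


# -- fixtures registry -----------------------------------------------------

def fast_test_phantom(seed: int = 0) -> Volume:
    """A 32^3 phantom for fast unit tests."""
    return make_phantom(default_head_spec(shape=(32, 32, 32), seed=seed))


def training_phantoms(n: int = 10, side: int = 64,
                      seed: int = 0) -> List[Volume]:
    """A small training set of 64^3 phantoms with varied seeds."""
    return [make_phantom(default_head_spec(shape=(side,) * 3, seed=seed + k))
            for k in range(n)]


def anisotropic_phantom(seed: int = 0) -> Volume:
    """A 96^3 phantom with 1.0 x 1.0 x 1.2 mm voxels for conform tests."""
    return make_phantom(default_head_spec(shape=(96, 96, 96),
                                          voxel_size=(1.0, 1.0, 1.2),
                                          seed=seed))
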