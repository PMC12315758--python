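"""Rician noise model and training-time noise regimes.

Magnitude MRI intensities are Rice distributed: each quadrature channel
carries zero-mean Gaussian noise of standard deviation ``sigma``, and the
magnitude M = sqrt((A + n1)^2 + n2^2) of a voxel with true intensity A then
follows

    p(M) = (M / sigma^2) exp(-(M^2 + A^2) / (2 sigma^2)) I0(A M / sigma^2),

Rayleigh in signal-free background (A = 0) and close to Gaussian for
A / sigma > 3.  Sigma is expressed as a fraction of the unit intensity range
of conformed volumes (so "9%" means sigma = 0.09).

Training uses three regimes: the standard one draws sigma uniformly in
[0, 9%] and applies a spatially variable field (x3 in the volume center, x1
at the outermost voxels, tricubic in between, so the ceiling is 27%); the
two refinement regimes draw stationary sigma in [0, 4%] and [4%, 9%].
Zero noise is deliberately inside the standard and low ranges: seeing clean
inputs during training is what teaches the network to leave clean images
alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy import ndimage, special

from .volume import Volume

__all__ = [
    "RiceParams", "SigmaField", "NoiseRegime", "REGIMES",
    "rice_pdf", "add_rician", "variable_sigma_field", "sample_training_sigma",
]


@dataclass(frozen=True)
class RiceParams:
    """Noise-free intensity A and per-channel Gaussian sigma."""
    A: float
    sigma: float

    def __post_init__(self):
        if self.A < 0 or self.sigma < 0:
            raise ValueError("RiceParams requires A >= 0 and sigma >= 0")


@dataclass
class SigmaField:
    """Per-voxel noise standard deviation, stationary or spatially variable."""
    data: np.ndarray
    base_sigma: float
    kind: str  # "stationary" | "variable"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.kind not in ("stationary", "variable"):
            raise ValueError(f"unknown sigma field kind {self.kind!r}")
        if (self.data < 0).any():
            raise ValueError("sigma field must be non-negative")

    @classmethod
    def stationary(cls, shape: Tuple[int, int, int], sigma: float) -> "SigmaField":
        return cls(np.full(shape, float(sigma), dtype=np.float32),
                   base_sigma=float(sigma), kind="stationary")


@dataclass(frozen=True)
class NoiseRegime:
    """A named sigma range plus the kind of sigma field it pairs with."""
    name: str
    sigma_low: float
    sigma_high: float
    field_kind: str

    def __post_init__(self):
        if not (0 <= self.sigma_low <= self.sigma_high <= 0.09):
            raise ValueError("regime sigma range must satisfy "
                             "0 <= low <= high <= 0.09")
        if self.field_kind not in ("stationary", "variable"):
            raise ValueError(f"unknown field kind {self.field_kind!r}")


REGIMES = {
    "standard": NoiseRegime("standard", 0.0, 0.09, "variable"),
    "refine_low": NoiseRegime("refine_low", 0.0, 0.04, "stationary"),
    "refine_high": NoiseRegime("refine_high", 0.04, 0.09, "stationary"),
}


def rice_pdf(M, params: RiceParams):
    """Rice probability density, stable for large A*M/sigma^2.

    Uses the exponentially scaled Bessel function, so the density is
    evaluated as (M/s^2) exp(-(M - A)^2 / (2 s^2)) i0e(A M / s^2).
    """
    if params.sigma <= 0:
        raise ValueError("rice_pdf requires sigma > 0 (degenerate otherwise)")
    M = np.asarray(M, dtype=np.float64)
    if (M < 0).any():
        raise ValueError("magnitude M must be non-negative")
    s2 = params.sigma ** 2
    z = params.A * M / s2
    return (M / s2) * np.exp(-((M - params.A) ** 2) / (2.0 * s2)) * special.i0e(z)


def add_rician(vol: Volume, field: SigmaField, seed: int) -> Volume:
    """Contaminate a unit-scale volume with Rician noise of the given field.

    Each voxel A becomes sqrt((A + n1)^2 + n2^2) with n1, n2 independent
    zero-mean Gaussians of the voxel's sigma.  Deterministic given ``seed``.
    """
    if vol.intensity_scale != "unit_0_1":
        raise ValueError("add_rician expects a unit_0_1 volume")
    if field.data.shape != vol.shape:
        raise ValueError(
            f"sigma field shape {field.data.shape} != volume shape {vol.shape}"
        )
    if float(field.data.max()) == 0.0:
        return vol.copy_with()
    rng = np.random.default_rng(seed)
    n1 = rng.standard_normal(vol.shape, dtype=np.float32) * field.data
    n2 = rng.standard_normal(vol.shape, dtype=np.float32) * field.data
    noisy = np.sqrt((vol.data + n1) ** 2 + n2 ** 2)
    # magnitude can exceed 1 on bright voxels; keep raw magnitudes but tag the
    # scale honestly so downstream validation is not violated
    noisy = np.clip(noisy, 0.0, 1.0).astype(np.float32)
    return vol.copy_with(data=noisy)


def variable_sigma_field(shape: Tuple[int, int, int],
                         base_sigma: float) -> SigmaField:
    """Spatially variable sigma: x3 at the volume center, x1 at the edges.

    A 3x3x3 multiplier control lattice (center 3, every boundary point 1) is
    expanded to the full grid with tricubic interpolation and clamped to
    [1, 3]; the field is ``base_sigma`` times that multiplier.  With the
    9% training ceiling the pointwise maximum is therefore 27%.
    """
    if base_sigma < 0:
        raise ValueError("base_sigma must be >= 0")
    shape = tuple(int(s) for s in shape)
    if any(s < 3 for s in shape):
        raise ValueError("variable field needs every dimension >= 3")
    control = np.ones((3, 3, 3), dtype=np.float64)
    control[1, 1, 1] = 3.0
    coords = np.meshgrid(
        *[np.linspace(0.0, 2.0, s) for s in shape], indexing="ij"
    )
    mult = ndimage.map_coordinates(control, np.stack(coords), order=3,
                                   mode="nearest")
    mult = np.clip(mult, 1.0, 3.0)
    return SigmaField(data=(base_sigma * mult).astype(np.float32),
                      base_sigma=float(base_sigma), kind="variable")


def sigma_field_for(regime: NoiseRegime, shape, base_sigma: float) -> SigmaField:
    """Build the sigma field matching a regime's field kind."""
    if regime.field_kind == "variable":
        return variable_sigma_field(shape, base_sigma)
    return SigmaField.stationary(shape, base_sigma)


def sample_training_sigma(regime: NoiseRegime, seed: int) -> float:
    """Uniform base-sigma draw on the regime's [low, high] range."""
    rng = np.random.default_rng(seed)
    return float(rng.uniform(regime.sigma_low, regime.sigma_high))
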