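"""In-memory representation of a structural MR volume.

A :class:`Volume` is the universal currency of the pipeline: a 3D floating
point intensity grid plus the minimal geometry (voxel sizes in mm, anatomical
axis codes) and an intensity-scale tag.  A :class:`ConformedVolume` is the
normalized form every downstream stage consumes: cubic, isotropic, RAS
oriented, intensities in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Tuple

import numpy as np

#: allowed intensity-scale tags
INTENSITY_SCALES = ("raw", "uint8_0_255", "unit_0_1")

_VALID_CODES = {"R", "L", "A", "P", "S", "I"}
_OPPOSITE = {"R": "L", "L": "R", "A": "P", "P": "A", "S": "I", "I": "S"}


def _validate_orientation(codes: Tuple[str, str, str]) -> None:
    codes = tuple(codes)
    if len(codes) != 3 or any(c not in _VALID_CODES for c in codes):
        raise ValueError(f"unrecognized orientation codes: {codes!r}")
    axes = {c if c in "RAS" else _OPPOSITE[c] for c in codes}
    if axes != {"R", "A", "S"}:
        raise ValueError(f"orientation codes do not span R/A/S axes: {codes!r}")


@dataclass
class Volume:
    """A 3D intensity grid with voxel geometry and intensity-scale metadata."""

    data: np.ndarray
    voxel_size: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    orientation: Tuple[str, str, str] = ("R", "A", "S")
    intensity_scale: str = "raw"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3D, got shape {self.data.shape}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel sizes must be positive: {self.voxel_size}")
        self.orientation = tuple(str(c).upper() for c in self.orientation)
        _validate_orientation(self.orientation)
        if self.intensity_scale not in INTENSITY_SCALES:
            raise ValueError(f"unknown intensity scale {self.intensity_scale!r}")
        if not np.isfinite(self.data).all():
            raise ValueError("volume data contains non-finite values")
        if self.intensity_scale == "unit_0_1":
            lo, hi = float(self.data.min()), float(self.data.max())
            if lo < -1e-6 or hi > 1 + 1e-6:
                raise ValueError(
                    f"unit_0_1 volume out of range: min={lo:.6g} max={hi:.6g}"
                )

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape

    def copy_with(self, **kwargs) -> "Volume":
        if "data" not in kwargs:
            kwargs["data"] = self.data.copy()
        return replace(self, **kwargs)


@dataclass
class ConformedVolume(Volume):
    """A conformed volume: cubic ``side**3`` grid, isotropic, RAS, unit scale."""

    side: int = 0
    iso_voxel: float = 1.0
    intensity_scale: str = "unit_0_1"

    def __post_init__(self) -> None:
        super().__post_init__()
        self.side = int(self.side) if self.side else self.data.shape[0]
        if self.data.shape != (self.side,) * 3:
            raise ValueError(
                f"conformed data must be cubic {self.side}^3, got {self.data.shape}"
            )
        iso = float(self.iso_voxel)
        if any(abs(v - iso) > 1e-6 for v in self.voxel_size):
            raise ValueError("conformed volume must have isotropic voxels")
        if self.orientation != ("R", "A", "S"):
            raise ValueError("conformed volume must be RAS oriented")
        if self.intensity_scale != "unit_0_1":
            raise ValueError("conformed volume must be on the unit [0,1] scale")
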