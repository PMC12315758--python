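"""Full-volume denoising with three-plane view aggregation.

A conformed volume is denoised once per anatomical plane: for every slice a
slab of the seven consecutive slices centred on it (edge slices replicate
the boundary slice) is passed through the network, and the denoised middle
slices are restacked into a volume.  The axial, coronal, and sagittal
volumes — produced with the same weights — are averaged voxelwise into the
final output, which suppresses plane-specific striping artifacts.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from typing import List, Optional

import numpy as np

from . import nn
from .io import conform, unconform
from .model import PLANES, SlabBatch, denoise_slab
from .volume import ConformedVolume, Volume

__all__ = ["PlaneStack", "extract_slabs", "denoise_plane", "view_aggregate",
           "denoise_volume"]

log = logging.getLogger("mridenoise")

#: normal axis of each plane in RAS voxel order (sagittal, coronal, axial)
_PLANE_AXIS = {"sagittal": 0, "coronal": 1, "axial": 2}


@dataclass
class PlaneStack:
    """All slabs of one anatomical plane, one per slice along its normal."""

    plane: str
    slabs: List[SlabBatch]

    def __post_init__(self):
        if self.plane not in PLANES:
            raise ValueError(f"unknown plane {self.plane!r}")


def extract_slabs(vol: ConformedVolume, plane: str,
                  channels: int = 7) -> PlaneStack:
    """Slabs of ``channels`` consecutive slices, one per slice of the plane."""
    if plane not in _PLANE_AXIS:
        raise ValueError(f"unknown plane {plane!r}")
    if vol.side < channels:
        raise ValueError(f"volume side {vol.side} smaller than slab depth")
    axis = _PLANE_AXIS[plane]
    stack = np.moveaxis(vol.data, axis, 0)  # slices first
    half = channels // 2
    slabs = []
    n = stack.shape[0]
    for k in range(n):
        idx = np.clip(np.arange(k - half, k + half + 1), 0, n - 1)
        slabs.append(SlabBatch(np.ascontiguousarray(stack[idx])[None],
                               plane=plane, native_res=vol.iso_voxel))
    return PlaneStack(plane=plane, slabs=slabs)


def denoise_plane(network: nn.Module, vol: ConformedVolume, plane: str,
                  batch_size: int = 8) -> ConformedVolume:
    """Denoise every slice of one plane and restack into a volume."""
    stack = extract_slabs(vol, plane, channels=network.config.input_channels)
    axis = _PLANE_AXIS[plane]
    data = np.stack([s.data[0] for s in stack.slabs])  # (n, C, H, W)
    outs = []
    for lo in range(0, data.shape[0], batch_size):
        batch = SlabBatch(data[lo:lo + batch_size], plane=plane,
                          native_res=vol.iso_voxel)
        pred = denoise_slab(network, batch)
        outs.append(pred.data[:, 0])
    denoised = np.concatenate(outs, axis=0)
    denoised = np.moveaxis(denoised, 0, axis)
    return ConformedVolume(data=np.clip(denoised, 0.0, 1.0),
                           voxel_size=vol.voxel_size,
                           orientation=vol.orientation,
                           intensity_scale="unit_0_1", side=vol.side,
                           iso_voxel=vol.iso_voxel)


def view_aggregate(vol_ax: Volume, vol_cor: Volume,
                   vol_sag: Volume) -> Volume:
    """Voxelwise mean of the three per-plane denoised volumes."""
    vols = (vol_ax, vol_cor, vol_sag)
    shapes = {v.shape for v in vols}
    if len(shapes) != 1:
        raise ValueError(f"view volumes disagree in shape: {shapes}")
    data = (vol_ax.data.astype(np.float64) + vol_cor.data + vol_sag.data) / 3.0
    return vol_ax.copy_with(data=data.astype(np.float32))


def denoise_volume(network: nn.Module, vol: Volume,
                   to_native: bool = False) -> Volume:
    """Conform, denoise along all three planes, and average the results.

    The same network weights are used for every plane.  The output stays in
    conformed space unless ``to_native`` asks for resampling back onto the
    input grid.
    """
    network.eval()
    conformed = vol if isinstance(vol, ConformedVolume) else conform(vol)
    per_plane = {}
    for plane in PLANES:
        t0 = time.perf_counter()
        per_plane[plane] = denoise_plane(network, conformed, plane)
        log.info("denoised %s plane in %.2fs", plane, time.perf_counter() - t0)
    out = view_aggregate(per_plane["axial"], per_plane["coronal"],
                         per_plane["sagittal"])
    out = ConformedVolume(data=np.clip(out.data, 0.0, 1.0),
                          voxel_size=conformed.voxel_size,
                          orientation=conformed.orientation,
                          intensity_scale="unit_0_1", side=conformed.side,
                          iso_voxel=conformed.iso_voxel)
    if to_native:
        return unconform(out, vol)
    return out
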