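"""Reading, writing, and conforming of NIfTI / MGH volumes.

"Conforming" is the standard normalization applied before denoising: reorient
to RAS, resample to a cubic grid with isotropic voxels of size
``min(v1, v2, v3)`` and edge length ``max(H, W, D)``, and rescale intensities
to the unit range through a clipped-histogram 8-bit mapping.  No bias-field
correction is performed.
"""

from __future__ import annotations

import os
from typing import Tuple

import nibabel as nib
import numpy as np
from scipy import ndimage

from .volume import ConformedVolume, Volume

_NIFTI_EXT = (".nii", ".nii.gz")
_MGH_EXT = (".mgz", ".mgh")

HIST_BINS = 1000
#: fraction of the most intense voxels cropped by the histogram rescaling
CROP_FRACTION = 1.0 / 1000.0


def _split_ext(path: str) -> str:
    lower = str(path).lower()
    if lower.endswith(".nii.gz"):
        return ".nii.gz"
    return os.path.splitext(lower)[1]


def read_volume(path: str) -> Volume:
    """Read a NIfTI (.nii/.nii.gz) or MGH (.mgz/.mgh) file into a Volume.

    Header voxel sizes and axis orientation are preserved untouched; the data
    are cast to float32.
    """
    ext = _split_ext(path)
    if ext not in _NIFTI_EXT + _MGH_EXT:
        raise ValueError(f"unsupported volume format {ext!r} for {path}")
    if not os.path.exists(path):
        raise IOError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj).astype(np.float32)
    except Exception as exc:  # nibabel raises a zoo of error types
        raise IOError(f"could not read volume {path}: {exc}") from exc
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise IOError(f"{path}: expected a 3D volume, got shape {data.shape}")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    codes = tuple(nib.orientations.aff2axcodes(img.affine))
    return Volume(data=data, voxel_size=zooms, orientation=codes,
                  intensity_scale="raw")


def write_volume(vol: Volume, path: str) -> None:
    """Write a Volume to NIfTI or MGH (chosen by file extension)."""
    ext = _split_ext(path)
    if ext not in _NIFTI_EXT + _MGH_EXT:
        raise ValueError(f"unsupported volume format {ext!r} for {path}")
    parent = os.path.dirname(os.path.abspath(path))
    if not os.path.isdir(parent):
        raise IOError(f"parent directory does not exist: {parent}")
    affine = _affine_from_geometry(vol.orientation, vol.voxel_size, vol.shape)
    data = np.asarray(vol.data, dtype=np.float32)
    try:
        if ext in _MGH_EXT:
            img = nib.MGHImage(data, affine)
        else:
            img = nib.Nifti1Image(data, affine)
            img.header.set_zooms(vol.voxel_size)
        nib.save(img, str(path))
    except Exception as exc:
        raise IOError(f"could not write volume {path}: {exc}") from exc


def _affine_from_geometry(orientation, voxel_size, shape) -> np.ndarray:
    ornt = nib.orientations.axcodes2ornt(tuple(orientation))
    # affine that maps this array, with these zooms, into RAS world space
    ras_aff = np.diag(list(voxel_size) + [1.0])
    reorder = nib.orientations.inv_ornt_aff(
        nib.orientations.ornt_transform(
            ornt, nib.orientations.axcodes2ornt(("R", "A", "S"))
        ),
        shape,
    )
    return ras_aff @ reorder


def to_ras(vol: Volume) -> Volume:
    """Permute/flip axes so the volume is in RAS orientation.

    Voxel sizes are permuted consistently; intensities are untouched.
    """
    ornt = nib.orientations.axcodes2ornt(vol.orientation)
    target = nib.orientations.axcodes2ornt(("R", "A", "S"))
    transform = nib.orientations.ornt_transform(ornt, target)
    data = nib.orientations.apply_orientation(vol.data, transform)
    # transform[a, 0] is the output position of input axis a
    perm = transform[:, 0].astype(int)
    voxel = tuple(vol.voxel_size[int(np.where(perm == k)[0][0])]
                  for k in range(3))
    return Volume(data=np.ascontiguousarray(data), voxel_size=voxel,
                  orientation=("R", "A", "S"),
                  intensity_scale=vol.intensity_scale)


def rescale_intensity(vol: Volume) -> Volume:
    """Clipped-histogram rescale to the unsigned 8-bit [0, 255] range.

    A 1000-bin histogram of the intensities is built; the clipping ceiling is
    the smallest bin edge above which at most one thousandth of the voxels
    lie.  Values above the ceiling are clipped, and [min, ceiling] is mapped
    linearly onto [0, 255].  A constant-valued input maps to all zeros.
    """
    data = np.asarray(vol.data, dtype=np.float64)
    lo = float(data.min())
    hi = float(data.max())
    if hi <= lo:  # constant image: degenerate, documented as all-zero
        out = np.zeros_like(data, dtype=np.float32)
        return vol.copy_with(data=out, intensity_scale="uint8_0_255")
    n = data.size
    budget = CROP_FRACTION * n
    # The bin-edge ceiling is refined by rebuilding the histogram over the
    # clipped range until it stabilizes; a single pass cannot resolve the
    # bulk when one extreme outlier stretches the range.
    ceiling = hi
    for _ in range(8):
        counts, edges = np.histogram(data, bins=HIST_BINS,
                                     range=(lo, ceiling))
        n_out = int((data > ceiling).sum())
        above = n_out + (n - n_out) - np.cumsum(counts)
        ok = above <= budget
        if not ok.any():
            break
        new_ceiling = float(edges[1:][np.argmax(ok)])
        if new_ceiling >= ceiling - 1e-12 or new_ceiling <= lo:
            break
        ceiling = new_ceiling
    if ceiling <= lo:
        ceiling = hi
    out = np.clip(data, lo, ceiling)
    out = (out - lo) * (255.0 / (ceiling - lo))
    return vol.copy_with(data=out.astype(np.float32),
                         intensity_scale="uint8_0_255")


def _resample_axis_coords(n_out: int, scale: float) -> np.ndarray:
    """Half-pixel-center source coordinates (no corner alignment)."""
    return (np.arange(n_out, dtype=np.float64) + 0.5) * scale - 0.5


def conform(vol: Volume, internal_interp: str = "linear") -> ConformedVolume:
    """Conform a volume: RAS, cubic max-dim grid, isotropic min-voxel, [0,1].

    Interpolation is per-axis linear with the half-pixel-center convention
    (no corner alignment); the per-axis scale factor is the ratio of output
    to input voxel size and is not recomputed from the grid sizes.  Volumes
    already tagged ``unit_0_1`` skip the histogram rescale (the linear cast
    to [0, 1] is then the identity), which makes conforming idempotent.
    """
    if internal_interp not in ("linear", "nearest"):
        raise ValueError(f"unsupported interpolation mode {internal_interp!r}")
    if min(vol.shape) < 2:
        raise ValueError(f"degenerate volume shape {vol.shape}")
    vol = to_ras(vol)
    iso = float(min(vol.voxel_size))
    side = int(max(vol.shape))
    order = 1 if internal_interp == "linear" else 0

    scales = [iso / v for v in vol.voxel_size]
    if vol.shape == (side,) * 3 and all(abs(s - 1.0) < 1e-12 for s in scales):
        data = vol.data.astype(np.float32)
    else:
        coords = np.meshgrid(
            *[_resample_axis_coords(side, s) for s in scales], indexing="ij"
        )
        data = ndimage.map_coordinates(
            vol.data.astype(np.float32), np.stack(coords), order=order,
            mode="constant", cval=0.0,
        )
    out = Volume(data=data, voxel_size=(iso,) * 3, orientation=("R", "A", "S"),
                 intensity_scale=vol.intensity_scale)
    if out.intensity_scale != "unit_0_1":
        if out.intensity_scale != "uint8_0_255":
            out = rescale_intensity(out)
        data = np.clip(out.data / 255.0, 0.0, 1.0).astype(np.float32)
    else:
        data = np.clip(out.data, 0.0, 1.0).astype(np.float32)
    return ConformedVolume(data=data, voxel_size=(iso,) * 3,
                           orientation=("R", "A", "S"),
                           intensity_scale="unit_0_1", side=side,
                           iso_voxel=iso)


def unconform(vol: ConformedVolume, target: Volume) -> Volume:
    """Resample a conformed volume back onto ``target``'s native grid.

    Optional inverse of :func:`conform` (off by default in the pipeline);
    intensities remain on the unit scale.
    """
    ras_target = to_ras(target)
    scales = [v / vol.iso_voxel for v in ras_target.voxel_size]
    coords = np.meshgrid(
        *[_resample_axis_coords(n, s)
          for n, s in zip(ras_target.shape, scales)], indexing="ij",
    )
    data = ndimage.map_coordinates(vol.data, np.stack(coords), order=1,
                                   mode="constant", cval=0.0)
    out = Volume(data=np.clip(data, 0, 1).astype(np.float32),
                 voxel_size=ras_target.voxel_size,
                 orientation=("R", "A", "S"), intensity_scale="unit_0_1")
    return out
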