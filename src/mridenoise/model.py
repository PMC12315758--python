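"""Denoising network architectures.

The main network is a nested (UNet++-style) encoder-decoder operating on
2.5D slabs of seven consecutive slices.  Its building blocks:

* **CBU** (convolutional block unit): two 3x3 convolutions whose outputs
  compete through an elementwise maxout, followed by a third 3x3 convolution;
  PReLU after every convolution, optional batch normalization, padding 1 so
  spatial shape is preserved.  The output variant appends a 1x1 convolution
  collapsing the features to a single channel.
* **Maxout** feature competition instead of channel concatenation, which
  keeps the filter count constant throughout the network.
* **VINN resolution normalization**: feature maps are rescaled bilinearly by
  F = R_o / R_i between the native voxel size R_o and the fixed internal
  resolution R_i (1.0 mm by default), making the network voxel-size
  invariant.  During training the factor can be perturbed by an inner-scale
  augmentation offset.
* Seven resolution rows: row 0 at native resolution, row 1 at the internal
  resolution, rows 2-6 reached by 2x2 max-pooling with argmax indices that
  the matching unpooling stages reuse.
* Six output heads Y_1..Y_6 on row 0, one per nested column, each a
  candidate residual-noise map; the final residual is their lambda-weighted
  average (trainable scalars, initialized at 1) and is subtracted from the
  noisy middle slice.

Two comparator architectures with the same slab interface are provided: a
plain VINN U-Net with filter doubling (32 -> 512 over five levels including
the bottleneck) and a 17-layer DnCNN-style multi-channel residual network.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import nn
from .nn import autograd as ag
from .nn.autograd import Tensor

PLANES = ("axial", "coronal", "sagittal")

__all__ = [
    "NetworkConfig", "SlabBatch", "CandidateSet",
    "maxout", "vinn_rescale", "CBU",
    "Fondue", "UNetVINN", "MCDnCNN",
    "build_fondue", "build_unet_vinn", "build_mcdncnn",
    "combine_candidates", "denoise_slab",
    "save_checkpoint", "load_checkpoint",
]


@dataclass
class NetworkConfig:
    """Architecture hyperparameters."""

    n_filt: int = 64
    rows: int = 7
    candidates: int = 6
    internal_res: float = 1.0
    use_batchnorm: bool = False
    input_channels: int = 7
    filter_doubling: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_filt < 1:
            raise ValueError("n_filt must be >= 1")
        if self.input_channels % 2 == 0:
            raise ValueError("input_channels must be odd (middle slice)")
        if self.rows == 7 and self.candidates != self.rows - 1:
            raise ValueError("with 7 rows the network has rows - 1 = 6 heads")
        if self.internal_res <= 0:
            raise ValueError("internal resolution must be positive")


@dataclass
class SlabBatch:
    """A BS x C x H x W stack of 2.5D slabs from one anatomical plane."""

    data: np.ndarray
    plane: str = "axial"
    native_res: float = 1.0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 4:
            raise ValueError(f"slab batch must be 4D, got {self.data.shape}")
        if self.plane not in PLANES:
            raise ValueError(f"unknown plane {self.plane!r}")
        if self.data.shape[2] < 16 or self.data.shape[3] < 16:
            raise ValueError("slab spatial dims must be >= 16")
        if self.native_res <= 0:
            raise ValueError("native resolution must be positive")

    @property
    def middle(self) -> np.ndarray:
        c = self.data.shape[1] // 2
        return self.data[:, c:c + 1]


@dataclass
class CandidateSet:
    """The candidate residual maps Y_N with their weights lambda_N."""

    ys: List[Tensor]
    lambdas: List[Tensor]

    def __post_init__(self):
        shapes = {tuple(y.data.shape) for y in self.ys}
        if len(shapes) != 1:
            raise ValueError(f"candidate maps disagree in shape: {shapes}")
        if len(self.ys) != len(self.lambdas):
            raise ValueError("need one lambda per candidate")

    @property
    def lambda_values(self) -> np.ndarray:
        return np.array([float(l.data) for l in self.lambdas])


def maxout(a, b) -> Tensor:
    """Elementwise maximum of two equally shaped feature stacks."""
    return ag.maximum(ag.as_tensor(a), ag.as_tensor(b))


def vinn_rescale(features, r_out: float, r_in: float, direction: str,
                 target_hw: Optional[Tuple[int, int]] = None,
                 offset: float = 0.0) -> Tensor:
    """Bilinear latent rescaling by F = R_o / R_i (+ optional inSA offset).

    ``to_internal`` scales spatial dims by F; ``to_native`` by 1/F and, when
    ``target_hw`` is given, restores exactly that shape (the inverse of a
    preceding ``to_internal``).
    """
    x = ag.as_tensor(features)
    if r_out <= 0 or r_in <= 0:
        raise ValueError("resolutions must be positive")
    F = r_out / r_in + offset
    if F <= 0:
        raise ValueError(f"non-positive rescale factor {F}")
    H, W = x.data.shape[2], x.data.shape[3]
    if direction == "to_internal":
        out_hw = (int(np.floor(H * F)), int(np.floor(W * F)))
        scale = (F, F)
    elif direction == "to_native":
        out_hw = target_hw if target_hw is not None else (
            int(round(H / F)), int(round(W / F)))
        scale = (1.0 / F, 1.0 / F)
    else:
        raise ValueError(f"unknown direction {direction!r}")
    if min(out_hw) < 4:
        raise ValueError(f"rescaled feature map too small: {out_hw}")
    return ag.bilinear_resize(x, out_hw, scale=scale)


class CBU(nn.Module):
    """Convolutional block unit (input / standard / output kinds)."""

    def __init__(self, in_ch: int, n_filt: int, kind: str,
                 use_batchnorm: bool, rng: np.random.Generator):
        super().__init__()
        if kind not in ("input", "standard", "output"):
            raise ValueError(f"unknown CBU kind {kind!r}")
        self.kind = kind
        self.conv1 = nn.Conv2d(in_ch, n_filt, 3, rng)
        self.conv2 = nn.Conv2d(n_filt, n_filt, 3, rng)
        self.conv3 = nn.Conv2d(n_filt, n_filt, 3, rng)
        self.act1, self.act2, self.act3 = (nn.PReLU(n_filt) for _ in range(3))
        if use_batchnorm:
            self.bn1, self.bn2, self.bn3 = (nn.BatchNorm2d(n_filt)
                                            for _ in range(3))
        else:
            self.bn1 = self.bn2 = self.bn3 = nn.Identity()
        if kind == "output":
            self.collapse = nn.Conv2d(n_filt, 1, 1, rng, padding=0)

    def features(self, x: Tensor) -> Tensor:
        h1 = self.act1(self.bn1(self.conv1(x)))
        h2 = self.act2(self.bn2(self.conv2(h1)))
        m = maxout(h1, h2)
        return self.act3(self.bn3(self.conv3(m)))

    def forward(self, x: Tensor) -> Tensor:
        out = self.features(x)
        if self.kind == "output":
            return self.collapse(out)
        return out


def _pad_to_multiple(x: Tensor, multiple: int) -> Tuple[Tensor, Tuple[int, int]]:
    H, W = x.data.shape[2], x.data.shape[3]
    ph = (-H) % multiple
    pw = (-W) % multiple
    return ag.pad2d(x, (ph, pw)), (H, W)


def _repeat_idx(idx: np.ndarray, channels: int) -> np.ndarray:
    if idx.shape[1] == channels:
        return idx
    if channels % idx.shape[1]:
        raise ValueError("cannot tile unpool indices to channel count")
    return np.repeat(idx, channels // idx.shape[1], axis=1)


class Fondue(nn.Module):
    """Nested competitive encoder-decoder with six candidate noise heads."""

    arch = "fondue"

    def __init__(self, config: NetworkConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        f = config.n_filt
        rows = config.rows
        bn = config.use_batchnorm
        # filters per row: constant, or doubling below the internal row
        if config.filter_doubling:
            self.row_filt = [f, f] + [f * 2 ** (i - 1) for i in range(2, rows)]
        else:
            self.row_filt = [f] * rows
        self.cbu_in = CBU(config.input_channels, f, "input", bn, rng)
        self.cbu_1_0 = CBU(f, self.row_filt[1], "standard", bn, rng)
        for i in range(2, rows):  # encoder spine
            self.add_module(
                f"cbu_{i}_0",
                CBU(self.row_filt[i - 1], self.row_filt[i], "standard", bn, rng))
        for i in range(1, rows - 1):  # nested blocks, i = 1..5, j = 1..6-i
            for j in range(1, rows - i):
                fi = self.row_filt[i]
                in_ch = fi if not config.filter_doubling else \
                    self.row_filt[i + 1] + fi
                self.add_module(f"cbu_{i}_{j}",
                                CBU(in_ch, fi, "standard", bn, rng))
        for j in range(1, rows):  # row-0 output columns
            self.add_module(f"cbu_0_{j}", CBU(f, f, "output", bn, rng))
        for n in range(1, config.candidates + 1):
            setattr(self, f"lam_{n}",
                    Tensor(np.float32(1.0), requires_grad=True))

    @property
    def lambdas(self) -> List[Tensor]:
        return [getattr(self, f"lam_{n}")
                for n in range(1, self.config.candidates + 1)]

    def forward(self, slab: SlabBatch, insa_offset: float = 0.0) -> CandidateSet:
        cfg = self.config
        rows = cfg.rows
        x = Tensor(slab.data)
        if x.data.shape[1] != cfg.input_channels:
            raise ValueError(
                f"expected {cfg.input_channels} input channels, "
                f"got {x.data.shape[1]}")
        H, W = x.data.shape[2], x.data.shape[3]
        r_out, r_in = slab.native_res, cfg.internal_res

        x00 = self.cbu_in(x)
        down = vinn_rescale(x00, r_out, r_in, "to_internal", offset=insa_offset)
        down, (Hi, Wi) = _pad_to_multiple(down, 2 ** (rows - 2))

        # encoder spine with index passing
        col0: Dict[int, Tensor] = {1: self.cbu_1_0(down)}
        pool_idx: Dict[int, np.ndarray] = {}
        for i in range(2, rows):
            pooled, idx = ag.maxpool2d(col0[i - 1])
            pool_idx[i] = idx
            col0[i] = getattr(self, f"cbu_{i}_0")(pooled)

        # nested grid: X[i][j]
        grid: Dict[int, Dict[int, Tensor]] = {i: {0: col0[i]}
                                              for i in range(1, rows)}
        for j in range(1, rows - 1):
            for i in range(1, rows - j):
                below = grid[i + 1][j - 1]
                idx = _repeat_idx(pool_idx[i + 1], below.data.shape[1])
                up = ag.maxunpool2d(below, idx)
                same_row = [grid[i][k] for k in range(j)]
                if cfg.filter_doubling and \
                        up.data.shape[1] != same_row[0].data.shape[1]:
                    fused = ag.concat([up, ag.maxout(same_row)], axis=1)
                else:
                    fused = ag.maxout([up] + same_row)
                grid[i][j] = getattr(self, f"cbu_{i}_{j}")(fused)

        # row 0: native-resolution columns and candidate heads
        row0_feats: List[Tensor] = [x00]
        ys: List[Tensor] = []
        for j in range(1, rows):
            below = ag.crop2d(grid[1][j - 1], (Hi, Wi))
            up = vinn_rescale(below, r_out, r_in, "to_native",
                              target_hw=(H, W), offset=insa_offset)
            fused = ag.maxout([up] + row0_feats)
            head: CBU = getattr(self, f"cbu_0_{j}")
            feats = head.features(fused)
            row0_feats.append(feats)
            ys.append(head.collapse(feats))
        return CandidateSet(ys=ys, lambdas=self.lambdas)

    def residual(self, slab: SlabBatch, insa_offset: float = 0.0) -> Tensor:
        return combine_candidates(self.forward(slab, insa_offset=insa_offset))


def combine_candidates(cands: CandidateSet) -> Tensor:
    """Lambda-weighted average of the candidate residual maps."""
    lam_sum = cands.lambdas[0]
    for lam in cands.lambdas[1:]:
        lam_sum = ag.add(lam_sum, lam)
    if abs(float(lam_sum.data)) < 1e-8:
        raise FloatingPointError("sum of candidate weights is numerically zero")
    acc = ag.mul(cands.ys[0], cands.lambdas[0])
    for y, lam in zip(cands.ys[1:], cands.lambdas[1:]):
        acc = ag.add(acc, ag.mul(y, lam))
    return ag.div(acc, lam_sum)


def denoise_slab(network: nn.Module, slab: SlabBatch,
                 insa_offset: float = 0.0) -> Tensor:
    """Denoised middle slice: input middle minus the predicted residual."""
    residual = network.residual(slab, insa_offset=insa_offset)
    middle = Tensor(slab.middle)
    return ag.sub(middle, residual)


class MCDnCNN(nn.Module):
    """17-layer multi-channel DnCNN: uniform 64-filter 3x3 convolutions."""

    arch = "mcdncnn"
    N_LAYERS = 17

    def __init__(self, config: NetworkConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        f = config.n_filt
        self.conv_in = nn.Conv2d(config.input_channels, f, 3, rng)
        for k in range(self.N_LAYERS - 2):
            self.add_module(f"conv_{k}", nn.Conv2d(f, f, 3, rng))
            self.add_module(f"bn_{k}", nn.BatchNorm2d(f))
        self.conv_out = nn.Conv2d(f, 1, 3, rng)

    def n_conv_layers(self) -> int:
        return self.N_LAYERS

    def residual(self, slab: SlabBatch, insa_offset: float = 0.0) -> Tensor:
        x = ag.relu(self.conv_in(Tensor(slab.data)))
        for k in range(self.N_LAYERS - 2):
            x = ag.relu(getattr(self, f"bn_{k}")(getattr(self, f"conv_{k}")(x)))
        return self.conv_out(x)

    forward = residual


class UNetVINN(nn.Module):
    """Plain VINN U-Net comparator: filter doubling 32 -> 512, five levels."""

    arch = "unet_vinn"
    LEVELS = 5

    def __init__(self, config: NetworkConfig, base_filters: int = 32):
        super().__init__()
        self.config = config
        self.base_filters = base_filters
        rng = np.random.default_rng(config.seed)
        bn = config.use_batchnorm
        filt = [base_filters * 2 ** k for k in range(self.LEVELS)]
        self.filters = filt
        self.cbu_in = CBU(config.input_channels, filt[0], "input", bn, rng)
        self.enc_0 = CBU(filt[0], filt[0], "standard", bn, rng)
        for k in range(1, self.LEVELS):
            self.add_module(f"enc_{k}", CBU(filt[k - 1], filt[k],
                                            "standard", bn, rng))
        for k in range(self.LEVELS - 2, -1, -1):
            self.add_module(f"dec_{k}", CBU(filt[k + 1] + filt[k], filt[k],
                                            "standard", bn, rng))
        self.out_block = CBU(2 * filt[0], filt[0], "output", bn, rng)

    @property
    def bottleneck_filters(self) -> int:
        return self.filters[-1]

    def residual(self, slab: SlabBatch, insa_offset: float = 0.0) -> Tensor:
        cfg = self.config
        x = Tensor(slab.data)
        H, W = x.data.shape[2], x.data.shape[3]
        x_native = self.cbu_in(x)
        down = vinn_rescale(x_native, slab.native_res, cfg.internal_res,
                            "to_internal", offset=insa_offset)
        down, (Hi, Wi) = _pad_to_multiple(down, 2 ** (self.LEVELS - 1))
        skips = []
        h = self.enc_0(down)
        idxs = []
        for k in range(1, self.LEVELS):
            skips.append(h)
            pooled, idx = ag.maxpool2d(h)
            idxs.append(idx)
            h = getattr(self, f"enc_{k}")(pooled)
        for k in range(self.LEVELS - 2, -1, -1):
            idx = _repeat_idx(idxs[k], h.data.shape[1])
            up = ag.maxunpool2d(h, idx)
            h = getattr(self, f"dec_{k}")(ag.concat([up, skips[k]], axis=1))
        h = ag.crop2d(h, (Hi, Wi))
        up = vinn_rescale(h, slab.native_res, cfg.internal_res, "to_native",
                          target_hw=(H, W), offset=insa_offset)
        return self.out_block(ag.concat([up, x_native], axis=1))

    forward = residual


def build_fondue(config: NetworkConfig) -> Fondue:
    return Fondue(config)


def build_mcdncnn(config: Optional[NetworkConfig] = None) -> MCDnCNN:
    if config is None:
        config = NetworkConfig()
    return MCDnCNN(config)


def build_unet_vinn(config: Optional[NetworkConfig] = None,
                    base_filters: int = 32) -> UNetVINN:
    if config is None:
        config = NetworkConfig()
    return UNetVINN(config, base_filters=base_filters)


_ARCHS = {"fondue": build_fondue, "mcdncnn": build_mcdncnn,
          "unet_vinn": build_unet_vinn}

CHECKPOINT_VERSION = 1


def save_checkpoint(path: str, network: nn.Module,
                    extra: Optional[dict] = None) -> None:
    """Serialize config + parameters (+ lambda weights) to a single file."""
    meta = {
        "version": CHECKPOINT_VERSION,
        "arch": network.arch,
        "config": asdict(network.config),
        "extra": extra or {},
    }
    if isinstance(network, UNetVINN):
        meta["base_filters"] = network.base_filters
    state = network.state_dict()
    with open(path, "wb") as fh:
        np.savez(fh, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **state)


def load_checkpoint(path: str) -> Tuple[nn.Module, dict]:
    with np.load(path) as blob:
        meta = json.loads(bytes(blob["__meta__"].tobytes()).decode())
        state = {k: blob[k] for k in blob.files if k != "__meta__"}
    if meta.get("version") != CHECKPOINT_VERSION:
        raise ValueError(f"unsupported checkpoint version {meta.get('version')}")
    config = NetworkConfig(**meta["config"])
    if meta["arch"] == "unet_vinn":
        net = build_unet_vinn(config, base_filters=meta.get("base_filters", 32))
    else:
        net = _ARCHS[meta["arch"]](config)
    net.load_state_dict(state)
    return net, meta.get("extra", {})
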