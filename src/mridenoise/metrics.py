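"""Image similarity metrics, perceptual losses, and paired-test reporting.

All metrics operate on images of identical shape (2D slices or 3D volumes,
with the pixel count generalizing to the voxel count) and assume the
conformed unit intensity scale unless a data range is passed explicitly.

* MAE / MSE: mean absolute / squared intensity difference.
* PSNR: 10 log10(MAXI^2 / MSE); identical images give an infinity sentinel.
* SSIM: mean over sliding Gaussian windows (11x11, sigma 1.5) of
  (2 mu_x mu_y + c1)(2 sigma_xy + c2) /
  ((mu_x^2 + mu_y^2 + c1)(sigma_x^2 + sigma_y^2 + c2)),
  with c1 = (k1 L)^2, c2 = (k2 L)^2, k1 = 0.01, k2 = 0.03.
* MS-SSIM: luminance at the coarsest of M dyadic scales, contrast-structure
  terms at every scale, exponents taken from the standard five-scale weights
  renormalized to the first M (M = 2 by default).
* Feature loss / LPIPS-style loss: mean absolute (resp. squared) difference
  of deep feature maps from a convolutional extractor.  The deterministic
  seeded-random extractor is the default backbone; loading pretrained
  classifier weights is an opt-in that requires the weights to be present.
* Dice / IOU overlap for binary masks, and paired t-tests with
  Benjamini-Hochberg FDR correction for method comparison tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from . import nn
from .nn import autograd as ag
from .nn.autograd import Tensor

__all__ = [
    "SSIMConfig", "FeatureExtractor", "MetricReport",
    "mae", "mse", "psnr", "ssim", "msssim",
    "feature_loss", "lpips_like", "dice_iou", "paired_compare",
    "metric_table",
]

#: standard five-scale MS-SSIM exponents (beta_j = gamma_j, alpha on scale M)
MSSSIM_WEIGHTS = (0.0448, 0.2856, 0.3001, 0.2363, 0.1333)


@dataclass(frozen=True)
class SSIMConfig:
    k1: float = 0.01
    k2: float = 0.03
    data_range: float = 1.0
    window_size: int = 11
    window_sigma: float = 1.5
    n_scales: int = 2

    def __post_init__(self):
        if self.k1 <= 0 or self.k2 <= 0:
            raise ValueError("k1 and k2 must be positive")
        if not 1 <= self.n_scales <= 5:
            raise ValueError("number of scales must be between 1 and 5")


def _check_pair(x, y) -> Tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    return x, y


def mae(x, y) -> float:
    x, y = _check_pair(x, y)
    return float(np.abs(x - y).mean())


def mse(x, y) -> float:
    x, y = _check_pair(x, y)
    return float(((x - y) ** 2).mean())


def psnr(x, y, data_range: float = 1.0) -> float:
    if data_range <= 0:
        raise ValueError("data range MAXI must be positive")
    err = mse(x, y)
    if err == 0:
        return float("inf")
    return float(10.0 * np.log10(data_range ** 2 / err))


def _gaussian_window(size: int, sigma: float) -> np.ndarray:
    r = size // 2
    g = np.exp(-0.5 * (np.arange(-r, r + 1) / sigma) ** 2)
    k = np.outer(g, g)
    return k / k.sum()


def _ssim_stats(x: np.ndarray, y: np.ndarray, config: SSIMConfig):
    """Windowed l(x,y) and contrast-structure maps over valid positions."""
    if x.ndim != 2:
        raise ValueError("SSIM operates on 2D images")
    size = config.window_size
    if min(x.shape) < size:
        raise ValueError(f"image {x.shape} smaller than {size}x{size} window")
    k = _gaussian_window(size, config.window_sigma)
    r = size // 2
    conv = lambda im: ndimage.convolve(im, k, mode="constant")[r:-r, r:-r]
    mx, my = conv(x), conv(y)
    sxx = conv(x * x) - mx * mx
    syy = conv(y * y) - my * my
    sxy = conv(x * y) - mx * my
    L = config.data_range
    c1 = (config.k1 * L) ** 2
    c2 = (config.k2 * L) ** 2
    lum = (2 * mx * my + c1) / (mx ** 2 + my ** 2 + c1)
    cs = (2 * sxy + c2) / (sxx + syy + c2)
    return lum, cs


def ssim(x, y, config: SSIMConfig = SSIMConfig()) -> float:
    """Mean structural-similarity index over sliding Gaussian windows."""
    x, y = _check_pair(x, y)
    lum, cs = _ssim_stats(x, y, config)
    return float((lum * cs).mean())


def _downsample2(im: np.ndarray) -> np.ndarray:
    h, w = (im.shape[0] // 2) * 2, (im.shape[1] // 2) * 2
    im = im[:h, :w]
    return im.reshape(h // 2, 2, w // 2, 2).mean(axis=(1, 3))


def msssim(x, y, config: SSIMConfig = SSIMConfig()) -> float:
    """Multi-scale SSIM with renormalized exponents over M scales."""
    x, y = _check_pair(x, y)
    M = config.n_scales
    needed = config.window_size * 2 ** (M - 1)
    if min(x.shape) < needed:
        raise ValueError(f"image {x.shape} too small for {M} dyadic scales")
    weights = np.array(MSSSIM_WEIGHTS[:M])
    weights = weights / weights.sum()
    value = 1.0
    for j in range(M):
        lum, cs = _ssim_stats(x, y, config)
        mcs = max(float(cs.mean()), 0.0)
        if j == M - 1:
            ml = max(float(lum.mean()), 0.0)
            value *= ml ** weights[j]
        value *= mcs ** weights[j]
        if j < M - 1:
            x, y = _downsample2(x), _downsample2(y)
    return float(value)


class FeatureExtractor(nn.Module):
    """Convolutional feature backbone for perceptual similarity.

    ``fixed_random_seeded`` builds a deterministic He-initialized conv stack
    (two 3x3 stages, 3 -> n_filt -> n_filt, ReLU after each), so perceptual
    losses need no downloaded weights.  ``pretrained_classifier`` is the
    opt-in backbone using published classifier weights and raises an
    explicit error when those weights are not available locally.
    """

    def __init__(self, origin: str = "fixed_random_seeded", seed: int = 0,
                 n_filt: int = 64, layers: Sequence[int] = (1,)):
        super().__init__()
        if origin not in ("fixed_random_seeded", "pretrained_classifier"):
            raise ValueError(f"unknown extractor origin {origin!r}")
        if origin == "pretrained_classifier":
            raise RuntimeError(
                "pretrained classifier weights are not available in this "
                "installation; use origin='fixed_random_seeded' instead")
        self.origin = origin
        self.seed = seed
        self.layers = tuple(int(l) for l in layers)
        if any(l < 1 or l > 2 for l in self.layers):
            raise ValueError("layer indices must be in {1, 2}")
        rng = np.random.default_rng(seed)
        self.conv1 = nn.Conv2d(3, n_filt, 3, rng)
        self.conv2 = nn.Conv2d(n_filt, n_filt, 3, rng)
        self.eval()

    def features(self, x: Tensor) -> List[Tensor]:
        h1 = ag.relu(self.conv1(x))
        h2 = ag.relu(self.conv2(h1))
        return [h1, h2]

    @staticmethod
    def prepare(image) -> Tensor:
        """Replicate a grayscale image/tensor to the 3-channel input layout."""
        if isinstance(image, Tensor):
            if image.data.ndim == 4 and image.data.shape[1] == 1:
                return ag.concat([image, image, image], axis=1)
            raise ValueError("tensor input must have shape (B, 1, H, W)")
        arr = np.asarray(image, dtype=np.float32)
        if arr.ndim != 2:
            raise ValueError("expected a 2D grayscale image")
        return Tensor(np.repeat(arr[None, None], 3, axis=1))


def _feature_distance(x, y, extractor: FeatureExtractor, squared: bool) -> Tensor:
    if extractor is None:
        raise RuntimeError("feature extractor is not initialized")
    fx = extractor.features(FeatureExtractor.prepare(x))
    fy = extractor.features(FeatureExtractor.prepare(y))
    total = None
    for l in extractor.layers:
        diff = ag.sub(fx[l - 1], fy[l - 1])
        term = ag.mean(ag.square(diff) if squared else ag.tabs(diff))
        total = term if total is None else ag.add(total, term)
    return ag.div(total, float(len(extractor.layers)))


def feature_loss(x, y, extractor: FeatureExtractor) -> float:
    """Mean absolute deep-feature difference (L1 perceptual loss)."""
    return float(_feature_distance(x, y, extractor, squared=False).data)


def lpips_like(x, y, extractor: FeatureExtractor) -> float:
    """Per-layer mean squared deep-feature difference (LPIPS-style)."""
    return float(_feature_distance(x, y, extractor, squared=True).data)


def feature_loss_t(pred: Tensor, target, extractor: FeatureExtractor) -> Tensor:
    """Differentiable feature loss for training (pred is a (B,1,H,W) tensor)."""
    return _feature_distance(pred, Tensor(np.asarray(target, np.float32)),
                             extractor, squared=False)


def lpips_like_t(pred: Tensor, target, extractor: FeatureExtractor) -> Tensor:
    return _feature_distance(pred, Tensor(np.asarray(target, np.float32)),
                             extractor, squared=True)


def dice_iou(mask_a, mask_b) -> Tuple[float, float]:
    """Dice-kappa and intersection-over-union of two binary masks."""
    a = np.asarray(mask_a)
    b = np.asarray(mask_b)
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    for m in (a, b):
        vals = np.unique(m)
        if not np.isin(vals, (0, 1, True, False)).all():
            raise ValueError("masks must be binary")
    a = a.astype(bool)
    b = b.astype(bool)
    inter = np.logical_and(a, b).sum()
    na, nb = a.sum(), b.sum()
    union = na + nb - inter
    if na + nb == 0:
        return 1.0, 1.0
    dice = 2.0 * inter / (na + nb)
    iou = inter / union if union else 1.0
    return float(dice), float(iou)


@dataclass
class MetricReport:
    """Per-image metric values plus optional paired-test comparisons."""

    values: pd.DataFrame  # columns: image, method, metric, value
    comparisons: Optional[pd.DataFrame] = None

    def aggregate(self) -> pd.DataFrame:
        return (self.values.groupby(["method", "metric"])["value"]
                .agg(["mean", "std"]).reset_index())

    def to_csv(self, path: str) -> None:
        self.values.to_csv(path, index=False)

    def to_json(self, path: Optional[str] = None) -> str:
        blob = {"values": self.values.to_dict(orient="records")}
        if self.comparisons is not None:
            blob["comparisons"] = self.comparisons.to_dict(orient="records")
        text = json.dumps(blob, indent=2, default=float)
        if path:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def paired_compare(values_by_method: Dict[str, Sequence[float]],
                   reference: str, metric: str = "metric",
                   higher_is_better: bool = True,
                   alpha: float = 0.05) -> MetricReport:
    """Paired t-tests of every method against a reference, FDR corrected.

    Labels follow the convention: ``better``/``worse`` at q < alpha in the
    direction given by ``higher_is_better``, otherwise ``ns``.
    """
    if reference not in values_by_method:
        raise ValueError(f"reference {reference!r} not among methods")
    if len(values_by_method) < 2:
        raise ValueError("need at least two methods to compare")
    lengths = {len(v) for v in values_by_method.values()}
    if len(lengths) != 1:
        raise ValueError("methods must have equal numbers of paired values")
    n = lengths.pop()
    if n < 3:
        raise ValueError("need at least three paired observations")
    ref = np.asarray(values_by_method[reference], dtype=float)
    rows = []
    for name, vals in values_by_method.items():
        if name == reference:
            continue
        v = np.asarray(vals, dtype=float)
        diff = v - ref
        if np.allclose(diff, 0.0):
            t_stat, p = 0.0, 1.0
        else:
            t_stat, p = stats.ttest_rel(v, ref)
            if not np.isfinite(p):
                p = 1.0
        rows.append({"method": name, "mean_diff": float(diff.mean()),
                     "t": float(t_stat), "p": float(p)})
    table = pd.DataFrame(rows)
    _, q, _, _ = multipletests(table["p"].to_numpy(), method="fdr_bh")
    table["q"] = q
    sign = 1.0 if higher_is_better else -1.0
    table["label"] = [
        "ns" if row.q >= alpha or row.mean_diff == 0 else
        ("better" if sign * row.mean_diff > 0 else "worse")
        for row in table.itertuples()
    ]
    long = pd.DataFrame([
        {"image": i, "method": m, "metric": metric, "value": float(v)}
        for m, vals in values_by_method.items() for i, v in enumerate(vals)
    ])
    return MetricReport(values=long, comparisons=table)


def metric_table(reference, images_by_method: Dict[str, Sequence[np.ndarray]],
                 config: SSIMConfig = SSIMConfig(),
                 extractor: Optional[FeatureExtractor] = None) -> MetricReport:
    """Compute the full metric panel of every method's images vs a reference.

    ``reference`` is a sequence of ground-truth images; each method supplies
    the same number of images.
    """
    if extractor is None:
        extractor = FeatureExtractor(seed=0)
    rows = []
    for method, images in images_by_method.items():
        if len(images) != len(reference):
            raise ValueError(f"method {method!r} image count mismatch")
        for i, (img, ref) in enumerate(zip(images, reference)):
            pairs = {
                "mae": mae(img, ref),
                "mse": mse(img, ref),
                "psnr": psnr(img, ref, config.data_range),
                "ssim": ssim(img, ref, config),
                "msssim": msssim(img, ref, config),
                "lpips_like": lpips_like(img, ref, extractor),
            }
            rows.extend({"image": i, "method": method, "metric": k,
                         "value": v} for k, v in pairs.items())
    return MetricReport(values=pd.DataFrame(rows))
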