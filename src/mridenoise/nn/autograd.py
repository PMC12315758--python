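"""A small reverse-mode automatic-differentiation engine on numpy arrays.

This is the compute backend for the denoising networks: 2D convolution
(im2col + GEMM), max-pooling with argmax indices, the matching unpooling,
bilinear feature rescaling, PReLU/ReLU, batch normalization, elementwise
maxout, and the usual arithmetic/reduction primitives, each with a hand
written backward pass.  Everything is deterministic: identical inputs and
parameters reproduce identical outputs bit for bit.

A lightweight autocast policy is provided: inside ``autocast()`` the GEMM
operands of convolutions are cast to float16 (master parameters stay
float32), emulating mixed-precision training.
"""

from __future__ import annotations

import contextlib
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_AUTOCAST = False


@contextlib.contextmanager
def autocast(enabled: bool = True):
    """Run convolution GEMMs in float16 while enabled."""
    global _AUTOCAST
    prev = _AUTOCAST
    _AUTOCAST = bool(enabled)
    try:
        yield
    finally:
        _AUTOCAST = prev


def _gemm_dtype():
    return np.float16 if _AUTOCAST else np.float32


class Tensor:
    """An array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: Tuple["Tensor", ...] = ()

    # -- plumbing ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        topo: List[Tensor] = []
        seen = set()

        def visit(t: Tensor) -> None:
            stack = [(t, iter(t._parents))]
            seen.add(id(t))
            while stack:
                node, it = stack[-1]
                advanced = False
                for p in it:
                    if id(p) not in seen and (p.requires_grad or p._parents):
                        seen.add(id(p))
                        stack.append((p, iter(p._parents)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(node)
                    stack.pop()

        visit(self)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operator sugar ---------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, other)

    def __neg__(self):
        return mul(self, -1.0)

    def mean(self):
        return mean(self)

    def sum(self):
        return tsum(self)

    def abs(self):
        return tabs(self)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents: Sequence[Tensor], backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad or p._parents for p in parents):
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(g: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


# -- arithmetic ------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data + b.data

    def backward(g):
        a._accumulate(_unbroadcast(g, a.data.shape))
        b._accumulate(_unbroadcast(g, b.data.shape))

    return _make(out_data, (a, b), backward)


def sub(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data - b.data

    def backward(g):
        a._accumulate(_unbroadcast(g, a.data.shape))
        b._accumulate(_unbroadcast(-g, b.data.shape))

    return _make(out_data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data * b.data

    def backward(g):
        a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _make(out_data, (a, b), backward)


def div(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data / b.data

    def backward(g):
        a._accumulate(_unbroadcast(g / b.data, a.data.shape))
        b._accumulate(_unbroadcast(-g * a.data / (b.data ** 2), b.data.shape))

    return _make(out_data, (a, b), backward)


def tsum(a: Tensor) -> Tensor:
    a = as_tensor(a)

    def backward(g):
        a._accumulate(np.full_like(a.data, float(g)))

    return _make(a.data.sum(), (a,), backward)


def mean(a: Tensor) -> Tensor:
    a = as_tensor(a)
    n = a.data.size

    def backward(g):
        a._accumulate(np.full_like(a.data, float(g) / n))

    return _make(a.data.mean(), (a,), backward)


def tabs(a: Tensor) -> Tensor:
    a = as_tensor(a)
    sign = np.sign(a.data)

    def backward(g):
        a._accumulate(g * sign)

    return _make(np.abs(a.data), (a,), backward)


def square(a: Tensor) -> Tensor:
    a = as_tensor(a)

    def backward(g):
        a._accumulate(g * 2.0 * a.data)

    return _make(a.data ** 2, (a,), backward)


def maximum(a: Tensor, b: Tensor) -> Tensor:
    """Elementwise maximum (the maxout primitive); ties route gradient to a."""
    a, b = as_tensor(a), as_tensor(b)
    if a.data.shape != b.data.shape:
        raise ValueError(f"maxout shape mismatch: {a.data.shape} vs {b.data.shape}")
    mask = a.data >= b.data

    def backward(g):
        a._accumulate(np.where(mask, g, 0.0))
        b._accumulate(np.where(mask, 0.0, g))

    return _make(np.maximum(a.data, b.data), (a, b), backward)


def maxout(stacks: Iterable[Tensor]) -> Tensor:
    """Fold elementwise maximum over a sequence of equally shaped stacks."""
    stacks = list(stacks)
    if not stacks:
        raise ValueError("maxout needs at least one input")
    out = stacks[0]
    for s in stacks[1:]:
        out = maximum(out, s)
    return out


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accumulate(g[tuple(sl)])

    return _make(np.concatenate([t.data for t in tensors], axis=axis),
                 tuple(tensors), backward)


# -- activations -----------------------------------------------------------

def relu(a: Tensor) -> Tensor:
    a = as_tensor(a)
    mask = a.data > 0

    def backward(g):
        a._accumulate(g * mask)

    return _make(np.where(mask, a.data, 0.0), (a,), backward)


def prelu(x: Tensor, alpha: Tensor) -> Tensor:
    """PReLU with one learnable slope per channel (axis 1 of BCHW)."""
    x, alpha = as_tensor(x), as_tensor(alpha)
    a = alpha.data.reshape(1, -1, *([1] * (x.data.ndim - 2)))
    pos = x.data > 0
    out_data = np.where(pos, x.data, a * x.data)

    def backward(g):
        x._accumulate(np.where(pos, g, a * g))
        ga = np.where(pos, 0.0, g * x.data)
        axes = (0,) + tuple(range(2, x.data.ndim))
        alpha._accumulate(ga.sum(axis=axes).reshape(alpha.data.shape))

    return _make(out_data, (x, alpha), backward)


# -- convolution -----------------------------------------------------------

def conv2d(x: Tensor, w: Tensor, b: Optional[Tensor], padding: int = 1) -> Tensor:
    """2D convolution, stride 1, square kernel, zero padding."""
    x, w = as_tensor(x), as_tensor(w)
    B, C, H, W = x.data.shape
    Co, Ci, kh, kw = w.data.shape
    if Ci != C:
        raise ValueError(f"conv2d channel mismatch: input {C}, weight expects {Ci}")
    dt = _gemm_dtype()
    if padding:
        xp = np.pad(x.data, ((0, 0), (0, 0), (padding,) * 2, (padding,) * 2))
    else:
        xp = x.data
    Ho, Wo = xp.shape[2] - kh + 1, xp.shape[3] - kw + 1
    cols = sliding_window_view(xp, (kh, kw), axis=(2, 3))
    cols = np.ascontiguousarray(cols.transpose(0, 2, 3, 1, 4, 5),
                                dtype=dt).reshape(B * Ho * Wo, C * kh * kw)
    wmat = w.data.reshape(Co, -1).astype(dt)
    out = cols @ wmat.T
    out = out.astype(np.float32)
    if b is not None:
        out += b.data.reshape(1, Co)
    out_data = out.reshape(B, Ho, Wo, Co).transpose(0, 3, 1, 2)
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        gmat = np.ascontiguousarray(
            g.transpose(0, 2, 3, 1), dtype=dt).reshape(B * Ho * Wo, Co)
        if b is not None:
            b._accumulate(gmat.astype(np.float32).sum(axis=0))
        w._accumulate((gmat.T @ cols).astype(np.float32).reshape(w.data.shape))
        gcols = (gmat @ wmat).astype(np.float32)
        gcols = gcols.reshape(B, Ho, Wo, C, kh, kw).transpose(0, 3, 1, 2, 4, 5)
        gxp = np.zeros_like(xp, dtype=np.float32)
        for i in range(kh):
            for j in range(kw):
                gxp[:, :, i:i + Ho, j:j + Wo] += gcols[:, :, :, :, i, j]
        if padding:
            gxp = gxp[:, :, padding:-padding, padding:-padding]
        x._accumulate(gxp)

    return _make(out_data, parents, backward)


# -- pooling ---------------------------------------------------------------

def maxpool2d(x: Tensor) -> Tuple[Tensor, np.ndarray]:
    """2x2/stride-2 max pooling; returns (pooled, argmax indices)."""
    x = as_tensor(x)
    B, C, H, W = x.data.shape
    if H % 2 or W % 2:
        raise ValueError(f"maxpool2d needs even spatial dims, got {H}x{W}")
    xr = x.data.reshape(B, C, H // 2, 2, W // 2, 2)
    xr = xr.transpose(0, 1, 2, 4, 3, 5).reshape(B, C, H // 2, W // 2, 4)
    idx = xr.argmax(axis=-1)
    out_data = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        gr = np.zeros((B, C, H // 2, W // 2, 4), dtype=np.float32)
        np.put_along_axis(gr, idx[..., None], g[..., None], axis=-1)
        gr = gr.reshape(B, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        x._accumulate(gr.reshape(B, C, H, W))

    return _make(out_data, (x,), backward), idx


def maxunpool2d(x: Tensor, idx: np.ndarray) -> Tensor:
    """Inverse of maxpool2d: place values at their argmax positions."""
    x = as_tensor(x)
    B, C, Hp, Wp = x.data.shape
    if idx.shape != (B, C, Hp, Wp):
        raise ValueError("unpool indices do not match input shape")
    buf = np.zeros((B, C, Hp, Wp, 4), dtype=np.float32)
    np.put_along_axis(buf, idx[..., None], x.data[..., None], axis=-1)
    out_data = buf.reshape(B, C, Hp, Wp, 2, 2).transpose(0, 1, 2, 4, 3, 5)
    out_data = out_data.reshape(B, C, Hp * 2, Wp * 2)

    def backward(g):
        gr = g.reshape(B, C, Hp, 2, Wp, 2).transpose(0, 1, 2, 4, 3, 5)
        gr = gr.reshape(B, C, Hp, Wp, 4)
        x._accumulate(np.take_along_axis(gr, idx[..., None], axis=-1)[..., 0])

    return _make(out_data, (x,), backward)


# -- resizing --------------------------------------------------------------

def _interp_matrix(n_in: int, n_out: int, scale: Optional[float]) -> np.ndarray:
    """Dense 1D bilinear interpolation matrix, half-pixel convention."""
    inv = (n_in / n_out) if scale is None else (1.0 / scale)
    src = (np.arange(n_out, dtype=np.float64) + 0.5) * inv - 0.5
    src = np.clip(src, 0.0, n_in - 1.0)
    i0 = np.floor(src).astype(int)
    i1 = np.minimum(i0 + 1, n_in - 1)
    w1 = src - i0
    A = np.zeros((n_out, n_in), dtype=np.float32)
    A[np.arange(n_out), i0] += (1.0 - w1).astype(np.float32)
    A[np.arange(n_out), i1] += w1.astype(np.float32)
    return A


def bilinear_resize(x: Tensor, out_hw: Tuple[int, int],
                    scale: Optional[Tuple[float, float]] = None) -> Tensor:
    """Bilinear resize of the two trailing axes (no corner alignment).

    If ``scale`` is given, the source coordinates use exactly that factor
    (the scale is not recomputed from the output size).
    """
    x = as_tensor(x)
    B, C, H, W = x.data.shape
    Ho, Wo = int(out_hw[0]), int(out_hw[1])
    if Ho < 1 or Wo < 1:
        raise ValueError(f"invalid resize target {out_hw}")
    sh, sw = (None, None) if scale is None else scale
    Ah = _interp_matrix(H, Ho, sh)
    Aw = _interp_matrix(W, Wo, sw)
    # y[b,c,o,p] = sum_h sum_w Ah[o,h] Aw[p,w] x[b,c,h,w]
    tmp = np.tensordot(x.data, Ah, axes=([2], [1]))      # B,C,W,Ho
    out_data = np.tensordot(tmp, Aw, axes=([2], [1]))    # B,C,Ho,Wo
    out_data = np.ascontiguousarray(out_data)

    def backward(g):
        t = np.tensordot(g, Aw, axes=([3], [0]))         # B,C,Ho,W
        gx = np.tensordot(t, Ah, axes=([2], [0]))        # B,C,W,H
        x._accumulate(np.ascontiguousarray(gx.transpose(0, 1, 3, 2)))

    return _make(out_data, (x,), backward)


def pad2d(x: Tensor, pad: Tuple[int, int]) -> Tensor:
    """Zero-pad the two trailing axes at the high side."""
    x = as_tensor(x)
    ph, pw = pad
    if ph == 0 and pw == 0:
        return x
    out_data = np.pad(x.data, ((0, 0), (0, 0), (0, ph), (0, pw)))

    def backward(g):
        x._accumulate(g[:, :, :x.data.shape[2], :x.data.shape[3]])

    return _make(out_data, (x,), backward)


def crop2d(x: Tensor, hw: Tuple[int, int]) -> Tensor:
    """Crop the two trailing axes down to ``hw`` (from the origin)."""
    x = as_tensor(x)
    H, W = hw
    if (H, W) == x.data.shape[2:]:
        return x
    out_data = np.ascontiguousarray(x.data[:, :, :H, :W])

    def backward(g):
        gx = np.zeros_like(x.data)
        gx[:, :, :H, :W] = g
        x._accumulate(gx)

    return _make(out_data, (x,), backward)


# -- batch normalization ---------------------------------------------------

def batchnorm2d(x: Tensor, gamma: Tensor, beta: Tensor,
                running_mean: np.ndarray, running_var: np.ndarray,
                training: bool, momentum: float = 0.1,
                eps: float = 1e-5) -> Tensor:
    """Batch normalization over (B, H, W) per channel."""
    x = as_tensor(x)
    B, C, H, W = x.data.shape
    if training:
        m = x.data.mean(axis=(0, 2, 3))
        v = x.data.var(axis=(0, 2, 3))
        running_mean *= (1 - momentum)
        running_mean += momentum * m
        running_var *= (1 - momentum)
        running_var += momentum * v
    else:
        m, v = running_mean, running_var
    inv = 1.0 / np.sqrt(v + eps)
    xhat = (x.data - m[None, :, None, None]) * inv[None, :, None, None]
    out_data = gamma.data[None, :, None, None] * xhat + \
        beta.data[None, :, None, None]
    n = B * H * W

    def backward(g):
        gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
        beta._accumulate(g.sum(axis=(0, 2, 3)))
        gxh = g * gamma.data[None, :, None, None]
        if training:
            s1 = gxh.sum(axis=(0, 2, 3), keepdims=True)
            s2 = (gxh * xhat).sum(axis=(0, 2, 3), keepdims=True)
            gx = (gxh - s1 / n - xhat * s2 / n) * inv[None, :, None, None]
        else:
            gx = gxh * inv[None, :, None, None]
        x._accumulate(gx.astype(np.float32))

    return _make(out_data.astype(np.float32), (x, gamma, beta), backward)
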