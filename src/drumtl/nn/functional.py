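"""Structured array operations: convolution, pooling, resampling, batch norm.

Convolutions use im2col + GEMM; the input-gradient of a stride-1
convolution is itself a convolution with the spatially flipped,
channel-transposed kernel, so the backward pass also runs on GEMM and no
scatter-add is needed.  Spatial resampling (bilinear up, area down) is
expressed as separable interpolation matrices applied along the height and
width axes, which makes the adjoint a pair of transposed matrix products.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import Tensor

__all__ = [
    "conv2d",
    "max_pool2d",
    "resize_bilinear",
    "avg_pool_to",
    "global_avg_pool",
    "batch_norm2d",
    "dropout",
]


def _im2col(x: np.ndarray, kh: int, kw: int, pad: int):
    """(N,C,H,W) -> (N*H*W, kh*kw*C) channels-last patch matrix.

    Channels-last ordering keeps the patch copy in contiguous C-sized runs,
    which is substantially faster than the naive NCHW layout.
    """
    n, c, h, w = x.shape
    xp = np.zeros((n, h + 2 * pad, w + 2 * pad, c), dtype=x.dtype)
    xp[:, pad : pad + h, pad : pad + w, :] = x.transpose(0, 2, 3, 1)
    v = sliding_window_view(xp, (kh, kw), axis=(1, 2))  # N,Ho,Wo,C,kh,kw
    ho, wo = v.shape[1:3]
    col = np.ascontiguousarray(v.transpose(0, 1, 2, 4, 5, 3))
    return col.reshape(n * ho * wo, kh * kw * c), (n, ho, wo)


def _conv_fwd(x: np.ndarray, w: np.ndarray, b: np.ndarray | None, pad: int):
    o, c, kh, kw = w.shape
    n, _, h, wd = x.shape
    if kh == 1 and kw == 1:
        col = np.ascontiguousarray(x.transpose(0, 2, 3, 1)).reshape(-1, c)
        ho, wo = h, wd
    else:
        col, (n, ho, wo) = _im2col(x, kh, kw, pad)
    wmat = w.transpose(2, 3, 1, 0).reshape(kh * kw * c, o)
    out = col @ wmat
    if b is not None:
        out += b
    return np.ascontiguousarray(out.reshape(n, ho, wo, o).transpose(0, 3, 1, 2)), col


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Stride-1 'same' 2-D convolution (cross-correlation), NCHW layout.

    Padding is ``k // 2`` so output spatial size equals input size for odd
    kernels (3x3 skip/refine convolutions, 1x1 projections).
    """
    o, c, kh, kw = w.shape
    pad = kh // 2
    y, col = _conv_fwd(x.data, w.data, b.data if b is not None else None, pad)
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(y, requires_grad=True, _parents=parents)

    def bwd(g):
        gmat = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(-1, o)
        dwmat = col.T @ gmat  # (kh*kw*c, o)
        w._accum(dwmat.reshape(kh, kw, c, o).transpose(3, 2, 0, 1))
        if b is not None:
            b._accum(gmat.sum(axis=0))
        if x.requires_grad or x._parents:
            # input gradient = conv of g with flipped kernel, channels swapped
            w_flip = np.ascontiguousarray(w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3))
            dx, _ = _conv_fwd(g, w_flip, None, pad)
            x._accum(dx)

    out._backward = bwd
    return out


def max_pool2d(x: Tensor, k: int = 2) -> Tensor:
    """Non-overlapping k x k max pooling."""
    n, c, h, w = x.data.shape
    if h % k or w % k:
        raise ValueError(f"spatial size {(h, w)} not divisible by pool size {k}")
    blocks = x.data.reshape(n, c, h // k, k, w // k, k)
    flat = np.ascontiguousarray(blocks.transpose(0, 1, 2, 4, 3, 5)).reshape(
        n, c, h // k, w // k, k * k
    )
    arg = flat.argmax(axis=-1)
    y = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
    out = Tensor(y, requires_grad=x.requires_grad, _parents=(x,))

    def bwd(g):
        dflat = np.zeros_like(flat)
        np.put_along_axis(dflat, arg[..., None], g[..., None], axis=-1)
        dx = (
            dflat.reshape(n, c, h // k, w // k, k, k)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h, w)
        )
        x._accum(dx)

    out._backward = bwd
    return out


@lru_cache(maxsize=None)
def _bilinear_matrix(n_out: int, n_in: int, dtype_str: str) -> np.ndarray:
    """Half-pixel-centre bilinear interpolation matrix (n_out, n_in)."""
    a = np.zeros((n_out, n_in), dtype=dtype_str)
    src = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
    src = np.clip(src, 0, n_in - 1)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = src - lo
    a[np.arange(n_out), lo] += 1.0 - frac
    a[np.arange(n_out), hi] += frac
    return a


@lru_cache(maxsize=None)
def _area_matrix(n_out: int, n_in: int, dtype_str: str) -> np.ndarray:
    """Block-average (area) downsampling matrix for integer factors."""
    if n_in % n_out:
        raise ValueError(f"area pooling needs integer factor, got {n_in}->{n_out}")
    f = n_in // n_out
    a = np.zeros((n_out, n_in), dtype=dtype_str)
    for i in range(n_out):
        a[i, i * f : (i + 1) * f] = 1.0 / f
    return a


def _apply_separable(x: Tensor, ah: np.ndarray, aw: np.ndarray) -> Tensor:
    y = np.einsum("oi,ncij,pj->ncop", ah, x.data, aw, optimize=True)
    out = Tensor(y, requires_grad=x.requires_grad, _parents=(x,))

    def bwd(g):
        x._accum(np.einsum("oi,ncop,pj->ncij", ah, g, aw, optimize=True))

    out._backward = bwd
    return out


def resize_bilinear(x: Tensor, size: tuple[int, int]) -> Tensor:
    """Bilinear resize of an NCHW tensor to ``size`` (half-pixel centres)."""
    h, w = x.data.shape[2:]
    ho, wo = size
    if (h, w) == (ho, wo):
        return x
    ds = str(x.data.dtype)
    return _apply_separable(x, _bilinear_matrix(ho, h, ds), _bilinear_matrix(wo, w, ds))


def avg_pool_to(x: Tensor, size: tuple[int, int]) -> Tensor:
    """Area (block-mean) downsampling of an NCHW tensor to ``size``."""
    h, w = x.data.shape[2:]
    ho, wo = size
    if (h, w) == (ho, wo):
        return x
    ds = str(x.data.dtype)
    return _apply_separable(x, _area_matrix(ho, h, ds), _area_matrix(wo, w, ds))


def global_avg_pool(x: Tensor) -> Tensor:
    """Spatial mean per channel: (N,C,H,W) -> (N,C)."""
    return x.mean(axis=(2, 3))


def batch_norm2d(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Per-channel batch normalisation with running statistics.

    ``running_mean``/``running_var`` are mutated in place in training mode
    (they are buffers, not differentiable parameters).
    """
    n, c, h, w = x.data.shape
    axes = (0, 2, 3)
    if training:
        mu = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mu, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu[None, :, None, None]) * inv_std[None, :, None, None]
    y = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]
    out = Tensor(y, requires_grad=True, _parents=(x, gamma, beta))
    m = n * h * w

    def bwd(g):
        gamma._accum((g * xhat).sum(axis=axes))
        beta._accum(g.sum(axis=axes))
        if not (x.requires_grad or x._parents):
            return
        gs = gamma.data[None, :, None, None] * inv_std[None, :, None, None]
        if training:
            gmean = g.mean(axis=axes)[None, :, None, None]
            gxhat = (g * xhat).mean(axis=axes)[None, :, None, None]
            x._accum(gs * (g - gmean - xhat * gxhat))
        else:
            x._accum(gs * g)

    out._backward = bwd
    return out


def dropout(x: Tensor, rate: float, rng: np.random.Generator, training: bool) -> Tensor:
    """Inverted dropout; identity when not training or rate == 0."""
    if not training or rate <= 0.0:
        return x
    keep = 1.0 - rate
    mask = (rng.random(x.data.shape) < keep).astype(x.data.dtype) / keep
    out = Tensor(x.data * mask, requires_grad=x.requires_grad, _parents=(x,))

    def bwd(g):
        x._accum(g * mask)

    out._backward = bwd
    return out
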