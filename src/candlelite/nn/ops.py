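"""Array-level forward/backward primitives.

Convolutions use an im2col gather (precomputed flat indices into the padded
input) so that the forward pass is a single GEMM and the input gradient is
a `bincount` scatter-add over the same indices.  The column matrix is
re-gathered in the backward pass instead of cached, trading a little
recomputation for a much smaller activation footprint.

All convolutions and pools are 'same'-padded (pad = k // 2); strides are
1 or 2 and stride-2 layers require even spatial input dims.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

__all__ = [
    "conv2d_forward",
    "conv2d_backward",
    "dwconv2d_forward",
    "dwconv2d_backward",
    "batchnorm_forward",
    "batchnorm_backward",
    "silu_forward",
    "silu_backward",
    "sigmoid_forward",
    "sigmoid_backward",
    "maxpool_forward",
    "maxpool_backward",
    "upsample2x_forward",
    "upsample2x_backward",
    "space_to_depth_forward",
    "space_to_depth_backward",
    "global_avg_pool_forward",
    "global_avg_pool_backward",
    "conv1d_channelwise_forward",
    "conv1d_channelwise_backward",
]


@lru_cache(maxsize=256)
def _conv_geometry(c: int, h: int, w: int, k: int, stride: int):
    """Flat gather indices mapping padded input -> (C*k*k, L) columns."""
    pad = k // 2
    hp, wp = h + 2 * pad, w + 2 * pad
    ho, wo = h // stride, w // stride
    oy = np.arange(ho) * stride
    ox = np.arange(wo) * stride
    ky, kx = np.mgrid[0:k, 0:k]
    # rows: channel-major then kernel offset; cols: output position
    rows_y = (oy[None, :, None] + ky.ravel()[:, None, None])  # (kk, ho, 1)
    rows_x = (ox[None, None, :] + kx.ravel()[:, None, None])  # (kk, 1, wo)
    pos = rows_y * wp + rows_x  # (kk, ho, wo)
    pos = pos.reshape(k * k, ho * wo)
    chan = (np.arange(c) * (hp * wp))[:, None, None]
    idx = (chan + pos[None]).reshape(c * k * k, ho * wo)
    return idx.astype(np.int64), (hp, wp), (ho, wo)


def _pad_input(x: np.ndarray, k: int) -> np.ndarray:
    pad = k // 2
    if pad == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))


def _im2col(x: np.ndarray, k: int, stride: int):
    n, c, h, w = x.shape
    idx, (hp, wp), (ho, wo) = _conv_geometry(c, h, w, k, stride)
    xp = _pad_input(x, k)
    col = xp.reshape(n, c * hp * wp)[:, idx.ravel()].reshape(n, c * k * k, ho * wo)
    return col, idx, (hp, wp), (ho, wo)


def conv2d_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray | None, stride: int):
    n = x.shape[0]
    co, ci, k, _ = w.shape
    col, _, _, (ho, wo) = _im2col(x, k, stride)
    y = np.matmul(w.reshape(co, ci * k * k), col)  # (n, co, L)
    if b is not None:
        y += b[:, None]
    return y.reshape(n, co, ho, wo)


def conv2d_backward(g: np.ndarray, x: np.ndarray, w: np.ndarray, has_bias: bool, stride: int):
    n, c, h, w_in = x.shape
    co, ci, k, _ = w.shape
    col, idx, (hp, wp), (ho, wo) = _im2col(x, k, stride)
    gflat = g.reshape(n, co, ho * wo)
    gw = np.tensordot(gflat, col, axes=([0, 2], [0, 2])).reshape(w.shape)
    gb = gflat.sum(axis=(0, 2)) if has_bias else None
    gcol = np.matmul(w.reshape(co, ci * k * k).T, gflat)  # (n, c*k*k, L)
    pad = k // 2
    idx_flat = idx.ravel()
    gx = np.empty_like(x)
    size = c * hp * wp
    for i in range(n):
        gxp = np.bincount(idx_flat, weights=gcol[i].ravel(), minlength=size)
        gxp = gxp.reshape(c, hp, wp)
        gx[i] = gxp[:, pad:pad + h, pad:pad + w_in]
    return gx, gw, gb


def dwconv2d_forward(x: np.ndarray, w: np.ndarray, stride: int):
    n, c, h, w_in = x.shape
    k = w.shape[-1]
    col, _, _, (ho, wo) = _im2col(x, k, stride)
    col = col.reshape(n, c, k * k, ho * wo)
    y = np.einsum("nckl,ck->ncl", col, w.reshape(c, k * k))
    return y.reshape(n, c, ho, wo)


def dwconv2d_backward(g: np.ndarray, x: np.ndarray, w: np.ndarray, stride: int):
    n, c, h, w_in = x.shape
    k = w.shape[-1]
    col, idx, (hp, wp), (ho, wo) = _im2col(x, k, stride)
    col = col.reshape(n, c, k * k, ho * wo)
    gflat = g.reshape(n, c, ho * wo)
    gw = np.einsum("ncl,nckl->ck", gflat, col).reshape(w.shape)
    gcol = gflat[:, :, None, :] * w.reshape(1, c, k * k, 1)
    pad = k // 2
    idx_flat = idx.ravel()
    gx = np.empty_like(x)
    size = c * hp * wp
    for i in range(n):
        gxp = np.bincount(idx_flat, weights=gcol[i].ravel(), minlength=size)
        gxp = gxp.reshape(c, hp, wp)
        gx[i] = gxp[:, pad:pad + h, pad:pad + w_in]
    return gx, gw


# ----------------------------------------------------------------------
# batchnorm


def batchnorm_forward(
    x: np.ndarray,
    gamma: np.ndarray,
    beta: np.ndarray,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    train: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
):
    """Returns (y, cache); updates running stats in place in train mode."""
    if train:
        axes = (0, 2, 3)
        mean = x.mean(axis=axes)
        var = x.var(axis=axes)
        running_mean *= 1 - momentum
        running_mean += momentum * mean
        running_var *= 1 - momentum
        running_var += momentum * var
    else:
        mean, var = running_mean, running_var
    invstd = 1.0 / np.sqrt(var + eps)
    xhat = (x - mean[:, None, None]) * invstd[:, None, None]
    y = gamma[:, None, None] * xhat + beta[:, None, None]
    return y, (xhat, invstd)


def batchnorm_backward(g: np.ndarray, gamma: np.ndarray, cache, train: bool):
    xhat, invstd = cache
    axes = (0, 2, 3)
    gbeta = g.sum(axis=axes)
    ggamma = (g * xhat).sum(axis=axes)
    if not train:
        gx = g * (gamma * invstd)[:, None, None]
        return gx, ggamma, gbeta
    m = g.shape[0] * g.shape[2] * g.shape[3]
    gx = (gamma * invstd)[:, None, None] / m * (
        m * g - gbeta[:, None, None] - xhat * ggamma[:, None, None]
    )
    return gx, ggamma, gbeta


# ----------------------------------------------------------------------
# activations


def stable_sigmoid(x: np.ndarray) -> np.ndarray:
    """Overflow-free logistic function."""
    z = np.exp(-np.abs(x))
    return np.where(x >= 0, 1.0 / (1.0 + z), z / (1.0 + z))


def silu_forward(x: np.ndarray):
    s = stable_sigmoid(x)
    return x * s, s


def silu_backward(g: np.ndarray, x: np.ndarray, s: np.ndarray):
    return g * (s * (1.0 + x * (1.0 - s)))


def sigmoid_forward(x: np.ndarray):
    y = stable_sigmoid(x)
    return y, y


def sigmoid_backward(g: np.ndarray, y: np.ndarray):
    return g * y * (1.0 - y)


# ----------------------------------------------------------------------
# pooling / resampling


def maxpool_forward(x: np.ndarray, k: int):
    """Stride-1 same-padded max pool; cache = flat argmax indices."""
    n, c, h, w = x.shape
    pad = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)), constant_values=-np.inf)
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    win = win.reshape(n, c, h, w, k * k)
    arg = win.argmax(axis=-1)
    y = np.take_along_axis(win, arg[..., None], axis=-1)[..., 0]
    return y, arg


def maxpool_backward(g: np.ndarray, x: np.ndarray, k: int, arg: np.ndarray):
    n, c, h, w = x.shape
    pad = k // 2
    hp, wp = h + 2 * pad, w + 2 * pad
    ky, kx = np.divmod(arg, k)  # offsets within the window
    oy, ox = np.mgrid[0:h, 0:w]
    ry = ky + oy  # row in padded input
    rx = kx + ox
    flat = (ry * wp + rx).reshape(n, c, -1)
    chan_off = (np.arange(c) * (hp * wp))[None, :, None]
    flat = flat + chan_off
    gx = np.empty_like(x)
    size = c * hp * wp
    for i in range(n):
        gxp = np.bincount(flat[i].ravel(), weights=g[i].ravel(), minlength=size)
        gxp = gxp.reshape(c, hp, wp)
        gx[i] = gxp[:, pad:pad + h, pad:pad + w]
    return gx


def upsample2x_forward(x: np.ndarray):
    return x.repeat(2, axis=2).repeat(2, axis=3)


def upsample2x_backward(g: np.ndarray):
    n, c, h2, w2 = g.shape
    return g.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5))


def space_to_depth_forward(x: np.ndarray):
    """Focus slice: (N,C,H,W) -> (N,4C,H/2,W/2)."""
    return np.concatenate(
        [x[:, :, ::2, ::2], x[:, :, 1::2, ::2], x[:, :, ::2, 1::2], x[:, :, 1::2, 1::2]],
        axis=1,
    )


def space_to_depth_backward(g: np.ndarray):
    n, c4, h, w = g.shape
    c = c4 // 4
    gx = np.empty((n, c, 2 * h, 2 * w), dtype=g.dtype)
    gx[:, :, ::2, ::2] = g[:, :c]
    gx[:, :, 1::2, ::2] = g[:, c:2 * c]
    gx[:, :, ::2, 1::2] = g[:, 2 * c:3 * c]
    gx[:, :, 1::2, 1::2] = g[:, 3 * c:]
    return gx


def global_avg_pool_forward(x: np.ndarray):
    return x.mean(axis=(2, 3), keepdims=True)


def global_avg_pool_backward(g: np.ndarray, h: int, w: int):
    return np.broadcast_to(g / (h * w), (*g.shape[:2], h, w)).copy()


# ----------------------------------------------------------------------
# channel-wise 1-D conv (attention)


def conv1d_channelwise_forward(x: np.ndarray, w: np.ndarray):
    """x: (N,C,1,1) treated as a channel sequence; same-padded 1-D conv."""
    n, c = x.shape[:2]
    k = w.shape[0]
    pad = k // 2
    v = x.reshape(n, c)
    vp = np.pad(v, ((0, 0), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(vp, k, axis=1)  # (n, c, k)
    y = win @ w
    return y.reshape(n, c, 1, 1)


def conv1d_channelwise_backward(g: np.ndarray, x: np.ndarray, w: np.ndarray):
    n, c = x.shape[:2]
    k = w.shape[0]
    pad = k // 2
    v = x.reshape(n, c)
    gv = g.reshape(n, c)
    vp = np.pad(v, ((0, 0), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(vp, k, axis=1)
    gw = np.einsum("nc,nck->k", gv, win)
    # input gradient: full correlation of g with the flipped kernel
    gp = np.pad(gv, ((0, 0), (pad, pad)))
    gwin = np.lib.stride_tricks.sliding_window_view(gp, k, axis=1)
    gx = gwin @ w[::-1]
    return gx.reshape(x.shape), gw
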