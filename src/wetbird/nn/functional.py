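"""Convolutional primitives with custom forward/backward rules.

All spatial operators use the NCHW layout.  Convolution is evaluated through
an im2col expansion followed by a batched matrix product; its input gradient
is scattered back with a slice-add loop over kernel taps, which keeps the
backward pass vectorised without resorting to ``np.add.at``.
"""
from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import Tensor, is_grad_enabled

# Global multiply-accumulate counter (used by the FLOP profiler).
_mac_counter = None


class count_macs:
    """Context manager accumulating conv/linear multiply-accumulates."""

    def __init__(self):
        self.macs = 0

    def __enter__(self):
        global _mac_counter
        self._prev = _mac_counter
        _mac_counter = self
        return self

    def __exit__(self, *exc):
        global _mac_counter
        _mac_counter = self._prev
        return False


def _pair(v):
    return tuple(v) if isinstance(v, (tuple, list)) else (v, v)


def _norm_pad(padding):
    """Normalize padding to ((top, bottom), (left, right))."""
    if isinstance(padding, int):
        return (padding, padding), (padding, padding)
    a, b = padding
    if isinstance(a, int) and isinstance(b, int):
        return (a, a), (b, b)
    return tuple(a), tuple(b)


def _im2col(xp: np.ndarray, kh: int, kw: int, sh: int, sw: int, dh: int, dw: int):
    """Extract sliding windows from a padded [N,C,H,W] array.

    Returns a view of shape [N, C, Ho, Wo, kh, kw].
    """
    eh, ew = (kh - 1) * dh + 1, (kw - 1) * dw + 1
    win = sliding_window_view(xp, (eh, ew), axis=(2, 3))
    win = win[:, :, ::sh, ::sw, ::dh, ::dw]
    return win


def _col_scatter(gcols: np.ndarray, xp_shape, kh, kw, sh, sw, dh, dw):
    """Inverse of _im2col: accumulate [N,C,Ho,Wo,kh,kw] grads into padded input."""
    gx = np.zeros(xp_shape, dtype=np.float32)
    Ho, Wo = gcols.shape[2], gcols.shape[3]
    for ki in range(kh):
        for kj in range(kw):
            gx[:, :, ki * dh: ki * dh + sh * Ho: sh,
                  kj * dw: kj * dw + sw * Wo: sw] += gcols[:, :, :, :, ki, kj]
    return gx


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride=1, padding=0,
           dilation=1, groups: int = 1) -> Tensor:
    """2-D cross-correlation, optionally strided/dilated/grouped."""
    sh, sw = _pair(stride)
    dh, dw = _pair(dilation)
    (pt, pb), (pl, pr) = _norm_pad(padding)
    N, C, H, W = x.data.shape
    Cout, Cg, kh, kw = w.data.shape
    if C != Cg * groups:
        raise ValueError(f"channel mismatch: input has {C}, weight expects {Cg * groups}")

    xp = np.pad(x.data, ((0, 0), (0, 0), (pt, pb), (pl, pr))) if (pt or pb or pl or pr) else x.data
    win = _im2col(xp, kh, kw, sh, sw, dh, dw)  # [N,C,Ho,Wo,kh,kw]
    Ho, Wo = win.shape[2], win.shape[3]
    L = Ho * Wo
    # [N, g, Cg*kh*kw, L]
    cols = win.transpose(0, 1, 4, 5, 2, 3).reshape(N, groups, Cg * kh * kw, L)
    wr = w.data.reshape(groups, Cout // groups, Cg * kh * kw)
    out = np.matmul(wr[None], cols)  # [N, g, Cout/g, L]
    out = out.reshape(N, Cout, Ho, Wo)
    if b is not None:
        out = out + b.data.reshape(1, Cout, 1, 1)
    if _mac_counter is not None:
        _mac_counter.macs += N * Cout * L * Cg * kh * kw

    prev = (x, w) if b is None else (x, w, b)
    if not (is_grad_enabled() and any(p.requires_grad for p in prev)):
        return Tensor(out)

    xp_shape = xp.shape

    def bw(g):
        gr = g.reshape(N, groups, Cout // groups, L)
        if w.requires_grad:
            gw = np.matmul(gr, cols.transpose(0, 1, 3, 2)).sum(axis=0)
            w._accum(gw.reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gcols = np.matmul(wr[None].transpose(0, 1, 3, 2), gr)  # [N,g,Cg*kh*kw,L]
            gcols = gcols.reshape(N, C, kh, kw, Ho, Wo).transpose(0, 1, 4, 5, 2, 3)
            gxp = _col_scatter(gcols, xp_shape, kh, kw, sh, sw, dh, dw)
            x._accum(gxp[:, :, pt: pt + H, pl: pl + W])

    return Tensor._make(out, prev, bw)


def unfold(x: Tensor, k: int, stride: int = 1, padding: int = 0) -> Tensor:
    """Sliding-window expansion: [N,C,H,W] -> [N, C*k*k, Ho, Wo].

    Window (ki, kj) of channel c lands at output channel c*k*k + ki*k + kj.
    """
    if k <= 0 or stride <= 0:
        raise ValueError("kernel and stride must be positive")
    N, C, H, W = x.data.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding))) if padding else x.data
    win = _im2col(xp, k, k, stride, stride, 1, 1)  # [N,C,Ho,Wo,k,k]
    Ho, Wo = win.shape[2], win.shape[3]
    out = np.ascontiguousarray(win.transpose(0, 1, 4, 5, 2, 3)).reshape(N, C * k * k, Ho, Wo)

    if not (is_grad_enabled() and x.requires_grad):
        return Tensor(out)

    xp_shape = xp.shape

    def bw(g):
        gcols = g.reshape(N, C, k, k, Ho, Wo).transpose(0, 1, 4, 5, 2, 3)
        gxp = _col_scatter(gcols, xp_shape, k, k, stride, stride, 1, 1)
        x._accum(gxp[:, :, padding: padding + H, padding: padding + W])

    return Tensor._make(out, (x,), bw)


def maxpool2d(x: Tensor, k: int, stride: int | None = None, padding: int = 0) -> Tensor:
    """Max pooling; padding is filled with -inf so it never wins."""
    s = stride if stride is not None else k
    N, C, H, W = x.data.shape
    if padding:
        xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                    constant_values=-np.inf)
    else:
        xp = x.data
    win = _im2col(xp, k, k, s, s, 1, 1)  # [N,C,Ho,Wo,k,k]
    Ho, Wo = win.shape[2], win.shape[3]
    flat = win.reshape(N, C, Ho, Wo, k * k)
    idx = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    if not (is_grad_enabled() and x.requires_grad):
        return Tensor(out)

    def bw(g):
        gx = np.zeros(xp.shape, dtype=np.float32)
        for t in range(k * k):
            mask = idx == t
            if not mask.any():
                continue
            ki, kj = divmod(t, k)
            gx[:, :, ki: ki + s * Ho: s, kj: kj + s * Wo: s] += g * mask
        x._accum(gx[:, :, padding: padding + H, padding: padding + W])

    return Tensor._make(out, (x,), bw)


def upsample_nearest(x: Tensor, scale: int = 2) -> Tensor:
    N, C, H, W = x.data.shape
    out = np.repeat(np.repeat(x.data, scale, axis=2), scale, axis=3)

    if not (is_grad_enabled() and x.requires_grad):
        return Tensor(out)

    def bw(g):
        x._accum(g.reshape(N, C, H, scale, W, scale).sum(axis=(3, 5)))

    return Tensor._make(out, (x,), bw)


def linear(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    out = x @ w
    if _mac_counter is not None:
        _mac_counter.macs += int(np.prod(out.shape)) * w.shape[-2]
    if b is not None:
        out = out + b
    return out
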