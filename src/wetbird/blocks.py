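"""Core computational blocks of the detector.

The blocks operate on NCHW feature maps and fall into two groups:

* standard one-stage-detector components (``ConvBnAct``, ``Bottleneck``,
  ``C2f``, ``SPPF``), and
* the small-target-oriented blocks this package exists for:

  - :class:`RFCAConv` — convolution whose attention is computed per sliding
    window in receptive-field space, with directional (coordinate) pooling,
    so that spatially distinct windows receive distinct weights.  Useful when
    targets are camouflaged against background texture.
  - :class:`C2fRFCA` — a C2f block whose bottlenecks end in an RFCAConv and
    drop the residual shortcut.
  - :class:`LSKA` — large separable kernel attention: a cascade of 1-D
    horizontal/vertical depth-wise kernels (plain then dilated) followed by a
    1x1 channel-mixing convolution, applied multiplicatively to the input.
  - :class:`SPPFLSKA` — SPPF with an LSKA recalibration inserted between the
    pooling concat and the channel-fusing 1x1 convolution.
  - :class:`CARAFE` — content-aware reassembly upsampling: per-output-position
    kernels are predicted from the input content, softmax-normalised, and
    shared across channels.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor, concat


@dataclass
class BlockConfig:
    """Hyperparameters of the attention/upsampling blocks.

    The defaults are the configuration used by the assembled detector.
    """
    in_channels: int = 64
    out_channels: int = 64
    kernel: int = 3
    stride: int = 1
    lska_K: int = 11
    lska_d: int = 3
    carafe_Cm: int = 60
    carafe_Kup: int = 5
    carafe_Kenc: int = 3
    carafe_sigma: int = 2

    def __post_init__(self):
        for f in ("in_channels", "out_channels", "kernel", "stride", "lska_K",
                  "lska_d", "carafe_Cm", "carafe_Kup", "carafe_Kenc", "carafe_sigma"):
            if int(getattr(self, f)) < 1:
                raise ValueError(f"{f} must be a positive integer")


def autopad(k: int) -> int:
    return k // 2


class ConvBnAct(nn.Module):
    """k x k convolution + batch norm + SiLU (the detector's standard conv)."""

    def __init__(self, c1, c2, k=1, s=1, p=None, g=1, act=True):
        super().__init__()
        self.conv = nn.Conv2d(c1, c2, k, stride=s, padding=autopad(k) if p is None else p,
                              groups=g, bias=False)
        self.bn = nn.BatchNorm2d(c2)
        self.act = nn.SiLU() if act else nn.Identity()

    def forward(self, x):
        return self.act(self.bn(self.conv(x)))


# ---------------------------------------------------------------------------
# Receptive-field expansion and RFCA convolution
# ---------------------------------------------------------------------------

def expand_to_receptive_field(x: Tensor | np.ndarray, k: int, stride: int = 1,
                              pad: int = 1) -> Tensor:
    """Expand a feature map into per-window receptive-field features.

    Returns [N, C*k*k, H', W'] where channel c*k*k + i*k + j holds window
    element (i, j) of input channel c, and H' = floor((H+2p-k)/s)+1.
    """
    if k <= 0 or stride <= 0:
        raise ValueError("window size and stride must be positive")
    if k % 2 == 0:
        raise ValueError("window size must be odd")
    if pad < 0:
        raise ValueError("padding must be non-negative")
    x = x if isinstance(x, Tensor) else Tensor(x)
    return nn.unfold(x, k, stride, pad)


def rf_to_spatial(rf: Tensor, c: int, k: int) -> Tensor:
    """Rearrange [N, C*k*k, H', W'] into the receptive-field spatial layout
    [N, C, k*H', k*W'] in which each k x k tile is one window."""
    n, _, h, w = rf.shape
    return rf.reshape(n, c, k, k, h, w).transpose(0, 1, 4, 2, 5, 3).reshape(n, c, k * h, k * w)


class RFCAConv(nn.Module):
    """Receptive-field coordinate-attention convolution.

    Pipeline: grouped k x k feature generation (one k^2-filter bank per input
    channel) -> BN+ReLU -> rearrangement into receptive-field spatial layout
    -> directional average pooling (per-row / per-column descriptors over the
    expanded layout) -> shared 1x1 bottleneck -> two sigmoid branches giving
    row and column attention -> multiplicative re-weighting -> a k x k,
    stride-k convolution collapsing each window back to one output position.

    With stride s the output resolution is ceil(H/s) x ceil(W/s); for s=1 the
    resolution is preserved.
    """

    def __init__(self, c1, c2, k=3, s=1, reduction=2, floor=8, cap=48):
        super().__init__()
        if k % 2 == 0:
            raise ValueError("RFCAConv requires an odd window size")
        self.c1, self.c2, self.k, self.s = c1, c2, k, s
        self.generate = nn.Sequential(
            nn.Conv2d(c1, c1 * k * k, k, stride=s, padding=k // 2, groups=c1, bias=False),
            nn.BatchNorm2d(c1 * k * k),
            nn.ReLU(),
        )
        mip = max(floor, min(cap, c1 // reduction))
        self.mip = mip
        self.conv1 = nn.Conv2d(c1, mip, 1, bias=True)
        self.bn1 = nn.BatchNorm2d(mip)
        self.act1 = nn.SiLU()
        self.conv_h = nn.Conv2d(mip, c1, 1, bias=True)
        self.conv_w = nn.Conv2d(mip, c1, 1, bias=True)
        self.collapse = nn.Sequential(
            nn.Conv2d(c1, c2, k, stride=k, bias=False),
            nn.BatchNorm2d(c2),
            nn.SiLU(),
        )

    def pooled_descriptors(self, rf_spatial: Tensor):
        """Directional average pooling over the receptive-field layout."""
        ph = rf_spatial.mean(axis=3, keepdims=True)            # [N,C,kH,1]
        pw = rf_spatial.mean(axis=2, keepdims=True)            # [N,C,1,kW]
        pw = pw.transpose(0, 1, 3, 2)                          # [N,C,kW,1]
        return ph, pw

    def attention(self, rf_spatial: Tensor):
        """Row/column sigmoid attention, broadcastable onto the RF layout."""
        if rf_spatial.shape[1] != self.c1:
            raise ValueError(f"expected {self.c1} channels, got {rf_spatial.shape[1]}")
        ph, pw = self.pooled_descriptors(rf_spatial)
        kh = ph.shape[2]
        y = concat([ph, pw], axis=2)
        y = self.act1(self.bn1(self.conv1(y)))
        ah = self.conv_h(y[:, :, :kh]).sigmoid()               # [N,C,kH,1]
        aw = self.conv_w(y[:, :, kh:]).sigmoid().transpose(0, 1, 3, 2)  # [N,C,1,kW]
        return ah, aw

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.c1:
            raise ValueError(f"RFCAConv configured for {self.c1} channels, got {x.shape[1]}")
        rf = self.generate(x)                                  # [N, C*k^2, H', W']
        rs = rf_to_spatial(rf, self.c1, self.k)                # [N, C, kH', kW']
        ah, aw = self.attention(rs)
        return self.collapse(rs * ah * aw)


class RFCANeck(nn.Module):
    """Bottleneck of C2fRFCA: standard conv then RFCAConv, no residual add."""

    def __init__(self, c):
        super().__init__()
        self.cv1 = ConvBnAct(c, c, 3)
        self.cv2 = RFCAConv(c, c, 3, 1)

    def forward(self, x):
        return self.cv2(self.cv1(x))


# ---------------------------------------------------------------------------
# C2f family
# ---------------------------------------------------------------------------

class Bottleneck(nn.Module):
    def __init__(self, c1, c2, shortcut=True):
        super().__init__()
        self.cv1 = ConvBnAct(c1, c2, 3)
        self.cv2 = ConvBnAct(c2, c2, 3)
        self.add = shortcut and c1 == c2

    def forward(self, x):
        y = self.cv2(self.cv1(x))
        return x + y if self.add else y


class _C2fBase(nn.Module):
    def __init__(self, c1, c2, n, make_block):
        super().__init__()
        if n < 1:
            raise ValueError("C2f requires at least one bottleneck")
        self.c = c2 // 2
        self.cv1 = ConvBnAct(c1, 2 * self.c, 1)
        self.cv2 = ConvBnAct((2 + n) * self.c, c2, 1)
        self.m = nn.ModuleList([make_block(self.c) for _ in range(n)])

    def forward(self, x):
        y = self.cv1(x)
        ys = [y[:, : self.c], y[:, self.c:]]
        for m in self.m:
            ys.append(m(ys[-1]))
        return self.cv2(concat(ys, axis=1))


class C2f(_C2fBase):
    def __init__(self, c1, c2, n=1, shortcut=False):
        super().__init__(c1, c2, n, lambda c: Bottleneck(c, c, shortcut))


class C2fRFCA(_C2fBase):
    """C2f whose bottlenecks are RFCA necks (conv + RFCAConv, no shortcut)."""

    def __init__(self, c1, c2, n=1):
        super().__init__(c1, c2, n, RFCANeck)


# ---------------------------------------------------------------------------
# SPPF and LSKA
# ---------------------------------------------------------------------------

class SPPF(nn.Module):
    def __init__(self, c1, c2, k=5):
        super().__init__()
        if k % 2 == 0:
            raise ValueError("SPPF pooling kernel must be odd")
        c_ = c1 // 2
        self.cv1 = ConvBnAct(c1, c_, 1)
        self.cv2 = ConvBnAct(c_ * 4, c2, 1)
        self.pool = nn.MaxPool2d(k, stride=1, padding=k // 2)

    def branches(self, x):
        y = self.cv1(x)
        p1 = self.pool(y)
        p2 = self.pool(p1)
        p3 = self.pool(p2)
        return [y, p1, p2, p3]

    def forward(self, x):
        return self.cv2(concat(self.branches(x), axis=1))


def _sep_pad(k: int, d: int, horizontal: bool):
    """Asymmetric 'same' padding for a 1-D kernel of size k, dilation d."""
    e = (k - 1) * d + 1
    lo, hi = (e - 1) // 2, e - 1 - (e - 1) // 2
    return ((0, 0), (lo, hi)) if horizontal else ((lo, hi), (0, 0))


class LSKA(nn.Module):
    """Large separable kernel attention.

    A K x K large-kernel depth-wise convolution is decomposed into a
    (2d-1)x(2d-1) depth-wise stage and a ceil(K/d) x ceil(K/d) depth-wise
    stage with dilation d, each further split into consecutive 1-D horizontal
    and vertical kernels, followed by a 1x1 channel-mixing convolution.  The
    resulting map multiplies the input (attention), so shape is preserved.
    """

    def __init__(self, c, K=11, d=3):
        super().__init__()
        if d < 1 or K < 2 * d - 1:
            raise ValueError("LSKA requires d >= 1 and K >= 2d-1")
        self.c, self.K, self.d = c, K, d
        k0 = 2 * d - 1
        k1 = -(-K // d)  # ceil
        self.conv0h = nn.Conv2d(c, c, (1, k0), padding=_sep_pad(k0, 1, True), groups=c, bias=False)
        self.conv0v = nn.Conv2d(c, c, (k0, 1), padding=_sep_pad(k0, 1, False), groups=c, bias=False)
        self.convsh = nn.Conv2d(c, c, (1, k1), padding=_sep_pad(k1, d, True), dilation=(1, d),
                                groups=c, bias=False)
        self.convsv = nn.Conv2d(c, c, (k1, 1), padding=_sep_pad(k1, d, False), dilation=(d, 1),
                                groups=c, bias=False)
        self.conv1 = nn.Conv2d(c, c, 1, bias=False)

    def attention(self, x):
        a = self.conv0v(self.conv0h(x))
        a = self.convsv(self.convsh(a))
        return self.conv1(a)

    def forward(self, x):
        if x.shape[1] != self.c:
            raise ValueError(f"LSKA configured for {self.c} channels, got {x.shape[1]}")
        return x * self.attention(x)


class SPPFLSKA(nn.Module):
    """SPPF with LSKA recalibration after the pooling concat.

    in-conv -> three serial max-pools -> concat(4 branches) -> LSKA ->
    1x1 channel-fusing convolution.
    """

    def __init__(self, c1, c2, k=5, K=11, d=3):
        super().__init__()
        if k % 2 == 0:
            raise ValueError("SPPF pooling kernel must be odd")
        c_ = c1 // 2
        self.cv1 = ConvBnAct(c1, c_, 1)
        self.cv2 = ConvBnAct(c_ * 4, c2, 1)
        self.pool = nn.MaxPool2d(k, stride=1, padding=k // 2)
        self.lska = LSKA(c_ * 4, K, d)

    def forward(self, x):
        y = self.cv1(x)
        p1 = self.pool(y)
        p2 = self.pool(p1)
        p3 = self.pool(p2)
        return self.cv2(self.lska(concat([y, p1, p2, p3], axis=1)))


# ---------------------------------------------------------------------------
# CARAFE
# ---------------------------------------------------------------------------

class CARAFE(nn.Module):
    """Content-aware reassembly upsampling by an integer ratio sigma.

    The kernel-prediction branch compresses channels to Cm, encodes content
    into sigma^2*Kup^2 coefficients per source position, pixel-shuffles them
    to the output resolution and softmax-normalises the Kup^2 weights at every
    output position.  Reassembly forms each output value as the convex
    combination of the Kup x Kup input neighborhood centred at the source
    position, with one kernel shared by all channels.
    """

    def __init__(self, c, cm=60, k_enc=3, k_up=5, sigma=2):
        super().__init__()
        if sigma < 1 or k_up % 2 == 0:
            raise ValueError("CARAFE requires integer sigma >= 1 and odd k_up")
        self.c, self.cm, self.k_enc, self.k_up, self.sigma = c, cm, k_enc, k_up, sigma
        self.compress = nn.Conv2d(c, cm, 1, bias=True)
        self.encoder = nn.Conv2d(cm, sigma * sigma * k_up * k_up, k_enc,
                                 padding=k_enc // 2, bias=True)

    def predict_kernels(self, x: Tensor) -> Tensor:
        """Return the normalised kernel field [N, Kup^2, sigma*H, sigma*W]."""
        if x.shape[1] != self.c:
            raise ValueError(f"CARAFE configured for {self.c} channels, got {x.shape[1]}")
        n, _, h, w = x.shape
        s, k2 = self.sigma, self.k_up * self.k_up
        raw = self.encoder(self.compress(x))                    # [N, s^2*k2, H, W]
        raw = raw.reshape(n, k2, s, s, h, w)
        raw = raw.transpose(0, 1, 4, 2, 5, 3).reshape(n, k2, s * h, s * w)
        return raw.softmax(axis=1)

    def reassemble(self, x: Tensor, kernels: Tensor) -> Tensor:
        """Apply a kernel field to the feature map; returns [N, C, sH, sW]."""
        n, c, h, w = x.shape
        s, k, r = self.sigma, self.k_up, self.k_up // 2
        if kernels.shape != (n, k * k, s * h, s * w):
            raise ValueError(f"kernel field shape {kernels.shape} inconsistent with input")
        xp = x.pad2d(r, r, r, r)
        out = None
        for t in range(k * k):
            ki, kj = divmod(t, k)
            shifted = xp[:, :, ki: ki + h, kj: kj + w]
            up = nn.upsample_nearest(shifted, s)
            term = up * kernels[:, t: t + 1]
            out = term if out is None else out + term
        return out

    def forward(self, x):
        return self.reassemble(x, self.predict_kernels(x))


def carafe_predict_kernels(x, module: CARAFE) -> Tensor:
    return module.predict_kernels(x if isinstance(x, Tensor) else Tensor(x))


def carafe_reassemble(x, kernels, sigma: int, k_up: int) -> Tensor:
    """Functional reassembly (Eq.-style weighted neighborhood sum)."""
    mod = CARAFE.__new__(CARAFE)
    mod.sigma, mod.k_up = sigma, k_up
    x = x if isinstance(x, Tensor) else Tensor(x)
    kernels = kernels if isinstance(kernels, Tensor) else Tensor(kernels)
    n, c, h, w = x.shape
    if kernels.shape != (n, k_up * k_up, sigma * h, sigma * w):
        raise ValueError("kernel field shape inconsistent with input")
    return CARAFE.reassemble(mod, x, kernels)
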