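"""Detector assembly: baseline network, ablation variants, profiling, I/O.

The architecture is a compact anchor-free one-stage detector (n-scale
depth/width multiples 0.33/0.25, strides 8/16/32, distribution-focal box
regression with 16 bins).  Four independently switchable modifications target
small, camouflaged objects:

* ``use_rfca``       — backbone stage-transition convolutions (P2-P5) and all
                       backbone C2f blocks become RFCAConv / C2fRFCA.
* ``use_sppf_lska``  — the SPPF gains an LSKA recalibration stage.
* ``use_bifpn_p2``   — the PAN neck is replaced by a bidirectional pyramid
                       with a high-resolution P2 fusion input and a unified
                       hidden width.
* ``use_carafe``     — nearest-neighbor upsampling in the neck is replaced by
                       content-aware reassembly.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .nn import Tensor, concat
from .nn.tensor import _stable_sigmoid
from .blocks import (BlockConfig, ConvBnAct, C2f, C2fRFCA, RFCAConv, SPPF,
                     SPPFLSKA, CARAFE)

REG_MAX = 16
STRIDES = (8, 16, 32)


@dataclass
class VariantFlags:
    use_rfca: bool = False
    use_sppf_lska: bool = False
    use_bifpn_p2: bool = False
    use_carafe: bool = False

    @classmethod
    def all_on(cls):
        return cls(True, True, True, True)

    @classmethod
    def from_names(cls, names):
        mapping = {"rfca": "use_rfca", "lska": "use_sppf_lska",
                   "bifpn_p2": "use_bifpn_p2", "carafe": "use_carafe"}
        flags = cls()
        for n in names:
            n = n.strip()
            if not n:
                continue
            if n not in mapping:
                raise ValueError(f"unknown variant name: {n!r} (choose from {sorted(mapping)})")
            setattr(flags, mapping[n], True)
        return flags


@dataclass
class ModelConfig:
    num_classes: int = 1
    depth_multiple: float = 0.33
    width_multiple: float = 0.25
    input_size: int = 640
    flags: VariantFlags = field(default_factory=VariantFlags)
    blocks: BlockConfig = field(default_factory=BlockConfig)
    seed: int = 0

    def __post_init__(self):
        if self.input_size % 32:
            raise ValueError("input_size must be divisible by 32")

    def width(self, c_base: int) -> int:
        return max(4, int(round(c_base * self.width_multiple / 4)) * 4)

    def depth(self, n_base: int) -> int:
        return max(1, round(n_base * self.depth_multiple))


@dataclass
class TrainConfig:
    epochs: int = 200
    patience: int = 50
    batch: int = 8
    workers: int = 8
    close_mosaic: int = 10
    lr0: float = 0.01
    lrf: float = 0.01
    momentum: float = 0.937
    weight_decay: float = 0.0005
    warmup_epochs: float = 3.0
    optimizer: str = "SGD"
    seed: int = 0


@dataclass
class Detection:
    box: tuple          # (x1, y1, x2, y2) pixels
    score: float
    class_id: int


# ---------------------------------------------------------------------------
# Sub-networks
# ---------------------------------------------------------------------------

class Backbone(nn.Module):
    def __init__(self, cfg: ModelConfig):
        super().__init__()
        w = cfg.width
        c1, c2, c3, c4, c5 = w(64), w(128), w(256), w(512), w(1024)
        self.channels = (c2, c3, c4, c5)  # P2..P5
        rfca = cfg.flags.use_rfca

        def stage_conv(a, b):
            return RFCAConv(a, b, 3, 2) if rfca else ConvBnAct(a, b, 3, 2)

        def stage_c2f(c, n):
            return C2fRFCA(c, c, n) if rfca else C2f(c, c, n, shortcut=True)

        self.stem = ConvBnAct(3, c1, 3, 2)
        self.conv2, self.c2f2 = stage_conv(c1, c2), stage_c2f(c2, cfg.depth(3))
        self.conv3, self.c2f3 = stage_conv(c2, c3), stage_c2f(c3, cfg.depth(6))
        self.conv4, self.c2f4 = stage_conv(c3, c4), stage_c2f(c4, cfg.depth(6))
        self.conv5, self.c2f5 = stage_conv(c4, c5), stage_c2f(c5, cfg.depth(3))
        bc = cfg.blocks
        self.sppf = (SPPFLSKA(c5, c5, 5, bc.lska_K, bc.lska_d)
                     if cfg.flags.use_sppf_lska else SPPF(c5, c5, 5))

    def forward(self, x):
        x = self.stem(x)
        p2 = self.c2f2(self.conv2(x))
        p3 = self.c2f3(self.conv3(p2))
        p4 = self.c2f4(self.conv4(p3))
        p5 = self.sppf(self.c2f5(self.conv5(p4)))
        return p2, p3, p4, p5


def _upsampler(cfg: ModelConfig, c: int):
    if cfg.flags.use_carafe:
        b = cfg.blocks
        return CARAFE(c, b.carafe_Cm, b.carafe_Kenc, b.carafe_Kup, b.carafe_sigma)
    return nn.Upsample(2)


class PANNeck(nn.Module):
    """Top-down + bottom-up path aggregation (the baseline neck)."""

    def __init__(self, cfg: ModelConfig, channels):
        super().__init__()
        _, c3, c4, c5 = channels
        n = cfg.depth(3)
        self.up5 = _upsampler(cfg, c5)
        self.td4 = C2f(c5 + c4, c4, n)
        self.up4 = _upsampler(cfg, c4)
        self.td3 = C2f(c4 + c3, c3, n)
        self.down3 = ConvBnAct(c3, c3, 3, 2)
        self.out4 = C2f(c4 + c3, c4, n)
        self.down4 = ConvBnAct(c4, c4, 3, 2)
        self.out5 = C2f(c5 + c4, c5, n)
        self.out_channels = (c3, c4, c5)

    def forward(self, feats):
        _, p3, p4, p5 = feats
        t4 = self.td4(concat([self.up5(p5), p4], axis=1))
        o3 = self.td3(concat([self.up4(t4), p3], axis=1))
        o4 = self.out4(concat([self.down3(o3), t4], axis=1))
        o5 = self.out5(concat([self.down4(o4), p5], axis=1))
        return o3, o4, o5


class BiFPNP2Neck(nn.Module):
    """Bidirectional pyramid with a P2 fusion input and unified width.

    The P2 feature is recalibrated by an RFCAConv, stride-2 aligned and summed
    into the bottom-up P3 node; fusion is plain element-wise summation after
    1x1 channel alignment; fusion nodes are refined by C2fRFCA.  Heads remain
    at P3/P4/P5.
    """

    def __init__(self, cfg: ModelConfig, channels):
        super().__init__()
        c2, c3, c4, c5 = channels
        w = cfg.width(240)  # unified hidden width (60 at n-scale)
        self.lat3 = ConvBnAct(c3, w, 1)
        self.lat4 = ConvBnAct(c4, w, 1)
        self.lat5 = ConvBnAct(c5, w, 1)
        self.p2_recal = RFCAConv(c2, w, 3, 1)
        self.p2_down = ConvBnAct(w, w, 3, 2)
        self.up5 = _upsampler(cfg, w)
        self.td4 = C2fRFCA(w, w, 1)
        self.up4 = _upsampler(cfg, w)
        self.td3 = C2fRFCA(w, w, 1)
        self.out3 = C2fRFCA(w, w, 1)
        self.down3 = ConvBnAct(w, w, 3, 2)
        self.out4 = C2fRFCA(w, w, 1)
        self.down4 = ConvBnAct(w, w, 3, 2)
        self.out5 = C2fRFCA(w, w, 1)
        self.out_channels = (w, w, w)

    def forward(self, feats):
        p2, p3, p4, p5 = feats
        l3, l4, l5 = self.lat3(p3), self.lat4(p4), self.lat5(p5)
        t4 = self.td4(self.up5(l5) + l4)
        t3 = self.td3(self.up4(t4) + l3)
        o3 = self.out3(t3 + self.p2_down(self.p2_recal(p2)))
        o4 = self.out4(self.down3(o3) + t4 + l4)
        o5 = self.out5(self.down4(o4) + l5)
        return o3, o4, o5


class Detect(nn.Module):
    """Decoupled anchor-free head: per-level box-distribution + class logits."""

    def __init__(self, channels, nc=1, reg_max=REG_MAX):
        super().__init__()
        self.nc, self.reg_max = nc, reg_max
        c2 = max(16, channels[0] // 4, reg_max * 4)
        c3 = max(channels[0], min(nc, 100))
        self.box = nn.ModuleList()
        self.cls = nn.ModuleList()
        for i, c in enumerate(channels):
            self.box.append(nn.Sequential(
                ConvBnAct(c, c2, 3), ConvBnAct(c2, c2, 3),
                nn.Conv2d(c2, 4 * reg_max, 1, bias=True)))
            self.cls.append(nn.Sequential(
                ConvBnAct(c, c3, 3), ConvBnAct(c3, c3, 3),
                nn.Conv2d(c3, nc, 1, bias=True)))
            # prior-aware bias init stabilises early training
            self.box[i][-1].bias.data[...] = 1.0
            self.cls[i][-1].bias.data[...] = float(
                np.log(5.0 / nc / (640.0 / STRIDES[i]) ** 2))

    def forward(self, feats):
        return [(self.box[i](f), self.cls[i](f)) for i, f in enumerate(feats)]


class DetectionModel(nn.Module):
    def __init__(self, cfg: ModelConfig):
        super().__init__()
        nn.seed_init(cfg.seed)
        self.cfg = cfg
        self.backbone = Backbone(cfg)
        neck_cls = BiFPNP2Neck if cfg.flags.use_bifpn_p2 else PANNeck
        self.neck = neck_cls(cfg, self.backbone.channels)
        self.head = Detect(self.neck.out_channels, cfg.num_classes)
        self.strides = STRIDES

    def forward(self, x):
        x = x if isinstance(x, Tensor) else Tensor(x)
        if x.ndim != 4 or x.shape[1] != 3:
            raise ValueError("expected [N,3,H,W] input")
        if x.shape[2] % 32 or x.shape[3] % 32:
            raise ValueError("input height/width must be divisible by 32")
        return self.head(self.neck(self.backbone(x)))


def build_model(cfg: ModelConfig | None = None, **kw) -> DetectionModel:
    if cfg is None:
        cfg = ModelConfig(**kw)
    return DetectionModel(cfg)


# ---------------------------------------------------------------------------
# Accounting
# ---------------------------------------------------------------------------

def count_parameters(model: nn.Module) -> int:
    """Exact number of trainable parameter elements."""
    return int(sum(p.data.size for p in model.parameters() if p.requires_grad))


def params_millions(model: nn.Module) -> float:
    return round(count_parameters(model) / 1e6, 2)


def estimate_flops(model: DetectionModel, input_size: int | None = None) -> float:
    """GFLOPs of one inference (2 x multiply-accumulates, conv/linear only)."""
    size = input_size or model.cfg.input_size
    was_training = model.training
    model.eval()
    x = Tensor(np.zeros((1, 3, size, size), np.float32))
    with nn.no_grad(), nn.count_macs() as mc:
        model(x)
    if was_training:
        model.train()
    return 2.0 * mc.macs / 1e9


# ---------------------------------------------------------------------------
# Decoding
# ---------------------------------------------------------------------------

_PROJ = np.arange(REG_MAX, dtype=np.float32)


def _softmax_np(z, axis):
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def flatten_raw(raw, strides=STRIDES):
    """Flatten per-level raw outputs to numpy arrays.

    Returns (dist [N,A,4,reg_max], cls_logits [N,A,nc], anchors [A,2] pixels,
    stride_per_anchor [A]).
    """
    dists, clss, anchors, strs = [], [], [], []
    for (box, cls), s in zip(raw, strides):
        n, _, h, w = box.shape
        d = box.data.reshape(n, 4, REG_MAX, h * w).transpose(0, 3, 1, 2)
        c = cls.data.reshape(n, cls.shape[1], h * w).transpose(0, 2, 1)
        yy, xx = np.mgrid[0:h, 0:w]
        pts = np.stack([(xx.ravel() + 0.5) * s, (yy.ravel() + 0.5) * s], axis=1)
        dists.append(d)
        clss.append(c)
        anchors.append(pts.astype(np.float32))
        strs.append(np.full(h * w, s, np.float32))
    return (np.concatenate(dists, 1), np.concatenate(clss, 1),
            np.concatenate(anchors, 0), np.concatenate(strs, 0))


def decode_boxes(dist, anchors, strides):
    """Distribution -> expected ltrb -> xyxy pixel boxes."""
    d = (_softmax_np(dist, -1) @ _PROJ) * strides[None, :, None]
    x1y1 = anchors[None] - d[..., :2]
    x2y2 = anchors[None] + d[..., 2:]
    return np.concatenate([x1y1, x2y2], axis=-1)


def box_iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU between two [*,4] xyxy box arrays."""
    lt = np.maximum(a[:, None, :2], b[None, :, :2])
    rb = np.minimum(a[:, None, 2:], b[None, :, 2:])
    wh = np.clip(rb - lt, 0, None)
    inter = wh[..., 0] * wh[..., 1]
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    return np.where(union > 0, inter / np.maximum(union, 1e-12), 0.0)


def nms(boxes: np.ndarray, scores: np.ndarray, iou_thresh: float) -> list[int]:
    """Greedy non-maximum suppression; returns kept indices, score-sorted."""
    order = list(np.argsort(-scores, kind="stable"))
    keep = []
    while order:
        i = order.pop(0)
        keep.append(int(i))
        if not order:
            break
        rest = np.array(order)
        ious = box_iou_matrix(boxes[i:i + 1], boxes[rest]).ravel()
        order = [int(o) for o, v in zip(rest, ious) if v <= iou_thresh]
    return keep


def decode_and_nms(raw, conf_thresh=0.25, iou_thresh=0.45, strides=STRIDES,
                   max_det=300) -> list[list[Detection]]:
    """Decode raw multi-scale predictions into per-image detection lists."""
    if not (0 <= conf_thresh <= 1 and 0 <= iou_thresh <= 1):
        raise ValueError("thresholds must lie in [0,1]")
    dist, cls_logits, anchors, strs = flatten_raw(raw, strides)
    boxes = decode_boxes(dist, anchors, strs)
    scores = _stable_sigmoid(cls_logits)
    out = []
    for n in range(boxes.shape[0]):
        dets = []
        cls_id = scores[n].argmax(axis=1)
        conf = scores[n].max(axis=1)
        m = conf >= conf_thresh
        b, s, c = boxes[n][m], conf[m], cls_id[m]
        for cl in np.unique(c):
            mm = c == cl
            for i in nms(b[mm], s[mm], iou_thresh):
                x1, y1, x2, y2 = b[mm][i]
                if x2 > x1 and y2 > y1:
                    dets.append(Detection((float(x1), float(y1), float(x2), float(y2)),
                                          float(s[mm][i]), int(cl)))
        dets.sort(key=lambda d: -d.score)
        out.append(dets[:max_det])
    return out


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_weights(model: DetectionModel, path):
    cfg = asdict(model.cfg)
    state = {f"param/{k}": v for k, v in model.state_dict().items()}
    buffers = {}
    for name, m in model.named_modules():
        if isinstance(m, nn.BatchNorm2d):
            buffers[f"buffer/{name}.running_mean"] = m.running_mean
            buffers[f"buffer/{name}.running_var"] = m.running_var
    np.savez(path, __config__=np.frombuffer(json.dumps(cfg).encode(), dtype=np.uint8),
             **state, **buffers)


def load_weights(path) -> DetectionModel:
    try:
        z = np.load(path)
    except (OSError, ValueError) as e:
        raise IOError(f"cannot read checkpoint {path}: {e}") from e
    if "__config__" not in z:
        raise IOError(f"{path} is not a model checkpoint")
    cfg_d = json.loads(bytes(z["__config__"]).decode())
    cfg_d["flags"] = VariantFlags(**cfg_d["flags"])
    cfg_d["blocks"] = BlockConfig(**cfg_d["blocks"])
    model = DetectionModel(ModelConfig(**cfg_d))
    model.load_state_dict({k[len("param/"):]: z[k] for k in z.files if k.startswith("param/")})
    for name, m in model.named_modules():
        if isinstance(m, nn.BatchNorm2d):
            m.running_mean = z[f"buffer/{name}.running_mean"].copy()
            m.running_var = z[f"buffer/{name}.running_var"].copy()
    return model
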