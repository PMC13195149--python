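"""Detection evaluation: greedy matching, precision/recall, AP, mAP, FPS.

Matching is confidence-ordered and single-use: each detection, taken in
descending confidence, claims the unmatched ground truth with the highest
IoU provided it clears the threshold; everything else is a false positive,
and unclaimed ground truths are false negatives.  AP integrates the
monotone-interpolated precision-recall curve on a 101-point recall grid;
mAP@0.5:0.95 averages AP over IoU thresholds 0.50 to 0.95 in steps of 0.05.
"""
from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field

import numpy as np

from .model import Detection, box_iou_matrix

IOU_THRESHOLDS = np.round(np.arange(0.50, 0.96, 0.05), 2)


def iou(a, b) -> float:
    """Intersection-over-union of two (x1,y1,x2,y2) rectangles."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a[2] <= a[0] or a[3] <= a[1] or b[2] <= b[0] or b[3] <= b[1]:
        raise ValueError("degenerate box")
    return float(box_iou_matrix(a[None], b[None])[0, 0])


@dataclass
class MatchResult:
    TP: int
    FP: int
    FN: int
    flags: list[bool]   # per detection, descending confidence

    def __post_init__(self):
        assert self.TP + self.FP == len(self.flags)


@dataclass
class PRCurve:
    recall: np.ndarray
    precision: np.ndarray  # monotone-interpolated P(R)


@dataclass
class EvalReport:
    precision: float
    recall: float
    ap_per_threshold: dict
    map50: float
    map5095: float
    num_classes: int
    per_class_ap50: dict = field(default_factory=dict)

    def to_dict(self):
        return {
            "precision": self.precision, "recall": self.recall,
            "map50": self.map50, "map5095": self.map5095,
            "num_classes": self.num_classes,
            "ap_per_threshold": {str(k): v for k, v in self.ap_per_threshold.items()},
            "per_class_ap50": {str(k): v for k, v in self.per_class_ap50.items()},
        }


def match_detections(dets: list[Detection], gts, iou_thresh: float) -> MatchResult:
    """Greedy confidence-ordered matching against single-use ground truths."""
    if not 0 < iou_thresh <= 1:
        raise ValueError("iou threshold must lie in (0, 1]")
    gts = [np.asarray(g, float) for g in gts]
    order = sorted(range(len(dets)), key=lambda i: -dets[i].score)
    used = [False] * len(gts)
    flags = []
    for i in order:
        best, best_iou = -1, 0.0
        db = np.asarray(dets[i].box, float)
        for j, g in enumerate(gts):
            if used[j]:
                continue
            v = box_iou_matrix(db[None], g[None])[0, 0]
            if v >= iou_thresh and v > best_iou:
                best, best_iou = j, v
        if best >= 0:
            used[best] = True
            flags.append(True)
        else:
            flags.append(False)
    tp = sum(flags)
    return MatchResult(TP=tp, FP=len(flags) - tp, FN=len(gts) - tp, flags=flags)


def precision(m: MatchResult) -> float:
    if m.TP + m.FP == 0:
        warnings.warn("precision undefined (no detections); returning 0", RuntimeWarning)
        return 0.0
    return m.TP / (m.TP + m.FP)


def recall(m: MatchResult) -> float:
    if m.TP + m.FN == 0:
        warnings.warn("recall undefined (no ground truths); returning 0", RuntimeWarning)
        return 0.0
    return m.TP / (m.TP + m.FN)


def _interp_curve(tp_flags: np.ndarray, scores: np.ndarray, n_gt: int) -> PRCurve:
    order = np.argsort(-scores, kind="stable")
    tp = tp_flags[order].astype(float)
    ctp = np.cumsum(tp)
    cfp = np.cumsum(1.0 - tp)
    rec = ctp / n_gt
    prec = ctp / np.maximum(ctp + cfp, 1e-12)
    # monotone (right-to-left running max) interpolation
    for i in range(len(prec) - 2, -1, -1):
        prec[i] = max(prec[i], prec[i + 1])
    return PRCurve(recall=rec, precision=prec)


def average_precision(dets_per_image: list[list[Detection]], gts_per_image: list,
                      iou_thresh: float = 0.5) -> float:
    """AP for one class: 101-point interpolated integral of P(R)."""
    n_gt = sum(len(g) for g in gts_per_image)
    if n_gt == 0:
        raise ValueError("average precision undefined without ground truths")
    scores, flags = [], []
    for dets, gts in zip(dets_per_image, gts_per_image):
        dets = sorted(dets, key=lambda d: -d.score)
        m = match_detections(dets, gts, iou_thresh)
        scores.extend(d.score for d in dets)
        flags.extend(m.flags)
    if not scores:
        return 0.0
    curve = _interp_curve(np.array(flags), np.array(scores), n_gt)
    grid = np.linspace(0, 1, 101)
    p_at = np.zeros_like(grid)
    for i, r in enumerate(grid):
        mask = curve.recall >= r - 1e-12
        p_at[i] = curve.precision[mask].max() if mask.any() else 0.0
    return float(p_at.mean())


def pr_curve(dets_per_image: list[list[Detection]], gts_per_image: list,
             iou_thresh: float = 0.5) -> PRCurve:
    """Dataset-wide interpolated precision-recall curve for one class."""
    n_gt = sum(len(g) for g in gts_per_image)
    if n_gt == 0:
        raise ValueError("PR curve undefined without ground truths")
    scores, flags = [], []
    for dets, gts in zip(dets_per_image, gts_per_image):
        dets = sorted(dets, key=lambda d: -d.score)
        scores.extend(d.score for d in dets)
        flags.extend(match_detections(dets, gts, iou_thresh).flags)
    return _interp_curve(np.array(flags, float), np.array(scores, float), n_gt)


def export_pr_curve(curve: PRCurve, path):
    """Write a PR curve as a two-column CSV for plotting."""
    with open(path, "w") as fh:
        fh.write("recall,precision\n")
        for r, p in zip(curve.recall, curve.precision):
            fh.write(f"{r:.6f},{p:.6f}\n")


def evaluate_detections(dets_per_image, gts_per_image, cls_per_image=None,
                        num_classes: int = 1, pr_iou: float = 0.5) -> EvalReport:
    """Aggregate AP per class per IoU threshold, plus operating-point P/R.

    ``gts_per_image`` holds xyxy boxes; ``cls_per_image`` the class of each
    ground-truth box (defaults to class 0).
    """
    if not gts_per_image or sum(len(g) for g in gts_per_image) == 0:
        raise ValueError("evaluation requires at least one labeled image")
    if cls_per_image is None:
        cls_per_image = [[0] * len(g) for g in gts_per_image]

    ap = {}
    per_class50 = {}
    for c in range(num_classes):
        d_c = [[d for d in dets if d.class_id == c] for dets in dets_per_image]
        g_c = [[g for g, gc in zip(gts, gcs) if gc == c]
               for gts, gcs in zip(gts_per_image, cls_per_image)]
        n_gt_c = sum(len(g) for g in g_c)
        for t in IOU_THRESHOLDS:
            if n_gt_c == 0:
                val = 0.0
            else:
                val = average_precision(d_c, g_c, float(t))
            ap.setdefault(float(t), []).append(val)
            if abs(t - 0.5) < 1e-9:
                per_class50[c] = val

    ap_mean = {t: float(np.mean(v)) for t, v in ap.items()}
    tp = fp = fn = 0
    for dets, gts in zip(dets_per_image, gts_per_image):
        m = match_detections(dets, gts, pr_iou)
        tp, fp, fn = tp + m.TP, fp + m.FP, fn + m.FN
    agg = MatchResult(tp, fp, fn + 0, [True] * tp + [False] * fp)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p, r = precision(agg), recall(agg)
    return EvalReport(precision=p, recall=r, ap_per_threshold=ap_mean,
                      map50=ap_mean[0.5], map5095=float(np.mean(list(ap_mean.values()))),
                      num_classes=num_classes, per_class_ap50=per_class50)


def evaluate_dataset(model_or_dets, samples, conf: float = 0.001, nms_iou: float = 0.7,
                     num_classes: int = 1) -> EvalReport:
    """Evaluate a model (or precomputed per-image detections) on samples.

    ``samples`` is a sequence of ``ImageSample``; ground-truth boxes are taken
    from their labels (converted to pixels).
    """
    from .data import labels_to_xyxy  # local import to avoid a cycle

    if len(samples) == 0:
        raise ValueError("empty dataset")
    gts, clss = [], []
    for s in samples:
        h, w = s.image.shape[:2]
        gts.append(labels_to_xyxy(s.labels, w, h))
        clss.append([l.class_id for l in s.labels])

    if isinstance(model_or_dets, list):
        dets = model_or_dets
    else:
        from . import nn
        from .model import decode_and_nms
        model = model_or_dets
        model.eval()
        dets = []
        with nn.no_grad():
            for s in samples:
                x = s.image.astype(np.float32).transpose(2, 0, 1)[None] / 255.0
                raw = model(x)
                dets.extend(decode_and_nms(raw, conf, nms_iou))
    return evaluate_detections(dets, gts, clss, num_classes=num_classes)


def measure_fps(model, input_size: int = 640, n_warmup: int = 1, n_timed: int = 5) -> float:
    """Wall-clock inference throughput; informational only."""
    if n_timed <= 0:
        raise ValueError("n_timed must be positive")
    from . import nn
    x = np.zeros((1, 3, input_size, input_size), np.float32)
    model.eval()
    with nn.no_grad():
        for _ in range(n_warmup):
            model(x)
        t0 = time.perf_counter()
        for _ in range(n_timed):
            model(x)
        dt = time.perf_counter() - t0
    return n_timed / dt
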