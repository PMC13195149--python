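"""Desk-scale training loop for the detector.

The loss follows the standard anchor-free recipe: task-aligned assignment of
grid anchors to ground-truth boxes, complete-IoU box regression, distribution
focal loss over the 16-bin edge distributions, and binary cross-entropy
classification weighted by the aligned target scores.  The optimiser is SGD
with momentum, decoupled weight decay, linear warmup and linear decay.
"""
from __future__ import annotations

import numpy as np

from . import nn
from .nn import Tensor, concat
from .nn.tensor import _stable_sigmoid
from .model import (DetectionModel, TrainConfig, REG_MAX, box_iou_matrix,
                    decode_boxes)
from .metrics import evaluate_dataset


# ---------------------------------------------------------------------------
# Target assignment (numpy, outside the autodiff graph)
# ---------------------------------------------------------------------------

def task_aligned_assign(pboxes, pscores, anchors, gt_boxes, gt_cls,
                        topk=10, alpha=0.5, beta=6.0, strides=None,
                        center_radius=1.0):
    """Assign anchors to ground truths by the aligned metric s^a * IoU^b.

    Candidates are anchors whose center lies inside the box, or — so that
    targets smaller than the anchor spacing still receive supervision —
    within ``center_radius`` strides of the box center.  The top-k per
    ground truth are kept; anchors claimed by several boxes go to the one
    with the highest aligned metric.  Returns (assigned_gt [A], target_score
    [A]) with -1 for background.
    """
    A = anchors.shape[0]
    assigned = np.full(A, -1, np.int64)
    tscore = np.zeros(A, np.float32)
    G = len(gt_boxes)
    if G == 0:
        return assigned, tscore
    gb = np.asarray(gt_boxes, np.float32).reshape(G, 4)
    in_gt = ((anchors[:, 0:1] > gb[None, :, 0].reshape(1, G)) &
             (anchors[:, 0:1] < gb[None, :, 2].reshape(1, G)) &
             (anchors[:, 1:2] > gb[None, :, 1].reshape(1, G)) &
             (anchors[:, 1:2] < gb[None, :, 3].reshape(1, G)))
    if strides is not None:
        gcx = (gb[:, 0] + gb[:, 2]) / 2
        gcy = (gb[:, 1] + gb[:, 3]) / 2
        near = (np.abs(anchors[:, 0:1] - gcx[None]) < center_radius * strides[:, None]) & \
               (np.abs(anchors[:, 1:2] - gcy[None]) < center_radius * strides[:, None])
        in_gt = in_gt | near
    ious = box_iou_matrix(pboxes, gb)
    sc = pscores[:, np.asarray(gt_cls, np.int64)]
    align = np.where(in_gt, (sc ** alpha) * (ious ** beta), 0.0)

    mask = np.zeros_like(align, bool)
    k = min(topk, A)
    top = np.argpartition(-align, k - 1, axis=0)[:k]
    for g in range(G):
        cand = top[:, g]
        mask[cand[align[cand, g] > 0], g] = True

    best_align = np.zeros(A, np.float32)
    for g in range(G):
        m = mask[:, g] & (align[:, g] > best_align)
        assigned[m] = g
        best_align[m] = align[m, g]

    for g in range(G):
        m = assigned == g
        if not m.any():
            continue
        amax = align[m, g].max()
        imax = ious[m, g].max()
        tscore[m] = align[m, g] / max(amax, 1e-9) * imax

    # minimum-supervision guarantee: a ground truth whose aligned metric
    # vanished everywhere (zero-IoU bootstrap, typical for sub-stride
    # targets) still trains its nearest anchor
    gcx = (gb[:, 0] + gb[:, 2]) / 2
    gcy = (gb[:, 1] + gb[:, 3]) / 2
    for g in range(G):
        m = assigned == g
        if m.any() and tscore[m].max() > 1e-6:
            continue
        d2 = (anchors[:, 0] - gcx[g]) ** 2 + (anchors[:, 1] - gcy[g]) ** 2
        d2 = d2 + (assigned >= 0) * 1e12  # prefer an unclaimed anchor
        a = int(np.argmin(d2))
        assigned[a] = g
        tscore[a] = max(tscore[a], 0.5)
    return assigned, tscore


# ---------------------------------------------------------------------------
# Loss
# ---------------------------------------------------------------------------

def _flatten_tensors(raw, strides):
    """Graph-preserving flatten of per-level outputs."""
    dists, clss, anchors, strs = [], [], [], []
    for (box, cls), s in zip(raw, strides):
        n, _, h, w = box.shape
        dists.append(box.reshape(n, 4, REG_MAX, h * w).transpose(0, 3, 1, 2))
        clss.append(cls.reshape(n, cls.shape[1], h * w).transpose(0, 2, 1))
        yy, xx = np.mgrid[0:h, 0:w]
        anchors.append(np.stack([(xx.ravel() + 0.5) * s, (yy.ravel() + 0.5) * s], 1))
        strs.append(np.full(h * w, s, np.float32))
    return (concat(dists, axis=1), concat(clss, axis=1),
            np.concatenate(anchors).astype(np.float32), np.concatenate(strs))


def _bce_with_logits(z: Tensor, y: np.ndarray) -> Tensor:
    """Elementwise stable binary cross-entropy with logits."""
    absz = z.relu() + (-z).relu()
    return z.relu() - z * Tensor(y) + (1.0 + (-absz).exp()).log()


def _ciou(pb: Tensor, tb: np.ndarray) -> Tensor:
    """Complete IoU between predicted boxes (tensor) and targets (constant)."""
    eps = 1e-7
    tx1, ty1, tx2, ty2 = tb[:, 0], tb[:, 1], tb[:, 2], tb[:, 3]
    px1, py1, px2, py2 = pb[:, 0], pb[:, 1], pb[:, 2], pb[:, 3]
    iw = _minimum(px2, tx2) - _maximum(px1, tx1)
    ih = _minimum(py2, ty2) - _maximum(py1, ty1)
    inter = iw.clip(0, 1e9) * ih.clip(0, 1e9)
    pw, ph = px2 - px1, py2 - py1
    area_p = pw * ph
    area_t = (tx2 - tx1) * (ty2 - ty1)
    union = area_p + Tensor(area_t) - inter + eps
    iou_v = inter / union
    # enclosing box diagonal and center distance
    cw = _maximum(px2, tx2) - _minimum(px1, tx1)
    ch = _maximum(py2, ty2) - _minimum(py1, ty1)
    c2 = cw * cw + ch * ch + eps
    rho2 = ((px1 + px2 - Tensor(tx1 + tx2)) ** 2 + (py1 + py2 - Tensor(ty1 + ty2)) ** 2) * 0.25
    tw, th = tx2 - tx1, ty2 - ty1
    v = (Tensor(np.arctan(tw / (th + eps))) - (pw / (ph + eps)).arctan()) ** 2 * (4 / np.pi ** 2)
    with_alpha = v / ((1.0 - iou_v) + v + eps)
    return iou_v - rho2 / c2 - v * Tensor(with_alpha.data)  # alpha treated as constant


def _maximum(a: Tensor, b):
    b = b if isinstance(b, Tensor) else Tensor(np.asarray(b, np.float32))
    from .nn import where_const
    return where_const(a.data >= b.data, a, b)


def _minimum(a: Tensor, b):
    b = b if isinstance(b, Tensor) else Tensor(np.asarray(b, np.float32))
    from .nn import where_const
    return where_const(a.data <= b.data, a, b)


_PROJ_COL = np.arange(REG_MAX, dtype=np.float32).reshape(REG_MAX, 1)


def detection_loss(raw, targets, strides, nc, box_gain=7.5, cls_gain=0.5, dfl_gain=1.5):
    """Composite detection loss.

    ``targets`` is a list (one per image) of (boxes_xyxy_pixels, class_ids).
    Returns (total loss tensor, dict of detached components).
    """
    dist_t, cls_t, anchors, strs = _flatten_tensors(raw, strides)
    N, A = cls_t.shape[0], cls_t.shape[1]

    pd_boxes = decode_boxes(dist_t.data, anchors, strs)
    pd_scores = _stable_sigmoid(cls_t.data)

    y = np.zeros((N, A, nc), np.float32)
    fg_n, fg_a, fg_w, fg_box = [], [], [], []
    for n in range(N):
        gtb, gtc = targets[n]
        assigned, ts = task_aligned_assign(pd_boxes[n], pd_scores[n], anchors, gtb, gtc,
                                           strides=strs)
        fg = np.nonzero(assigned >= 0)[0]
        for a in fg:
            y[n, a, gtc[assigned[a]]] = ts[a]
        if len(fg):
            fg_n.append(np.full(len(fg), n))
            fg_a.append(fg)
            fg_w.append(ts[fg])
            fg_box.append(np.asarray(gtb, np.float32).reshape(-1, 4)[assigned[fg]])

    denom = max(float(y.sum()), 1.0)
    loss_cls = _bce_with_logits(cls_t, y).sum() / denom

    if fg_n:
        idx_n = np.concatenate(fg_n)
        idx_a = np.concatenate(fg_a)
        w = np.concatenate(fg_w).astype(np.float32)
        tb = np.concatenate(fg_box)
        dist_fg = dist_t[(idx_n, idx_a)]                    # [F,4,reg_max]
        probs = dist_fg.softmax(axis=2)
        d = (probs @ Tensor(_PROJ_COL)).reshape(-1, 4)      # stride units
        s_fg = strs[idx_a].reshape(-1, 1)
        a_fg = anchors[idx_a]
        d_px = d * Tensor(s_fg)
        pb = concat([Tensor(a_fg) - d_px[:, :2], Tensor(a_fg) + d_px[:, 2:]], axis=1)
        ciou = _ciou(pb, tb)
        wt = Tensor(w)
        loss_box = ((1.0 - ciou) * wt).sum() / denom

        # distribution focal loss on the two neighbouring integer bins
        t_ltrb = np.concatenate([a_fg - tb[:, :2], tb[:, 2:] - a_fg], axis=1) / s_fg
        t_ltrb = np.clip(t_ltrb, 0, REG_MAX - 1 - 0.01)
        tl = np.floor(t_ltrb).astype(np.int64)
        wr = t_ltrb - tl
        wl = 1.0 - wr
        logp = (probs + 1e-9).log()
        F = tl.shape[0]
        fi = np.arange(F)[:, None]
        ei = np.arange(4)[None, :]
        ce = -(logp[(fi, ei, tl)] * Tensor(wl.astype(np.float32))
               + logp[(fi, ei, tl + 1)] * Tensor(wr.astype(np.float32)))
        loss_dfl = (ce.mean(axis=1) * wt).sum() / denom
    else:
        loss_box = Tensor(0.0)
        loss_dfl = Tensor(0.0)

    total = loss_box * box_gain + loss_cls * cls_gain + loss_dfl * dfl_gain
    parts = {"box": float(loss_box.data), "cls": float(loss_cls.data),
             "dfl": float(loss_dfl.data), "total": float(total.data)}
    return total, parts


# ---------------------------------------------------------------------------
# Data helpers
# ---------------------------------------------------------------------------

def sample_to_xy(sample):
    """ImageSample -> (CHW float image in [0,1], (boxes_xyxy_px, class_ids))."""
    from .data import labels_to_xyxy
    h, w = sample.image.shape[:2]
    x = sample.image.astype(np.float32).transpose(2, 0, 1) / 255.0
    boxes = np.asarray(labels_to_xyxy(sample.labels, w, h), np.float32).reshape(-1, 4)
    cls = np.asarray([l.class_id for l in sample.labels], np.int64)
    return x, (boxes, cls)


def mosaic4(samples, rng):
    """Online 4-image mosaic (optional augmentation; off for offline runs)."""
    from .data import ImageSample, YoloLabel
    s = samples[0].image.shape[0]
    canvas = np.zeros((2 * s, 2 * s, 3), np.uint8)
    labels = []
    for q, smp in enumerate(samples[:4]):
        oy, ox = (q // 2) * s, (q % 2) * s
        canvas[oy:oy + s, ox:ox + s] = smp.image
        for l in smp.labels:
            labels.append(YoloLabel(l.class_id, (l.cx * s + ox) / (2 * s),
                                    (l.cy * s + oy) / (2 * s), l.w / 2, l.h / 2))
    return ImageSample(canvas[::2, ::2].copy(), labels, samples[0].id + "_mosaic")


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------

def train(model: DetectionModel, train_set, val_set, cfg: TrainConfig,
          evaluator=None, use_mosaic: bool = False, eval_conf: float = 0.05,
          verbose: bool = False):
    """Optimise the model; returns the per-epoch metric history.

    ``evaluator`` maps (model, val_set) -> metric dict; the default runs the
    full mAP evaluation.  Early stopping triggers after ``cfg.patience``
    epochs without improvement in mAP@0.5.
    """
    if len(train_set) == 0 or len(val_set) == 0:
        raise ValueError("train and validation sets must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    opt = nn.SGD(model.parameters(), lr=cfg.lr0, momentum=cfg.momentum,
                 weight_decay=cfg.weight_decay)
    nb = max(1, (len(train_set) + cfg.batch - 1) // cfg.batch)
    warmup_iters = max(1, int(cfg.warmup_epochs * nb))

    if evaluator is None:
        def evaluator(m, vs):
            rep = evaluate_dataset(m, vs, conf=eval_conf, nms_iou=0.7,
                                   num_classes=m.cfg.num_classes)
            return {"P": rep.precision, "R": rep.recall,
                    "map50": rep.map50, "map5095": rep.map5095}

    history = []
    best_map, best_epoch = -1.0, 0
    it = 0
    for epoch in range(cfg.epochs):
        model.train()
        order = rng.permutation(len(train_set))
        epoch_loss, nb_seen = 0.0, 0
        for b0 in range(0, len(order), cfg.batch):
            idx = order[b0:b0 + cfg.batch]
            batch = [train_set[i] for i in idx]
            if use_mosaic and epoch < cfg.epochs - cfg.close_mosaic and len(batch) >= 4:
                batch = [mosaic4([batch[j % len(batch)] for j in range(q, q + 4)], rng)
                         for q in range(len(batch))]
            xs, tgts = zip(*(sample_to_xy(s) for s in batch))
            x = Tensor(np.stack(xs))
            lr_sched = cfg.lr0 * ((1 - epoch / cfg.epochs) * (1 - cfg.lrf) + cfg.lrf)
            opt.lr = lr_sched * min(1.0, (it + 1) / warmup_iters)
            raw = model(x)
            loss, parts = detection_loss(raw, list(tgts), model.strides,
                                         model.cfg.num_classes)
            opt.zero_grad()
            loss.backward()
            _clip_grad_norm(opt.params, 10.0)
            opt.step()
            epoch_loss += parts["total"]
            nb_seen += 1
            it += 1
        metrics = evaluator(model, val_set)
        rec = {"epoch": epoch, "loss": epoch_loss / nb_seen, "lr": opt.lr, **metrics}
        history.append(rec)
        if verbose:
            print(" ".join(f"{k}={v:.4f}" if isinstance(v, float) else f"{k}={v}"
                           for k, v in rec.items()))
        if metrics.get("map50", 0.0) > best_map:
            best_map, best_epoch = metrics["map50"], epoch
        if epoch - best_epoch >= cfg.patience:
            break
    return history


def _clip_grad_norm(params, max_norm):
    total = 0.0
    for p in params:
        if p.grad is not None:
            total += float((p.grad ** 2).sum())
    total = np.sqrt(total)
    if total > max_norm:
        scale = max_norm / (total + 1e-12)
        for p in params:
            if p.grad is not None:
                p.grad *= scale
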