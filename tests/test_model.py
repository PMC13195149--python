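"""Assembly, accounting, decoding, serialization and training contracts."""
import numpy as np
import pytest

import wetbird as wb
from wetbird import nn
from wetbird.nn import Tensor
from wetbird.model import Detection, nms, box_iou_matrix
from conftest import tiny_model


# ---------------------------------------------------------------------------
# Parameter accounting
# ---------------------------------------------------------------------------

def audit_walker(model) -> int:
    """Independent parameter census from layer metadata (not the arrays)."""
    total = 0
    for m in model.modules():
        if isinstance(m, nn.Conv2d):
            kh, kw = m.k
            total += m.c2 * (m.c1 // m.groups) * kh * kw
            if m.bias is not None:
                total += m.c2
        elif isinstance(m, nn.BatchNorm2d):
            total += 2 * m.c
    return total


@pytest.mark.parametrize("flags", [
    wb.VariantFlags(),
    wb.VariantFlags(use_rfca=True),
    wb.VariantFlags(use_sppf_lska=True),
    wb.VariantFlags(use_bifpn_p2=True),
    wb.VariantFlags(use_carafe=True),
    wb.VariantFlags.all_on(),
])
def test_count_agrees_with_audit_walker(flags):
    m = wb.build_model(flags=flags)
    assert wb.count_parameters(m) == audit_walker(m)


def test_single_conv_parameter_count():
    conv = nn.Conv2d(16, 32, 3, bias=True)
    assert sum(p.data.size for p in conv.parameters()) == 3 * 3 * 16 * 32 + 32


def test_parameter_monotonicity_of_variants():
    base = wb.count_parameters(wb.build_model())
    assert wb.count_parameters(wb.build_model(flags=wb.VariantFlags(use_bifpn_p2=True))) < base
    for f in ("use_rfca", "use_sppf_lska", "use_carafe"):
        m = wb.build_model(flags=wb.VariantFlags(**{f: True}))
        assert wb.count_parameters(m) > base, f


# ---------------------------------------------------------------------------
# FLOPs
# ---------------------------------------------------------------------------

def test_flops_closed_form_single_conv():
    class One(nn.Module):
        def __init__(self):
            super().__init__()
            self.c = nn.Conv2d(32, 32, 1, bias=False)

        def forward(self, x):
            return self.c(x)

    m = One()
    with nn.count_macs() as mc:
        m(Tensor(np.zeros((1, 32, 10, 10), np.float32)))
    assert 2 * mc.macs == 2 * 32 * 32 * 10 * 10


def test_flops_quadruple_when_side_doubles():
    m = tiny_model()
    g1 = wb.estimate_flops(m, 160)
    g2 = wb.estimate_flops(m, 320)
    assert abs(g2 / g1 - 4.0) < 1e-6


# ---------------------------------------------------------------------------
# Forward contract
# ---------------------------------------------------------------------------

def test_forward_three_levels_with_pyramid_strides(rng):
    m = tiny_model()
    m.eval()
    with nn.no_grad():
        raw = m(rng.standard_normal((1, 3, 320, 320)).astype(np.float32))
    assert len(raw) == 3
    for (box, cls), s in zip(raw, (8, 16, 32)):
        assert box.shape == (1, 64, 320 // s, 320 // s)
        assert cls.shape == (1, 1, 320 // s, 320 // s)
        assert np.isfinite(box.data).all() and np.isfinite(cls.data).all()


def test_forward_spatial_dims_halve(rng):
    m = tiny_model()
    m.eval()
    with nn.no_grad():
        r640 = m(np.zeros((1, 3, 320, 320), np.float32))
        r320 = m(np.zeros((1, 3, 160, 160), np.float32))
    for (b6, _), (b3, _) in zip(r640, r320):
        assert b6.shape[2] == 2 * b3.shape[2]


def test_forward_deterministic(rng):
    m = tiny_model(seed=5)
    m.eval()
    x = rng.standard_normal((1, 3, 96, 96)).astype(np.float32)
    with nn.no_grad():
        a = m(x)
        b = m(x)
    for (ba, _), (bb, _) in zip(a, b):
        assert np.array_equal(ba.data, bb.data)


def test_forward_rejects_bad_size():
    m = tiny_model()
    with pytest.raises(ValueError):
        m(np.zeros((1, 3, 100, 100), np.float32))


@pytest.mark.parametrize("bits", range(16))
def test_all_flag_combinations_build_forward_backward(bits):
    flags = wb.VariantFlags(*(bool(bits >> i & 1) for i in range(4)))
    m = tiny_model(flags=flags, seed=bits)
    x = Tensor(np.random.default_rng(bits).standard_normal((1, 3, 160, 160)).astype(np.float32), True)
    raw = m(x)
    loss = sum(((b * b).sum() + (c * c).sum() for b, c in raw), Tensor(0.0))
    loss.backward()
    n_with_grad = sum(p.grad is not None and np.isfinite(p.grad).all()
                      for p in m.parameters())
    assert n_with_grad == sum(1 for _ in m.parameters())


# ---------------------------------------------------------------------------
# Decode + NMS
# ---------------------------------------------------------------------------

def _det(box, score, cid=0):
    return Detection(tuple(map(float, box)), float(score), cid)


def brute_force_nms(dets, iou_thresh):
    """All-pairs suppression oracle on a handful of boxes."""
    dets = sorted(dets, key=lambda d: -d.score)
    kept = []
    for d in dets:
        boxes = np.array([k.box for k in kept]) if kept else np.zeros((0, 4))
        if kept and (box_iou_matrix(np.array(d.box)[None], boxes) > iou_thresh).any():
            continue
        kept.append(d)
    return kept


def test_nms_matches_bruteforce_oracle(rng):
    for trial in range(50):
        r = np.random.default_rng(trial)
        n = r.integers(1, 10)
        xy = r.uniform(0, 50, (n, 2))
        wh = r.uniform(5, 25, (n, 2))
        boxes = np.concatenate([xy, xy + wh], 1).astype(np.float32)
        scores = r.random(n).astype(np.float32)
        keep = nms(boxes, scores, 0.5)
        oracle = brute_force_nms([_det(b, s) for b, s in zip(boxes, scores)], 0.5)
        assert sorted(map(tuple, boxes[keep].tolist())) == \
            sorted(tuple(d.box) for d in oracle)


def test_two_overlapping_boxes_keep_higher_score():
    boxes = np.array([[0, 0, 10, 10], [1, 1, 11, 11]], np.float32)
    keep = nms(boxes, np.array([0.6, 0.9], np.float32), 0.3)
    assert keep == [1]


def test_decode_empty_and_singleton(rng):
    m = tiny_model()
    m.eval()
    with nn.no_grad():
        raw = m(np.zeros((1, 3, 96, 96), np.float32))
    none = wb.decode_and_nms(raw, conf_thresh=1.0, iou_thresh=0.5)
    assert none == [[]]
    some = wb.decode_and_nms(raw, conf_thresh=0.0, iou_thresh=0.99)
    assert all(d.score >= e.score for d, e in zip(some[0], some[0][1:]))
    for d in some[0]:
        assert d.box[2] > d.box[0] and d.box[3] > d.box[1] and 0 <= d.score <= 1


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def test_save_load_roundtrip(tmp_path, rng):
    m = tiny_model(flags=wb.VariantFlags(use_rfca=True), seed=2)
    x = rng.standard_normal((1, 3, 96, 96)).astype(np.float32)
    m.eval()
    with nn.no_grad():
        before = m(x)
    path = tmp_path / "w.npz"
    wb.save_weights(m, path)
    m2 = wb.load_weights(path)
    assert wb.count_parameters(m2) == wb.count_parameters(m)
    for (n1, p1), (n2, p2) in zip(sorted(m.named_parameters()), sorted(m2.named_parameters())):
        assert n1 == n2 and np.array_equal(p1.data, p2.data)
    m2.eval()
    with nn.no_grad():
        after = m2(x)
    for (b1, c1), (b2, c2) in zip(before, after):
        assert np.array_equal(b1.data, b2.data) and np.array_equal(c1.data, c2.data)


def test_load_mismatched_flags_raises(tmp_path):
    m = tiny_model(flags=wb.VariantFlags(use_bifpn_p2=True))
    path = tmp_path / "w.npz"
    wb.save_weights(m, path)
    other = tiny_model(flags=wb.VariantFlags())
    with pytest.raises(ValueError):
        other.load_state_dict({k[len("param/"):]: v for k, v in np.load(path).items()
                               if k.startswith("param/")})


def test_load_missing_file_raises(tmp_path):
    with pytest.raises(IOError):
        wb.load_weights(tmp_path / "absent.npz")


# ---------------------------------------------------------------------------
# Training contracts
# ---------------------------------------------------------------------------

def _mini_sets():
    cfg = wb.SceneConfig(image_size=96, n_birds_range=(1, 3),
                         bird_area_fraction_range=(0.003, 0.01), seed=42)
    tr = wb.generate_samples(8, cfg)
    vl = wb.generate_samples(2, wb.SceneConfig(image_size=96, n_birds_range=(1, 3),
                                               bird_area_fraction_range=(0.003, 0.01), seed=43))
    return tr, vl


def test_training_reduces_loss():
    tr, vl = _mini_sets()
    m = tiny_model(seed=0)
    hist = wb.train(m, tr, vl, wb.TrainConfig(epochs=5, batch=4, seed=0),
                    evaluator=lambda *_: {"map50": 0.0})
    assert hist[-1]["loss"] < hist[0]["loss"]


def test_early_stop_with_frozen_metric():
    tr, vl = _mini_sets()
    m = tiny_model(seed=1)
    hist = wb.train(m, tr, vl, wb.TrainConfig(epochs=50, patience=1, batch=4, seed=0),
                    evaluator=lambda *_: {"map50": 0.5})
    assert len(hist) == 2  # improvement at epoch 0, stop after one stagnant epoch


def test_same_seed_reproduces_epoch_loss():
    tr, vl = _mini_sets()
    losses = []
    for _ in range(2):
        m = tiny_model(seed=7)
        hist = wb.train(m, tr, vl, wb.TrainConfig(epochs=1, batch=4, seed=9),
                        evaluator=lambda *_: {"map50": 0.0})
        losses.append(hist[0]["loss"])
    assert losses[0] == losses[1]


def test_empty_dataset_rejected():
    m = tiny_model()
    with pytest.raises(ValueError):
        wb.train(m, [], [], wb.TrainConfig(epochs=1))
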