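# wetbird

Small-object detection toolkit for wetland bird monitoring.

Ecologists monitoring wetland health count and localise birds in fixed-camera
imagery where the targets are tiny (usually < 10% of the image area),
camouflaged against ripple and reed texture, partially occluded, and densely
clustered.  `wetbird` implements a compact one-stage anchor-free detector
augmented with four modules aimed at exactly this regime, together with the
data pipeline, a synthetic-scene benchmark, and the evaluation stack —
runnable end to end on a single CPU with no deep-learning framework
dependency (the package ships its own numpy autograd backend).

## The model

The baseline is an n-scale CSP-style detector (strides 8/16/32, decoupled
head, 16-bin distribution-focal box regression; 3.01 M parameters at one
class).  Four independently switchable modifications target small,
low-contrast objects:

| flag | module | idea | params (M) |
|------|--------|------|-----------|
| — | baseline | | 3.01 |
| `use_rfca` | RFCAConv / C2fRFCA | attention computed per sliding window in receptive-field space, with directional (row/column) pooled descriptors — windows at different positions get different effective filters | 3.13 |
| `use_sppf_lska` | SPPF-LSKA | large separable kernel attention (1-D depth-wise pairs, plain + dilated, then 1×1) recalibrates the pooled-context concat | 3.28 |
| `use_bifpn_p2` | BiFPN-P2 neck | bidirectional fusion at one narrow unified width with a high-resolution P2 input (RFCA-recalibrated, stride-aligned) | 1.99 |
| `use_carafe` | CARAFE | upsampling kernels predicted from content, softmax-normalised per output position: `Y(l) = Σ_{j∈N(l)} w_l(j) X(j)` | 3.14 |
| all four | full model | | **2.50** |

Evaluation follows the standard detection metrics: `P = TP/(TP+FP)`,
`R = TP/(TP+FN)`, and `mAP = (1/m) Σ_i ∫ P(R) dR` with 101-point
interpolation, at IoU 0.5 and averaged over 0.50:0.05:0.95.

See `docs/methods.md` for the full account of each block, the loss, the
synthetic-scene generator and the numerical choices.

## Worked example

Train the reduced-width full-variant detector on 100 synthetic 160×160
wetland scenes and evaluate on 20 held-out scenes:

```python
import wetbird as wb

scene = dict(image_size=160, n_birds_range=(1, 4),
             bird_area_fraction_range=(0.002, 0.01))
train_set = wb.generate_samples(100, wb.SceneConfig(**scene, seed=100))
val_set   = wb.generate_samples(20,  wb.SceneConfig(**scene, seed=101))

model = wb.build_model(wb.ModelConfig(width_multiple=0.0625, input_size=160,
                                      flags=wb.VariantFlags.all_on(), seed=0))
print("trainable parameters:", wb.count_parameters(model))

hist = wb.train(model, train_set, val_set,
                wb.TrainConfig(epochs=30, batch=8, seed=0), verbose=True)
rep = wb.evaluate_dataset(model, val_set, conf=0.05, nms_iou=0.7)
print(f"held-out  P={rep.precision:.3f} R={rep.recall:.3f} "
      f"mAP@0.5={rep.map50:.3f} mAP@0.5:0.95={rep.map5095:.3f}")
```

Output (abridged):

```
trainable parameters: 420535
epoch=0  loss=16.3497 lr=0.0033 P=0.0000 R=0.0000 map50=0.0000 map5095=0.0000
epoch=7  loss=5.4657  lr=0.0077 P=0.1722 R=0.6200 map50=0.2654 map5095=0.0649
epoch=14 loss=3.8751  lr=0.0054 P=0.3714 R=0.7800 map50=0.6411 map5095=0.2080
epoch=21 loss=3.2277  lr=0.0031 P=0.3962 R=0.8400 map50=0.6698 map5095=0.2530
epoch=29 loss=2.8248  lr=0.0004 P=0.5057 R=0.8800 map50=0.7806 map5095=0.3615
held-out  P=0.506 R=0.880 mAP@0.5=0.781 mAP@0.5:0.95=0.361
```

The loss falls steadily and mAP@0.5 climbs well past 0.5 within 30 epochs:
the tiny detector learns to find dark elliptical targets a few pixels wide
against rippled, streaked backgrounds (recall 0.88 at a 0.05 operating
confidence — misses are rare, residual errors are mostly loose
localisation).  `420535` is the parameter count of the width-0.0625 full
variant; at the standard width multiple 0.25 the same architecture has
2,498,916 parameters (2.50 M).

The same workflow is scriptable from the shell:

```bash
wetbird synth data/demo --n 100 --seed 0 --image-size 160
wetbird augment data/demo runs/aug --seed 0
wetbird train data/demo runs/exp --seed 0 --variant rfca,lska,bifpn_p2,carafe
wetbird eval  data/demo runs/exp/weights.npz runs/exp/eval
wetbird profile --variants none,rfca,lska,bifpn_p2,carafe,all
wetbird detect runs/exp/weights.npz data/demo/images/scene_00000.png
```

`wetbird profile` prints the parameter/FLOP table above from freshly built
models.

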