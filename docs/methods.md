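# Methods

This note documents the models, numerical choices and scope of `wetbird` in
the package's own terms: what is computed, under which assumptions, and what
the bundled synthetic benchmark does and does not demonstrate.

## Problem setting

Wetland bird monitoring from fixed cameras produces images in which the
targets are small (typically well under 10% of the image area), low-contrast
against water ripple and vegetation texture, frequently occluded, and
variably dense.  Generic one-stage detectors underperform in this regime for
three architectural reasons: convolutional weight sharing homogenises local
responses exactly where camouflage demands position-specific ones; limited
receptive fields make background texture indistinguishable from target
texture; and aggressive downsampling plus fixed-interpolation upsampling
destroys the few pixels a small target occupies.

`wetbird` implements a compact anchor-free detector (strides 8/16/32,
distribution-focal box regression, decoupled head) together with four
independently switchable counter-measures, and the tooling to train and
evaluate it end to end on synthetic wetland-like scenes.

## The four blocks

**Receptive-field coordinate attention convolution (`RFCAConv`).**  A k x k
grouped convolution (one k²-filter bank per input channel) generates window
features which are rearranged into a receptive-field spatial layout of size
[C, kH, kW], in which each k x k tile holds one sliding window.  Directional
average pooling over the rows and columns of this layout yields two
positional descriptor vectors; a shared 1x1 bottleneck (reduction 2, floored
at 8 and capped at 48 channels) followed by two sigmoid branches produces
row and column attention.  Because the descriptors are indexed by window
*and* intra-window position, the re-weighting is window-specific — different
image locations receive different effective filters, which is the point in
camouflage conditions.  A k x k convolution with stride k collapses each
re-weighted window back to one output position, so stride-1 blocks preserve
resolution and stride-s blocks emit ceil(H/s).  k = 3 everywhere, zero
padding k//2.

**C2f with RFCA necks (`C2fRFCA`).**  The split/concat C2f topology is kept;
each bottleneck becomes a standard 3x3 convolution followed by an RFCAConv,
and the residual add is dropped (the attention path already mixes the
identity information, and removing the shortcut keeps the block cheap).

**Large separable kernel attention (`LSKA`).**  A K x K depth-wise kernel is
decomposed into a (2d-1) x (2d-1) depth-wise stage and a ceil(K/d) x
ceil(K/d) depth-wise stage with dilation d, each split into consecutive 1-D
horizontal and vertical kernels, followed by a 1x1 channel-mixing
convolution; the result multiplies the block input.  Defaults K = 11, d = 3
(1-D kernel lengths 5 and 4); all attention-branch convolutions are
bias-free.  Rank-1 kernels reproduce the equivalent 2-D depth-wise
convolution to 1e-5 (tested), and the gradient footprint of one output
equals the analytic composition of the kernel supports.

**SPPF with LSKA (`SPPFLSKA`).**  The fast spatial-pyramid module (1x1
in-conv, three serial 5x5 max-pools — equivalent to parallel 5/9/13 pools,
an identity the tests check exactly — and branch concat) gains an LSKA
recalibration between the concat and the 1x1 fusion convolution, so
multi-scale context is re-weighted with a large effective receptive field
before channel fusion.

**Content-aware reassembly upsampling (`CARAFE`).**  Channels are compressed
to Cm = 60 by a 1x1 convolution; a 3x3 encoder predicts sigma²·Kup²
coefficients per source position (sigma = 2, Kup = 5); pixel-shuffling and a
softmax over the Kup² axis yield one normalised kernel per *output* position,
shared by all channels.  Each output value is the convex combination of the
Kup x Kup input neighborhood centred at its source position.  Borders use
zero padding, so constant inputs are preserved exactly only where the
neighborhood avoids the border strip (tested as such); reassembly equals a
brute-force weighted-neighborhood sum to 1e-6.

## Assembly and the parameter budget

The baseline uses n-scale multiples (depth 0.33, width 0.25), C2f repeats
3/6/6/3, SPPF at P5, a PAN neck and a decoupled head with 16-bin
distribution-focal regression (the DFL projection is a fixed buffer, not a
trainable parameter).  With one class this yields exactly 3,011,027
trainable parameters (3.01 M).

Flags compose freely (all 16 combinations build, forward and backpropagate;
tested):

* `use_rfca` replaces the four backbone stage-transition convolutions
  (P2-P5) and all backbone C2f blocks; the stem is untouched.  3.13 M.
* `use_sppf_lska` swaps the SPPF; the LSKA acts on the 4-branch concat
  (512 channels at n-scale).  3.28 M.
* `use_bifpn_p2` replaces the neck with a bidirectional pyramid at a unified
  hidden width of 60 channels (scaled by the width multiple): 1x1 laterals
  from P3-P5, a P2 input recalibrated by an RFCAConv and stride-2 aligned
  into the bottom-up P3 node, plain-summation fusion, C2fRFCA refinement at
  the five fusion nodes, and heads kept at P3/P4/P5.  1.99 M — the P2 detail
  path plus narrow unified widths is cheaper than the PAN it replaces.
* `use_carafe` swaps the neck's two nearest-neighbor upsamplers.  3.14 M.
* All four together: 2,498,916 parameters (2.50 M), a 17% reduction against
  the baseline.

Where the architecture leaves internal hyperparameters open, they were fixed
once against this parameter budget and are not training-tuned: the RFCA
bottleneck reduction rule (2, floor 8, cap 48), CARAFE Cm = 60, and the
neck width 60.  The FLOP estimate counts 2 x multiply-accumulates of
convolutions at batch 1 (8.08 G for the baseline at 640 px); pooling,
normalisation and activations are excluded, and FLOPs/FPS are reported as
informational only.

## Numerical infrastructure

No GPU tensor library is assumed: the package carries a small reverse-mode
autograd over float32 numpy arrays (`wetbird.nn`) with im2col-based
convolution (strided/dilated/grouped), max-pooling, nearest upsampling,
batch normalisation and the elementwise operations the blocks need.
Convolution forward is a batched matrix product; the input gradient is
scattered by a slice-add loop over kernel taps.  Primitives are verified
against scipy oracles and numeric differentiation.  Determinism: a single
seed controls weight initialisation, data order and augmentation draws; all
operations are deterministic on CPU, and repeated runs with the same seed
are bitwise identical (tested at the level of epoch-1 loss and of generated
datasets).

## Training

The loss is the standard anchor-free composite, stated here because the
architecture itself does not fix one: task-aligned assignment (candidates
are anchors whose centre lies inside a box *or* within one stride of its
centre; top-10 per target by score^0.5 · IoU^6; conflicts resolved by the
higher metric; target scores normalised per ground truth), complete-IoU box
loss, distribution focal loss
on the two neighbouring integer bins of each edge distance, and
score-weighted binary cross-entropy, with gains 7.5/1.5/0.5.  SGD uses
momentum 0.937 and decoupled weight decay 5e-4 on convolution weights only;
the rate warms up linearly for the first 3 epochs of iterations and decays
linearly from lr0 = 0.01 to lr0·lrf.  Gradients are clipped at global norm
10.  Two details matter specifically for sub-stride targets, whose boxes can
contain no anchor centre at all: the centre-proximity candidate rule above,
and a minimum-supervision guarantee — a ground truth whose aligned metric
vanishes everywhere (the zero-IoU bootstrap regime) is assigned its nearest
anchor with a floored target score of 0.5.  Without the guarantee the
aligned metric score^0.5 · IoU^6 is self-extinguishing: once predictions
collapse to background, every candidate has zero IoU, the target stops
supervising anything, and the collapse is permanent.  Defaults in
`TrainConfig` (200 epochs, patience 50 on mAP@0.5, batch 8, 640 px) mirror
the intended full-scale protocol; desk-scale runs override them explicitly.  A 4-image mosaic is available but off by default; the
offline pipeline below is the reference augmentation.

## Data pipeline

Labels are plain-text `class cx cy w h` rows normalised to image size;
parsing is strict (range violations and non-numeric tokens name the
offending line).  Splitting is a seeded 7:2:1 permutation with round(n·ratio)
for validation and test and the remainder to train, so 2000 images give
1400/400/200.  Offline augmentation produces exactly two perturbed copies
per training image — rotation in [-15°, 15°] about the image centre (same
canvas, zero fill, bilinear), then noise, then brightness in [0.7, 1.3] —
alternating Gaussian noise (sigma in [5, 15] on the 8-bit scale) with
salt-and-pepper (density in [0.002, 0.01]) deterministically, which makes
the 1:1 family ratio exact rather than merely expected.  Boxes follow
rotation by corner transformation and axis-aligned hull, are clipped to the
canvas, and are dropped when the clipped area falls below 20% of the
original — a choice made for small-target integrity; whether labels should
rotate at all is not standardised, and the 20% threshold is this package's
convention.

## Synthetic scenes

The generator emulates the regime the detector targets: backgrounds are
band-limited noise plus sinusoidal ripple fields (water), anisotropic
smoothed-noise streaks (vegetation) or vertical gradients with a warm tint
(low sun); targets are dark rotated ellipses with a head blob, area
fractions log-uniform in [0.0004, 0.01] at 640 px defaults, 3-20 per scene,
with optional vegetation streaks drawn over a target after rendering
(labels keep the full amodal extent).  Placement rejects candidates whose
centre falls inside an existing target's box and raises a generation error
when a scene is too crowded to place, while still allowing partial overlap.
Every label is the exact bounding box of the rendered support, so the
generator is its own ground truth (verified to 1 px by re-rendering masks
from recorded geometry).  Per-image seeds are spawned from the dataset seed,
so any single image is regenerable in isolation.

What the synthetic benchmark does *not* show: real plumage texture, motion
blur, compression artefacts, inter-class confusion (gulls vs. herons), or
annotation noise.  Passing the suite demonstrates that the implementation is
internally correct and trainable, not that field accuracy figures transfer.

## Evaluation

Matching is greedy in descending confidence with single-use ground truths
and an IoU floor; precision TP/(TP+FP) and recall TP/(TP+FN) return 0 with a
warning when undefined.  AP integrates the monotone-interpolated
precision-recall curve on a 101-point recall grid; mAP@0.5:0.95 averages
thresholds 0.50:0.05:0.95 and classes.  Metric sweeps use confidence 0.001
and NMS IoU 0.7; user-facing detection uses 0.25/0.45.  All metric code is
cross-checked against brute-force matchers and hand-integrated curves on
small instances.

## Desk-scale problem sizes

The shipped checks run on one CPU with scaled-down sizes chosen once: the
pipeline-count check uses 2000 scenes at 96 px (the counts are
size-independent); the learnability check trains the full-variant model at
width multiple 0.0625 on 100 scenes of 160 px (1-4 targets, area fractions
0.002-0.01 so that targets remain resolvable by the stride-8 head — at
smaller canvases the boxes fall between anchor centres, which is precisely
the small-object failure mode the P2 fusion mitigates at full scale) for 30
epochs, and requires strictly decreasing loss plus mAP@0.5 >= 0.5 on 20
held-out scenes for a majority of three seeds.

## Known limitations

* The numpy backend is single-threaded and CPU-bound; full-scale 640-px
  training is out of its intended use.
* Heads stay at P3/P4/P5 in every variant; objects much smaller than the
  stride-8 grid must rely on the P2 fusion path rather than a dedicated P2
  head.
* The LSKA-augmented SPPF variant costs 3.28 M parameters with the canonical
  decomposition; the 512->512 channel-mixing convolution alone contributes
  0.26 M, which bounds how light any faithful configuration can be.
* CARAFE's zero-padded borders slightly attenuate features in the outermost
  sigma·(Kup//2) output rows/columns.
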