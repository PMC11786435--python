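# Methods

## Architecture

SWNet is represented as an explicit node/edge graph (`NetworkGraph`) so
that structural audits — layer counting, parameter accounting, shape
propagation — are pure graph computations, independent of any weights.
The graph executor (`GraphModel`) instantiates one engine layer per
parametric node and handles the fan-out at stage inputs (four branches
consume the same tensor) with gradient accumulation on the way back.

Three conventions pin the published arithmetic down exactly:

* **Branch wiring.** Each stage's four branches all consume the stage
  input: the stem convolution's output for stage 1, the post-concatenation
  batch norm for stages 2–4.  Each branch is a stride-1 convolution
  followed by a stride-2 convolution at the stage's branch width.  This is
  the only wiring consistent with both the listed activation resolutions
  (224→112→56→28→14) and the convolutional parameter total of 9,368,192
  (9,364,320 weights + 3,872 biases).
* **Convolution biases are kept** even though every convolution is
  followed by batch normalization (which makes the bias redundant — its
  gradient through a training-mode batch norm is exactly zero).  The
  parameter total only reproduces with biases included.
* **Layer counting.**  The 113-layer total counts convolution (33), batch
  norm (37 = 33 post-conv + 4 post-concat), ReLU (33), concatenation (4),
  global average pooling (1), fully connected (3) and dropout (2) nodes;
  the input node and the terminal softmax are not counted separately.

The fully connected stack is FC 300 → dropout 0.5 → FC 64 → dropout 0.5 →
FC `num_classes`, with no rectifiers between the FC layers (the rectifier
count is exhausted by the convolutions).  All convolutions are 3×3 with
same-padding 1; stride-2 convolutions use the same padding so even sides
halve exactly.  Batch-norm epsilon is 1e-5 and running-statistics momentum
0.1; weights are He fan-in initialized from a seeded generator.  The
`width_multiplier` scales stage widths as ⌈m·{32,64,128,256}⌉; FC sizes do
not scale.

## Numerical engine

The engine is pure NumPy with channels-last activations.  Convolutions use
the shift-and-matmul formulation: the 3×3 kernel acts as nine shifted
slices of the padded input times (C_in × C_out) weight slabs, so forward
and backward passes are BLAS matrix products and strided slice arithmetic
with no im2col buffer and no scatter loops.  Every backward formula
(convolution, batch norm in both training and eval mode, ReLU, dropout,
concatenation split, pooling broadcast, dense, softmax Jacobian) is checked
against central finite differences through the full DAG in float64
(`tests/test_engine.py`); default training runs in float32.

Training is mini-batch SGD with classical momentum 0.9 on the softmax
cross-entropy.  Defaults follow the published configuration — learning
rate 0.001, 100 epochs — with batch size 32 where the publication is
silent.  There are no schedules, no early stopping and no validation-based
selection; a non-finite loss aborts with a diagnostic.  One seed drives
initialization, shuffling, dropout masks and augmentation, so a fixed
configuration is bit-reproducible on one device.  Optional augmentation
(rotation ±30°, isotropic scaling 0.8–1.2× with center crop/edge pad) is
off by default.

## Metrics

The confusion matrix takes malignant as the positive class (labels encode
benign = 0, malignant = 1).  F1 is implemented as the standard harmonic
mean 2PR/(P+R); the published precision/recall/F1 triple (100%, 99.90%,
99.95%) satisfies exactly this form.  Zero-denominator rates are reported
as 0 with a logged warning rather than NaN, so degenerate evaluations stay
comparable.

## Grad-CAM and the saliency-mass statistic

Gradients are taken on the pre-softmax class score (standard Grad-CAM);
the target class defaults to the prediction.  Channel weights are spatial
means of the score gradient; the rectified weighted sum is bilinearly
upsampled and max-normalized per image, with an explicit flag for
identically-zero maps.  The default nine-layer audit set is the stem
convolution, the last convolution of each stage, and the four
post-concatenation batch norms.  `saliency_mass(heatmap, mask)` — the
fraction of total map mass inside a boolean region — turns heatmaps into a
comparable scalar; it is additive over a mask and its complement.

## Feature fusion

Two modes: (1) concatenation of global-average-pool feature vectors from
several source models/datasets, standardized per dimension on the training
split and classified by a multinomial-logistic (softmax) head; (2) dataset
pooling, i.e. training the network end-to-end on the union manifest with
source tags retained.  Canonical-correlation and SVM fusion variants are
deliberately out of scope.  Fused vectors carry provenance spans
(source, offset, length) that reconstruct each component exactly.

## Synthetic data generator

The generator emulates the features of dermoscopy data this package's
analyses need and nothing more:

* **Lesion morphology (the class signal).**  Lesions are radial polygons
  r(θ) = R·(1 + a·Σ c_k sin(kθ + φ_k)) on a skin-toned canvas.  Benign
  lesions use low boundary-perturbation amplitude a ∈ [0.02, 0.08] and a
  single near-base-pigment patch; malignant lesions use a ∈ [0.25, 0.45]
  and 3–4 patches drawn from distinct clinical variegation pigments
  (black, blue-gray, red, dark brown).  The amplitude ranges do not
  overlap, so a threshold on the generative parameter recovers every
  label — the labels are information-bearing by construction, and the
  signal survives stride-2 downsampling.
* **Confounds (the bias dial).**  A multiplicative cosine-falloff vignette
  (near-black outside the inner radius, default 0.70 of the half-side)
  emulates dermatoscope optics; hair is rendered as 1–3 px dark quadratic
  arcs placed one-per-cell on a jittered grid, which keeps n strokes as at
  least n disjoint components.  Both are applied with per-class
  probabilities, making the label↔artifact phi coefficient a controlled
  quantity (e.g. (0.1, 0.9) on balanced classes gives expected phi 0.8).
* **Skin tone** is a base-canvas color from five anchors, recorded as a
  covariate and never used as a label signal.

What the generator does *not* model: photorealistic texture, real
dermoscopy intensity statistics, lesion-size/label correlations, or image
noise beyond a small Gaussian perturbation.  Passing tests therefore show
that the pipeline detects and mitigates a *constructed* shortcut under
controlled correlation, not that any particular real dataset is biased.

## Desk-scale study sizes

The stochastic properties run on a width-1/8 network at 64×64 input
(resolutions 64→32→16→8→4; global-average-pool width 128): one 15-epoch
run on 200 images takes about a minute on one CPU.  The learning property
trains on 200 confound-free images; the label-shuffled control uses 100
images at 32×32 for 8 epochs across three seeds, evaluated on a fresh
80-image set against the binomial chance band.  The bias experiment uses
two 100-image sources with perfectly opposed vignette↔label coupling
(phi = +1 and −1), a 60-image confound-free test set, and 24 vignetted
probe images scored at the final post-concatenation batch norm against the
geometric vignette-ring mask.

## Known limitations

* The engine is single-threaded NumPy; full-width 224×224 training is out
  of desk-scale reach (the full network is still executable — the
  acceptance script runs a forward pass through it).
* Batch norm couples examples within a batch, so per-batch statistics make
  training-mode outputs batch-size dependent (eval mode is not).
* The synthetic lesions are stylized; conclusions about real dermoscopy
  data require real images.
* `ham10000_relabel` honors exactly the seven documented dx codes and
  raises on anything else (e.g. "vasc"), by design.
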