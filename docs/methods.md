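# Methods

## Problem and model

A fundus photograph shows the retina through a circular optical field. The
optic disc — a bright, slightly elliptical region where the optic nerve
exits — lies nasally, i.e. on opposite sides of the image midline in left
and right eyes, while the macula sits at the center of a macula-centered
photograph. Eye laterality is therefore a binary classification problem whose
discriminative signal is the position of the disc relative to the macula and
the fundus rim.

The classifier is a convolutional network ending in global average pooling
(GAP) and a single affine layer producing two logits and, after softmax, a
probability vector (P1, P2) for (left, right). The GAP head is a structural
requirement: it makes the class activation map (CAM) well defined as
R(x,y) = Σₖ wₖᶜ·fₖ(x,y), the class-weight-weighted sum of the last
convolutional layer's feature maps. Ties (P1 = P2) resolve to LEFT, a fixed
documented convention.

Two backbones are provided:

* `tiny` — four conv/BatchNorm/ReLU blocks (8, 16, 32, 32 channels) with
  2×2 max-pooling after the first two blocks, then GAP and the affine head.
  The last conv layer therefore works on a quarter-resolution grid with a
  ~26-pixel receptive field at input side 64. The receptive field is sized
  deliberately: wide enough to cover the optic disc together with its rim
  surround (a locally mirror-asymmetric pattern), but narrower than the
  disc-to-macula distance. Wider fields let the network discriminate with
  macula-anchored features — the macula sits at the rotation center and is
  invariant under the augmentation, making those features easy to learn —
  which drags the CAM toward the image center and away from the disc.
* `inception_v3` — the standard Inception-V3 topology (stem, 3 × module A,
  reduction A, 4 × module B, reduction B, 2 × module C: 11 inception modules)
  at 299×299, with a 2-way GAP head. Batch normalization is folded away
  (plain conv + ReLU); at two classes the topology, not per-layer
  normalization, is what the backbone contributes. It is provided for
  architectural fidelity and is exercised in tests only as a forward pass.

All layers (im2col convolution, batch normalization, max/average pooling,
channel-concatenated branches, GAP, affine) carry hand-written backward
passes in numpy (`_nn.py`), so training is deterministic on any CPU given a
seed. Batch normalization in the `tiny` backbone was found necessary for
stability: plain conv stacks collapse to chance-level constant predictions
at the aggressive initial learning rate the self-adaptive schedule starts
from (l₀ = 0.1 with momentum 0.9).

## Training

Mini-batch SGD with momentum 0.9 minimizes mean categorical cross-entropy
plus an L2 penalty λ·Σw² (λ = 10⁻⁴; convolution and affine weights only,
biases and BN parameters exempt). True-class probabilities are clamped at
10⁻⁷ before the logarithm. Per-image augmentation applies a rotation about
the image center uniform on [−30°, +30°] followed by an integer horizontal
shift with magnitude uniform on {0..10} px and random sign; vacated pixels
are black. Momentum and λ are this package's choices (standard values); the
optimizer family, the loss, and the augmentation bounds are fixed inputs of
the method. Validation loss — the controller's Loss signal — includes the
L2 term, matching the objective the training loop reports.

## The self-adaptive controller

The controller (`adaptive_controller`) is a pure state machine over per-epoch
validation metrics; it exchanges only plain values with the training loop
and replays any metric stream to an identical action sequence.

Monitor: M = (1 − Accuracy)·Loss. Defaults: l₀ = 0.1, α = 0.5, k = 5,
M_threshold = 0.005, accuracy gate 0.95, loss gate 0.1, reload period 10,
minimum learning rate 10⁻⁵.

Semantics that the method statement leaves open, resolved here:

* The alert compares every epoch to the **fixed baseline** (the monitor of
  the last strictly improving epoch), not to consecutive predecessors; the
  comparison is non-strict (≥) exactly as in the update rule. One epoch
  below the baseline cancels the alert; stagnation afterwards re-arms it
  against the then-current previous monitor.
* After a reduction the alert closes and comparison resumes from the current
  epoch; chained reductions occur if non-improvement persists.
* M_best is initialized to M_threshold so the chained pool condition
  Mₙ ≤ M_best ≤ M_threshold is satisfiable from an empty pool; with an
  infinite initial M_best it could never hold. Pool ties (Mₙ = M_best)
  replace the snapshot, keeping the most recent weights.
* The learning rate is floored at 10⁻⁵ to avoid underflow in long runs; a
  reload restores weights only and resets optimizer momentum.
* Within one epoch, actions are emitted in the fixed order save → reduce →
  reload, so a snapshot saved at a reload boundary can be reloaded
  immediately. Reload epochs are counted globally (epoch mod 10).

With the default gates, M_threshold = (1 − 0.95)·0.1 is exactly the
supremum of monitors that can pass — verified by grid search in the tests.

## Preprocessing

`crop_dark_border` sums, per row and column, the per-pixel maximum channel
and keeps lines whose sum exceeds 2% of the peak line sum (robust to
dark-but-nonzero sensor noise; the statistic realizes "pixel summation"
without an externally fixed threshold). `to_square` center-crops the longer
dimension, removing the odd extra pixel from the trailing side. `resize` is
bilinear with the half-pixel-centered convention. `circular_mask` zeroes
pixels beyond mask_ratio (default 0.95) of half the post-crop side; after
border cropping the fundus circle spans the square, so no separate circle
fit is needed. Enhancement is applied after normalization.

CLAHE is implemented in-package (`clahe_channel`): per-tile histograms on an
8×8 grid clipped at `clahe_clip` (default 2.0) times the uniform level with
uniform redistribution of the excess, per-tile CDF mappings, and bilinear
interpolation between the four surrounding tile centers. The tile grid is
laid out symmetrically, so the operator commutes with horizontal mirroring
up to rounding at any image size — a contract the scikit-image
implementation, which anchors its tile grid at the top-left corner, does not
satisfy; a test cross-checks the two implementations (correlation ≈ 0.996
on the equalized field). CLAHE runs on the CIELAB luminance channel only,
preserving hue. LSACR uses the Gaussian-background-subtraction form
clip(4·I − 4·G_σ(I) + 128) with σ = side/30 per channel (the cited
local-space-average-color literature's constants). GRAY is Rec.601 luma
replicated to three channels.

## Synthetic data

The generator (`synth_fundus`) emulates macula-centered 45° photographs:
a fundus disc of radius h/2 on a black landscape canvas (black side bars as
with real camera sensors), base color ≈ (200, 90, 40) with Gaussian pixel
noise σ = 8 (so the enhancement comparison has realistic work to do), an
overexposed rim annulus (+20% brightness beyond 95.5% of the radius), a
Gaussian-darkened macula at center (radius fraction 0.12), a bright
elliptical disc displaced 0.55 fundus radii toward the laterality side
(radius fraction 0.18), and six quadratic-Bezier vessel arcs leaving the
disc. Right-eye images are the exact horizontal mirror of the left-eye
rendering for the same seed, so the two classes are mirror populations by
construction and the mirror-consistency property is exact.

Poor-quality images (for the exclusion rule: ≥50% of the field obscured or
the disc only partially visible) are rendered by a seeded choice between a
black half-plane past the center or a strip occluding the outer half of the
disc; the recorded obscured/visible fractions are measured from the actual
masks, not assumed.

What the generator does **not** emulate: retinal pathology, camera color
profiles, vignetting, focus/illumination gradients, disc-size and
disc-position variability, or torsional rotation of the eye. Passing tests
therefore demonstrate that the pipeline's mechanics are correct and that the
laterality cue the generator encodes is recoverable — not that the trained
tiny model would transfer to clinical photographs.

## Evaluation

Left eye is the positive class. Wilson score intervals (95%) for accuracy,
sensitivity and specificity; ROC by threshold sweep over P1 (an image is
called LEFT when P1 ≥ t; reported labels use t = 0.5 with the LEFT
tie-break); AUC as the trapezoid under the sweep, which equals the
Mann-Whitney probability with ties counted ½ (asserted against brute-force
pairwise enumeration in the tests); DeLong variance for the AUC interval,
clipped to [0, 1]. Reports round to 4 decimals but always carry the raw
counts.

## Problem sizes and defaults

Training-based tests and examples run at desk scale: 400 clean synthetic
images on a 256×192 canvas, CLAHE enhancement, tiny backbone at input side
64, batch 32, 20 epochs, three seeds. The preprocessing geometry contract is
verified at the three native camera formats (2560×1920, 3280×2480,
4700×3100). Full-scale settings (299×299 input, Inception-V3 backbone) are
configuration values, not code changes.

## Known limitations

* The numpy engine is single-threaded per operation and desk-scale by
  design; Inception-V3 is trainable in principle but impractically slow.
* CLAHE equivariance is exact only up to floating-point rounding (≤2
  intensity levels) near tile centers of odd-sized grids.
* The generator's laterality convention (disc toward the label side) is
  internal; only pixel/label consistency matters for the learning task.
* DeLong intervals degenerate to zero width at AUC = 1 on separable data —
  expected behavior of the estimator, not an error.
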