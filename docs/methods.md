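# Methods

This note documents the models, the synthetic-data assumptions, the
parameter defaults and the numerical choices behind `semgdet`, in the
spirit of a package methods appendix.  It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself
compute.

## 1. Signal model of the synthetic generator

Each record is four muscle channels (biceps brachii, triceps brachii,
extensor carpi ulnaris, extensor carpi radialis) sampled at 2000 Hz
for 5 s.  Channel `ch` of a record with motion class `k` and angle
fraction `a ∈ [0,1]` is

    x_ch(t) = g_{k,ch} · A·a · e(t) · n_ch(t) + m(t) + d(t) + ε(t)

* `n_ch(t)` — Gaussian white noise band-pass filtered to 20–450 Hz
  (order-4 Butterworth, forward–backward), peak-normalised.  This is a
  standard surrogate for the sEMG interference pattern: it has the
  right second-order statistics and a controllable spectrum, but no
  motor-unit structure.
* `e(t)` — trapezoidal burst envelope on [1 s, 4 s] with 10 % rise and
  fall, so the default 2–4 s analysis crop lands inside the plateau.
* `g` — class-conditional gain matrix: elbow classes load on
  biceps/triceps, wrist flexion/extension on extensor carpi ulnaris,
  pronation/supination on extensor carpi radialis, mirroring which
  channels the channel-reduction experiments retain.
* Antagonist pairs (flexion vs extension) share gains but differ in the
  *sign of a half-wave skew* applied to the dominant channel: positive
  half-waves are scaled by (1+α) and negative by (1−α) with α = ±0.6.
  A pure sign flip of a zero-mean noise carrier would be statistically
  invisible; the skew instead makes the extreme excursion point up for
  one class and down for its antagonist, which is what renders as
  "opposite amplitudes" and what the box ordinate encodes.  The skewed
  carrier is re-band-limited afterwards, because rectification leaks
  energy below 20 Hz; the generator guarantees ≥ 95 % of carrier power
  inside 20–450 Hz (tested).
* Contaminants: 50 Hz mains sinusoid (0.05 mV), slow sinusoidal drift
  (0.08 mV at 0.3 Hz), broadband floor (0.01 mV).  Amplitudes are in
  arbitrary millivolt units — the protocol never states absolute
  voltages, so all downstream code is scale-invariant (the image
  amplitude axis is calibrated per dataset, not per record).

The plateau amplitude is linear in the angle fraction, which is the
ground truth the angle decoder must recover.  Per-record seeds are
`master_seed + record_index`, so datasets are reproducible
record-by-record.

**What the generator does not emulate**: motor-unit action potentials
and recruitment, fatigue, electrode shift, inter-subject variability,
movement artifacts.  Passing tests therefore demonstrate that the
pipeline's mechanics are correct and self-consistent, not that the
classifier would reach any particular accuracy on human recordings.

## 2. Preprocessing

Order-4 Butterworth band-pass 20–450 Hz and a Q = 30 IIR notch at
50 Hz, both applied forward–backward (zero phase).  The protocol fixes
only the corner frequencies; order and Q are package choices surfaced
in config (`filter.order`, `filter.notch_q`).  Both filters are LTI,
so they commute — exactly in steady state, and only approximately near
the signal ends where the high-Q notch rings for a couple of seconds
(the tests compare interiors).  The active-window crop defaults to
[2 s, 4 s], the steady part of the movement.

## 3. Channel evaluation and fusion

`evaluate_channel_subsets` reproduces the comparative-experiment
procedure: train one classifier per channel subset, report
verification accuracy and wall time.  The budget classifier is
multinomial logistic regression on per-channel RMS, mean-absolute
value and skewness — deliberately lightweight so the comparison runs
in seconds; it is a stand-in for the image classifier, adequate
because the synthetic classes are separable in exactly those
statistics (gain pattern → RMS/MAV; antagonist skew → skewness).
Fusion is weighted linear summation with weights constrained to sum
to 1; the default is uniform over the four retained channels, since
the protocol states the constraint but not the weights.  Fused-record
peak metadata is re-measured on the fused trace inside the burst
window.

## 4. Imaging and labels

Images are W×W (448 default, 160 in the demo profile) white-background
plots of the fused trace: time → x linearly across the width,
amplitude → y linearly about the centre baseline row, y increasing
downward, 2-px black line, no axes.  The full-scale amplitude
(`amp_range`) is fixed per *dataset* so that equal voltages land on
equal rows in every image — without this, the box ordinate would not
be comparable across images and angle decoding would be meaningless.

The auto-label covers the action: x from burst start to burst end, y
from the baseline row to the row of the signed peak excursion.  Labels
are stored centre + half-extents in array order `[cx, cy, half_h,
half_w]` (half_h = distance from the top edge of the box to its
centre) and serialized to JSON with keys `{image_path, class_id, cx,
cy, half_h, half_w}`.  Rounding is clamped so boxes stay strictly
inside the image.

Augmentation (horizontal flip, shift, colour jitter, rotation, random
scale) shares one forward affine map between pixels and label corners,
so the transformed label always brackets the transformed pixels
(tested against brute-force mask transforms at IoU ≥ 0.95).  Flip
reverses time but remains label-consistent.  Mosaic composition is
deliberately rejected.

## 5. MGNet

The block table (stride-2 first conv; bottlenecks t=1/16, 6/24×2,
6/32×3; Ghost stage to 64 channels ×4 at stride 2; bottlenecks 6/96×3,
6/128×3, 6/160×3, 6/320; 1×1 conv to 1280; 7×7 average pool; K=6) is
declarative (`BlockSpec`) and audited: a forward pass at 448×448
checks every row's feature-map size, and per-kernel parameter counts
are exposed (`kernel_parameter_table`).  Package conventions where the
protocol is silent: ReLU6 and batch normalization after every
convolution, inverted-residual skips at stride 1 with equal channel
counts, no expansion convolution when t = 1, Ghost ratio 2, the Ghost
stage downsampling with a final stride-2 depthwise convolution, and a
regression head of two linear outputs from the pooled vector.  The
printed grand-total parameter count of the reference table is not
asserted because it is inconsistent with the sum of its own rows; the
audit reports computed sums instead.

A `width_multiplier` scales all channel counts (kept even for the
Ghost split).  Classifier training: Adam at 3e-4, batch 16, up to 3000
epochs, learning rate halved after 3 consecutive epochs without
improvement, checkpoints (weights + batch-norm running statistics +
architecture hash) every 200 epochs.  Scaled-down runs in the tests
use multiplier 0.25, 64-px inputs and ≤ 10 epochs — sizes chosen so a
training run is seconds, which is all a correctness test needs.

## 6. Detector

Backbone taps at strides 16 and 32 feed 1×1 lateral projections; the
top-down path upsamples the deep scale, splices and fuses with a 3×3
convolution; the bottom-up path downsamples the fused shallow scale
with a stride-2 convolution, splices with the deep lateral and fuses
again.  Each fused scale gets a 1×1 head emitting, per anchor,
(tx, ty, th, tw, objectness, 6 class scores).  Decoding: centre =
(cell + σ(txy))·stride, half-extents = anchor/2·exp(t), confidence =
σ(objectness)·σ(best class).  Anchors are 3 per scale from k-means
under IoU distance on the training labels (median update, sorted by
area, small triple → stride 16).

Numerical choices that matter:

* **exp clamp ±3** on the scale outputs — bounds boxes to [0.05×, 20×]
  anchor size, keeping the loss out of its degenerate far field.
* **Near-zero head initialisation** (weights ×0.03, objectness bias −2)
  — raw outputs start near zero, so boxes start anchor-sized at cell
  centres with useful IoU.  With ordinary He-initialised heads the box
  loss starts at |t| ≈ 2.5 where its gradient is dominated by the
  unbounded aspect term and training can diverge.
* **Box-loss gradients by central finite differences** with respect to
  the four decoded coordinates (ε = 1e-3), clipped to ±2, then chained
  analytically through the decode map (σ′, exp).  The loss is a cheap
  piecewise-smooth scalar of four variables; numerical
  differentiation is simpler and as accurate as hand-derived
  IoU/enclosing-box gradients here.  Gradients pushing a clamped scale
  parameter further out of range are zeroed.
* **Aspect term**: the printed signed form `L_gt/W_gt − L/W` can drive
  the loss negative, so the default wraps it in an absolute value;
  `mode="literal"` preserves the signed form for fidelity.
* **Objectness**: binary cross-entropy summed over cells and averaged
  over images, positives weighted 20×, negatives 0.5× — one positive
  cell per image faces several hundred background cells, and without
  re-weighting the positive signal at the finer grid is swamped within
  a 300-iteration budget.
* Class scores train as independent sigmoids (binary cross-entropy
  against one-hot), the single-stage convention.

Anchor assignment is best width/height-IoU over all six anchors; the
responsible cell is the one containing the box centre.  Soft-NMS uses
Gaussian decay with σ = 0.5 and a score floor of exp(−3); σ → 0
recovers hard suppression.

The demo training profile — 160×160 inputs, width multiplier 0.25,
neck width 32, Adam 1e-3, 300 iterations, full-batch — was chosen as
the smallest configuration that exercises both scales of the real
architecture; the eight-image memorization run finishes in about a
minute on one CPU.

## 7. Evaluation

AP per class: detections score-sorted (ties: higher IoU, then lower
index), greedily matched one-to-one to ground truth at the IoU
threshold, precision envelope, all-points interpolated area.  The
all-points convention is used rather than 11-point sampling because it
is the convention of the 0.50–0.95 threshold grid the package also
reports.  mAP is the arithmetic mean over classes; classes with no
ground truth are excluded and logged.  The implementation is tested
for exact agreement against an exhaustive per-prefix oracle, and the
1−IoU loss term against a pixel-rasterised IoU on integer boxes.
Confusion matrices come in six-class form and pooled into the three
degrees of freedom (elbow, wrist_EC, wrist_RLR).

## 8. Angle decoding

Ordinates are measured relative to the rendered baseline row (the
zero-voltage axis), which gives the absolute values in the decode rule
meaning for excursions below the baseline.  Two reference modes:
against a labelled reference frame (validation protocol), or against a
calibrated full-scale ordinate for inference on unlabelled images —
the latter is how the end-to-end test recovers ground-truth angles, by
calibrating the full-scale ordinate from the labelled frame and the
known angle fraction.  Only the elbow maximum (135°) comes from the
protocol; the wrist maxima (flexion/extension 80°, pronation/
supination 90°) are package defaults, flagged as conventions in the
config.

## 9. Known limitations

* Data are synthetic; no claim transfers to human recordings
  (Section 1).
* Batch normalization uses whole-batch statistics during the
  full-batch demo training, coupling images within an iteration;
  inference uses running statistics.
* The detector trains with one box per image (the protocol's single-
  action setting); multi-box images are representable but untested at
  training time, and composite/continuous motions are out of scope.
* Paper-scale training (448-px images, 90 000 images, 3000 epochs) is
  outside the intended use of this implementation; the numpy engine is
  built for correctness and desk-scale experiments.
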