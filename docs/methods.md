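# Methods

## Problem and scope

`fhpose` classifies forward head posture (FHP) versus normal posture from
17-joint 3D keypoint sets in the Human3.6M convention, the output format of
standard 2D→3D pose-lifting tools. The upstream image stages (2D detection,
3D lifting) are out of scope; the package starts from their numeric output.
Axis semantics everywhere: x = depth (anterior positive), y = width
(subject's left positive), z = height. Coordinates are unitless.

## Normalization

The lifter emits coordinates already roughly in [−1, 1], but with arbitrary
global yaw and scale. `normalize_pose` applies, in order: pelvis centring,
a yaw-only rotation aligning the horizontal projection of pelvis→left-hip
with +y, and uniform max-abs scaling to [−1, 1]. Yaw-only (rather than full
3D) alignment is deliberate: pitch and roll carry the postural signal that
distinguishes FHP, so removing them would erase the class difference. The
transform is recorded in a `NormalizationReport` (rotation, scale factor,
pelvis offset) for audit. A degenerate hip axis (left hip vertically above
the pelvis) raises an error rather than guessing an orientation.

Whether orientation should be normalized at inference is exposed as the
`align_yaw` flag (default on): with it on, classification is provably
invariant to yaw/scale/translation of the input (tested to 1e-9); turning it
off reproduces raw-frame behaviour for sensitivity analyses.

## Shoulder angle

No canonical formula exists for the "shoulder angle" of rounded-shoulder
analysis on this keypoint set, so the package adopts a protraction-style
definition: per side, project thorax→shoulder onto the horizontal plane and
measure its signed angle from the lateral axis (positive anterior), then
average sides. It is a diagnostic feature (inspected via Gaussian KDE with
Scott's-rule default bandwidth), not a classifier input; the classifier uses
the raw 13-joint coordinates precisely because the scalar angle alone does
not separate the classes.

## Labeling criterion (tragus/acromion proxy)

Clinically, FHP is diagnosed when the tragus lies anterior to the acromion.
Neither landmark exists in the 17-joint set, so the criterion is proxied by
the head keypoint versus the shoulder midpoint: a normalized pose is FHP iff
`head_x − (l_shoulder_x + r_shoulder_x)/2 > margin`. The margin defaults to
0.05 (post-normalization units), small enough that the two classes touch at
the boundary — near-boundary samples are intentional, mirroring the overlap
real posture distributions show. No quantitative craniovertebral-angle
threshold is applicable because that angle is unmeasurable here.

## Synthetic generator

The generator articulates a seated 17-joint skeleton from fixed
anthropometric proportions (hip half-width 0.12, lumbar/thoracic spine
0.22 + 0.22, thorax→head 0.22, shoulder half-width 0.18; legs seated with
thighs forward). Class-conditional draws:

| parameter | Normal | FHP | units |
|---|---|---|---|
| head pitch | N(0, 6) | N(35, 8) | degrees |
| shoulder protraction | N(5, 5) | N(20, 8) | degrees |

FHP head pitch around 35° forward flexion and visibly protracted shoulders
are typical of slouched device use; normal posture is vertically aligned
with small variation. Arm configuration is drawn uniformly from four
sedentary templates (driving, phone, tablet, rest) with small Gaussian
jitter (sd 0.01). Global yaw is uniform in ±30° (a seated subject facing
roughly toward the camera) and additive keypoint noise defaults to sd 0.02
— about 2 % of body scale, a plausible lifter-error magnitude. Class balance
defaults to 859/2387 FHP.

The drawn pitch is clamped — by a Brent root solve on the normalized
anterior offset — so every pose satisfies its label's margin criterion
*before* yaw and noise; a nudge of 0.015 rad keeps clamped poses strictly
off the boundary so floating-point round-trips cannot flip labels. Poses are
emitted in the lifter convention (canonical max-abs normalization, then yaw,
then noise), so downstream `normalize_pose` exactly reconstructs the frame
in which the label was enforced; at zero noise the stored labels are
recoverable at 100 % by the one-feature threshold.

What the generator does **not** emulate: image-driven artefacts (occlusion,
depth ambiguity, identity-correlated errors), temporal correlation across
video frames, anthropometric diversity (segment lengths are fixed), and
genuinely ambiguous postures beyond the clamped boundary mass. Passing tests
therefore certify the pipeline's mechanics — normalization invariances,
graph propagation, training protocol, metric formulas — and its ability to
recover a known geometric mechanism, not accuracy on real image-derived
data, which is substantially harder (published accuracies on such data are
in the high 70s).

## Models

**GCN.** Node features are the 3 coordinates of each of the 13 joints.
Propagation uses the symmetric renormalized adjacency with self-loops,
Â = D^(−1/2)(A+I)D^(−1/2) — the standard first-order spectral rule, chosen
for stability on small graphs. Two convolutions (16, 32 channels), ReLU,
dropout after each during training; flattened (416) into a 64-unit dense
ReLU layer (the latent space) and a linear softmax head. Exactly one dense
layer precedes the classification layer.

**FFNN baseline.** 39 → 128 → 64 → 2 with ReLU and dropout, mirroring the
GCN's capacity and honouring the same 64-unit penultimate contract.

Both are implemented in numpy with hand-written backpropagation and Adam;
at this scale (≲30 k parameters) that is faster and more transparent than a
deep-learning framework, and gradients are verified against central finite
differences in the test suite. Initialization is fan-in-scaled uniform
(±√(6/fan_in)), biases zero, seeded. Dropout is inverted (rescaled at train
time) and disabled at inference, so inference is deterministic.

## Training protocol

Stratified 70/15/15 split with largest-remainder rounding of the overall
sizes; per-class quotas are largest-remainder rounded and then adjusted to
the overall sizes, preferring adjustments that keep every class in every
split (for very small n a 1-sample split cannot contain both classes; sizes
win). Adam at learning rate 1e-3 (the conventional default), batch 16,
categorical cross-entropy with an epsilon clamp of 1e-12 inside the log,
max 200 epochs with early stopping (patience 20 on validation loss); the
best-validation-loss weights are restored. Dropout-rate selection trains one
model per grid value (default grid 0.0–0.5) and picks the best fixed-split
validation accuracy, ties to the lowest rate; fixed-split selection was
chosen over internal k-fold for determinism and speed. Argmax ties resolve
to class 0 (Normal).

## Latent analysis

Penultimate (64-d) activations are embedded with t-SNE (perplexity 30 by
default, PCA initialization, seeded — deterministic single-threaded) and
summarized by the anisotropy ratio λ2/λ1 of the two largest eigenvalues of
the sample covariance (n−1 denominator). "First two eigenvalues" is read as
the two largest of the feature covariance in the 64-d space, the only
reading consistent with the isotropy interpretation. The GCN-vs-FFNN ratio
ordering is dataset-dependent; on synthetic data both models typically
collapse to near-1-dimensional feature clouds (ratios ≪ 1) because one
latent direction suffices, so ratios are reported for inspection, not
asserted against any reference values.

## Problem sizes

Default tests train on 120–400-sample datasets (moderate noise) — at those
sizes the separable mechanism is comfortably recoverable and the full suite
runs in well under a minute. `scripts/acceptance.py` uses the full default
conditions (2387 samples) for both models.

## Known limitations

- The generator's boundary clamping concentrates probability mass exactly at
  the decision margin; with noise these samples are irreducibly ambiguous,
  which bounds attainable accuracy slightly below 100 %.
- `split_dataset` requires ≥ 10 samples and two represented classes.
- t-SNE determinism holds per (seed, scikit-learn version, thread count).
- The CLI's `evaluate` scores whatever labeled file it is given; keeping the
  test split held out is the caller's responsibility (the `train` command
  reports proper held-out metrics itself).
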