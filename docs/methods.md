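# Methods

This note records the models and procedures ethotrace implements, the
parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic-data tests do and do not demonstrate
about real footage.

## Video input and preprocessing

Frames are decoded in a producer thread feeding a bounded queue (default
capacity 64), so analysis never waits on I/O while buffered frames exist;
the buffer delivers every frame exactly once and in order regardless of
capacity.  The native container is uncompressed RIFF/AVI (24-bit BI_RGB),
chosen because it is lossless — segmentation of synthetic footage is then
exact — and universally readable; other containers are handled through an
imageio backend when one is installed.

Preprocessing masks pixels outside the region of interest to 0, converts
sRGB to CIE-XYZ with the standard D65 matrix and keeps the Y (luminance)
channel — chromaticity and luminance are coded separately in XYZ, which
makes the grayscale robust to illumination variation — then min–max
normalizes to [0, 255] and median-filters (default 3×3).  Normalization is
per frame, consistent with streaming operation; a global normalization would
require a second pass.  A constant frame has no spread to normalize and maps
to 0 with a logged warning.

## Segmentation

Manual thresholding marks pixels above a user gray level *g* as foreground
(bright-on-dark convention; an `invert` flag covers dark animals on light
backgrounds, the common case for bees on arena floors).  Otsu's method
computes, from the normalized histogram p_i, the class weights ω₀/ω₁ and
means μ₀/μ₁ at every candidate level and picks the k maximizing
σ_b² = ω₀ω₁(μ₁ − μ₀)².  Numerical choices: candidates are all levels with
both classes nonempty; ties break toward the smallest k (deterministic);
frames with a single gray level raise a degenerate-histogram error.  The
variance decomposition σ_w² + σ_b² = σ_t² is asserted in tests at every
level.

Morphological cleanup applies, in order, dilation (bridges fragments of one
body detected separately), subtraction of the morphological gradient of the
dilated mask (strips edge residue), and erosion (removes specks).  Kernels
are elliptical 3×3 by default, one iteration; the kernel sizes are
configurable because the right size depends on animal scale in pixels.

A `Detector` contract (frame in → scored boxes/masks out, validated against
image bounds) lets externally trained instance-segmentation models plug into
the same pipeline for heterogeneous scenes; the built-in reference detector
(threshold + connected components) satisfies the contract on homogeneous
scenes.  Deep detectors themselves are intentionally out of scope: the
package supplies the data forge and the scoring machinery around them.

## Tracking

Contours are external 8-connected components without hierarchy; each
carries its filled pixel count (area), the major-axis length of its
minimum-area rotated bounding rectangle (+1 px to convert pixel-center span
to extent), and its centroid.  Length-by-rotated-rectangle was chosen over
perimeter because the paired-posture heuristic needs a body length and a
perimeter double-counts.  A user filter gates area, length, and
area-to-length ratio.

When fewer contours than the expected group size n are present, the
largest-area contour is assumed to contain the merge and its pixels are
split into (deficit + 1) clusters by k-means: k-means++ seeding (first
center uniform over the pixels, each next center drawn with probability
proportional to squared distance to the nearest chosen center), then Lloyd
iterations to a local minimum of the within-cluster sum of squares φ, best
of 10 restarts, fully determined by the tracker seed.  On tiny instances
the restarted optimum equals the brute-force best partition (tested).

Identity maintenance solves the assignment problem on the Euclidean
distance matrix between the previous frame's labeled centroids and the new
centroids, using the classical reduce-rows / reduce-columns / cover-zeros
procedure; its cost equals the exhaustive n! minimum (tested for n ≤ 6).
First-frame labels sort centroids by (y, x).  Unequal set sizes are padded
at prohibitive cost so genuine matches are unaffected; an unmatched
identity records a gap (NaN) for that frame and re-anchors by nearest
assignment when detections return, with the event logged after a
configurable run of empty frames (default 10).

## Kinematics

All statistics operate on the (frames × individuals × 2) trajectory array;
gaps contribute no step.  Distances multiply by the cm/px scale when one is
set; thresholds may be given in cm (converted via the scale) or px.
Specific readings where the definitions left room:

- Turning angle averages |arctan(Δy/Δx)| in degrees over displacement
  steps (f − 1 steps for f positions); the two-argument arctangent folded
  into [0°, 90°] keeps vertical steps finite (90°).  Zero-length steps
  contribute 0°.
- Meandering divides the summed absolute step angle by tracked distance —
  degrees per unit length in the scaled unit.
- The activity budget classifies each per-frame step mf as resting
  (mf ≤ tl, boundary inclusive), intermediate (tl < mf ≤ th), or fast
  (mf > th); counts divide by fps.  Worked defaults from bee assays:
  ti = 1.41 cm, tl = 0.046 cm frame⁻¹; both must be set by the user.
- Centrality counts pair-membership events per frame (a frame where j is
  within ti of two others adds 2 to j's centrality); network density uses
  distinct ever-interacting pairs as edges, nd = 2m/(n(n−1)).  Frame-wise
  counts feed centrality; the binary edge set feeds density.
- Polarization and angular momentum use unit headings from the displacement
  into each frame; individuals with a gap or zero displacement are excluded
  and the divisor i reduced; a frame with no mover is undefined and excluded
  from the state-time counts.  The radial vector d is normalized to unit
  length so r ∈ [0, 1], consistent with the 0.35/0.65 state thresholds —
  an unnormalized distance would make r scale-dependent and the thresholds
  meaningless.
- The detection rate multiplies (1 − outlier-steps/steps) by the detected
  fraction of (frame, identity) slots and clamps to [0, 1]; a step is an
  outlier when its speed exceeds 2 × the 95th percentile of the pooled
  group speed.  A literal reading of the defining sum would carry speed
  units; the implemented proportion reading matches the quantity's stated
  meaning and its examples (one teleport step among 100 → 0.99; 10%
  undetected, no outliers → 0.90).

## Training-data forge and scoring

The forge samples source frames at random (seeded), segments animals with
the preprocessing + detection stages, and pastes each harvested pixel set
at a random fully-in-bounds position on a randomly drawn background,
recording box/class/mask concurrently.  Plain copy-paste, no blending or
feathering.  Pasted objects may overlap up to IoU 0.2 (configurable);
objects per image are drawn uniformly from a configurable range.  The same
seed reproduces the dataset byte for byte.  Annotations serialize to nested
JSON (image → object → {box{center{x,y}, width, height}, class, mask}) and
round-trip losslessly.

Scoring: box IoU = |A∩B|/|A∪B|; matching is greedy in descending score
with each target matched at most once (TP iff IoU ≥ x, default x = 0.5;
unmatched targets are FN); precision TP/(TP+FP) and recall TP/(TP+FN)
accumulate along the ranked list; interpolated precision at recall level r
is the maximum precision at any recall ≥ r; AP averages the interpolated
precision over the 11 levels 0, 0.1, …, 1.0 (divisor 11).  Greedy-by-score
matching is the standard convention for AP; an optimal matching would
differ only in contrived ties.

## Paired-posture heuristic and recognizer

Body statistics (median and standard deviation of area and length) come
only from frames whose contour count equals the group size — those frames
contain no crossings, so every contour is a single body.  The label is 1
iff area ∈ [2(M_a − sd_a), 2(M_a + sd_a)] and length ∈
[2(M_l − sd_l), 2(M_l + sd_l)], all bounds inclusive.  Widening either sd
can only turn 0-labels into 1-labels (monotonicity, tested).  The crop fed
to the recognizer is the merged blob's joint bounding box resized to the
input size (default 64×64, 32×32 in tests), grayscale in [0, 1].

The recognizer is a compact NumPy-implemented CNN: 3×3 convolution blocks
(8, 16, 32 channels) each with Elu activation, batch normalization before
a 2×2 max-pool; a 64-unit dense inner layer with Elu and dropout 0.5; a
single sigmoid output; binary cross-entropy loss; SGD with learning rate
10⁻⁴ and momentum 0.9, minibatch 8.  He-scaled Gaussian initialisation;
one seed drives initialisation, shuffling, and dropout, so training is
bit-reproducible on one machine configuration.  Depth and widths are
configurable; the defaults are the parsimonious setting that overfits 40
separable synthetic crops to 100% training accuracy within a handful of
epochs (the sanity bound is 200).

Evaluation: 2×2 confusion matrix, global accuracy (trace/total), Cohen's
kappa (p_o − p_e)/(1 − p_e) with chance agreement p_e from the marginals,
and Z = kappa/SE₀ with the large-sample null variance
(p_e + p_e² − Σᵢ pᵢ₊p₊ᵢ(pᵢ₊ + p₊ᵢ))/(N(1 − p_e)²); significance is the
two-sided 5% level.  The implementation agrees with the statsmodels
inter-rater routine (cross-checked in tests).

## Synthetic scenes: what they emulate, and what they do not

Animals render as filled 2:1 ellipses without anti-aliasing, so masks are
exact and "body length" is well defined.  Scenes control group size, body
length (default 24 px), speed (default 2 px/frame), heading noise, uniform
or procedurally cluttered backgrounds, lane-based (crossing-free) or random
layouts, scripted merge events (one blob rides attached to another for k
frames, with a linear approach/retreat ramp), and head-to-head pair poses
built from two ellipses joined along their major axes at 0.98 of the
semi-major offset — combined area and length ≈ 2× a single body, inside
the heuristic's window.  Pose sets give singles a 3% body-length jitter,
a realistic within-colony size variation, so the measured sd defines a
non-degenerate window; the pair itself is built at the nominal size.
Ground truth (programmed centroid, rasterized area, measured length, pair
flag per blob per frame) is exported as CSV next to the video.

Passing round-trip tests therefore shows the geometry and bookkeeping of
the pipeline are correct under ideal contrast, rigid bodies, and known
group size.  They do not exercise appearance variation, shadows, limb
articulation, partial occlusion by scenery, compression artifacts, or
long total-detection losses — on real footage, threshold and filter
settings, and for heterogeneous scenes an external detector, carry that
burden.

## Problem sizes and runtime

Default verification sizes: 50 random 16×16 images for threshold-selection
oracle checks, 100 assignment instances (n ≤ 6), 20 k-means instances
(≤ 12 points), a 300-frame three-animal round trip, a 20-image forge, a
20-frame pose set, and 40 crops for the recognizer sanity check.  At these
sizes the full test suite runs in roughly six minutes and the acceptance
script in under two on one CPU core.

## Known limitations

- Identity maintenance is purely positional; after a long total loss or a
  crossing of visually identical animals, labels may swap (flagged, not
  repaired — appearance-based re-identification is out of scope).
- The occlusion splitter assumes the merged blob is the largest contour and
  splits it alone; simultaneous merges of more than one pair in one frame
  with additional missing animals can mis-apportion clusters.
- The k-means split separates overlapping bodies geometrically; it does not
  reconstruct true boundaries of deeply interpenetrating shapes.
- The detection-rate outlier rule assumes roughly homogeneous group speed;
  a genuinely fast animal among slow ones inflates the outlier count.
- The native codec is uncompressed AVI; compressed containers need an
  imageio backend present at run time.
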