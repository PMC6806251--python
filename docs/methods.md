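# Methods

`posepheno` classifies the actions of one *target* person in untrimmed
multi-person video, working entirely from per-frame 2D pose detections
(17 COCO keypoints plus a bounding box per person hypothesis). The
pipeline has four stages: short-term tracking, long-term appearance
fusion, pose-evolution featurization, and a compact convolutional
classifier over five actions (sit, sit-to-stand, stand, walk,
stand-to-sit). The motivating application is motor-behaviour
phenotyping of patients (for example during MDS-UPDRS assessment
visits), where clinicians, nurses and staff share the frame with the
patient and the recording contains long occlusions and scene cuts.

## Short-term tracking

Detections in consecutive frames are associated by solving a bipartite
assignment that maximises total intersection-over-union (IoU), using the
Hungarian algorithm (`scipy.optimize.linear_sum_assignment` on cost
1 − IoU). Assigned pairs whose IoU falls below a threshold — default
0.1, deliberately permissive since geometry only has to disambiguate
between people, not localise precisely — or whose boxes do not overlap
at all are demoted to unmatched. Unmatched boxes open new tracklets; a
tracklet that misses a single frame is closed. There is no motion model
and no look-ahead: recovering an identity across a gap is entirely the
long-term stage's job, which keeps the two failure domains cleanly
separated.

Boxes are half-open pixel rectangles (0-based, origin top-left, y down),
so IoU arithmetic is exact and width = x_max − x_min. Ties between
equal-cost assignments resolve to the lowest combined index, making the
stage fully deterministic.

## Long-term tracking (appearance-based tracklet fusion)

Occlusions, scene changes and camera cuts fragment each identity into
many tracklets. Fusion proceeds in three steps:

1. **Pruning.** A tracklet survives iff its length is ≥ 5 frames *and*
   the mean fraction of keypoints with confidence ≥ 0.5 is at least 0.5.
   This operationalises "prune by length and number of estimated
   keypoints" with a concrete confidence cut, since detector confidences
   rather than keypoint counts are what the input format carries.
2. **Sparse sampling.** One representative detection per tracklet: the
   highest box-confidence one, ties to the earliest frame.
3. **Fusion.** Each representative is embedded in a fixed-dimension
   appearance space; a tracklet joins the target track iff the Euclidean
   distance between its embedding and the reference tracklet's embedding
   is ≤ τ. Embeddings are L2-normalised before the distance so τ is
   scale-free across embedders; default τ = 0.7, roughly half the
   typical distance between unrelated identities on the unit sphere
   (≈ √2). The reference tracklet is the one piece of supervision: a
   user-supplied tracklet id known to be the target.

When two accepted tracklets overlap on a frame, the detection from the
lower-affinity tracklet wins; the reference always beats everything.
The embedder is a pluggable contract with two implementations: a
passthrough of appearance vectors carried in the detection stream (used
with the simulator) and an image-patch embedder (crop the box, partition
into a fixed grid, concatenate per-cell mean intensities) for when raw
frames are available. Deep re-identification backbones can be slotted
in behind the same contract but are deliberately out of scope.

Tracker quality is measured by treating fusion as a binary classifier
over tracklets (target = positive class): the *tracklet binary accuracy*
is the fraction of accept/reject decisions matching ground-truth
identity. We also report *frame coverage*: the fraction of the target's
visible frames present in the fused track.

## Pose-evolution maps

A clip of F frames is summarised as a (14·C) × H × W tensor:

* The 17 COCO keypoints reduce to 14 joints: eyes and ears merge into a
  single "head" keypoint at their confidence-weighted mean (confidence =
  mean of the four), the nose and the 12 body joints pass through. If
  all four head parts have zero confidence the head joint renders as a
  zero heatmap.
* Each joint in each frame becomes a Gaussian heatmap with amplitude
  equal to the keypoint confidence (default σ = 2 px at working
  resolution; keypoints below confidence 0.05 are dropped). Gaussians
  are evaluated within 6σ of the centre and are exactly zero beyond —
  the truncated tail mass is < 1e−7 and no spatial maximum can be
  affected.
* Frame f at relative time t = f/(F−1) spreads its heatmaps over C
  channels (default 3) with piecewise-linear weights o_j(t): the clip
  is divided into C−1 intervals of length l = T/(C−1), and on interval
  k channel k ramps down while channel k+1 ramps up. The weights form
  an exact partition of unity with one-hot endpoints; with C = 3 the
  middle channel is a tent over the clip's midpoint. (A natural but
  wrong alternative, l = T/C, leaves the encoding discontinuous and not
  summing to one; the C−1-interval tiling is the only reading consistent
  with triangular profiles.)
* Time-weighted heatmaps are summed over the clip and every (joint,
  channel) slice is divided by its own spatial maximum, so each nonzero
  slice peaks at exactly 1 and an all-zero slice stays zero (guarded
  against division by zero; a wholly empty clip yields an all-zero map
  and a warning).

Useful consequences, all verified by tests: a static pose produces
identical channel slices per joint (the channel weights factor out and
normalisation cancels them); reversing a clip's frame order maps channel
j to channel C+1−j; translating the keypoints translates the map.

Working resolution is the native frame size scaled by 0.125 (1080×1920
→ 135×240). Augmentation adds i.i.d. Gaussian noise clipped back to
[0, 1], seed-reproducible.

## Clip segmentation and dataset assembly

Annotated action segments (inclusive frame intervals, one label from
the five classes, non-overlapping per subject) are cut into clips:
segments shorter than 0.2 s (six frames at 30 fps) are dropped as too
short to carry an action; segments longer than 4 s are divided
left-to-right into 4 s pieces, and a trailing remainder is kept iff it
is itself ≥ 0.2 s (transitions are typically short, so discarding
remainders would systematically delete them). Class balancing
undersamples any class above a cap (default 4000) by seeded uniform
sampling without replacement. Train/test splitting is by subject, so
no person contributes clips to both sides.

## Classifier

Two blocks of two 3×3 convolutions (128 then 256 filters; the first
layer of each block has stride 2, the second stride 1, 'same' padding),
each followed by ReLU → batch normalisation → dropout in that order;
then global average pooling to a 256-vector and a 5-way affine layer
with softmax cross-entropy. For C = 3 the input is 42 × H × W and the
network has ~1.08 M parameters. Pose-evolution maps are sparse and
carry no image context, so this shallow randomly-initialised network is
sufficient and trains on a CPU.

The layers are implemented directly on numpy: convolutions lower to a
single BLAS matmul per pass via im2col, which is what makes CPU
training practical. Training uses Adam at base learning rate 0.01,
batch size 70 and dropout 0.3. Batch-norm running statistics are
bias-corrected exponential moving averages (momentum 0.9), so
evaluation-mode normalisation is sensible even after few batches — with
small corpora and batch 70 an epoch can be only a handful of steps.
Early stopping monitors validation weighted accuracy: training stops
when it reaches 0.995, or when no improvement above 0.005 is seen for
3 epochs (default budget 20 epochs); the best-validation weights are
restored. The seed controls weight initialisation, batch order and
dropout masks, so a fixed seed reproduces training exactly on the same
BLAS build.

## Evaluation

Confusion matrices use rows = true label, columns = predicted, in the
fixed order sit, sit-to-stand, stand, walk, stand-to-sit. Per-class
accuracy is diagonal over row sum (unsupported classes omitted);
weighted overall accuracy is the class-support-weighted mean of
per-class accuracies, identically trace/total. The end-to-end report
bundles tracker binary accuracy, fused-track frame coverage, clip
counts, the confusion matrix and weighted accuracy as JSON.

## The scene simulator

No clinical recordings ship with the package, so every stage is
validated on a keypoint-level simulator that reproduces the statistical
structure the pipeline assumes:

* **Actors** are parametric 2D skeletons. Canonical sit and stand
  postures are fixed offset tables (anchored to a ground point, y up
  negative); sit-to-stand interpolates linearly between them with the
  phase, stand-to-sit is the reversed path; walking superimposes
  antiphase sinusoidal ankle/wrist oscillation (cadence 1.2 Hz) on the
  standing posture and advances the root at 0.45 skeleton-scales per
  second. Bystanders stand at staggered depths — farther actors are
  smaller and higher in the frame, as in a frontal camera view — which
  keeps boxes from degenerately coinciding when the target walks past.
* **Detections**: per visible actor and frame, keypoints get Gaussian
  jitter (default σ = 1 px), confidences ~ clipped N(0.85, 0.08), the
  box is the tight keypoint box padded by 10% of its diagonal, box
  confidence ~ U(0.7, 1).
* **Appearance** is generated data, not rendered pixels: each actor has
  an identity vector on the 16-dimensional unit sphere (rejection-
  sampled to pairwise distance ≥ 1) and each detection carries identity
  + N(0, 0.05² I). This preserves exactly the property fusion exploits
  — intra-identity distances ≪ inter-identity distances (separation-to-
  noise ratio 20) — without modelling clothing or lighting.
* **Disturbances**: per-actor occlusion windows (detections removed),
  scene changes (all positions re-randomised), and i.i.d. detection
  dropout (default 2% in the benchmark scene).

The canonical benchmark scene is 600 frames (20 s at 30 fps) with three
actors, a scripted target cycle (sit 20% → sit-to-stand 10% → stand 20%
→ walk 30% → stand-to-sit 10% → sit 10%), one occlusion window on the
target and one on a bystander (10% of the scene each), and one scene
change at 80%. Everything is driven by one seeded generator: the same
configuration and seed give byte-identical streams.

What the simulator does *not* emulate — and therefore what passing
tests do not show about real data: detector-specific error structure
(correlated keypoint failures, duplicate detections, identity-dependent
confidence bias), camera motion, perspective-correct kinematics,
pathological gait, appearance drift over time (clothing changes), and
crowded scenes where people embrace or persistently overlap. Tracker
and classifier scores on the benchmark scenes are ceiling-ish by
design; they validate the machinery, not clinical performance.

## Validation problem sizes

The heavyweight checks run at sizes chosen to exercise the pipeline
honestly while staying desk-scale: assignment optimality on 1,000
random frame pairs (≤ 6 boxes per side, against exhaustive permutation
search); tracker recovery over 20 seeded benchmark scenes; and the
classifier sanity pair at 500 train / 100 test clips per class on
42 × 34 × 60 maps (clips of 60 frames at frame size 270 × 480, scaled
by 0.125), paired with an identical run on label-permuted data that
must stay at chance (0.2). The acceptance script uses 150/50 clips per
class for the classifier pair, which is past the corpus size where test
accuracy saturates on simulated clips.

## Known limitations

* Fusion uses a fixed distance threshold; no calibration against an
  impostor distribution is attempted, so τ must be re-examined for any
  new embedder.
* One representative detection per tracklet: a tracklet whose
  highest-confidence detection falls on an identity-swap segment will
  be judged by the wrong person's appearance. Short-term identity swaps
  during prolonged box overlap are the main residual error source in
  benchmark scenes.
* The classifier sees absolute image coordinates: it is not invariant
  to large translations of where in the frame the action occurs, and a
  scene change inside a clip can smear heatmaps horizontally enough to
  look like walking.
* Training determinism is only guaranteed on a fixed BLAS build and
  thread count.
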