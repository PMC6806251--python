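# posepheno

Target-specific action classification from multi-person 2D pose
streams: cascaded pose tracking, pose-evolution maps, and a compact
convolutional classifier.

## The problem

Clinical assessment of motor behaviour — for instance of Parkinson's
disease patients during an MDS-UPDRS visit — increasingly uses video.
The recordings are untrimmed, span rooms and hallways, and the patient
shares the frame with clinicians and staff, with long occlusions and
scene cuts. Off-the-shelf pose estimators give per-frame detections
for *everyone*; turning those into action labels for *one* person
requires (a) following that person through the whole recording and
(b) a representation of their movement a classifier can learn from.

`posepheno` implements that pipeline for five basic actions — sit,
sit-to-stand, stand, walk, stand-to-sit — consuming per-frame COCO
17-keypoint detections (JSON-lines) and rater-annotated action
segments (CSV). It ships a keypoint-level scene simulator with
ground-truth identities, so every stage is testable end to end without
clinical data.

## Method at a glance

1. **Short-term tracking.** Detections in consecutive frames are
   linked by maximum-total-IoU bipartite matching (Hungarian
   algorithm) into *tracklets*; any missed frame closes a tracklet.
2. **Long-term tracking.** Tracklets are pruned by length and keypoint
   quality; one representative detection per tracklet (highest box
   confidence) is embedded in an appearance space; tracklet T_i joins
   the target track iff ‖f_i − f_ref‖₂ ≤ τ against a user-supplied
   reference tracklet (embeddings L2-normalised, τ = 0.7).
3. **Pose evolution.** Each action clip becomes a (14·C) × H × W
   tensor: per joint, Gaussian keypoint heatmaps are spread over C
   time-encoding channels with piecewise-linear weights
   (C−1 intervals of length l = T/(C−1), partition of unity), summed
   over the clip, and each (joint, channel) slice is normalised to
   peak 1.
4. **Classification.** A 4-layer CNN (3×3×128, 3×3×128, 3×3×256,
   3×3×256; strides 2/1/2/1; ReLU + batch norm + dropout 0.3; global
   average pooling; 5-way softmax) trained with Adam (lr 0.01, batch
   70). Implemented in numpy with im2col-lowered convolutions; trains
   on a CPU.

Weighted overall accuracy (support-weighted mean of per-class
accuracies = confusion-matrix trace over total) and tracker binary
accuracy (fusion treated as a target/non-target classifier over
tracklets) are the headline metrics. See `docs/methods.md` for the
full model description and design rationale.

## Worked example

```bash
python examples/02_track_target.py
```

```
short-term tracklets: 36
after pruning:        35
reference tracklet:   8
accepted by fusion:   13/35
tracklet binary accuracy: 1.000
fused-track frame coverage: 1.000
```

A 20 s three-actor scene with two long occlusions and a scene change
fragments into 36 tracklets; appearance fusion accepts exactly the 13
that belong to the target (binary accuracy 1.0) and the fused track
recovers every frame in which the target was visible.

```bash
python examples/04_train_classifier.py
```

```
train maps: (300, 42, 34, 60), test maps: (75, 42, 34, 60)
parameters: 1,084,165
  ...
  epoch 7: loss 0.001, val weighted acc 1.000
test weighted overall accuracy: 1.000
confusion matrix (rows = truth, order: sit, sit-to-stand, stand, walk, stand-to-sit)
[[15  0  0  0  0]
 [ 0 15  0  0  0]
 [ 0  0 15  0  0]
 [ 0  0  0 15  0]
 [ 0  0  0  0 15]]
```

Sixty simulated clips per class suffice for the network to separate
the five actions perfectly on held-out clips from a different seed —
the simulator's actions are cleanly distinguishable in this
representation (sit/stand by geometry, the two transitions by the
*direction* of the time encoding, walking by horizontal smear).

The other examples: `01_simulate_scene.py` (scene anatomy),
`03_pose_evolution_map.py` (the representation itself),
`05_full_pipeline.py` (tracking → clips → featurize → classify on one
untrimmed recording). A thin CLI wraps the same stages
(`posepheno simulate|track|clips|featurize|train|predict|evaluate|run-all`).

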