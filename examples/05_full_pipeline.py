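"""The whole pipeline on one untrimmed synthetic recording.

Simulates a scene, tracks the target, segments the annotated actions
into duration-bounded clips, featurizes each clip from the *fused track*
(not ground truth), and classifies it with a network trained on a
separate simulated corpus.  The report bundles tracking and
classification quality the way the package's evaluation stage does.
"""

import json
import math

import numpy as np

from posepheno import (
    ACTION_LABELS,
    ModelConfig,
    benchmark_scenario,
    build_model,
    generate_scenario,
    predict,
    segment_clips,
    train,
)
from posepheno.evaluation import end_to_end_report
from posepheno.pipeline import make_clip_map_dataset, run_tracking
from posepheno.pose_evolution import pose_evolution_map, scale_keypoints
from posepheno.simulate import ClipDatasetConfig

# compact geometry keeps this demo under a couple of minutes
frame_size, scale = (270, 480), 160.0
scenario = benchmark_scenario(
    seed=5, n_frames=900, frame_size=frame_size, skeleton_scale=scale
)
stream, truth, segments = generate_scenario(scenario)
result = run_tracking(stream, truth, scenario.target.actor_id)
print(f"tracklets {len(result.tracklets)}, accuracy {result.accuracy:.3f}, "
      f"coverage {result.coverage:.3f}")

clip_cfg = ClipDatasetConfig(frame_size=frame_size, skeleton_scale=scale)
X_train, y_train = make_clip_map_dataset(n_per_class=60, seed=5, clip_config=clip_cfg)
rng = np.random.default_rng(5)
order = rng.permutation(len(X_train))
config = ModelConfig(input_shape=X_train.shape[1:], epochs=14, seed=5)
model = build_model(config)
train(model, X_train[order[30:]], y_train[order[30:]],
      X_train[order[:30]], y_train[order[:30]], config)

clips = segment_clips(segments, fps=scenario.fps, track=result.track)
H, W = math.ceil(frame_size[0] * 0.125), math.ceil(frame_size[1] * 0.125)
X_scene = np.stack([
    pose_evolution_map(scale_keypoints(c.keypoints, 0.125), C=3, H=H, W=W).tensor
    for c in clips
]).astype(np.float32)
pred = [ACTION_LABELS[k] for k in predict(model, X_scene).argmax(axis=1)]

report = end_to_end_report(
    tracklet_truth=result.tracklet_truth,
    tracklet_pred=result.tracklet_pred,
    target_visible_frames=[f for f, _, a in truth if a == scenario.target.actor_id],
    track=result.track,
    clip_true_labels=[c.label for c in clips],
    clip_pred_labels=pred,
)
print(json.dumps({k: v for k, v in report.items() if k != "confusion_matrix"},
                 indent=2))
print("confusion matrix (rows = truth):")
print(np.array(report["confusion_matrix"]))
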