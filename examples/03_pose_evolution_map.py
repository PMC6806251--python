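"""Build a pose-evolution map for one action clip.

A sit-to-stand clip is rendered into the time-colorized representation:
each of the 14 joints gets C = 3 channels whose weights encode when in
the clip the joint occupied each location (channel 1 = start, channel 3
= end), every (joint, channel) slice normalised to peak 1.
"""

import numpy as np

from posepheno import generate_clip_dataset, pose_evolution_map, time_encoding
from posepheno.pose_evolution import scale_keypoints
from posepheno.simulate import ClipDatasetConfig

print("time-encoding weights (C = 3):")
for t in (0.0, 0.25, 0.5, 0.75, 1.0):
    print(f"  t = {t:.2f} -> {np.round(time_encoding(t, 1.0, 3), 3)}")

cfg = ClipDatasetConfig()
clips, labels = generate_clip_dataset(1, clip_len_frames=60, seed=1, config=cfg)
clip = clips[labels.index("sit-to-stand")]

# work at 1/8 resolution, like the full pipeline
pe = pose_evolution_map(scale_keypoints(clip, 0.125), C=3, H=34, W=60, sigma=2.0)
print(f"\nclip: sit-to-stand, {clip.shape[0]} frames")
print(f"map shape (14 joints x 3 channels, H, W): {pe.shape}")
print(f"value range: [{pe.tensor.min():.3f}, {pe.tensor.max():.3f}]")
nose_start = pe.joint_slice(0, 0)  # nose, channel 1 (clip start)
nose_end = pe.joint_slice(0, 2)    # nose, channel 3 (clip end)
print(f"nose peak row at clip start: {np.unravel_index(nose_start.argmax(), nose_start.shape)[0]}")
print(f"nose peak row at clip end:   {np.unravel_index(nose_end.argmax(), nose_end.shape)[0]}")
print("(the nose rises between channels: the actor stood up)")
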