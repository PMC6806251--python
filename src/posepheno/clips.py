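"""Turning annotation segments into fixed-bounded action clips.

Segments shorter than 0.2 s (six frames at 30 fps) are too short to carry
an action and are dropped; segments longer than 4 s are cut left-to-right
into 4 s pieces, keeping a trailing remainder iff it is itself at least
0.2 s.  Class balancing undersamples over-represented classes to a cap,
and train/test splitting is by subject so no subject leaks across sides.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .long_term import Track
from .types import AnnotationSegment, ValidationError


@dataclass
class ActionClip:
    """A single-label clip of the target's keypoint sequence."""

    subject_id: str
    start_frame: int
    end_frame: int  # inclusive
    label: str
    keypoints: Optional[np.ndarray] = None  # (n_frames, 17, 3)

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame + 1

    def duration_s(self, fps: float) -> float:
        return self.n_frames / fps


def segment_clips(
    segments: Sequence[AnnotationSegment],
    fps: float = 30.0,
    min_s: float = 0.2,
    max_s: float = 4.0,
    track: Optional[Track] = None,
) -> list[ActionClip]:
    """Cut annotation segments into duration-bounded clips.

    Deterministic: segments below ``min_s`` are excluded, segments above
    ``max_s`` are divided into consecutive ``max_s`` pieces left-to-right
    and a trailing remainder is kept iff it is at least ``min_s``.  When a
    fused ``track`` is supplied, each clip carries the target keypoint
    sequence for its frames (frames the track misses become zero-confidence
    rows).
    """
    min_frames = int(math.ceil(min_s * fps))
    max_frames = int(round(max_s * fps))
    clips: list[ActionClip] = []
    for seg in segments:
        start = seg.start_frame
        while start <= seg.end_frame:
            end = min(seg.end_frame, start + max_frames - 1)
            n = end - start + 1
            if n >= min_frames:
                clips.append(
                    ActionClip(
                        subject_id=seg.subject_id,
                        start_frame=start,
                        end_frame=end,
                        label=seg.label,
                        keypoints=(
                            extract_clip_keypoints(track, start, end)
                            if track is not None
                            else None
                        ),
                    )
                )
            start = end + 1
    return clips


def extract_clip_keypoints(track: Track, start_frame: int, end_frame: int) -> np.ndarray:
    """Target keypoints for a frame interval, zero-confidence where absent."""
    n = end_frame - start_frame + 1
    out = np.zeros((n, 17, 3))
    for det in track.detections:
        if start_frame <= det.frame_index <= end_frame:
            out[det.frame_index - start_frame] = det.keypoints
    return out


def balance_classes(
    clips: Sequence[ActionClip], cap: int, seed: int
) -> list[ActionClip]:
    """Undersample classes exceeding ``cap`` to exactly ``cap`` clips.

    Sampling is uniform without replacement and seed-deterministic;
    classes at or below the cap are untouched.  Output preserves the input
    order of the retained clips.
    """
    if cap <= 0:
        raise ValidationError("cap must be > 0")
    rng = np.random.default_rng(seed)
    by_label: dict[str, list[int]] = {}
    for i, clip in enumerate(clips):
        by_label.setdefault(clip.label, []).append(i)
    keep: set[int] = set()
    for label in sorted(by_label):
        indices = by_label[label]
        if len(indices) > cap:
            chosen = rng.choice(len(indices), size=cap, replace=False)
            keep.update(indices[i] for i in chosen)
        else:
            keep.update(indices)
    return [clip for i, clip in enumerate(clips) if i in keep]


def split_by_subject(
    clips: Sequence[ActionClip], test_subject_ids: Sequence[str]
) -> tuple[list[ActionClip], list[ActionClip]]:
    """Partition clips into (train_val, test) with zero subject overlap."""
    test_ids = set(test_subject_ids)
    present = {c.subject_id for c in clips}
    missing = test_ids - present
    if missing:
        warnings.warn(
            f"test subject ids not present in the data: {sorted(missing)}",
            stacklevel=2,
        )
    train = [c for c in clips if c.subject_id not in test_ids]
    test = [c for c in clips if c.subject_id in test_ids]
    return train, test
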