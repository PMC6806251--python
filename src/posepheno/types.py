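"""Domain types shared by every pipeline stage.

Conventions used throughout the package:

* Coordinates are pixels, 0-based, origin at the top-left corner, y pointing
  down.  Boxes are ``(x_min, y_min, x_max, y_max)`` and half-open, so
  ``width = x_max - x_min``.
* Frames are indexed from 0; wall-clock time is ``t = frame_index / fps``.
* Keypoints follow the 17-point COCO convention (nose, eyes, ears,
  shoulders, elbows, wrists, hips, knees, ankles), each entry ``(x, y,
  confidence)`` with confidence in ``[0, 1]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

#: Number of keypoints per person hypothesis (COCO convention).
N_KEYPOINTS = 17

#: COCO keypoint names, in order.
COCO_KEYPOINT_NAMES = (
    "nose",
    "left_eye",
    "right_eye",
    "left_ear",
    "right_ear",
    "left_shoulder",
    "right_shoulder",
    "left_elbow",
    "right_elbow",
    "left_wrist",
    "right_wrist",
    "left_hip",
    "right_hip",
    "left_knee",
    "right_knee",
    "left_ankle",
    "right_ankle",
)

#: The five action classes, in the fixed label order used by every stage.
ACTION_LABELS = ("sit", "sit-to-stand", "stand", "walk", "stand-to-sit")

LABEL_TO_INDEX = {label: i for i, label in enumerate(ACTION_LABELS)}


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


@dataclass
class Detection:
    """One person hypothesis in one frame.

    Parameters
    ----------
    frame_index
        0-based frame number, non-negative.
    box
        ``(x_min, y_min, x_max, y_max)`` pixel box, half-open.
    box_conf
        Detector confidence for the box, in ``[0, 1]``.
    keypoints
        Array of shape ``(17, 3)``; columns are x, y, confidence.
    appearance
        Optional fixed-dimension appearance vector (either produced by the
        scene simulator or by an image-patch embedder).
    """

    frame_index: int
    box: tuple[float, float, float, float]
    box_conf: float
    keypoints: np.ndarray
    appearance: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.box = tuple(float(v) for v in self.box)
        if len(self.box) != 4:
            raise ValidationError(f"box must have 4 coordinates, got {len(self.box)}")
        x0, y0, x1, y1 = self.box
        if not (x0 < x1 and y0 < y1):
            raise ValidationError(f"degenerate box {self.box}: need x_min < x_max and y_min < y_max")
        if self.frame_index < 0:
            raise ValidationError(f"frame_index must be >= 0, got {self.frame_index}")
        if not (0.0 <= self.box_conf <= 1.0):
            raise ValidationError(f"box_conf must be in [0, 1], got {self.box_conf}")
        kp = np.asarray(self.keypoints, dtype=float)
        if kp.shape != (N_KEYPOINTS, 3):
            raise ValidationError(
                f"keypoints must have shape ({N_KEYPOINTS}, 3), got {kp.shape}"
            )
        conf = kp[:, 2]
        if np.any(conf < 0.0) or np.any(conf > 1.0):
            raise ValidationError("keypoint confidences must be in [0, 1]")
        self.keypoints = kp
        if self.appearance is not None:
            vec = np.asarray(self.appearance, dtype=float)
            if vec.ndim != 1 or vec.size == 0:
                raise ValidationError("appearance must be a non-empty 1-D vector")
            if not np.all(np.isfinite(vec)):
                raise ValidationError("appearance vector must be finite")
            self.appearance = vec


@dataclass
class FrameDetections:
    """All person hypotheses for a single frame (possibly none)."""

    frame_index: int
    detections: list[Detection] = field(default_factory=list)

    def __post_init__(self) -> None:
        for det in self.detections:
            if det.frame_index != self.frame_index:
                raise ValidationError(
                    f"detection frame_index {det.frame_index} != frame {self.frame_index}"
                )

    def __len__(self) -> int:
        return len(self.detections)


@dataclass(frozen=True)
class AnnotationSegment:
    """A rater-annotated action interval for one subject.

    ``start_frame`` and ``end_frame`` are inclusive; the segment spans
    ``end_frame - start_frame + 1`` frames.
    """

    subject_id: str
    start_frame: int
    end_frame: int
    label: str

    def __post_init__(self) -> None:
        if self.label not in ACTION_LABELS:
            raise ValidationError(
                f"unknown label {self.label!r}; allowed labels: {', '.join(ACTION_LABELS)}"
            )
        if self.start_frame > self.end_frame:
            raise ValidationError(
                f"start_frame {self.start_frame} > end_frame {self.end_frame}"
            )
        if self.start_frame < 0:
            raise ValidationError("start_frame must be >= 0")

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame + 1

    def duration_s(self, fps: float) -> float:
        return self.n_frames / fps


def validate_segments_non_overlapping(segments: Iterable[AnnotationSegment]) -> None:
    """Check that segments are non-overlapping within each subject."""
    by_subject: dict[str, list[AnnotationSegment]] = {}
    for seg in segments:
        by_subject.setdefault(seg.subject_id, []).append(seg)
    for subject, segs in by_subject.items():
        ordered = sorted(segs, key=lambda s: s.start_frame)
        for prev, cur in zip(ordered, ordered[1:]):
            if cur.start_frame <= prev.end_frame:
                raise ValidationError(
                    f"overlapping segments for subject {subject!r}: "
                    f"[{prev.start_frame}, {prev.end_frame}] and "
                    f"[{cur.start_frame}, {cur.end_frame}]"
                )


def iter_stream_detections(stream: Sequence[FrameDetections]) -> Iterable[Detection]:
    """Flatten a frame stream into its detections, in frame order."""
    for frame in stream:
        yield from frame.detections
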