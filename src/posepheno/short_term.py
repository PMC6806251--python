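"""Short-term tracking: IoU-based bipartite matching between consecutive
frames, solved with the Hungarian algorithm.

Detections in frame ``t`` are matched one-to-one against the last boxes of
the tracklets alive at frame ``t - 1`` so as to maximise total IoU; pairs
whose IoU falls below the threshold (or is exactly zero, i.e. the boxes do
not overlap at all) are demoted to unmatched.  Unmatched current boxes
start new tracklets; a tracklet that misses even a single frame is closed —
recovering identities across gaps is the long-term tracker's job.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .types import Detection, FrameDetections, ValidationError

Box = tuple[float, float, float, float]


def iou(box_a: Sequence[float], box_b: Sequence[float]) -> float:
    """Intersection over union of two half-open axis-aligned boxes."""
    ax0, ay0, ax1, ay1 = box_a
    bx0, by0, bx1, by1 = box_b
    area_a = (ax1 - ax0) * (ay1 - ay0)
    area_b = (bx1 - bx0) * (by1 - by0)
    if area_a <= 0 or area_b <= 0:
        raise ValidationError(f"degenerate (zero-area) box: {box_a} / {box_b}")
    ix = max(0.0, min(ax1, bx1) - max(ax0, bx0))
    iy = max(0.0, min(ay1, by1) - max(ay0, by0))
    inter = ix * iy
    return inter / (area_a + area_b - inter)


def iou_matrix(prev: Sequence[Box], cur: Sequence[Box]) -> np.ndarray:
    """Pairwise IoU, shape ``(len(prev), len(cur))``."""
    mat = np.zeros((len(prev), len(cur)))
    for i, a in enumerate(prev):
        for j, b in enumerate(cur):
            mat[i, j] = iou(a, b)
    return mat


def match_frames(
    prev: Sequence[Box],
    cur: Sequence[Box],
    iou_threshold: float = 0.1,
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """One-to-one box assignment between two frames.

    Maximises total IoU (equivalently minimises Σ(1 − IoU) over the padded
    square problem); any assigned pair with IoU below the threshold, or
    with no overlap at all, is demoted to unmatched.  Ties between
    equal-cost assignments are broken towards the lowest combined index
    order, which is what ``linear_sum_assignment`` produces on a cost
    matrix scanned row-major.

    Returns
    -------
    (matched, unmatched_prev, unmatched_cur)
        ``matched`` is a list of ``(prev_index, cur_index)`` pairs; each
        input box appears in exactly one of the three buckets.
    """
    if not (0.0 <= iou_threshold <= 1.0):
        raise ValidationError(f"iou_threshold must be in [0, 1], got {iou_threshold}")
    if not prev or not cur:
        return [], list(range(len(prev))), list(range(len(cur)))
    scores = iou_matrix(prev, cur)
    rows, cols = linear_sum_assignment(1.0 - scores)
    matched = []
    matched_prev, matched_cur = set(), set()
    for i, j in zip(rows, cols):
        s = scores[i, j]
        if s <= 0.0 or s < iou_threshold:
            continue  # demoted: non-overlapping or below threshold
        matched.append((int(i), int(j)))
        matched_prev.add(int(i))
        matched_cur.add(int(j))
    unmatched_prev = [i for i in range(len(prev)) if i not in matched_prev]
    unmatched_cur = [j for j in range(len(cur)) if j not in matched_cur]
    return matched, unmatched_prev, unmatched_cur


@dataclass
class Tracklet:
    """An identity-consistent run of detections over consecutive frames."""

    tracklet_id: int
    detections: list[Detection] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.detections:
            raise ValidationError("tracklet must contain at least one detection")
        frames = [d.frame_index for d in self.detections]
        if any(b - a != 1 for a, b in zip(frames, frames[1:])):
            raise ValidationError("tracklet frames must be consecutive with no gaps")

    @property
    def start_frame(self) -> int:
        return self.detections[0].frame_index

    @property
    def end_frame(self) -> int:
        return self.detections[-1].frame_index

    def __len__(self) -> int:
        return len(self.detections)

    def mean_keypoint_score(self, conf_threshold: float = 0.5) -> float:
        """Mean over detections of the fraction of confident keypoints.

        A keypoint counts as "estimated" when its confidence is at least
        ``conf_threshold``; this realises length/keypoint-count pruning.
        """
        fracs = [
            float(np.mean(d.keypoints[:, 2] >= conf_threshold)) for d in self.detections
        ]
        return float(np.mean(fracs))


def build_tracklets(
    stream: Sequence[FrameDetections],
    iou_threshold: float = 0.1,
) -> list[Tracklet]:
    """Link a detection stream into tracklets frame by frame.

    Tracklets are initialised on the first frame and propagated forward one
    frame at a time; any unmatched box instantiates a new tracklet.  Every
    input detection ends up in exactly one tracklet; ids are assigned in
    order of creation.
    """
    # each run carries its creation index so ids are stable and deterministic
    finished: list[tuple[int, list[Detection]]] = []
    active: list[tuple[int, list[Detection]]] = []  # creation-ordered
    next_id = 0
    prev_frame_index: int | None = None

    for frame in stream:
        if prev_frame_index is not None and frame.frame_index != prev_frame_index + 1:
            # a gap in the frame index closes every active tracklet
            finished.extend(active)
            active = []
        if active:
            prev_boxes = [run[-1].box for _, run in active]
            cur_boxes = [d.box for d in frame.detections]
            matched, unmatched_prev, unmatched_cur = match_frames(
                prev_boxes, cur_boxes, iou_threshold
            )
        else:
            matched, unmatched_prev = [], []
            unmatched_cur = list(range(len(frame.detections)))

        new_active = []
        for i, j in sorted(matched):
            active[i][1].append(frame.detections[j])
            new_active.append(active[i])
        for i in unmatched_prev:
            finished.append(active[i])
        for j in unmatched_cur:
            new_active.append((next_id, [frame.detections[j]]))
            next_id += 1
        new_active.sort(key=lambda p: p[0])
        active = new_active
        prev_frame_index = frame.frame_index

    finished.extend(active)
    finished.sort(key=lambda p: p[0])
    return [Tracklet(tracklet_id=k, detections=run) for k, run in finished]
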