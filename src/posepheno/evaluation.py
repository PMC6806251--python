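"""Evaluation metrics: confusion matrix, per-class and weighted accuracy,
tracker binary accuracy, and the end-to-end report.

Convention: confusion-matrix rows are the true label, columns the
predicted label, both in the fixed order sit, sit-to-stand, stand, walk,
stand-to-sit.  The weighted overall accuracy is the class-support-weighted
mean of per-class accuracies, which is identically trace / total.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .long_term import Track, tracklet_classification_accuracy
from .types import ACTION_LABELS, LABEL_TO_INDEX, ValidationError


def _to_indices(labels: Sequence) -> np.ndarray:
    out = []
    for lab in labels:
        if isinstance(lab, str):
            if lab not in LABEL_TO_INDEX:
                raise ValidationError(f"unknown label {lab!r}")
            out.append(LABEL_TO_INDEX[lab])
        else:
            idx = int(lab)
            if not (0 <= idx < len(ACTION_LABELS)):
                raise ValidationError(f"label index {idx} out of range")
            out.append(idx)
    return np.asarray(out, dtype=np.int64)


def confusion(true_labels: Sequence, pred_labels: Sequence) -> np.ndarray:
    """5×5 count matrix, rows = truth, columns = prediction."""
    y_true = _to_indices(true_labels)
    y_pred = _to_indices(pred_labels)
    if len(y_true) != len(y_pred):
        raise ValidationError(
            f"label length mismatch: {len(y_true)} vs {len(y_pred)}"
        )
    k = len(ACTION_LABELS)
    cm = np.zeros((k, k), dtype=np.int64)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def per_class_accuracy(cm: np.ndarray) -> dict[str, float]:
    """Diagonal over row sum, per class; classes with no support omitted."""
    cm = np.asarray(cm)
    if cm.size == 0:
        raise ValidationError("empty confusion matrix")
    supports = cm.sum(axis=1)
    out = {}
    for i, label in enumerate(ACTION_LABELS[: cm.shape[0]]):
        if supports[i] > 0:
            out[label] = float(cm[i, i] / supports[i])
    return out


def weighted_overall_accuracy(cm: np.ndarray) -> float:
    """Support-weighted mean of per-class accuracies = trace / total."""
    cm = np.asarray(cm)
    total = cm.sum()
    if cm.size == 0 or total == 0:
        raise ValidationError("empty confusion matrix")
    return float(np.trace(cm) / total)


def end_to_end_report(
    tracklet_truth: Sequence[bool],
    tracklet_pred: Sequence[bool],
    target_visible_frames: Sequence[int],
    track: Track,
    clip_true_labels: Sequence,
    clip_pred_labels: Sequence,
) -> dict:
    """Bundle the pipeline metrics into a JSON-serializable report.

    Covers the tracker treated as a binary classifier, the fused track's
    coverage of the target's visible frames, clip counts per class, the
    confusion matrix and weighted overall accuracy.
    """
    cm = confusion(clip_true_labels, clip_pred_labels)
    visible = set(int(f) for f in target_visible_frames)
    covered = visible & set(track.frames)
    counts = {label: 0 for label in ACTION_LABELS}
    for lab in clip_true_labels:
        name = lab if isinstance(lab, str) else ACTION_LABELS[int(lab)]
        counts[name] += 1
    return {
        "tracklet_binary_accuracy": tracklet_classification_accuracy(
            tracklet_pred, tracklet_truth
        ),
        "track_frame_coverage": (len(covered) / len(visible)) if visible else 0.0,
        "n_tracklets": len(tracklet_truth),
        "clip_counts": counts,
        "confusion_matrix": cm.tolist(),
        "per_class_accuracy": per_class_accuracy(cm),
        "weighted_overall_accuracy": weighted_overall_accuracy(cm),
    }


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
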