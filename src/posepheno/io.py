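"""Readers and writers for the on-disk formats.

* ``detections.jsonl`` — one frame per line:
  ``{"frame": int, "detections": [{"box": [x0, y0, x1, y1], "box_conf": f,
  "keypoints": [[x, y, c] * 17], "appearance": [f * D]?}, ...]}``.
  JSON-lines rather than one monolithic document so long videos can be
  streamed frame by frame.
* ``annotations.csv`` — header ``subject_id,start_frame,end_frame,label``;
  frames inclusive; labels restricted to the five action classes.
* tracklets / tracks / clips — plain CSV via pandas.
* pose-evolution maps — a compressed NPZ keyed by clip id, with a JSON
  sidecar of labels.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .types import (
    ACTION_LABELS,
    AnnotationSegment,
    Detection,
    FrameDetections,
    ValidationError,
    validate_segments_non_overlapping,
)


class ParseError(ValueError):
    """Raised when an on-disk record cannot be decoded."""


# ---------------------------------------------------------------------------
# Detection streams (JSON-lines)
# ---------------------------------------------------------------------------

def _detection_to_obj(det: Detection) -> dict:
    obj = {
        "box": [float(v) for v in det.box],
        "box_conf": float(det.box_conf),
        "keypoints": [[float(x), float(y), float(c)] for x, y, c in det.keypoints],
    }
    if det.appearance is not None:
        obj["appearance"] = [float(v) for v in det.appearance]
    return obj


def write_detections(stream: Iterable[FrameDetections], path: str | Path) -> None:
    """Serialize a frame stream to JSON-lines with full float precision."""
    appearance_dim: int | None = None
    with open(path, "w") as fh:
        for frame in stream:
            for det in frame.detections:
                if det.appearance is not None:
                    if appearance_dim is None:
                        appearance_dim = det.appearance.size
                    elif det.appearance.size != appearance_dim:
                        raise ValidationError(
                            "appearance vectors have mixed dimensions: "
                            f"{appearance_dim} vs {det.appearance.size}"
                        )
            record = {
                "frame": int(frame.frame_index),
                "detections": [_detection_to_obj(d) for d in frame.detections],
            }
            # repr-roundtrip floats: json keeps full double precision
            fh.write(json.dumps(record) + "\n")


def read_detections(path: str | Path) -> list[FrameDetections]:
    """Read a detection stream, validating schema and frame ordering."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such detection file: {path}")
    frames: list[FrameDetections] = []
    last_index = -1
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                record = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ParseError(f"{path}:{lineno}: invalid JSON: {exc}") from exc
            try:
                frame_index = int(record["frame"])
                dets = []
                for obj in record["detections"]:
                    kp = np.asarray(obj["keypoints"], dtype=float)
                    if kp.ndim != 2 or kp.shape != (17, 3):
                        raise ValidationError(
                            f"expected 17 keypoints of (x, y, conf), got shape {kp.shape}"
                        )
                    dets.append(
                        Detection(
                            frame_index=frame_index,
                            box=tuple(obj["box"]),
                            box_conf=float(obj["box_conf"]),
                            keypoints=kp,
                            appearance=(
                                np.asarray(obj["appearance"], dtype=float)
                                if "appearance" in obj
                                else None
                            ),
                        )
                    )
            except (KeyError, TypeError, ValidationError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if frame_index <= last_index:
                raise ValidationError(
                    f"{path}:{lineno}: frame_index {frame_index} not strictly "
                    f"increasing (previous {last_index})"
                )
            last_index = frame_index
            frames.append(FrameDetections(frame_index=frame_index, detections=dets))
    return frames


# ---------------------------------------------------------------------------
# Annotations (CSV)
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = ["subject_id", "start_frame", "end_frame", "label"]


def write_annotations(segments: Sequence[AnnotationSegment], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "subject_id": s.subject_id,
                "start_frame": s.start_frame,
                "end_frame": s.end_frame,
                "label": s.label,
            }
            for s in segments
        ],
        columns=ANNOTATION_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_annotations(path: str | Path) -> list[AnnotationSegment]:
    """Read annotation segments; rejects unknown labels and overlaps."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such annotation file: {path}")
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    segments = []
    for _, row in df.iterrows():
        label = str(row["label"])
        if label not in ACTION_LABELS:
            raise ValidationError(
                f"unknown label {label!r}; allowed labels: {', '.join(ACTION_LABELS)}"
            )
        segments.append(
            AnnotationSegment(
                subject_id=str(row["subject_id"]),
                start_frame=int(row["start_frame"]),
                end_frame=int(row["end_frame"]),
                label=label,
            )
        )
    validate_segments_non_overlapping(segments)
    return segments


# ---------------------------------------------------------------------------
# Pose-evolution map containers (NPZ + JSON sidecar)
# ---------------------------------------------------------------------------

def write_maps(
    maps: dict[str, np.ndarray],
    labels: dict[str, str],
    path: str | Path,
) -> None:
    """Write pose-evolution maps keyed by clip id, labels in a sidecar."""
    path = Path(path)
    np.savez_compressed(path, **{str(k): np.asarray(v) for k, v in maps.items()})
    sidecar = path.with_suffix(path.suffix + ".labels.json")
    sidecar.write_text(json.dumps({str(k): labels.get(k) for k in maps}, indent=0))


def read_maps(path: str | Path) -> tuple[dict[str, np.ndarray], dict[str, str]]:
    path = Path(path)
    with np.load(path) as npz:
        maps = {k: npz[k] for k in npz.files}
    sidecar = path.with_suffix(path.suffix + ".labels.json")
    labels = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return maps, labels
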