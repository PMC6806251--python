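"""Shared fixtures: small hand-built detections and streams."""

from __future__ import annotations

import numpy as np
import pytest

from posepheno.types import Detection, FrameDetections


def make_keypoints(x: float = 50.0, y: float = 100.0, conf: float = 0.9) -> np.ndarray:
    """A blob of 17 keypoints around (x, y) with uniform confidence."""
    rng = np.random.default_rng(abs(hash((round(x), round(y)))) % 2**31)
    kp = np.column_stack(
        [
            x + rng.uniform(-10, 10, 17),
            y + rng.uniform(-20, 20, 17),
            np.full(17, conf),
        ]
    )
    return kp


def make_detection(
    frame: int,
    x: float = 50.0,
    y: float = 100.0,
    size: float = 40.0,
    box_conf: float = 0.9,
    kp_conf: float = 0.9,
    appearance=None,
) -> Detection:
    return Detection(
        frame_index=frame,
        box=(x - size / 2, y - size, x + size / 2, y + size),
        box_conf=box_conf,
        keypoints=make_keypoints(x, y, kp_conf),
        appearance=appearance,
    )


def make_stream(
    n_frames: int,
    actors: list[dict],
) -> list[FrameDetections]:
    """Stream of moving boxes; each actor dict: x0, y0, vx (px/frame),
    optionally absent_frames (set)."""
    frames = []
    for f in range(n_frames):
        dets = []
        for actor in actors:
            if f in actor.get("absent_frames", set()):
                continue
            dets.append(
                make_detection(
                    f,
                    x=actor["x0"] + f * actor.get("vx", 0.0),
                    y=actor.get("y0", 100.0),
                    size=actor.get("size", 40.0),
                    appearance=actor.get("appearance"),
                )
            )
        frames.append(FrameDetections(frame_index=f, detections=dets))
    return frames


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
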