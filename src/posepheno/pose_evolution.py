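"""Pose-evolution maps: time-encoded, colorized joint heatmaps.

A clip of F frames of 2D body keypoints is summarised as a fixed-size
tensor.  Per frame and joint, a Gaussian heatmap encodes the estimated
joint location (amplitude = keypoint confidence).  Each frame's heatmaps
are spread over C colour channels by a piecewise-linear time-encoding
o_j(t) of the frame's relative time t ∈ [0, 1], the weighted heatmaps are
summed over the clip, and every (joint, channel) slice is normalised by
its own spatial maximum.  Concatenating the 14 joint maps joint-major
yields the (14·C) × H × W pose-evolution map.

The time axis is divided into C−1 intervals of length l = T/(C−1); on
interval k the encoding ramps channel k down linearly and channel k+1 up,
so the channels form a continuous partition of unity (triangular
profiles with one-hot endpoints).

The 17 COCO keypoints are reduced to 14 joints by merging the four eye and
ear keypoints into a single "head" keypoint at their confidence-weighted
mean (confidence = mean of the four), keeping the nose; output order:
nose, head, then shoulders, elbows, wrists, hips, knees, ankles
(left before right).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .types import ValidationError

#: Joints of the reduced skeleton, in slice order.
REDUCED_JOINT_NAMES = (
    "nose",
    "head",
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

N_REDUCED = 14

#: Keypoints below this confidence are treated as missing (zero heatmap).
MIN_KEYPOINT_CONF = 0.05

#: Gaussians are evaluated within this many sigmas of the centre and are
#: exactly zero beyond (tail mass < 1e-7; spatial maxima are unaffected).
GAUSSIAN_CUTOFF_SIGMAS = 6.0

_HEAD_PARTS = (1, 2, 3, 4)  # left_eye, right_eye, left_ear, right_ear
_BODY_PARTS = tuple(range(5, 17))


def reduce_keypoints(kp17: np.ndarray) -> np.ndarray:
    """Reduce 17 COCO keypoints to the 14-joint skeleton.

    Parameters
    ----------
    kp17
        Array ``(17, 3)`` of (x, y, confidence).

    Returns
    -------
    Array ``(14, 3)`` in :data:`REDUCED_JOINT_NAMES` order.  When all four
    head parts have zero confidence the head keypoint has confidence 0 at
    an undefined (zero) location, which downstream renders as a zero
    heatmap.
    """
    kp17 = np.asarray(kp17, dtype=float)
    if kp17.shape != (17, 3):
        raise ValidationError(f"expected (17, 3) keypoints, got {kp17.shape}")
    out = np.zeros((N_REDUCED, 3))
    out[0] = kp17[0]  # nose
    head = kp17[list(_HEAD_PARTS)]
    weights = head[:, 2]
    total = weights.sum()
    if total > 0:
        out[1, :2] = (head[:, :2] * weights[:, None]).sum(axis=0) / total
    out[1, 2] = weights.mean()
    out[2:] = kp17[list(_BODY_PARTS)]
    return out


def time_encoding(t: float, T: float = 1.0, C: int = 3) -> np.ndarray:
    """Piecewise-linear channel weights for a frame at time ``t``.

    With l = T/(C−1) and k = min(C−1, ⌊t/l⌋ + 1):
    o_k(t) = (k·l − t)/l, o_{k+1}(t) = (t − (k−1)·l)/l, all others 0.
    The weights are in [0, 1] and sum to 1 for every t in [0, T].
    """
    if C < 2:
        raise ValidationError("C must be >= 2")
    if not (0.0 <= t <= T):
        raise ValidationError(f"t = {t} outside [0, {T}]")
    # r = t / l is the fractional interval position; computed this way the
    # endpoints come out exactly one-hot
    r = t * (C - 1) / T
    k = min(C - 1, int(math.floor(r)) + 1)
    u = min(1.0, max(0.0, r - (k - 1)))
    out = np.zeros(C)
    out[k - 1] = 1.0 - u
    out[k] = u
    return out


def _gaussian_window(
    acc: np.ndarray, weights: np.ndarray, x: float, y: float, conf: float, sigma: float
) -> None:
    """Add ``weights[c] * conf * G_{x,y,sigma}`` into ``acc`` (C, H, W), in place."""
    H, W = acc.shape[-2:]
    r = GAUSSIAN_CUTOFF_SIGMAS * sigma
    x0 = max(0, int(math.ceil(x - r)))
    x1 = min(W, int(math.floor(x + r)) + 1)
    y0 = max(0, int(math.ceil(y - r)))
    y1 = min(H, int(math.floor(y + r)) + 1)
    if x0 >= x1 or y0 >= y1:
        return
    xs = np.arange(x0, x1) - x
    ys = np.arange(y0, y1) - y
    g = conf * np.exp(-(ys[:, None] ** 2 + xs[None, :] ** 2) / (2.0 * sigma**2))
    acc[..., y0:y1, x0:x1] += weights[:, None, None] * g


def joint_heatmap(
    keypoint: Sequence[float], conf: float, H: int, W: int, sigma: float
) -> np.ndarray:
    """Gaussian heatmap for one joint in one frame.

    Grid value at (x, y) is ``conf · exp(−((x−kx)² + (y−ky)²) / 2σ²)``
    (zero beyond the numerical cutoff radius).  A keypoint outside the
    grid is fine — whatever tail falls inside is kept.
    """
    if sigma <= 0:
        raise ValidationError("sigma must be > 0")
    grid = np.zeros((1, H, W))
    if conf > 0:
        kx, ky = float(keypoint[0]), float(keypoint[1])
        _gaussian_window(grid, np.ones(1), kx, ky, float(conf), sigma)
    return grid[0]


@dataclass
class PoseEvolutionMap:
    """A (14·C) × H × W pose-evolution tensor for one clip."""

    tensor: np.ndarray
    channels: int
    clip_id: Optional[str] = None
    label: Optional[str] = None

    def joint_slice(self, joint: int, channel: int) -> np.ndarray:
        """The H × W slice for (joint, channel), joint-major layout."""
        return self.tensor[joint * self.channels + channel]

    @property
    def shape(self) -> tuple[int, ...]:
        return self.tensor.shape


def pose_evolution_map(
    keypoint_sequence: np.ndarray,
    C: int = 3,
    H: int = 135,
    W: int = 240,
    sigma: float = 2.0,
    clip_id: Optional[str] = None,
    label: Optional[str] = None,
) -> PoseEvolutionMap:
    """Aggregate a clip's keypoints into a pose-evolution map.

    Parameters
    ----------
    keypoint_sequence
        ``(F, 17, 3)`` (reduced internally) or ``(F, 14, 3)`` keypoints in
        heatmap-grid pixel coordinates.  Frame f maps to relative time
        ``t = f / (F − 1)`` (t = 0 for a single-frame clip).
    C, H, W, sigma
        Channels, grid size, Gaussian width (grid pixels).

    Each (joint, channel) slice is the time-weighted sum of that joint's
    heatmaps, divided by its own spatial maximum; a slice whose maximum is
    zero is left all-zero.  Keypoints with confidence below
    :data:`MIN_KEYPOINT_CONF` contribute nothing.
    """
    seq = np.asarray(keypoint_sequence, dtype=float)
    if seq.ndim != 3 or seq.shape[2] != 3:
        raise ValidationError(f"expected (F, 17|14, 3) keypoints, got {seq.shape}")
    F = seq.shape[0]
    if F < 1:
        raise ValidationError("clip must contain at least one frame")
    if seq.shape[1] == 17:
        seq = np.stack([reduce_keypoints(frame) for frame in seq])
    elif seq.shape[1] != N_REDUCED:
        raise ValidationError(f"expected 17 or {N_REDUCED} joints, got {seq.shape[1]}")

    encodings = np.stack(
        [time_encoding(f / (F - 1) if F > 1 else 0.0, 1.0, C) for f in range(F)]
    )  # (F, C)

    acc = np.zeros((N_REDUCED, C, H, W))
    for i in range(N_REDUCED):
        for f in range(F):
            x, y, conf = seq[f, i]
            if conf < MIN_KEYPOINT_CONF:
                continue
            _gaussian_window(acc[i], encodings[f], x, y, conf, sigma)

    maxima = acc.max(axis=(2, 3), keepdims=True)
    nonzero = maxima > 0
    np.divide(acc, maxima, out=acc, where=nonzero)
    if not nonzero.any():
        warnings.warn("clip produced an all-zero pose-evolution map", stacklevel=2)
    tensor = acc.reshape(N_REDUCED * C, H, W)
    return PoseEvolutionMap(tensor=tensor, channels=C, clip_id=clip_id, label=label)


def augment(
    pe_map: PoseEvolutionMap, noise_sigma: float, seed: int
) -> PoseEvolutionMap:
    """Additive white-noise augmentation, clipped back to [0, 1]."""
    if noise_sigma < 0:
        raise ValidationError("noise_sigma must be >= 0")
    if noise_sigma == 0:
        return PoseEvolutionMap(
            tensor=pe_map.tensor.copy(),
            channels=pe_map.channels,
            clip_id=pe_map.clip_id,
            label=pe_map.label,
        )
    rng = np.random.default_rng(seed)
    noisy = pe_map.tensor + rng.normal(0.0, noise_sigma, size=pe_map.tensor.shape)
    np.clip(noisy, 0.0, 1.0, out=noisy)
    return PoseEvolutionMap(
        tensor=noisy, channels=pe_map.channels, clip_id=pe_map.clip_id, label=pe_map.label
    )


def scale_keypoints(keypoints: np.ndarray, factor: float) -> np.ndarray:
    """Scale keypoint x/y coordinates (confidences untouched)."""
    out = np.array(keypoints, dtype=float, copy=True)
    out[..., :2] *= factor
    return out
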