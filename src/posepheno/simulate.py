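"""Synthetic multi-actor keypoint scenes with ground-truth identities.

The clinical recordings the pipeline is designed for — untrimmed
multi-person videos of a target subject performing sit / stand / walk /
transition actions, with staff walking through, long occlusions and scene
cuts — are emulated here at the keypoint level.  Actors are parametric
2D skeletons (17 COCO keypoints) driven by scripted action kinematics;
each visible actor yields one detection per frame with Gaussian keypoint
jitter, a padded tight bounding box, and an appearance vector drawn from
an identity-specific Gaussian cluster.  Appearance vectors are generated
data, not rendered pixels: the identity-cluster model preserves exactly
the property the appearance-affinity fusion exploits (intra-identity
distances ≪ inter-identity distances).

Everything is driven by a single seeded generator, so the same
configuration and seed reproduce the stream byte-for-byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .types import (
    ACTION_LABELS,
    AnnotationSegment,
    Detection,
    FrameDetections,
    ValidationError,
)

#: Default appearance-vector dimension.
DEFAULT_APPEARANCE_DIM = 16

#: Default appearance cluster spread around each identity vector.
DEFAULT_APPEARANCE_NOISE = 0.05

#: Walking cadence (gait cycles per second) of the scripted skeleton.
WALK_CADENCE_HZ = 1.2

#: Root advance while walking, in units of skeleton scale per second.
WALK_SPEED_SCALES_PER_S = 0.45

# COCO indices
_L_ANKLE, _R_ANKLE = 15, 16
_L_WRIST, _R_WRIST = 9, 10
_L_HIP, _R_HIP = 11, 12

# Canonical skeletons: (x, y) offsets from the actor's ground anchor in
# units of skeleton scale; y is negative above the ground (image y is down).
_STAND = np.array(
    [
        (0.00, -1.02),  # nose
        (-0.03, -1.05), (0.03, -1.05),  # eyes
        (-0.06, -1.03), (0.06, -1.03),  # ears
        (-0.14, -0.90), (0.14, -0.90),  # shoulders
        (-0.18, -0.70), (0.18, -0.70),  # elbows
        (-0.20, -0.50), (0.20, -0.50),  # wrists
        (-0.10, -0.52), (0.10, -0.52),  # hips
        (-0.11, -0.26), (0.11, -0.26),  # knees
        (-0.12, -0.02), (0.12, -0.02),  # ankles
    ]
)

_SIT = np.array(
    [
        (0.00, -0.80),
        (-0.03, -0.83), (0.03, -0.83),
        (-0.06, -0.81), (0.06, -0.81),
        (-0.14, -0.68), (0.14, -0.68),
        (-0.18, -0.48), (0.18, -0.48),
        (-0.20, -0.30), (0.20, -0.30),
        (-0.10, -0.30), (0.10, -0.30),  # hips lowered
        (-0.20, -0.28), (0.20, -0.28),  # knees forward
        (-0.22, -0.02), (0.22, -0.02),
    ]
)

_ANKLE_SWING = 0.12  # scale units, horizontal
_ANKLE_LIFT = 0.06  # scale units, vertical
_WRIST_SWING = 0.10


def pose_template(label: str, phase: float, scale: float) -> np.ndarray:
    """Canonical 17-keypoint skeleton for an action at a given phase.

    Coordinates are pixels relative to the actor's ground anchor (y up is
    negative); confidences are 1.  ``phase`` is the position within the
    action cycle (walk) or transition (sit-to-stand / stand-to-sit),
    in [0, 1).

    * sit / stand — static canonical postures (phase ignored).
    * walk — upright posture with antiphase sinusoidal ankle/wrist
      oscillation; horizontal root translation is the caller's job.
    * sit-to-stand — linear interpolation sit → stand at ``phase``;
      stand-to-sit is the same path reversed.
    """
    if label not in ACTION_LABELS:
        raise ValidationError(
            f"unknown label {label!r}; allowed labels: {', '.join(ACTION_LABELS)}"
        )
    if label == "sit":
        xy = _SIT.copy()
    elif label == "stand":
        xy = _STAND.copy()
    elif label == "sit-to-stand":
        xy = (1.0 - phase) * _SIT + phase * _STAND
    elif label == "stand-to-sit":
        return pose_template("sit-to-stand", 1.0 - phase, scale)
    else:  # walk
        xy = _STAND.copy()
        s = math.sin(2.0 * math.pi * phase)
        xy[_L_ANKLE] += (_ANKLE_SWING * s, -_ANKLE_LIFT * max(0.0, s))
        xy[_R_ANKLE] += (-_ANKLE_SWING * s, -_ANKLE_LIFT * max(0.0, -s))
        # arms swing opposite the same-side leg
        xy[_L_WRIST] += (-_WRIST_SWING * s, 0.0)
        xy[_R_WRIST] += (_WRIST_SWING * s, 0.0)
    out = np.ones((17, 3))
    out[:, :2] = xy * scale
    return out


@dataclass
class ActorSpec:
    """One scripted actor: identity cluster + skeleton geometry."""

    actor_id: str
    identity_vector: np.ndarray
    appearance_noise_sigma: float = DEFAULT_APPEARANCE_NOISE
    skeleton_scale: float = 520.0
    #: vertical ground-line position as a fraction of frame height; actors
    #: at different depths from the camera stand on different lines
    ground_frac: float = 0.92
    is_target: bool = False

    def __post_init__(self) -> None:
        vec = np.asarray(self.identity_vector, dtype=float)
        if vec.ndim != 1:
            raise ValidationError("identity_vector must be 1-D")
        if self.appearance_noise_sigma < 0:
            raise ValidationError("appearance_noise_sigma must be >= 0")
        self.identity_vector = vec


@dataclass
class ScenarioConfig:
    """A full scripted scene: actors, target action script, disturbances."""

    n_frames: int
    actors: list[ActorSpec]
    action_script: list[tuple[str, float]]  # (label, duration seconds) for the target
    fps: float = 30.0
    occlusion_windows: list[tuple[str, int, int]] = field(default_factory=list)
    scene_changes: list[int] = field(default_factory=list)
    keypoint_jitter_sigma: float = 1.0
    detection_dropout_prob: float = 0.0
    frame_size: tuple[int, int] = (1080, 1920)  # (height, width)
    seed: int = 0

    def __post_init__(self) -> None:
        targets = [a for a in self.actors if a.is_target]
        if len(targets) != 1:
            raise ValidationError(
                f"exactly one actor must be the target, got {len(targets)}"
            )
        ids = [a.actor_id for a in self.actors]
        if len(set(ids)) != len(ids):
            raise ValidationError("actor ids must be unique")
        vecs = [a.identity_vector for a in self.actors]
        for i in range(len(vecs)):
            for j in range(i + 1, len(vecs)):
                if vecs[i].shape == vecs[j].shape and np.allclose(vecs[i], vecs[j]):
                    raise ValidationError("identity vectors of distinct actors must differ")
        for actor_id, start, end in self.occlusion_windows:
            if actor_id not in ids:
                raise ValidationError(f"occlusion window for unknown actor {actor_id!r}")
            if not (0 <= start < end <= self.n_frames):
                raise ValidationError(
                    f"occlusion window [{start}, {end}) outside [0, {self.n_frames})"
                )
        for f in self.scene_changes:
            if not (0 <= f < self.n_frames):
                raise ValidationError(f"scene change frame {f} outside [0, {self.n_frames})")
        if any(d <= 0 for _, d in self.action_script):
            raise ValidationError("action script durations must be positive")
        script_frames = sum(round(d * self.fps) for _, d in self.action_script)
        if script_frames != self.n_frames:
            raise ValidationError(
                f"action script covers {script_frames} frames but scenario has "
                f"{self.n_frames}; durations must sum to n_frames / fps"
            )

    @property
    def target(self) -> ActorSpec:
        return next(a for a in self.actors if a.is_target)


def random_actors(
    n_actors: int,
    seed: int,
    dim: int = DEFAULT_APPEARANCE_DIM,
    appearance_noise_sigma: float = DEFAULT_APPEARANCE_NOISE,
    min_separation: float = 1.0,
    skeleton_scale: float = 520.0,
) -> list[ActorSpec]:
    """Draw actors with identity vectors on the unit sphere.

    Vectors are rejection-sampled until all pairwise Euclidean distances
    are at least ``min_separation``, so the separation-to-noise ratio of
    the appearance model is controlled.  Actor 0 is the target.
    """
    rng = np.random.default_rng(seed)
    vectors: list[np.ndarray] = []
    while len(vectors) < n_actors:
        v = rng.normal(size=dim)
        v /= np.linalg.norm(v)
        if all(np.linalg.norm(v - u) >= min_separation for u in vectors):
            vectors.append(v)
    # bystanders stand at staggered depths from the camera (farther people
    # are higher in the frame and smaller), like staff in a frontal view
    fracs = np.linspace(0.92, 0.80, n_actors)
    return [
        ActorSpec(
            actor_id=f"actor{i}",
            identity_vector=vec,
            appearance_noise_sigma=appearance_noise_sigma,
            skeleton_scale=skeleton_scale * (0.55 + 0.45 * (frac - 0.80) / 0.12),
            ground_frac=float(frac),
            is_target=(i == 0),
        )
        for i, (vec, frac) in enumerate(zip(vectors, fracs))
    ]


def _script_timeline(
    script: Sequence[tuple[str, float]], fps: float
) -> tuple[list[str], list[float]]:
    """Per-frame (label, phase) for the target's action script."""
    labels: list[str] = []
    phases: list[float] = []
    for label, duration in script:
        n = round(duration * fps)
        for f in range(n):
            labels.append(label)
            if label in ("sit-to-stand", "stand-to-sit"):
                phases.append(f / max(1, n - 1))
            elif label == "walk":
                phases.append((f * WALK_CADENCE_HZ / fps) % 1.0)
            else:
                phases.append(0.0)
    return labels, phases


def _padded_box(kp: np.ndarray) -> tuple[float, float, float, float]:
    """Tight keypoint bounding box padded by 10% of its diagonal."""
    x0, y0 = kp[:, 0].min(), kp[:, 1].min()
    x1, y1 = kp[:, 0].max(), kp[:, 1].max()
    pad = 0.10 * math.hypot(x1 - x0, y1 - y0)
    pad = max(pad, 1.0)  # never degenerate
    return (x0 - pad, y0 - pad, x1 + pad, y1 + pad)


def generate_scenario(
    config: ScenarioConfig,
) -> tuple[list[FrameDetections], list[tuple[int, int, str]], list[AnnotationSegment]]:
    """Render a scripted scene into a detection stream.

    Returns
    -------
    (stream, ground_truth, segments)
        ``ground_truth`` rows are ``(frame_index, detection_index,
        actor_id)`` aligned with the stream; ``segments`` are the target's
        action annotations derived from the script.
    """
    rng = np.random.default_rng(config.seed)
    H0, W0 = config.frame_size
    labels, phases = _script_timeline(config.action_script, config.fps)

    # initial ground-anchor x positions: actors spread across the frame
    n = len(config.actors)
    margin = 0.12 * W0
    slots = np.linspace(margin, W0 - margin, n)
    anchor_x = {a.actor_id: float(x) for a, x in zip(config.actors, rng.permuted(slots))}
    walk_direction = 1.0

    occluded: dict[str, set[int]] = {a.actor_id: set() for a in config.actors}
    for actor_id, start, end in config.occlusion_windows:
        occluded[actor_id].update(range(start, end))
    scene_changes = set(config.scene_changes)

    target_id = config.target.actor_id
    stream: list[FrameDetections] = []
    truth: list[tuple[int, int, str]] = []

    for f in range(config.n_frames):
        if f in scene_changes:
            # cut to a different view: every anchor teleports to a fresh
            # uniform position (re-drawn a few times to avoid pile-ups)
            placed: list[float] = []
            for a in config.actors:
                for _ in range(20):
                    x = float(rng.uniform(margin, W0 - margin))
                    if all(abs(x - p) > 0.08 * W0 for p in placed):
                        break
                placed.append(x)
            anchor_x = {a.actor_id: x for a, x in zip(config.actors, placed)}
        # advance the target while walking, bouncing off the frame margins
        if labels[f] == "walk":
            step = (
                walk_direction
                * WALK_SPEED_SCALES_PER_S
                * config.target.skeleton_scale
                / config.fps
            )
            nx = anchor_x[target_id] + step
            if nx < margin or nx > W0 - margin:
                walk_direction = -walk_direction
                nx = anchor_x[target_id] + walk_direction * abs(step)
            anchor_x[target_id] = nx

        detections = []
        frame_truth = []
        for actor in config.actors:
            if f in occluded[actor.actor_id]:
                continue
            if (
                config.detection_dropout_prob > 0
                and rng.random() < config.detection_dropout_prob
            ):
                continue
            if actor.is_target:
                kp = pose_template(labels[f], phases[f], actor.skeleton_scale)
            else:
                kp = pose_template("stand", 0.0, actor.skeleton_scale)
            kp = kp.copy()
            kp[:, 0] += anchor_x[actor.actor_id]
            kp[:, 1] += actor.ground_frac * H0
            if config.keypoint_jitter_sigma > 0:
                kp[:, :2] += rng.normal(
                    0.0, config.keypoint_jitter_sigma, size=(17, 2)
                )
            kp[:, 2] = np.clip(rng.normal(0.85, 0.08, size=17), 0.05, 1.0)
            appearance = actor.identity_vector + rng.normal(
                0.0, actor.appearance_noise_sigma, size=actor.identity_vector.size
            )
            detections.append(
                Detection(
                    frame_index=f,
                    box=_padded_box(kp),
                    box_conf=float(rng.uniform(0.7, 1.0)),
                    keypoints=kp,
                    appearance=appearance,
                )
            )
            frame_truth.append(actor.actor_id)
        stream.append(FrameDetections(frame_index=f, detections=detections))
        truth.extend((f, i, aid) for i, aid in enumerate(frame_truth))

    # target annotations from the script
    segments: list[AnnotationSegment] = []
    cursor = 0
    for label, duration in config.action_script:
        nf = round(duration * config.fps)
        if nf > 0:
            segments.append(
                AnnotationSegment(
                    subject_id=target_id,
                    start_frame=cursor,
                    end_frame=cursor + nf - 1,
                    label=label,
                )
            )
        cursor += nf
    return stream, truth, segments


def benchmark_scenario(
    seed: int,
    n_frames: int = 600,
    n_actors: int = 3,
    min_separation: float = 1.0,
    appearance_noise_sigma: float = DEFAULT_APPEARANCE_NOISE,
    detection_dropout_prob: float = 0.02,
    frame_size: tuple[int, int] = (1080, 1920),
    skeleton_scale: float = 520.0,
) -> ScenarioConfig:
    """The canonical evaluation scene for the tracking stages.

    600 frames (20 s at 30 fps) with 3 actors, two long occlusion windows
    (one on the target, one on a bystander), and one scene change —
    enough fragmentation that long-term fusion is actually exercised.
    The target cycles sit → sit-to-stand → stand → walk → stand-to-sit.
    """
    actors = random_actors(
        n_actors,
        seed=seed,
        min_separation=min_separation,
        appearance_noise_sigma=appearance_noise_sigma,
        skeleton_scale=skeleton_scale,
    )
    # script proportions of the scene length, rounded to exact frame counts
    fractions = [
        ("sit", 0.20),
        ("sit-to-stand", 0.10),
        ("stand", 0.20),
        ("walk", 0.30),
        ("stand-to-sit", 0.10),
        ("sit", 0.10),
    ]
    frames = [round(frac * n_frames) for _, frac in fractions]
    frames[-1] = n_frames - sum(frames[:-1])
    script = [(label, nf / 30.0) for (label, _), nf in zip(fractions, frames)]
    return ScenarioConfig(
        n_frames=n_frames,
        actors=actors,
        action_script=script,
        occlusion_windows=[
            (actors[0].actor_id, int(0.35 * n_frames), int(0.45 * n_frames)),
            (actors[1].actor_id, int(0.60 * n_frames), int(0.70 * n_frames)),
        ],
        scene_changes=[int(0.80 * n_frames)],
        keypoint_jitter_sigma=1.0,
        detection_dropout_prob=detection_dropout_prob,
        frame_size=frame_size,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Balanced clip corpus
# ---------------------------------------------------------------------------

@dataclass
class ClipDatasetConfig:
    """Conditions for single-actor labelled clip generation."""

    frame_size: tuple[int, int] = (270, 480)
    skeleton_scale: float = 160.0
    keypoint_jitter_sigma: float = 1.0
    conf_mean: float = 0.9
    conf_sigma: float = 0.05
    fps: float = 30.0


def generate_clip_dataset(
    n_per_class: int,
    clip_len_frames: int,
    seed: int,
    config: Optional[ClipDatasetConfig] = None,
) -> tuple[list[np.ndarray], list[str]]:
    """Balanced labelled keypoint sequences for classifier training.

    Returns exactly ``n_per_class`` clips per action label, each a
    ``(clip_len_frames, 17, 3)`` single-actor keypoint series in native
    pixel coordinates of ``config.frame_size``.  Walking clips translate
    the root horizontally (direction chosen to stay inside the frame);
    transitions sweep their phase 0 → 1 across the clip.
    """
    if n_per_class < 1 or clip_len_frames < 1:
        raise ValidationError("n_per_class and clip_len_frames must be >= 1")
    cfg = config or ClipDatasetConfig()
    rng = np.random.default_rng(seed)
    H0, W0 = cfg.frame_size
    ground_y = 0.92 * H0
    clips: list[np.ndarray] = []
    labels: list[str] = []
    for label in ACTION_LABELS:
        for _ in range(n_per_class):
            F = clip_len_frames
            walk_span = (
                WALK_SPEED_SCALES_PER_S * cfg.skeleton_scale * F / cfg.fps
            )
            margin = 0.30 * cfg.skeleton_scale
            if label == "walk":
                lo, hi = margin, W0 - margin - walk_span
                start_x = rng.uniform(lo, max(lo + 1.0, hi))
                direction = 1.0 if rng.random() < 0.5 else -1.0
                if direction < 0:
                    start_x = min(W0 - margin, start_x + walk_span)
            else:
                start_x = rng.uniform(margin, W0 - margin)
                direction = 0.0
            phase0 = rng.uniform(0.0, 1.0)  # walk gait phase offset
            seq = np.zeros((F, 17, 3))
            for f in range(F):
                if label in ("sit-to-stand", "stand-to-sit"):
                    phase = f / max(1, F - 1)
                elif label == "walk":
                    phase = (phase0 + f * WALK_CADENCE_HZ / cfg.fps) % 1.0
                else:
                    phase = 0.0
                kp = pose_template(label, phase, cfg.skeleton_scale)
                x = start_x
                if label == "walk":
                    x += direction * WALK_SPEED_SCALES_PER_S * cfg.skeleton_scale * f / cfg.fps
                kp[:, 0] += x
                kp[:, 1] += ground_y
                if cfg.keypoint_jitter_sigma > 0:
                    kp[:, :2] += rng.normal(0.0, cfg.keypoint_jitter_sigma, size=(17, 2))
                kp[:, 2] = np.clip(
                    rng.normal(cfg.conf_mean, cfg.conf_sigma, size=17), 0.05, 1.0
                )
                seq[f] = kp
            clips.append(seq)
            labels.append(label)
    return clips, labels
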