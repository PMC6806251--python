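"""Long-term tracking: appearance-based tracklet fusion to a reference.

Short-term tracking fragments an identity into many tracklets whenever the
person is occluded, leaves the scene, or the camera cuts.  This stage
prunes unreliable tracklets, samples one representative detection per
tracklet (the highest-confidence box), embeds each representative into a
fixed-dimension appearance space, and accepts a tracklet into the target
track iff the Euclidean distance between its embedding and the reference
tracklet's embedding is at most τ.  Embeddings are L2-normalised before
the distance so τ is scale-free.

The embedder is a pluggable contract: the scene simulator supplies
identity-clustered appearance vectors directly (``PassthroughEmbedder``),
while for raw video frames a simple image-patch embedder
(``PatchMeanEmbedder``) crops the box and concatenates block-mean
intensities on a fixed grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Protocol, Sequence

import numpy as np

from .short_term import Tracklet
from .types import Detection, ValidationError


@dataclass(frozen=True)
class AppearanceEmbedding:
    """A fixed-dimension appearance vector for one sampled detection."""

    vector: np.ndarray
    source_tracklet_id: int = -1
    source_frame: int = -1

    def __post_init__(self) -> None:
        vec = np.asarray(self.vector, dtype=float)
        if vec.ndim != 1:
            raise ValidationError("embedding must be a 1-D vector")
        if not np.all(np.isfinite(vec)):
            raise ValidationError("embedding entries must be finite")
        object.__setattr__(self, "vector", vec)

    @property
    def dim(self) -> int:
        return self.vector.size


class Embedder(Protocol):
    def __call__(self, detection: Detection) -> np.ndarray: ...


class PassthroughEmbedder:
    """Return the appearance vector already attached to the detection."""

    def __call__(self, detection: Detection) -> np.ndarray:
        if detection.appearance is None:
            raise ValidationError(
                "detection has no appearance vector; use an image-patch embedder "
                "or attach appearance features upstream"
            )
        return np.asarray(detection.appearance, dtype=float)


class PatchMeanEmbedder:
    """Embed a detection by block-mean intensities of its image crop.

    The box is cropped from the frame (clipped to the image), partitioned
    into a ``grid × grid`` array of cells, and the mean intensity of each
    cell is concatenated into a ``grid²`` vector.  Deterministic by
    construction.

    Parameters
    ----------
    frame_source
        Callable mapping a frame index to a 2-D grayscale image array.
    grid
        Cells per side; embedding dimension is ``grid ** 2``.
    """

    def __init__(self, frame_source: Callable[[int], np.ndarray], grid: int = 4):
        if grid < 1:
            raise ValidationError("grid must be >= 1")
        self.frame_source = frame_source
        self.grid = grid

    def __call__(self, detection: Detection) -> np.ndarray:
        image = np.asarray(self.frame_source(detection.frame_index), dtype=float)
        if image.ndim == 3:  # collapse colour channels
            image = image.mean(axis=2)
        h, w = image.shape
        x0, y0, x1, y1 = detection.box
        x0 = int(np.clip(np.floor(x0), 0, w - 1))
        y0 = int(np.clip(np.floor(y0), 0, h - 1))
        x1 = int(np.clip(np.ceil(x1), x0 + 1, w))
        y1 = int(np.clip(np.ceil(y1), y0 + 1, h))
        crop = image[y0:y1, x0:x1]
        g = self.grid
        ys = np.linspace(0, crop.shape[0], g + 1).astype(int)
        xs = np.linspace(0, crop.shape[1], g + 1).astype(int)
        cells = np.empty(g * g)
        for i in range(g):
            for j in range(g):
                block = crop[ys[i] : max(ys[i + 1], ys[i] + 1),
                             xs[j] : max(xs[j + 1], xs[j] + 1)]
                cells[i * g + j] = block.mean()
        return cells


# ---------------------------------------------------------------------------
# Pruning and sampling
# ---------------------------------------------------------------------------

def prune_tracklets(
    tracklets: Sequence[Tracklet],
    min_length: int = 5,
    min_mean_keypoint_conf: float = 0.5,
) -> list[Tracklet]:
    """Drop short or poorly-estimated tracklets before fusion.

    A tracklet survives iff its length is at least ``min_length`` frames
    and the mean (over its detections) fraction of keypoints with
    confidence ≥ 0.5 is at least ``min_mean_keypoint_conf``.
    """
    if min_length < 0 or min_mean_keypoint_conf < 0:
        raise ValidationError("pruning thresholds must be >= 0")
    return [
        t
        for t in tracklets
        if len(t) >= min_length and t.mean_keypoint_score() >= min_mean_keypoint_conf
    ]


def sample_representative(tracklet: Tracklet) -> Detection:
    """The highest box-confidence detection; ties go to the earliest frame."""
    if len(tracklet.detections) == 0:
        raise ValidationError("cannot sample from an empty tracklet")
    best = tracklet.detections[0]
    for det in tracklet.detections[1:]:
        if det.box_conf > best.box_conf:
            best = det
    return best


def embed(
    detection: Detection,
    embedder: Optional[Embedder] = None,
    source_tracklet_id: int = -1,
) -> AppearanceEmbedding:
    """Embed one detection with the given (default: passthrough) embedder."""
    fn = embedder if embedder is not None else PassthroughEmbedder()
    return AppearanceEmbedding(
        vector=fn(detection),
        source_tracklet_id=source_tracklet_id,
        source_frame=detection.frame_index,
    )


def affinity(emb_a: AppearanceEmbedding, emb_b: AppearanceEmbedding) -> float:
    """Euclidean distance between two appearance embeddings."""
    if emb_a.dim != emb_b.dim:
        raise ValidationError(f"embedding dimension mismatch: {emb_a.dim} vs {emb_b.dim}")
    return float(np.linalg.norm(emb_a.vector - emb_b.vector))


def _l2_normalized(emb: AppearanceEmbedding) -> AppearanceEmbedding:
    norm = float(np.linalg.norm(emb.vector))
    if norm == 0.0:
        return emb
    return AppearanceEmbedding(
        vector=emb.vector / norm,
        source_tracklet_id=emb.source_tracklet_id,
        source_frame=emb.source_frame,
    )


# ---------------------------------------------------------------------------
# Fusion
# ---------------------------------------------------------------------------

@dataclass
class Track:
    """The fused long-term trajectory of the target."""

    detections: list[Detection]
    tracklet_ids: list[int]
    affinities: dict[int, float] = field(default_factory=dict)
    accepted: dict[int, bool] = field(default_factory=dict)
    reference_id: int = -1

    @property
    def frames(self) -> list[int]:
        return [d.frame_index for d in self.detections]

    def __len__(self) -> int:
        return len(self.detections)


def fuse_to_track(
    tracklets: Sequence[Tracklet],
    reference_id: int,
    tau: float = 0.7,
    embedder: Optional[Embedder] = None,
) -> Track:
    """Fuse all tracklets within appearance distance τ of the reference.

    Each (pruned) tracklet contributes one representative detection whose
    L2-normalised embedding is compared with the reference tracklet's; a
    tracklet is accepted iff the distance is ≤ τ.  Accepted detections are
    concatenated in frame order; where two accepted tracklets overlap on a
    frame the detection from the lower-affinity tracklet wins.  The
    reference tracklet is always accepted.
    """
    if tau < 0:
        raise ValidationError("tau must be >= 0")
    by_id = {t.tracklet_id: t for t in tracklets}
    if reference_id not in by_id:
        raise ValidationError(
            f"reference tracklet {reference_id} is not among the candidate "
            "tracklets — it may have been pruned; relax min_tracklet_length / "
            "min_mean_keypoint_conf so the reference survives pruning"
        )

    embeddings = {
        t.tracklet_id: _l2_normalized(
            embed(sample_representative(t), embedder, t.tracklet_id)
        )
        for t in tracklets
    }
    ref_emb = embeddings[reference_id]
    affinities = {tid: affinity(e, ref_emb) for tid, e in embeddings.items()}
    accepted = {tid: (aff <= tau) for tid, aff in affinities.items()}
    accepted[reference_id] = True

    # lower affinity wins frame conflicts; reference beats everything
    def priority(tid: int) -> tuple[float, int]:
        return (-1.0 if tid == reference_id else affinities[tid], tid)

    chosen: dict[int, tuple[tuple[float, int], Detection, int]] = {}
    for tid, ok in accepted.items():
        if not ok:
            continue
        p = priority(tid)
        for det in by_id[tid].detections:
            f = det.frame_index
            if f not in chosen or p < chosen[f][0]:
                chosen[f] = (p, det, tid)

    frames_sorted = sorted(chosen)
    return Track(
        detections=[chosen[f][1] for f in frames_sorted],
        tracklet_ids=sorted(tid for tid, ok in accepted.items() if ok),
        affinities=affinities,
        accepted=accepted,
        reference_id=reference_id,
    )


def tracklet_classification_accuracy(
    predicted_labels: Sequence[bool],
    truth_labels: Sequence[bool],
) -> float:
    """Binary accuracy of the fusion decision against ground-truth identity.

    Treats target tracklets as the positive class: the long-term tracker
    acts as a binary classifier that accepts target tracklets and rejects
    the rest.
    """
    if len(predicted_labels) != len(truth_labels):
        raise ValidationError(
            f"label length mismatch: {len(predicted_labels)} vs {len(truth_labels)}"
        )
    if len(predicted_labels) == 0:
        raise ValidationError("cannot compute accuracy of an empty label list")
    pred = np.asarray(predicted_labels, dtype=bool)
    truth = np.asarray(truth_labels, dtype=bool)
    return float(np.mean(pred == truth))
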