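"""Pipeline configuration: a flat key=value text format, read strictly.

Unknown keys are errors (fail fast), every stage records a metadata block
(config hash + seed) next to its outputs so deterministic stages can be
reproduced byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

from .types import ValidationError


@dataclass
class PipelineConfig:
    """Tunable parameters shared by the pipeline stages.

    Attributes
    ----------
    fps
        Video frame rate; time is derived as ``frame_index / fps``.
    iou_threshold
        Minimum IoU for a frame-to-frame box match in short-term tracking.
    min_tracklet_length, min_mean_keypoint_conf
        Tracklet pruning thresholds applied before long-term fusion.
    affinity_threshold
        τ: a tracklet joins the target track iff the Euclidean distance
        between its (L2-normalised) representative embedding and the
        reference embedding is ≤ τ.
    heatmap_sigma
        Gaussian kernel width (pixels, at working resolution) for joint
        heatmaps.
    channels
        C, the number of time-encoding channels (≥ 2).
    downscale
        Factor mapping native pixel coordinates to the working heatmap
        resolution.
    frame_height, frame_width
        Native frame size in pixels; working resolution is
        ``ceil(downscale * native)``.
    """

    fps: float = 30.0
    iou_threshold: float = 0.1
    min_tracklet_length: int = 5
    min_mean_keypoint_conf: float = 0.5
    affinity_threshold: float = 0.7
    heatmap_sigma: float = 2.0
    channels: int = 3
    frame_height: int = 1080
    frame_width: int = 1920
    downscale: float = 0.125
    clip_min_s: float = 0.2
    clip_max_s: float = 4.0
    balance_cap: int = 4000
    learning_rate: float = 0.01
    batch_size: int = 70
    dropout: float = 0.3
    epochs: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.channels < 2:
            raise ValidationError("channels must be >= 2")
        for name in ("fps", "heatmap_sigma", "downscale", "learning_rate"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        for name in (
            "iou_threshold",
            "min_tracklet_length",
            "min_mean_keypoint_conf",
            "affinity_threshold",
            "dropout",
        ):
            value = getattr(self, name)
            if not (value >= 0 and value == value):  # finite, non-negative
                raise ValidationError(f"{name} must be finite and >= 0")

    @property
    def map_height(self) -> int:
        import math

        return math.ceil(self.frame_height * self.downscale)

    @property
    def map_width(self) -> int:
        import math

        return math.ceil(self.frame_width * self.downscale)

    # -- flat key=value persistence -------------------------------------

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Read a flat ``key = value`` config file; unknown keys are errors."""
        fields = {f.name: f for f in dataclasses.fields(cls)}
        kwargs: dict[str, object] = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValidationError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
            key, value = (part.strip() for part in line.split("=", 1))
            if key not in fields:
                raise ValidationError(f"{path}:{lineno}: unknown config key {key!r}")
            ftype = fields[key].type
            if ftype in ("int", int):
                kwargs[key] = int(value)
            elif ftype in ("float", float):
                kwargs[key] = float(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)  # type: ignore[arg-type]

    def to_file(self, path: str | Path) -> None:
        lines = [
            f"{f.name} = {getattr(self, f.name)}" for f in dataclasses.fields(self)
        ]
        Path(path).write_text("\n".join(lines) + "\n")

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        """Stable hash of the configuration (seed included)."""
        payload = json.dumps(self.as_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_metadata(path: str | Path, config: PipelineConfig, stage: str, **extra) -> None:
    """Write the reproducibility sidecar for a stage output."""
    meta = {
        "stage": stage,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "config": config.as_dict(),
    }
    meta.update(extra)
    Path(path).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
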