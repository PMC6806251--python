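"""The compact convolutional action classifier over pose-evolution maps.

Architecture: two blocks of two 3×3 convolutions (128 then 256 filters;
first layer of each block stride 2, second stride 1), each convolution
followed by ReLU, batch normalisation and dropout; then global average
pooling to a 256-vector and a 5-way affine layer trained with softmax
cross-entropy.  Pose-evolution inputs are sparse and carry no image
context, so this shallow randomly-initialised network suffices.

Training uses Adam (base learning rate 0.01), batch size 70 and dropout
probability 0.3 by default, with early stopping on validation weighted
accuracy; the seed controls weight initialisation, batch order and
dropout masks.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import nn
from .types import ACTION_LABELS, LABEL_TO_INDEX, ValidationError


@dataclass
class ModelConfig:
    """Hyperparameters of the classification network."""

    input_shape: tuple[int, int, int]  # (14·C, H, W)
    classes: int = 5
    block_widths: tuple[int, int] = (128, 256)
    block_strides: tuple[int, int] = (2, 1)  # per layer within a block
    kernel: int = 3
    dropout: float = 0.3
    learning_rate: float = 0.01
    batch_size: int = 70
    epochs: int = 20
    early_stop_patience: int = 3
    early_stop_accuracy: float = 0.995
    early_stop_min_delta: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in (*self.block_widths, self.kernel, self.batch_size,
                                self.learning_rate, self.classes, self.epochs)):
            raise ValidationError("model hyperparameters must be positive")


class PoseEvolutionNet:
    """The trained network: layer stack + label bookkeeping."""

    def __init__(self, config: ModelConfig):
        c_in, h, w = config.input_shape
        if h < 4 or w < 4:
            raise ValidationError(
                f"input spatial size {h}×{w} below the receptive-field minimum (4×4)"
            )
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        layers: list[nn.Layer] = []
        prev = c_in
        for width in config.block_widths:
            for stride in config.block_strides:
                layers.append(nn.Conv2d(prev, width, config.kernel, stride, self.rng))
                layers.append(nn.ReLU())
                layers.append(nn.BatchNorm(width))
                layers.append(nn.Dropout(config.dropout, self.rng))
                prev = width
        layers.append(nn.GlobalAvgPool())
        layers.append(nn.Dense(prev, config.classes, self.rng))
        self.layers = layers

    # -- plumbing -------------------------------------------------------

    def parameters(self) -> list[tuple[np.ndarray, np.ndarray]]:
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    @property
    def n_parameters(self) -> int:
        return int(sum(p.size for p, _ in self.parameters()))

    def forward(self, x_nchw: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.ascontiguousarray(
            np.transpose(np.asarray(x_nchw, dtype=np.float32), (0, 2, 3, 1))
        )
        expected = self.config.input_shape
        if x_nchw.shape[1:] != expected:
            raise ValidationError(
                f"input shape {tuple(x_nchw.shape[1:])} does not match model "
                f"config {tuple(expected)}"
            )
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dlogits: np.ndarray) -> None:
        grad = dlogits
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def state(self) -> list[np.ndarray]:
        arrays = [p.copy() for p, _ in self.parameters()]
        for layer in self.layers:
            if isinstance(layer, nn.BatchNorm):
                arrays.append(layer.running_mean.copy())
                arrays.append(layer.running_var.copy())
                arrays.append(np.array([layer.updates], dtype=np.int64))
        return arrays

    def load_state(self, arrays: Sequence[np.ndarray]) -> None:
        arrays = list(arrays)
        k = 0
        for p, _ in self.parameters():
            p[...] = arrays[k]
            k += 1
        for layer in self.layers:
            if isinstance(layer, nn.BatchNorm):
                layer.running_mean[...] = arrays[k]
                layer.running_var[...] = arrays[k + 1]
                layer.updates = int(np.asarray(arrays[k + 2]).ravel()[0])
                k += 3


def build_model(config: ModelConfig) -> PoseEvolutionNet:
    """Instantiate the network with seeded random initialisation."""
    return PoseEvolutionNet(config)


def _as_label_indices(labels: Sequence, classes: int) -> np.ndarray:
    arr = []
    for lab in labels:
        if isinstance(lab, str):
            if lab not in LABEL_TO_INDEX:
                raise ValidationError(f"unknown label {lab!r}")
            arr.append(LABEL_TO_INDEX[lab])
        else:
            idx = int(lab)
            if not (0 <= idx < classes):
                raise ValidationError(f"label index {idx} outside [0, {classes})")
            arr.append(idx)
    return np.asarray(arr, dtype=np.int64)


def train(
    model: PoseEvolutionNet,
    train_maps: np.ndarray,
    train_labels: Sequence,
    val_maps: np.ndarray,
    val_labels: Sequence,
    config: Optional[ModelConfig] = None,
) -> list[dict]:
    """Train with Adam + early stopping; returns the per-epoch history.

    History entries carry ``epoch``, ``train_loss`` (mean over batches)
    and ``val_weighted_accuracy``.  The weights that achieved the best
    validation weighted accuracy are restored at the end.  Raises if any
    class is absent from the training labels.
    """
    cfg = config or model.config
    y_train = _as_label_indices(train_labels, cfg.classes)
    y_val = _as_label_indices(val_labels, cfg.classes)
    present = np.unique(y_train)
    if present.size < cfg.classes:
        missing = sorted(set(range(cfg.classes)) - set(present.tolist()))
        names = [ACTION_LABELS[i] if i < len(ACTION_LABELS) else str(i) for i in missing]
        raise ValidationError(f"classes absent from training data: {names}")

    X = np.asarray(train_maps, dtype=np.float32)
    optimizer = nn.Adam(model.parameters(), lr=cfg.learning_rate)
    shuffle_rng = np.random.default_rng(cfg.seed)
    history: list[dict] = []
    best_acc, best_state, best_epoch = -1.0, None, -1

    for epoch in range(cfg.epochs):
        order = shuffle_rng.permutation(len(X))
        losses = []
        for start in range(0, len(X), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            logits = model.forward(X[idx], train=True)
            loss, dlogits = nn.softmax_cross_entropy(logits, y_train[idx])
            model.backward(dlogits)
            optimizer.step()
            losses.append(loss)
        val_probs = predict(model, val_maps)
        val_pred = val_probs.argmax(axis=1)
        val_acc = _weighted_accuracy(y_val, val_pred, cfg.classes)
        history.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(losses)),
                "val_weighted_accuracy": val_acc,
            }
        )
        if val_acc > best_acc + cfg.early_stop_min_delta:
            best_epoch = epoch  # meaningful improvement resets patience
        if val_acc > best_acc:
            best_acc, best_state = val_acc, model.state()
        if val_acc >= cfg.early_stop_accuracy:
            break
        if epoch - best_epoch >= cfg.early_stop_patience:
            break
    if best_state is not None:
        model.load_state(best_state)
    return history


def _weighted_accuracy(y_true: np.ndarray, y_pred: np.ndarray, classes: int) -> float:
    # support-weighted mean of per-class accuracies == overall fraction correct
    return float(np.mean(y_true == y_pred))


def predict(
    model: PoseEvolutionNet, maps: np.ndarray, batch_size: int = 256
) -> np.ndarray:
    """Class-probability rows (softmax over the logits), batched."""
    X = np.asarray(maps, dtype=np.float32)
    out = []
    for start in range(0, len(X), batch_size):
        logits = model.forward(X[start : start + batch_size], train=False)
        out.append(nn.softmax(logits.astype(np.float64)))
    return np.concatenate(out, axis=0)


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------

def save_model(model: PoseEvolutionNet, path: str | Path) -> None:
    """Single-file checkpoint with the config (seed included) embedded."""
    arrays = {f"arr_{i}": a for i, a in enumerate(model.state())}
    cfg = copy.deepcopy(vars(model.config))
    cfg["input_shape"] = list(cfg["input_shape"])
    cfg["block_widths"] = list(cfg["block_widths"])
    cfg["block_strides"] = list(cfg["block_strides"])
    np.savez_compressed(path, __config__=json.dumps(cfg), **arrays)


def load_model(path: str | Path) -> PoseEvolutionNet:
    with np.load(path, allow_pickle=False) as npz:
        cfg = json.loads(str(npz["__config__"]))
        arrays = [npz[f"arr_{i}"] for i in range(len(npz.files) - 1)]
    cfg["input_shape"] = tuple(cfg["input_shape"])
    cfg["block_widths"] = tuple(cfg["block_widths"])
    cfg["block_strides"] = tuple(cfg["block_strides"])
    model = PoseEvolutionNet(ModelConfig(**cfg))
    model.load_state(arrays)
    return model
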