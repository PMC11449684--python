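"""Seeded minibatch training with Adam, and batched prediction.

Defaults mirror the reference experimental setup: Adam with initial
learning rate 1e-4 (beta1 0.9, beta2 0.999, eps 1e-8), minibatch size
64, and an epoch budget of 64, minimizing categorical cross-entropy on
softmax outputs.  The returned model carries the parameters of the
best-validation-accuracy epoch (ties resolved to the earliest epoch).
All shuffling derives from the config seed, so a run is fully
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._nn import Adam, Model, cross_entropy, softmax

__all__ = ["TrainConfig", "History", "TrainingError", "train", "predict"]


class TrainingError(RuntimeError):
    """Configuration mismatch or training divergence."""


@dataclass(frozen=True)
class TrainConfig:
    optimizer: str = "adam"
    learning_rate: float = 1e-4
    batch_size: int = 64
    max_epochs: int = 64
    seed: int = 0
    loss: str = "cross_entropy"
    early_stop_patience: int | None = None

    def __post_init__(self):
        if self.optimizer != "adam":
            raise TrainingError(f"unsupported optimizer {self.optimizer!r}")
        if self.loss != "cross_entropy":
            raise TrainingError(f"unsupported loss {self.loss!r}")
        if self.learning_rate < 0:
            raise TrainingError("learning_rate must be >= 0")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise TrainingError("batch_size and max_epochs must be >= 1")


@dataclass
class History:
    """Per-epoch traces; lengths equal the number of completed epochs."""

    train_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    best_epoch: int = -1

    def num_epochs(self) -> int:
        return len(self.train_loss)

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "epoch": np.arange(1, self.num_epochs() + 1),
            "train_loss": self.train_loss,
            "train_accuracy": self.train_accuracy,
            "val_loss": self.val_loss,
            "val_accuracy": self.val_accuracy,
        })


def _evaluate(model: Model, images: np.ndarray, labels: np.ndarray,
              batch_size: int) -> tuple[float, float]:
    losses, correct = [], 0
    for start in range(0, len(labels), batch_size):
        xb = images[start:start + batch_size]
        yb = labels[start:start + batch_size]
        probs = softmax(model.forward(xb, train=False))
        losses.append(cross_entropy(probs, yb) * len(yb))
        correct += int((probs.argmax(axis=1) == yb).sum())
    return float(np.sum(losses) / len(labels)), correct / len(labels)


def train(model: Model, train_set, val_set, cfg: TrainConfig) -> tuple[Model, History]:
    """Fit ``model`` on ``train_set``, selecting by validation accuracy.

    The training-accuracy trace is measured on the fly over the
    shuffled minibatches of each epoch (the conventional running
    estimate); validation metrics come from a full inference pass.
    Raises :class:`TrainingError` on a class-count mismatch or if the
    loss becomes non-finite.
    """
    if model.num_classes != train_set.num_classes:
        raise TrainingError(
            f"model has {model.num_classes} outputs but data has "
            f"{train_set.num_classes} classes")
    rng = np.random.Generator(np.random.PCG64(cfg.seed))
    opt = Adam(model, lr=cfg.learning_rate)
    history = History()
    best_state, best_val_acc, best_epoch = None, -1.0, -1
    n = len(train_set)
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        epoch_loss, correct = 0.0, 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb = train_set.images[idx]
            yb = train_set.labels[idx]
            logits = model.forward(xb, train=True)
            probs = softmax(logits)
            loss = cross_entropy(probs, yb)
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite loss at epoch {epoch + 1}")
            epoch_loss += loss * len(yb)
            correct += int((probs.argmax(axis=1) == yb).sum())
            dlogits = probs.astype(np.float32)
            dlogits[np.arange(len(yb)), yb] -= 1.0
            dlogits /= len(yb)
            model.backward(dlogits)
            opt.step()
        history.train_loss.append(epoch_loss / n)
        history.train_accuracy.append(correct / n)
        vl, va = _evaluate(model, val_set.images, val_set.labels, cfg.batch_size)
        history.val_loss.append(vl)
        history.val_accuracy.append(va)
        if va > best_val_acc:
            best_val_acc, best_epoch = va, epoch
            best_state = model.get_state()
        if (cfg.early_stop_patience is not None
                and epoch - best_epoch >= cfg.early_stop_patience):
            break
    if best_state is not None:
        model.set_state(best_state)
    history.best_epoch = best_epoch
    return model, history


def predict(model: Model, images: np.ndarray, batch_size: int = 64):
    """Class probabilities and argmax labels for preprocessed images.

    Rows of the returned score matrix sum to 1; the label is the index
    of the maximum, lowest index winning ties.
    """
    images = np.asarray(images, np.float32)
    if images.ndim == 3:
        images = images[None]
    if images.shape[1:] != tuple(model.input_shape):
        raise TrainingError(
            f"images of shape {images.shape[1:]} do not match model input "
            f"{tuple(model.input_shape)}")
    chunks = [softmax(model.forward(images[s:s + batch_size], train=False))
              for s in range(0, len(images), batch_size)]
    probs = np.concatenate(chunks, axis=0)
    return probs, probs.argmax(axis=1)
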