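"""Training loop: Adam on cross-entropy for a fixed number of epochs,
with per-epoch accuracy and loss recorded on the validation partition.

The default schedule is 30 epochs, learning rate 1e-3, batch size 32.
Runs are deterministic given (seed, model spec, data): batch order each
epoch is drawn from a generator seeded by the run seed, and all arithmetic
is plain single-threaded NumPy.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

from .cnn import CNNClassifier
from .dataset import LabelledTileSet, SplitAssignment

__all__ = ["TrainingHistory", "train", "evaluate"]


@dataclass
class TrainingHistory:
    """Per-epoch training record."""

    epochs: int
    seed: int
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)

    def validate(self) -> None:
        for name in ("train_loss", "val_loss", "val_accuracy"):
            values = getattr(self, name)
            if len(values) != self.epochs:
                raise ValueError(f"{name} has {len(values)} entries for {self.epochs} epochs")
            if not all(np.isfinite(v) for v in values):
                raise ValueError(f"{name} contains non-finite values")
        if any(v < 0 for v in self.train_loss + self.val_loss):
            raise ValueError("losses must be non-negative")
        if any(not 0 <= a <= 1 for a in self.val_accuracy):
            raise ValueError("accuracies must lie in [0, 1]")

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["epoch", "train_loss", "val_loss", "val_accuracy"])
            for e in range(self.epochs):
                writer.writerow(
                    [e + 1, self.train_loss[e], self.val_loss[e], self.val_accuracy[e]]
                )


class _Adam:
    """Standard Adam updates, one slot per parameter tensor."""

    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for k in params:
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * grads[k]
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * grads[k] ** 2
            m_hat = self.m[k] / (1 - self.beta1**self.t)
            v_hat = self.v[k] / (1 - self.beta2**self.t)
            params[k] -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def _scores(model: CNNClassifier, x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    probs = model.predict_proba_array(x)
    accuracy = float((probs.argmax(axis=1) == y).mean())
    loss = float(-np.log(probs[np.arange(len(y)), y] + 1e-12).mean())
    return accuracy, loss


def train(
    model: CNNClassifier,
    dataset: LabelledTileSet,
    split: SplitAssignment,
    epochs: int = 30,
    learning_rate: float = 1e-3,
    batch_size: int = 32,
    seed: int = 0,
) -> tuple[CNNClassifier, TrainingHistory]:
    """Fit the classifier on the training partition.

    Returns the model (updated in place) and the per-epoch history of
    train loss, validation loss and validation accuracy.  Raises if the
    training partition holds a single class or if the loss turns
    non-finite.
    """
    train_ids = sorted(split.train_ids)
    val_ids = sorted(split.val_ids)
    missing = (split.train_ids | split.val_ids) ^ set(dataset.tile_ids)
    if missing:
        raise ValueError(f"split does not cover the dataset exactly ({len(missing)} ids differ)")
    x_train = model._check_input(dataset.images(train_ids))
    y_train = dataset.labels(train_ids)
    if len(np.unique(y_train)) < 2:
        raise ValueError("training partition contains a single class; both classes required")
    x_val = model._check_input(dataset.images(val_ids)) if val_ids else None
    y_val = dataset.labels(val_ids) if val_ids else None

    rng = np.random.default_rng(seed)
    optimiser = _Adam(model.params, lr=learning_rate)
    history = TrainingHistory(epochs=epochs, seed=seed)
    n = len(y_train)
    for epoch in range(epochs):
        order = rng.permutation(n)
        batch_losses = []
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            loss, grads = model.loss_and_grads(x_train[idx], y_train[idx])
            if not np.isfinite(loss):
                raise ValueError(f"non-finite loss at epoch {epoch + 1}")
            if learning_rate > 0:
                optimiser.step(model.params, grads)
            batch_losses.append(loss)
        history.train_loss.append(float(np.mean(batch_losses)))
        if x_val is not None:
            acc, vloss = _scores(model, x_val, y_val)
        else:  # no validation partition: score the training data instead
            acc, vloss = _scores(model, x_train, y_train)
        history.val_accuracy.append(acc)
        history.val_loss.append(vloss)
    history.validate()
    return model, history


def evaluate(model: CNNClassifier, dataset: LabelledTileSet, ids) -> tuple[float, float]:
    """Accuracy and mean cross-entropy of the model on the given tiles.

    Accuracy is the fraction of tiles whose argmax class matches the
    label; loss is the mean negative log-probability of the true class.
    """
    ids = sorted(ids)
    if not ids:
        raise ValueError("ids must be nonempty")
    x = model._check_input(dataset.images(ids))
    y = dataset.labels(ids)
    return _scores(model, x, y)
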