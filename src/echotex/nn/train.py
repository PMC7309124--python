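"""SGD training of the multi-resolution network.

The reference protocol: stochastic gradient descent with learning rate
1e-4 and momentum 0.1, mini-batches of 64, 100 epochs, validation
accuracy monitored each epoch and the best-validation epoch kept as the
final model. Patches enter as [0, 1] floats with a single channel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ..io_via import HCC
from ..patches import Patch
from .layers import softmax, softmax_cross_entropy
from .model import MultiResNet

__all__ = ["TrainConfig", "SGD", "train", "predict_proba", "patches_to_arrays"]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 100
    batch_size: int = 64
    learning_rate: float = 0.0001
    momentum: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.epochs, self.batch_size) < 1 or self.learning_rate <= 0 or self.momentum < 0:
            raise ValueError("training hyperparameters must be positive")


class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, params, learning_rate: float, momentum: float) -> None:
        self.params = list(params)
        self.lr = learning_rate
        self.mu = momentum
        self.velocity = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        for p, v in zip(self.params, self.velocity):
            v *= self.mu
            v += p.grad
            p.value -= self.lr * v


def patches_to_arrays(patches: Sequence[Patch]) -> tuple[np.ndarray, np.ndarray]:
    """Stack patches into (n, 1, s, s) float32 in [0, 1] plus 0/1 labels (HCC = 1)."""
    x = np.stack([p.pixels for p in patches]).astype(np.float32) / 255.0
    y = np.array([1 if p.label == HCC else 0 for p in patches], dtype=np.int64)
    return x[:, None, :, :], y


def _as_xy(data) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(data, tuple):
        x, y = data
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[:, None]
        return x, np.asarray(y, dtype=np.int64)
    return patches_to_arrays(data)


def train(
    model: MultiResNet,
    train_data,
    val_data,
    tc: TrainConfig = TrainConfig(),
) -> tuple[MultiResNet, dict]:
    """Train in place; return the model restored to its best epoch + history.

    ``train_data``/``val_data`` are either lists of patches or ``(x, y)``
    array pairs. History records the mean training loss and validation
    accuracy per epoch. Seeded end to end (batch order and dropout).
    """
    x_train, y_train = _as_xy(train_data)
    x_val, y_val = _as_xy(val_data)
    if len(x_train) < 1:
        raise ValueError("empty training data")
    if set(np.unique(y_train).tolist()) - {0, 1}:
        raise ValueError("labels must be binary")

    rng = np.random.default_rng(tc.seed)
    opt = SGD(model.params(), tc.learning_rate, tc.momentum)
    history: dict[str, list[float]] = {"train_loss": [], "val_accuracy": []}
    best = (-np.inf, None)

    for _ in range(tc.epochs):
        order = rng.permutation(len(x_train))
        losses = []
        for start in range(0, len(order), tc.batch_size):
            idx = order[start : start + tc.batch_size]
            logits = model.forward(x_train[idx], train=True)
            loss, dlogits = softmax_cross_entropy(logits, y_train[idx])
            model.zero_grad()
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
        history["train_loss"].append(float(np.mean(losses)))

        val_logits = model.predict_logits(x_val)
        val_acc = float(np.mean(np.argmax(val_logits, axis=1) == y_val))
        history["val_accuracy"].append(val_acc)
        if val_acc > best[0]:
            best = (val_acc, model.get_state())

    if best[1] is not None:
        model.set_state(best[1])
    history["best_val_accuracy"] = best[0]
    return model, history


def predict_proba(model: MultiResNet, data) -> np.ndarray:
    """Class probabilities (columns: PAR, HCC) in evaluation mode."""
    x, _ = _as_xy(data) if not isinstance(data, np.ndarray) else (data, None)
    if isinstance(data, np.ndarray):
        x = data.astype(np.float32)
        if x.ndim == 3:
            x = x[:, None]
    logits = model.predict_logits(x)
    return softmax(logits)
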