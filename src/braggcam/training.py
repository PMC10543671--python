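"""Training engine: Adam with an exponentially decaying learning rate.

The reference recipe trains for 50 epochs at batch size 128 with Adam and an
exponentially decaying learning rate initialized to 1e-5 (appropriate for
full-size 512x512 training runs); the desk preset scales this to 15 epochs at
batch size 32 with the standard Adam rate 1e-3 and decay 0.9/epoch, which
suits the small 64x64 networks the test suite trains.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .frames import LabelledDataset
from .models import CNNModel

__all__ = [
    "TrainConfig",
    "desk_train_config",
    "fullscale_train_config",
    "TrainingDivergedError",
    "Adam",
    "cross_entropy",
    "train",
    "predict",
]


class TrainingDivergedError(RuntimeError):
    """Raised when the optimization produces a non-finite loss."""


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 15
    batch_size: int = 32
    lr_init: float = 1e-3
    #: multiplicative per-epoch factor: lr(t) = lr_init * lr_decay**t
    lr_decay: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.lr_decay <= 1.0):
            raise ValueError("lr_decay must be in (0, 1]")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.lr_init < 0:
            raise ValueError("lr_init must be >= 0")

    def lr_at(self, epoch: int) -> float:
        return self.lr_init * self.lr_decay**epoch


def desk_train_config(**overrides) -> TrainConfig:
    return replace(TrainConfig(), **overrides)


def fullscale_train_config(**overrides) -> TrainConfig:
    """The reference full-scale recipe (50 epochs, batch 128, Adam at 1e-5)."""
    return replace(
        TrainConfig(epochs=50, batch_size=128, lr_init=1e-5, lr_decay=0.95), **overrides
    )


class Adam:
    """Adam optimizer over a network's parameter arrays."""

    def __init__(self, net, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.net = net
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(layer.params[name]) for layer, name in net.param_items()]
        self.v = [np.zeros_like(layer.params[name]) for layer, name in net.param_items()]
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (layer, name) in enumerate(self.net.param_items()):
            g = layer.grads.get(name)
            if g is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            layer.params[name] = layer.params[name] - lr * mhat / (np.sqrt(vhat) + self.eps)


def cross_entropy(logits: np.ndarray, y: np.ndarray) -> Tuple[float, np.ndarray]:
    """Mean cross-entropy on raw scores; returns (loss, dloss/dlogits)."""
    n = logits.shape[0]
    shifted = logits - logits.max(axis=1, keepdims=True)
    logZ = np.log(np.exp(shifted).sum(axis=1, keepdims=True))
    logp = shifted - logZ
    loss = -logp[np.arange(n), y].mean()
    dlogits = np.exp(logp)
    dlogits[np.arange(n), y] -= 1.0
    return float(loss), dlogits / n


def _dataset_arrays(
    model: CNNModel, dataset: LabelledDataset, binary: bool
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    if binary:
        if dataset.binary_labels is None:
            raise ValueError("dataset has no hit/miss labels; call binarize_labels first")
        y = dataset.binary_labels
    else:
        y = dataset.labels
    if y.min() < 0 or y.max() >= model.spec.n_classes:
        raise ValueError("labels out of range for the model's class count")
    x = model.preprocess(dataset.frames)
    return x, np.asarray(y), dataset.is_test


def train(
    model: CNNModel,
    dataset: LabelledDataset,
    cfg: TrainConfig,
    binary: bool = False,
    verbose: bool = False,
) -> Tuple[CNNModel, List[Dict[str, float]]]:
    """Fit ``model`` in place on the dataset's train split.

    Returns the model and a per-epoch history of train loss, train accuracy
    and test accuracy.  A fixed seed gives a reproducible history.
    """
    x, y, is_test = _dataset_arrays(model, dataset, binary)
    x_tr, y_tr = x[~is_test], y[~is_test]
    x_te, y_te = x[is_test], y[is_test]
    if len(x_tr) == 0:
        raise ValueError("dataset has an empty train split")

    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.net)
    history: List[Dict[str, float]] = []
    for epoch in range(cfg.epochs):
        lr = cfg.lr_at(epoch)
        order = rng.permutation(len(x_tr))
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            logits, _, caches = model.net.forward(x_tr[idx], want_caches=True)
            loss, dlogits = cross_entropy(logits, y_tr[idx])
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite loss {loss} at epoch {epoch}, batch {start // cfg.batch_size}"
                )
            model.net.backward(dlogits, caches)
            if lr > 0:
                opt.step(lr)
            losses.append(loss)
        train_acc = _accuracy_on(model, x_tr, y_tr)
        test_acc = _accuracy_on(model, x_te, y_te) if len(x_te) else float("nan")
        history.append(
            {
                "epoch": epoch,
                "lr": lr,
                "train_loss": float(np.mean(losses)),
                "train_accuracy": train_acc,
                "test_accuracy": test_acc,
            }
        )
        if verbose:
            print(
                f"epoch {epoch:3d}  lr {lr:.2e}  loss {history[-1]['train_loss']:.4f}  "
                f"train acc {train_acc:.3f}  test acc {test_acc:.3f}"
            )
    return model, history


def _accuracy_on(model: CNNModel, x: np.ndarray, y: np.ndarray,
                 batch: int = 256) -> float:
    if len(x) == 0:
        return float("nan")
    correct = 0
    for start in range(0, len(x), batch):
        logits = model.forward_batch(x[start : start + batch])
        correct += int((np.argmax(logits, axis=1) == y[start : start + batch]).sum())
    return correct / len(x)


def predict(
    model: CNNModel, frames, batch: int = 256
) -> Tuple[np.ndarray, np.ndarray]:
    """Predicted labels and the raw score matrix.

    The label is the argmax of the scores; exact ties break toward the lowest
    class index (numpy argmax first-occurrence semantics).
    """
    x = model.preprocess(frames)
    scores = np.vstack(
        [model.forward_batch(x[s : s + batch]) for s in range(0, len(x), batch)]
    )
    return np.argmax(scores, axis=1), scores
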