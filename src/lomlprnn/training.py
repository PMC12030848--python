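"""Cross-entropy training loop.

Protocol: mini-batches of 32, up to 100 epochs, learning rate multiplied by
0.9 after every epoch, adaptive-moment (Adam) optimisation at an initial
rate of 1e-3. Shuffling, initialisation and optimiser state are all driven
by one integer seed, so a run is bit-reproducible on a single thread.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._autograd import Tensor
from .metrics import cross_entropy

__all__ = ["TrainConfig", "TrainHistory", "Adam", "train", "loss_on_logits"]


@dataclass
class TrainConfig:
    batch_size: int = 32
    max_epochs: int = 100
    lr_decay: float = 0.9
    initial_lr: float = 1e-3
    optimizer_name: str = "adam"
    seed: int = 0
    patience: int | None = None      # early stop on train loss plateau

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not 0.0 < self.lr_decay <= 1.0:
            raise ValueError("lr_decay must be in (0, 1]")
        if self.optimizer_name != "adam":
            raise ValueError("only the adam optimizer is implemented")

    def lr_at_epoch(self, epoch: int) -> float:
        """Learning rate used during ``epoch`` (0-based)."""
        return self.initial_lr * self.lr_decay ** epoch


@dataclass
class TrainHistory:
    loss: list[float] = field(default_factory=list)
    accuracy: list[float] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"epoch": np.arange(1, len(self.loss) + 1),
                             "train_loss": self.loss,
                             "train_accuracy_pct": self.accuracy})

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        return path


class Adam:
    """Adaptive-moment optimiser over a fixed parameter list."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        for i, p in enumerate(self.params):
            g = p.grad if p.grad is not None else 0.0
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            m_hat = self.m[i] / (1 - b1 ** self.t)
            v_hat = self.v[i] / (1 - b2 ** self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


def loss_on_logits(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Differentiable mean cross-entropy from logits (log-sum-exp form)."""
    labels = np.asarray(labels, dtype=np.int64)
    n, m = logits.shape
    onehot = np.zeros((n, m))
    onehot[np.arange(n), labels - 1] = 1.0
    shifted = logits - Tensor(logits.data.max(axis=1, keepdims=True))
    lse = shifted.exp().sum(axis=1, keepdims=True).log()
    logp = shifted - lse
    return -(logp * Tensor(onehot)).sum() * (1.0 / n)


def train(model, train_set, config: TrainConfig):
    """Fit ``model`` on ``train_set``; returns ``(model, TrainHistory)``."""
    if train_set.n_samples == 0:
        raise ValueError("training set is empty")
    x_all = train_set.as_batch()
    if x_all.shape[1] != model.config.bands:
        raise ValueError(
            f"band mismatch: data has {x_all.shape[1]}, model expects "
            f"{model.config.bands}")
    y_all = train_set.labels
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.parameters(), lr=config.initial_lr)
    history = TrainHistory()
    best_loss = np.inf
    stale = 0
    n = train_set.n_samples
    for epoch in range(config.max_epochs):
        opt.lr = config.lr_at_epoch(epoch)
        order = rng.permutation(n)
        epoch_loss = 0.0
        correct = 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb = Tensor(x_all[idx])
            yb = y_all[idx]
            logits = model.logits(xb)
            loss = loss_on_logits(logits, yb)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch + 1}, batch "
                    f"{start // config.batch_size + 1}: {loss.data!r}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * idx.size
            correct += int((logits.data.argmax(axis=1) + 1 == yb).sum())
        history.loss.append(epoch_loss / n)
        history.accuracy.append(100.0 * correct / n)
        if config.patience is not None:
            if history.loss[-1] < best_loss - 1e-6:
                best_loss = history.loss[-1]
                stale = 0
            else:
                stale += 1
                if stale >= config.patience:
                    break
    return model, history
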