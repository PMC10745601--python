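"""Seeded training, validation and prediction loops.

The regime follows the reference setup: Adam, learning rate 1e-4, batch
size 128, mean-squared-error loss, dropout 0.4 in the fusion head, 300
epochs.  Every source of randomness (parameter init, shuffling, validation
split, dropout) derives deterministically from one integer seed, so a run
is bit-reproducible on a given machine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import compute_metrics
from .network import AffinityModel, ModelConfig

__all__ = ["TrainConfig", "TrainHistory", "Adam", "set_global_seed", "train", "predict", "evaluate"]


@dataclass
class TrainConfig:
    epochs: int = 300
    learning_rate: float = 1e-4
    batch_size: int = 128
    seed: int = 0
    val_fraction: float = 0.1
    checkpoint_policy: str = "best_val"  # or "last"

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not (0.0 <= self.val_fraction < 1.0):
            raise ValueError("val_fraction must lie in [0, 1)")
        if self.checkpoint_policy not in ("best_val", "last"):
            raise ValueError(f"unknown checkpoint_policy {self.checkpoint_policy!r}")

    def to_dict(self) -> dict:
        return {
            "epochs": self.epochs,
            "learning_rate": self.learning_rate,
            "batch_size": self.batch_size,
            "seed": self.seed,
            "val_fraction": self.val_fraction,
            "checkpoint_policy": self.checkpoint_policy,
        }

    @classmethod
    def from_dict(cls, d) -> "TrainConfig":
        return cls(**d)


@dataclass
class TrainHistory:
    seed: int
    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    val_rmse: list = field(default_factory=list)
    val_pcc: list = field(default_factory=list)

    @property
    def epochs_run(self) -> int:
        return len(self.train_loss)

    def to_dataframe(self) -> pd.DataFrame:
        data = {"epoch": np.arange(1, self.epochs_run + 1), "train_loss": self.train_loss}
        if self.val_loss:
            data["val_loss"] = self.val_loss
            data["val_rmse"] = self.val_rmse
            data["val_pcc"] = self.val_pcc
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def set_global_seed(seed: int) -> dict:
    """Derive the named random streams used across a run from one seed.

    Returns generators for model initialization, batch shuffling, dropout
    and the validation split; child seeds stay below 2**31.
    """
    seed = int(seed) % (2**31)
    np.random.seed(seed)  # legacy global state, for any indirect consumers
    names = ("init", "shuffle", "dropout", "split", "data")
    return {
        name: np.random.default_rng(np.random.SeedSequence([seed, i]))
        for i, name in enumerate(names)
    }


class Adam:
    """Adam optimizer over a flat parameter list."""

    def __init__(self, params, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g**2
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class TrainingDiverged(Exception):
    """The loss became non-finite."""


def _mse_loss(model, batch_samples, rng):
    from .autodiff import Tensor

    preds, _ = model.forward_batch(batch_samples, training=True, rng=rng)
    y = np.array([[s.affinity] for s in batch_samples])
    err = preds - Tensor(y)
    return (err * err).mean()


def train(dataset, model_cfg: ModelConfig, train_cfg: TrainConfig):
    """Fit a model on featurized samples; returns ``(model, history)``.

    A ``val_fraction`` slice (seeded shuffle) is held out for per-epoch
    validation and checkpoint selection; with ``val_fraction=0`` the history
    carries no validation entries and the final parameters are returned.
    """
    dataset = list(dataset)
    if not dataset:
        raise ValueError("dataset must be nonempty")
    streams = set_global_seed(train_cfg.seed)
    model = AffinityModel(model_cfg, seed=int(streams["init"].integers(2**31)))

    n_val = int(round(train_cfg.val_fraction * len(dataset)))
    order = streams["split"].permutation(len(dataset))
    val_set = [dataset[i] for i in order[:n_val]]
    train_set = [dataset[i] for i in order[n_val:]]
    if not train_set:
        raise ValueError("validation split left no training samples")

    opt = Adam(model.parameters(), lr=train_cfg.learning_rate)
    history = TrainHistory(seed=train_cfg.seed)
    best_val = np.inf
    best_state = None

    for _epoch in range(train_cfg.epochs):
        perm = streams["shuffle"].permutation(len(train_set))
        epoch_loss = 0.0
        for b_idx, lo in enumerate(range(0, len(perm), train_cfg.batch_size)):
            batch = [train_set[i] for i in perm[lo : lo + train_cfg.batch_size]]
            model.zero_grad()
            loss = _mse_loss(model, batch, streams["dropout"])
            if not np.isfinite(loss.data):
                raise TrainingDiverged(
                    f"non-finite loss in epoch {_epoch + 1}, batch {b_idx}"
                )
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(batch)
        history.train_loss.append(epoch_loss / len(train_set))

        if val_set:
            preds, _ = model.forward_batch(val_set, training=False)
            y = np.array([s.affinity for s in val_set])
            p = preds.data.ravel()
            val_mse = float(np.mean((p - y) ** 2))
            history.val_loss.append(val_mse)
            history.val_rmse.append(float(np.sqrt(val_mse)))
            if len(val_set) >= 2 and np.std(y) > 0 and np.std(p) > 0:
                history.val_pcc.append(float(np.corrcoef(y, p)[0, 1]))
            else:
                history.val_pcc.append(float("nan"))
            if val_mse < best_val:
                best_val = val_mse
                best_state = model.state_arrays()

    if train_cfg.checkpoint_policy == "best_val" and best_state is not None:
        model.load_state_arrays(best_state)
    return model, history


def predict(model: AffinityModel, dataset, batch_size: int = 128):
    """Evaluation-mode predictions, order-preserving and deterministic."""
    dataset = list(dataset)
    out = []
    for lo in range(0, len(dataset), batch_size):
        batch = dataset[lo : lo + batch_size]
        preds, _ = model.forward_batch(batch, training=False)
        out.extend(
            (s.complex_id, float(v)) for s, v in zip(batch, preds.data.ravel())
        )
    return out


def evaluate(model: AffinityModel, dataset, batch_size: int = 128):
    """Metrics of the model on a featurized dataset."""
    preds = dict(predict(model, dataset, batch_size=batch_size))
    y_true = [s.affinity for s in dataset]
    y_pred = [preds[s.complex_id] for s in dataset]
    return compute_metrics(y_true, y_pred)
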