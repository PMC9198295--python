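"""Feedforward neural-network classifier over feature-gene scores.

A three-layer network — input (one unit per feature gene), one hidden
layer of logistic units, and a single sigmoid output — trained by
full-batch gradient descent on binary cross-entropy.  The output is the
probability a sample belongs to the treatment (tumor) group; labels are
assigned at the 0.5 threshold, with exactly 0.5 counting as treatment.

The architecture is deliberately the smallest one consistent with a
three-layer description: no momentum, no regularization, no early stopping
on held-out data (the cohorts are far too small); training stops when the
loss change drops below ``tol`` or at ``max_epochs``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortLabels
from .scoring import ScoreMatrix

__all__ = ["NNConfig", "NNModel", "train_nn", "predict_nn"]


@dataclass
class NNConfig:
    hidden_units: int = 5
    learning_rate: float = 0.1
    max_epochs: int = 10000
    tol: float = 1e-6
    seed: int = 0
    init_range: float = 0.5

    def __post_init__(self) -> None:
        if self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class NNModel:
    """Trained weights plus the feature schema they were fit on."""

    W1: np.ndarray  # hidden x features
    b1: np.ndarray  # hidden
    W2: np.ndarray  # hidden
    b2: float
    feature_schema: list[str]
    config: NNConfig
    final_loss: float = np.nan
    epochs_run: int = 0
    history: list[float] = field(default_factory=list, repr=False)

    def forward(self, S: np.ndarray) -> np.ndarray:
        hidden = _sigmoid(S @ self.W1.T + self.b1)
        p = _sigmoid(hidden @ self.W2 + self.b2)
        # keep probabilities in the open interval even when saturated
        return np.clip(p, 1e-12, 1.0 - 1e-12)

    def to_json(self, path) -> None:
        payload = {
            "W1": self.W1.tolist(),
            "b1": self.b1.tolist(),
            "W2": self.W2.tolist(),
            "b2": self.b2,
            "feature_schema": self.feature_schema,
            "config": vars(self.config),
            "final_loss": self.final_loss,
            "epochs_run": self.epochs_run,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "NNModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            W1=np.array(d["W1"], dtype=float),
            b1=np.array(d["b1"], dtype=float),
            W2=np.array(d["W2"], dtype=float),
            b2=float(d["b2"]),
            feature_schema=list(d["feature_schema"]),
            config=NNConfig(**d["config"]),
            final_loss=float(d["final_loss"]),
            epochs_run=int(d["epochs_run"]),
        )


def _bce(p: np.ndarray, y: np.ndarray) -> float:
    eps = 1e-12
    p = np.clip(p, eps, 1 - eps)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def train_nn(scores: ScoreMatrix, labels: CohortLabels, cfg: NNConfig | None = None) -> NNModel:
    """Fit the network on binary scores by full-batch gradient descent."""
    cfg = cfg or NNConfig()
    samples = scores.scores.index
    S = scores.scores.values.astype(float)
    if not np.isin(S, (0.0, 1.0)).all():
        raise ValueError("score entries must be binary")
    y = labels.binary().reindex(samples)
    if y.isna().any():
        raise ValueError(f"unlabeled samples in score matrix: {list(samples[y.isna()])}")
    y = y.values.astype(float)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")

    n, f = S.shape
    rng = np.random.default_rng(cfg.seed)
    W1 = rng.uniform(-cfg.init_range, cfg.init_range, size=(cfg.hidden_units, f))
    b1 = rng.uniform(-cfg.init_range, cfg.init_range, size=cfg.hidden_units)
    W2 = rng.uniform(-cfg.init_range, cfg.init_range, size=cfg.hidden_units)
    b2 = float(rng.uniform(-cfg.init_range, cfg.init_range))

    prev_loss = np.inf
    history: list[float] = []
    epochs = 0
    for epoch in range(cfg.max_epochs):
        H = _sigmoid(S @ W1.T + b1)  # n x hidden
        p = _sigmoid(H @ W2 + b2)  # n
        loss = _bce(p, y)
        history.append(loss)
        epochs = epoch + 1
        if abs(prev_loss - loss) < cfg.tol:
            break
        prev_loss = loss
        # BCE + sigmoid output: d loss / d output pre-activation = (p - y)/n
        delta_out = (p - y) / n
        gW2 = H.T @ delta_out
        gb2 = delta_out.sum()
        delta_h = np.outer(delta_out, W2) * H * (1 - H)  # n x hidden
        gW1 = delta_h.T @ S
        gb1 = delta_h.sum(axis=0)
        W2 -= cfg.learning_rate * gW2
        b2 -= cfg.learning_rate * gb2
        W1 -= cfg.learning_rate * gW1
        b1 -= cfg.learning_rate * gb1

    model = NNModel(
        W1=W1,
        b1=b1,
        W2=W2,
        b2=b2,
        feature_schema=list(scores.scores.columns),
        config=cfg,
        final_loss=history[-1],
        epochs_run=epochs,
        history=history,
    )
    return model


def predict_nn(model: NNModel, scores: ScoreMatrix) -> pd.DataFrame:
    """Per-sample treatment probability and 0.5-threshold label.

    The score columns must match the model's feature schema exactly (same
    genes, same order).
    """
    cols = list(scores.scores.columns)
    if cols != model.feature_schema:
        missing = [g for g in model.feature_schema if g not in cols]
        extra = [g for g in cols if g not in model.feature_schema]
        raise ValueError(
            f"score schema mismatch: missing={missing}, extra={extra}, "
            f"expected order {model.feature_schema}"
        )
    p = model.forward(scores.scores.values.astype(float))
    label = np.where(p >= 0.5, "treatment", "control")
    return pd.DataFrame(
        {"probability": p, "label": label}, index=scores.scores.index
    )
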