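"""The band-power state classifier: a 5-150-2 SELU/softmax network.

A deliberately small fully connected network maps one five-component
normalized band-power feature vector to two class probabilities
(``normal`` vs ``artificial OBBB / activated drainage``).  Architecture:

* input layer, 5 units (one per frequency band);
* one hidden layer, 150 units, SELU activation, with bias;
* output layer, 2 units, softmax, *no* bias.

Training minimises categorical cross-entropy with L2 regularization of
the non-output layer's weights and biases, by backpropagation with Adam
updates.  Weights are LeCun-normal initialised (the scheme paired with
SELU).  Everything is plain numpy and fully seed-reproducible.

The module follows the model/results convention: build a
:class:`BandPowerClassifier` from feature arrays, call :meth:`fit`, and
work with the returned :class:`ClassifierResults` (accuracy curves,
``summary()``, prediction, serialization).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FEATURE_COLUMNS, feature_matrix
from .recording import ConfigurationError

__all__ = [
    "ClassifierSpec",
    "TrainConfig",
    "split_dataset",
    "BandPowerClassifier",
    "ClassifierResults",
    "CLASS_LABELS",
]

#: Output-neuron order: index 0 = normal behaviour ('0'), index 1 =
#: artificial OBBB / drainage activation ('1').
CLASS_LABELS: tuple[str, str] = ("normal_behavior", "artificial_obbb")

_SELU_ALPHA = 1.6732632423543772
_SELU_SCALE = 1.0507009873554805


@dataclass(frozen=True)
class ClassifierSpec:
    """Network architecture and regularization."""

    input_size: int = 5
    hidden_size: int = 150
    output_size: int = 2
    l2: float = 1e-4  # weights *and* biases of the non-output layer

    def __post_init__(self) -> None:
        if min(self.input_size, self.hidden_size, self.output_size) < 1:
            raise ConfigurationError("layer sizes must be positive")
        if self.l2 < 0:
            raise ConfigurationError("l2 must be >= 0")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization protocol."""

    epochs: int = 200
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0
    train_fraction: float = 0.70

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ConfigurationError("epochs must be >= 1")
        if not 0 < self.train_fraction < 1:
            raise ConfigurationError("train_fraction must lie in (0, 1)")


def split_dataset(
    X: np.ndarray,
    y: np.ndarray,
    train_fraction: float = 0.70,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, dict[int, tuple[int, int]]]:
    """Per-class shuffled 70/30 split.

    Each class contributes ``floor(train_fraction * n_class)`` training
    examples, the remainder to testing, so 715 examples per class yield
    the standard 500/215.  Returns ``(X_train, y_train, X_test, y_test,
    counts)`` with ``counts[class] = (n_train, n_test)``.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    if X.shape[0] != y.shape[0]:
        raise ConfigurationError("X and y lengths differ")
    rng = np.random.default_rng(seed)
    tr_idx, te_idx = [], []
    counts: dict[int, tuple[int, int]] = {}
    for cls in np.unique(y):
        idx = np.nonzero(y == cls)[0]
        if idx.size < 2:
            raise ConfigurationError(f"class {cls} has fewer than 2 examples")
        rng.shuffle(idx)
        n_train = int(np.floor(train_fraction * idx.size))
        tr_idx.append(idx[:n_train])
        te_idx.append(idx[n_train:])
        counts[int(cls)] = (n_train, idx.size - n_train)
    tr = np.concatenate(tr_idx)
    te = np.concatenate(te_idx)
    rng.shuffle(tr)
    return X[tr], y[tr], X[te], y[te], counts


def _selu(z: np.ndarray) -> np.ndarray:
    return _SELU_SCALE * np.where(z > 0, z, _SELU_ALPHA * (np.exp(np.minimum(z, 0.0)) - 1.0))


def _selu_grad(z: np.ndarray) -> np.ndarray:
    return _SELU_SCALE * np.where(z > 0, 1.0, _SELU_ALPHA * np.exp(np.minimum(z, 0.0)))


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class BandPowerClassifier:
    """Model object holding the training design (features + labels).

    Parameters
    ----------
    X : array (n, 5)
        Normalized band-power feature vectors.
    y : int array (n,)
        Class indices, 0 = normal behaviour, 1 = artificial OBBB.
    spec
        Architecture / regularization; defaults to the standard 5-150-2.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray,
                 spec: ClassifierSpec | None = None) -> None:
        self.X = np.asarray(X, dtype=np.float64)
        self.y = np.asarray(y, dtype=np.int64)
        self.spec = spec or ClassifierSpec()
        if self.X.ndim != 2 or self.X.shape[1] != self.spec.input_size:
            raise ConfigurationError(
                f"X must be (n, {self.spec.input_size}); got {self.X.shape}"
            )
        if self.X.shape[0] != self.y.shape[0]:
            raise ConfigurationError("X and y lengths differ")
        if np.any((self.y < 0) | (self.y >= self.spec.output_size)):
            raise ConfigurationError("labels out of range")
        if not np.all(np.isfinite(self.X)):
            raise ConfigurationError("X contains non-finite values; drop invalid windows")

    @classmethod
    def from_feature_table(cls, table: pd.DataFrame,
                           spec: ClassifierSpec | None = None) -> "BandPowerClassifier":
        """Build from a features table (valid windows only; labels mapped
        via ``CLASS_LABELS``)."""
        df = table[table["valid"]]
        unknown = set(df["label"]) - set(CLASS_LABELS)
        if unknown:
            raise ConfigurationError(f"non-training labels in table: {sorted(unknown)}")
        y = df["label"].map({lbl: i for i, lbl in enumerate(CLASS_LABELS)}).to_numpy()
        return cls(feature_matrix(table), y, spec)

    def fit(self, config: TrainConfig | None = None,
            eval_set: tuple[np.ndarray, np.ndarray] | None = None) -> "ClassifierResults":
        """Train by backpropagation; returns results with accuracy curves.

        ``eval_set`` supplies the held-out test set tracked per epoch.
        """
        cfg = config or TrainConfig()
        spec = self.spec
        rng = np.random.default_rng(cfg.seed)
        # LeCun normal: std = 1/sqrt(fan_in)
        W1 = rng.normal(0.0, 1.0 / np.sqrt(spec.input_size),
                        (spec.input_size, spec.hidden_size))
        b1 = np.zeros(spec.hidden_size)
        W2 = rng.normal(0.0, 1.0 / np.sqrt(spec.hidden_size),
                        (spec.hidden_size, spec.output_size))
        params = [W1, b1, W2]
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        n = self.X.shape[0]
        train_curve = np.empty(cfg.epochs)
        test_curve = np.full(cfg.epochs, np.nan)

        def accuracy(X: np.ndarray, y: np.ndarray) -> float:
            proba = _forward(X, params)[-1]
            return float(np.mean(proba.argmax(axis=1) == y))

        for epoch in range(cfg.epochs):
            order = rng.permutation(n)
            for lo in range(0, n, cfg.batch_size):
                batch = order[lo : lo + cfg.batch_size]
                Xb, yb = self.X[batch], self.y[batch]
                z1, h, proba = _forward(Xb, params)
                if not np.all(np.isfinite(proba)):
                    raise FloatingPointError(
                        f"non-finite network output at epoch {epoch}, step {step}"
                    )
                nb = Xb.shape[0]
                dlogits = proba.copy()
                dlogits[np.arange(nb), yb] -= 1.0
                dlogits /= nb
                gW2 = h.T @ dlogits
                dh = dlogits @ params[2].T
                dz1 = dh * _selu_grad(z1)
                gW1 = Xb.T @ dz1 + spec.l2 * params[0]
                gb1 = dz1.sum(axis=0) + spec.l2 * params[1]
                step += 1
                for p, g, mi, vi in zip(params, (gW1, gb1, gW2), m, v):
                    mi += (1 - beta1) * (g - mi)
                    vi += (1 - beta2) * (g * g - vi)
                    mhat = mi / (1 - beta1**step)
                    vhat = vi / (1 - beta2**step)
                    p -= cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)
            train_curve[epoch] = accuracy(self.X, self.y)
            if eval_set is not None:
                test_curve[epoch] = accuracy(*eval_set)
        return ClassifierResults(self, cfg, params, train_curve, test_curve)


def _forward(X: np.ndarray, params: list[np.ndarray]):
    z1 = X @ params[0] + params[1]
    h = _selu(z1)
    return z1, h, _softmax(h @ params[2])


class ClassifierResults:
    """Fitted network: weights, accuracy curves, prediction, persistence."""

    def __init__(self, model: BandPowerClassifier, config: TrainConfig,
                 params: list[np.ndarray], train_curve: np.ndarray,
                 test_curve: np.ndarray) -> None:
        self.model = model
        self.config = config
        self.params = params
        self.train_accuracy = np.asarray(train_curve)
        self.test_accuracy = np.asarray(test_curve)

    # -- prediction ---------------------------------------------------------

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Softmax class probabilities, shape (n, 2)."""
        X = np.asarray(X, dtype=np.float64)
        return _forward(X, self.params)[-1]

    def predict_response(self, features: pd.DataFrame) -> pd.DataFrame:
        """Raw per-window response: the OBBB/activation output neuron.

        Returns the feature table's bookkeeping columns plus a
        ``response`` column in [0, 1]; invalid windows yield NaN gaps,
        never zeros.
        """
        out = features.loc[:, ["recording_id", "window_start_s", "label", "norm",
                               "valid"]].copy()
        response = np.full(len(features), np.nan)
        mask = features["valid"].to_numpy()
        if mask.any():
            X = features.loc[mask, list(FEATURE_COLUMNS)].to_numpy(dtype=np.float64)
            response[mask] = self.predict_proba(X)[:, 1]
        out["response"] = response
        return out

    def score(self, X: np.ndarray, y: np.ndarray) -> float:
        return float(np.mean(self.predict_proba(X).argmax(axis=1) == np.asarray(y)))

    # -- reporting ----------------------------------------------------------

    @property
    def final_train_accuracy(self) -> float:
        return float(self.train_accuracy[-1])

    @property
    def final_test_accuracy(self) -> float:
        return float(self.test_accuracy[-1])

    def summary(self) -> str:
        spec, cfg = self.model.spec, self.config
        classes, counts = np.unique(self.model.y, return_counts=True)
        lines = [
            "Band-power state classifier",
            "===========================",
            f"architecture      {spec.input_size}-{spec.hidden_size}-{spec.output_size} "
            "(SELU hidden with bias, softmax output without bias)",
            f"regularization    L2 lambda={spec.l2:g} on non-output weights and biases",
            f"optimizer         Adam lr={cfg.learning_rate:g}, batch={cfg.batch_size}, "
            f"epochs={cfg.epochs}, seed={cfg.seed}",
            "training examples "
            + ", ".join(f"{CLASS_LABELS[c]}: {n}" for c, n in zip(classes, counts)),
            f"final accuracy    train={self.final_train_accuracy:.3f}"
            + (f", test={self.final_test_accuracy:.3f}"
               if np.isfinite(self.test_accuracy[-1]) else ""),
        ]
        return "\n".join(lines)

    def curves_frame(self) -> pd.DataFrame:
        """Per-epoch accuracy table (epoch, train_acc, test_acc)."""
        return pd.DataFrame({
            "epoch": np.arange(1, len(self.train_accuracy) + 1),
            "train_acc": self.train_accuracy,
            "test_acc": self.test_accuracy,
        })

    # -- persistence (plain JSON keeps the artifact text-only) --------------

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "spec": vars(self.model.spec),
            "config": vars(self.config),
            "weights": {
                "W1": self.params[0].tolist(),
                "b1": self.params[1].tolist(),
                "W2": self.params[2].tolist(),
            },
            "train_accuracy": self.train_accuracy.tolist(),
            "test_accuracy": self.test_accuracy.tolist(),
        }
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(payload))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "ClassifierResults":
        payload = json.loads(Path(path).read_text())
        spec = ClassifierSpec(**payload["spec"])
        cfg = TrainConfig(**payload["config"])
        params = [np.array(payload["weights"][k]) for k in ("W1", "b1", "W2")]
        dummy = BandPowerClassifier(np.zeros((2, spec.input_size)),
                                    np.array([0, 1]), spec)
        return cls(dummy, cfg, params,
                   np.array(payload["train_accuracy"]),
                   np.array(payload["test_accuracy"]))
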