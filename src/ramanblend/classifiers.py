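"""Binary spectral classifiers: a 1-D CNN and a fully connected network.

The CNN follows the DeepCID-style layout: two down-sampling blocks
(valid convolution, ReLU, non-overlapping max pooling, dropout), a
flatten, two fully connected ReLU layers, and a single sigmoid output
unit.  Block filter counts are 32 and 64; the first fully connected
layer's input width is fixed by the flattened conv output (final length
x 64 feature maps) and both hidden dense layers have 1024 units.  The
FCNN removes the convolutional blocks: its first hidden layer has as many
units as the input has dimensions, the second has 1024.

Both share the same initialization (truncated normal, mu=0, sigma=0.1;
biases 0.1), ReLU activations, binary cross-entropy loss, and Adam with a
learning rate of 1e-4; the study schedule trains 100 epochs at batch
size 1 (both overridable).  Dropout is disabled at prediction time, so
evaluation is deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from . import nn
from .dataset import SpectrumSet

__all__ = [
    "TrainConfig",
    "CNNClassifier",
    "FCNNClassifier",
    "build_classifier",
    "train_classifier",
    "predict",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 100
    learning_rate: float = 1e-4
    batch_size: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


class _NeuralBinaryClassifier(BaseEstimator, ClassifierMixin):
    """Shared training loop; subclasses define the architecture."""

    _is_conv = False

    def _build_net(self, input_dim: int, rng):  # pragma: no cover - abstract
        raise NotImplementedError

    def build(self, input_dim: int):
        """Initialize (seeded) network weights without training."""
        rng = np.random.default_rng(self.seed)
        self._net = self._build_net(input_dim, rng)
        self.input_dim_ = input_dim
        self.classes_ = np.array([0, 1])
        self.history_ = []
        return self

    def _shape_input(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.input_dim_:
            raise ValueError(f"expected {self.input_dim_} features, got {X.shape[1]}")
        return X[:, None, :] if self._is_conv else X

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or y.shape != (X.shape[0],):
            raise ValueError("X must be 2-D with one label per row")
        if not np.all(np.isin(y, (0.0, 1.0))):
            raise ValueError("labels must be binary {0,1}")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        self.build(X.shape[1])
        rng = np.random.default_rng(self.seed + 1)  # shuffling/dropout stream
        opt = nn.Adam(self._net.params(), lr=self.learning_rate)
        n = X.shape[0]
        bs = min(self.batch_size, n)
        Xs = self._shape_input(X)
        for epoch in range(self.epochs):
            perm = rng.permutation(n)
            total = 0.0
            for start in range(0, n, bs):
                sel = perm[start:start + bs]
                xb, yb = Xs[sel], y[sel]
                b = xb.shape[0]
                logits = self._net.forward(xb, train=True, rng=rng).ravel()
                loss = float(np.mean(nn.bce_with_logits(logits, yb)))
                if not np.isfinite(loss):
                    raise RuntimeError(f"training diverged at epoch {epoch}")
                total += loss * b
                dlogits = ((nn.sigmoid(logits) - yb) / b).reshape(b, 1)
                self._net.backward(dlogits)
                opt.step(self._net.grads())
            self.history_.append(total / n)
        return self

    def decision_function(self, X):
        return self._net.forward(self._shape_input(X), train=False).ravel()

    def predict_proba(self, X):
        p = nn.sigmoid(self.decision_function(X))
        return np.column_stack([1.0 - p, p])

    def predict(self, X):
        p = self.predict_proba(X)[:, 1]
        return (p >= self.threshold).astype(int)


class CNNClassifier(_NeuralBinaryClassifier):
    """Two conv/pool/dropout blocks, then 1024-1024 dense layers, sigmoid out."""

    _is_conv = True

    def __init__(self, filters1: int = 32, filters2: int = 64, kernel: int = 5,
                 pool: int = 2, dropout: float = 0.5, fc_units: int = 1024,
                 epochs: int = 100, learning_rate: float = 1e-4,
                 batch_size: int = 1, seed: int = 0, threshold: float = 0.5):
        self.filters1 = filters1
        self.filters2 = filters2
        self.kernel = kernel
        self.pool = pool
        self.dropout = dropout
        self.fc_units = fc_units
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.seed = seed
        self.threshold = threshold

    def _conv_output_length(self, input_dim: int) -> int:
        length = input_dim
        for _ in range(2):
            length = length - self.kernel + 1
            if length < 1:
                return 0
            length //= self.pool
            if length < 1:
                return 0
        return length

    def _min_input_dim(self) -> int:
        # smallest input surviving both conv+pool stages
        length = 1
        for _ in range(2):
            length = length * self.pool + self.kernel - 1
        return length

    def _build_net(self, input_dim: int, rng):
        lout = self._conv_output_length(input_dim)
        if lout < 1:
            raise ValueError(
                f"input_dim={input_dim} too short for two conv/pool stages; "
                f"need at least {self._min_input_dim()}"
            )
        flat = lout * self.filters2
        return nn.Sequential([
            nn.Conv1D(1, self.filters1, self.kernel, rng), nn.ReLU(),
            nn.MaxPool1D(self.pool), nn.Dropout(self.dropout),
            nn.Conv1D(self.filters1, self.filters2, self.kernel, rng), nn.ReLU(),
            nn.MaxPool1D(self.pool), nn.Dropout(self.dropout),
            nn.Flatten(),
            nn.Dense(flat, self.fc_units, rng), nn.ReLU(),
            nn.Dense(self.fc_units, self.fc_units, rng), nn.ReLU(),
            nn.Dense(self.fc_units, 1, rng),
        ])


class FCNNClassifier(_NeuralBinaryClassifier):
    """The CNN with its convolutional blocks removed.

    Hidden layers: (input_dim, 1024) with ReLU, then the sigmoid output.
    """

    def __init__(self, hidden2: int = 1024, epochs: int = 100,
                 learning_rate: float = 1e-4, batch_size: int = 1,
                 seed: int = 0, threshold: float = 0.5):
        self.hidden2 = hidden2
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.seed = seed
        self.threshold = threshold

    def _build_net(self, input_dim: int, rng):
        return nn.Sequential([
            nn.Dense(input_dim, input_dim, rng), nn.ReLU(),
            nn.Dense(input_dim, self.hidden2, rng), nn.ReLU(),
            nn.Dense(self.hidden2, 1, rng),
        ])

    def n_parameters(self, input_dim: int) -> int:
        return (input_dim * input_dim + input_dim
                + input_dim * self.hidden2 + self.hidden2
                + self.hidden2 + 1)


def build_classifier(arch: str, seed: int = 0, config: TrainConfig = TrainConfig(),
                     **kwargs):
    """Construct an untrained classifier ('cnn' or 'fcnn')."""
    common = dict(epochs=config.epochs, learning_rate=config.learning_rate,
                  batch_size=config.batch_size, seed=seed)
    common.update(kwargs)
    if arch == "cnn":
        return CNNClassifier(**common)
    if arch == "fcnn":
        return FCNNClassifier(**common)
    raise ValueError(f"unknown architecture {arch!r}")


def train_classifier(model, train: SpectrumSet, config: TrainConfig | None = None):
    """Train on a normalized SpectrumSet (labels from the set)."""
    if config is not None:
        model.set_params(epochs=config.epochs, learning_rate=config.learning_rate,
                         batch_size=config.batch_size, seed=config.seed)
    return model.fit(train.matrix, train.labels)


def predict(model, spectra: SpectrumSet, threshold: float | None = None):
    """Return (labels, probabilities) on a SpectrumSet, dropout disabled."""
    proba = model.predict_proba(spectra.matrix)[:, 1]
    thr = model.threshold if threshold is None else threshold
    return (proba >= thr).astype(int), proba


def save_model(model, path) -> None:
    """Persist architecture tag, hyperparameters, and weights to .npz."""
    arch = "cnn" if isinstance(model, CNNClassifier) else "fcnn"
    meta = {"arch": arch, "params": model.get_params(),
            "input_dim": int(model.input_dim_),
            "history": [float(v) for v in model.history_]}
    arrays = {f"p{i}": p for i, p in enumerate(model._net.params())}
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_model(path):
    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["meta"]))
    cls = CNNClassifier if meta["arch"] == "cnn" else FCNNClassifier
    model = cls(**meta["params"])
    model.build(meta["input_dim"])
    model.history_ = meta["history"]
    for i, p in enumerate(model._net.params()):
        p[...] = data[f"p{i}"]
    return model
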