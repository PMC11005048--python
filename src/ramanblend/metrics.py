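"""Evaluation metrics: confusion counts, balanced accuracy, mean spectra,
the discrete Fréchet distance, and 2-component PCA scores.

Balanced accuracy is the arithmetic mean of sensitivity (TPR = tp/(tp+fn))
and specificity (TNR = tn/(tn+fp)), the standard summary for imbalanced
two-class data.

The discrete Fréchet distance ("coupling distance") between two point
sequences P, Q is the minimum over monotone couplings of the maximum
coupled Euclidean pair distance, computed by the dynamic program

    ca(i,j) = max(d(p_i, q_j), min(ca(i-1,j), ca(i-1,j-1), ca(i,j-1)))

where the three admissible moves advance P, advance Q, or advance both.
Applied here to mean spectra, with curve x-coordinates defaulting to the
native feature index ("index" mode); "wavenumber" and "none" (pure 1-D
intensity sequences) modes are also available since the distance is range-
and scale-dependent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .dataset import SpectrumSet

__all__ = [
    "ConfusionCounts",
    "confusion",
    "sensitivity",
    "specificity",
    "balanced_accuracy",
    "mean_spectrum",
    "discrete_frechet",
    "pca_scores",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(y_true, y_pred) -> ConfusionCounts:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise ValueError("y_true and y_pred must be equal-length and non-empty")
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def sensitivity(c: ConfusionCounts) -> float:
    if c.tp + c.fn == 0:
        raise ValueError("no positive samples: sensitivity undefined")
    return c.tp / (c.tp + c.fn)


def specificity(c: ConfusionCounts) -> float:
    if c.tn + c.fp == 0:
        raise ValueError("no negative samples: specificity undefined")
    return c.tn / (c.tn + c.fp)


def balanced_accuracy(c: ConfusionCounts) -> float:
    return 0.5 * (sensitivity(c) + specificity(c))


def mean_spectrum(spectra: SpectrumSet, x_mode: str = "index") -> np.ndarray:
    """Columnwise mean spectrum as a curve, pooled over classes.

    ``x_mode``: "index" pairs the mean with feature index 0..D-1,
    "wavenumber" with the axis values, "none" returns a 1-D sequence.
    """
    if spectra.n_samples == 0:
        raise ValueError("cannot take the mean of an empty set")
    y = spectra.matrix.mean(axis=0)
    if x_mode == "none":
        return y
    if x_mode == "index":
        x = np.arange(y.size, dtype=float)
    elif x_mode == "wavenumber":
        x = spectra.wavenumbers
    else:
        raise ValueError(f"unknown x_mode {x_mode!r}")
    return np.column_stack([x, y])


def discrete_frechet(p, q) -> float:
    """Discrete Fréchet distance between two curves.

    Curves are ``(n, d)`` point arrays or 1-D intensity sequences (treated
    as points on a line).  Symmetric, nonnegative, zero iff the sequences
    are identical.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.size == 0 or q.size == 0:
        raise ValueError("curves must be non-empty")
    if p.ndim == 1:
        p = p[:, None]
    if q.ndim == 1:
        q = q[:, None]
    # pairwise Euclidean distances, (|P|, |Q|)
    d = np.sqrt(((p[:, None, :] - q[None, :, :]) ** 2).sum(axis=2))
    n, m = d.shape
    ca = np.empty((n, m))
    ca[0, 0] = d[0, 0]
    for j in range(1, m):
        ca[0, j] = max(ca[0, j - 1], d[0, j])
    for i in range(1, n):
        ca[i, 0] = max(ca[i - 1, 0], d[i, 0])
        row, prev = ca[i], ca[i - 1]
        for j in range(1, m):
            row[j] = max(d[i, j], min(prev[j], prev[j - 1], row[j - 1]))
    return float(ca[-1, -1])


def pca_scores(x, n_components: int = 2) -> np.ndarray:
    """Scores of mean-centered data on the top-variance axes.

    Sign convention: each component is flipped if its largest-magnitude
    loading is negative, so scores are reproducible across runs.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[0] < n_components:
        raise ValueError("need at least as many rows as components")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(x)
    for k in range(n_components):
        load = pca.components_[k]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, k] = -scores[:, k]
    return scores
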