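"""Preprocessing: dead-feature removal and global min-max normalization.

Smoothing and baseline correction can leave a subset of feature columns
identically zero; those columns carry no signal and would distort a global
range shift, so they are removed first.  Normalization is a single global
(whole-matrix) min-max shift into [0, 1] — one range shift for the whole
dataset, not per-feature or per-spectrum — computed once on the principal
data and reusable for any later data via the stored parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .dataset import SpectrumSet

__all__ = [
    "NormalizationParams",
    "ZeroFeatureRemover",
    "GlobalMinMaxScaler",
    "drop_zero_features",
    "minmax_normalize",
    "preprocess_set",
]


@dataclass(frozen=True)
class NormalizationParams:
    observed_min: float
    observed_max: float
    mode: str = "global"

    def __post_init__(self):
        if self.observed_max <= self.observed_min:
            raise ValueError("observed_max must exceed observed_min")

    def apply(self, x: np.ndarray) -> np.ndarray:
        return (x - self.observed_min) / (self.observed_max - self.observed_min)

    def invert(self, x: np.ndarray) -> np.ndarray:
        return x * (self.observed_max - self.observed_min) + self.observed_min


class ZeroFeatureRemover(BaseEstimator, TransformerMixin):
    """Drop feature columns whose every entry is exactly zero.

    Fitted attributes: ``removed_idx_`` (original indices of dropped
    columns) and ``kept_idx_``.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.size == 0:
            raise ValueError("empty matrix")
        dead = np.all(X == 0.0, axis=0)
        if dead.all():
            raise ValueError("degenerate data: every feature column is zero")
        self.removed_idx_ = np.where(dead)[0]
        self.kept_idx_ = np.where(~dead)[0]
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return X[:, self.kept_idx_]


class GlobalMinMaxScaler(BaseEstimator, TransformerMixin):
    """Whole-matrix min-max scaler onto [0, 1].

    Unlike the per-feature scaler, a single (min, max) pair is taken over
    the entire matrix so relative band intensities across wavenumbers are
    preserved.  Fitted attribute: ``params_`` (:class:`NormalizationParams`).
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.size == 0:
            raise ValueError("empty matrix")
        lo, hi = float(X.min()), float(X.max())
        if hi == lo:
            raise ValueError("degenerate data: constant matrix cannot be normalized")
        self.params_ = NormalizationParams(lo, hi)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        return self.params_.apply(np.asarray(X, dtype=float))

    def inverse_transform(self, X):
        return self.params_.invert(np.asarray(X, dtype=float))


def drop_zero_features(spectra: SpectrumSet):
    """Remove all-zero columns; returns ``(reduced_set, removed_indices)``."""
    remover = ZeroFeatureRemover().fit(spectra.matrix)
    out = SpectrumSet(
        matrix=remover.transform(spectra.matrix),
        labels=spectra.labels,
        wavenumbers=spectra.wavenumbers[remover.kept_idx_],
        provenance=spectra.provenance,
        name=spectra.name,
    )
    return out, remover.removed_idx_.tolist()


def minmax_normalize(spectra: SpectrumSet):
    """Globally min-max normalize into [0, 1]; returns ``(set, params)``."""
    scaler = GlobalMinMaxScaler().fit(spectra.matrix)
    out = SpectrumSet(
        matrix=scaler.transform(spectra.matrix),
        labels=spectra.labels,
        wavenumbers=spectra.wavenumbers,
        provenance=spectra.provenance,
        name=spectra.name,
    )
    return out, scaler.params_


def preprocess_set(spectra: SpectrumSet):
    """Full preprocessing: drop dead columns, then normalize if needed.

    Data already lying inside [0, 1] and attaining (near) full range is
    passed through unchanged, mirroring datasets delivered pre-normalized.
    Returns ``(set, removed_indices, params_or_None)``.
    """
    reduced, removed = drop_zero_features(spectra)
    lo, hi = reduced.matrix.min(), reduced.matrix.max()
    if 0.0 <= lo and hi <= 1.0:
        return reduced, removed, None
    normed, params = minmax_normalize(reduced)
    return normed, removed, params
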