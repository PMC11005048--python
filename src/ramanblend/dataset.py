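"""Labelled spectral datasets and their on-disk CSV exchange format.

A :class:`SpectrumSet` is the currency passed between every stage of the
pipeline: an ``(n_samples, n_features)`` intensity matrix, a binary label per
row (1 = positive class), a shared wavenumber axis, and a per-row provenance
flag recording whether a spectrum is real or synthetic (``blend`` / ``vae``).

The CSV layout is self-describing: one header row containing the wavenumbers
followed by a literal ``label`` column and an optional ``provenance`` column.
Values are written with 9 significant digits, which round-trips float32-scale
training data exactly.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

PROVENANCES = ("real", "blend", "vae")

__all__ = [
    "Spectrum",
    "SpectrumSet",
    "DatasetProfile",
    "FormatError",
    "read_spectra_csv",
    "write_spectra_csv",
    "concat_sets",
    "sample_rows",
    "round_half_up",
]


class FormatError(ValueError):
    """Raised when an on-disk spectral file violates the CSV contract."""


def round_half_up(x: float) -> int:
    """Round to the nearest integer, ties away from zero (toward positives)."""
    return int(np.floor(x + 0.5))


@dataclass(frozen=True)
class Spectrum:
    """A single Raman spectrum: intensity as a function of Raman shift."""

    wavenumbers: np.ndarray
    intensities: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.wavenumbers, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        if w.ndim != 1 or y.ndim != 1 or w.shape != y.shape:
            raise ValueError("wavenumbers and intensities must be equal-length 1-D")
        if w.size < 2:
            raise ValueError("a spectrum needs at least 2 points")
        if not np.all(np.diff(w) > 0):
            raise ValueError("wavenumbers must be strictly increasing")
        object.__setattr__(self, "wavenumbers", w)
        object.__setattr__(self, "intensities", y)


@dataclass
class SpectrumSet:
    """A labelled set of spectra sharing one wavenumber axis.

    Parameters
    ----------
    matrix : (n_samples, n_features) float array
    labels : (n_samples,) int array of {0, 1}; 1 is the positive class
    wavenumbers : (n_features,) strictly increasing axis
    provenance : (n_samples,) array of {"real", "blend", "vae"}
    name : free-text identifier
    """

    matrix: np.ndarray
    labels: np.ndarray
    wavenumbers: np.ndarray
    provenance: np.ndarray = None
    name: str = ""

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D")
        n, d = self.matrix.shape
        if self.labels.shape != (n,):
            raise ValueError("labels length must match number of rows")
        if self.wavenumbers.shape != (d,):
            raise ValueError("wavenumber axis length must match number of columns")
        if not np.all(np.isin(self.labels, (0, 1))):
            raise ValueError("labels must be binary {0,1}")
        if np.isnan(self.matrix).any():
            raise ValueError("matrix contains missing values")
        if self.provenance is None:
            self.provenance = np.full(n, "real", dtype=object)
        else:
            self.provenance = np.asarray(self.provenance, dtype=object)
            if self.provenance.shape != (n,):
                raise ValueError("provenance length must match number of rows")
            bad = set(self.provenance) - set(PROVENANCES)
            if bad:
                raise ValueError(f"unknown provenance values: {sorted(bad)}")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def class_counts(self) -> dict:
        return {c: int(np.sum(self.labels == c)) for c in (0, 1)}

    def provenance_counts(self) -> dict:
        vals, counts = np.unique(self.provenance.astype(str), return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))

    def select(self, idx, name: str | None = None) -> "SpectrumSet":
        idx = np.asarray(idx, dtype=int)
        return SpectrumSet(
            matrix=self.matrix[idx],
            labels=self.labels[idx],
            wavenumbers=self.wavenumbers,
            provenance=self.provenance[idx],
            name=self.name if name is None else name,
        )

    def profile(self) -> "DatasetProfile":
        return DatasetProfile(
            n_features=self.n_features,
            class_prior=float(np.mean(self.labels)),
            intensity_range=(float(self.matrix.min()), float(self.matrix.max())),
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, SpectrumSet):
            return NotImplemented
        return (
            self.matrix.shape == other.matrix.shape
            and np.array_equal(self.matrix, other.matrix)
            and np.array_equal(self.labels, other.labels)
            and np.array_equal(self.wavenumbers, other.wavenumbers)
            and np.array_equal(
                self.provenance.astype(str), other.provenance.astype(str)
            )
        )


@dataclass(frozen=True)
class DatasetProfile:
    n_features: int
    class_prior: float
    intensity_range: tuple = field(default=(0.0, 1.0))

    def __post_init__(self):
        if not (0.0 < self.class_prior < 1.0):
            raise ValueError("class_prior must lie strictly between 0 and 1")


def read_spectra_csv(path) -> SpectrumSet:
    """Read a labelled spectral matrix from CSV.

    Header = wavenumbers, then ``label`` and optionally ``provenance``.
    Provenance defaults to ``real`` when the column is absent.
    """
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.ParserError as exc:  # ragged rows
        raise FormatError(f"{path}: malformed CSV ({exc})") from exc
    cols = list(df.columns)
    if "label" not in cols:
        raise FormatError(f"{path}: missing required 'label' column")
    has_prov = "provenance" in cols
    wn_cols = [c for c in cols if c not in ("label", "provenance")]
    try:
        wavenumbers = np.array([float(c) for c in wn_cols])
    except ValueError:
        bad = [c for c in wn_cols if not _is_number(c)]
        raise FormatError(f"{path}: non-numeric wavenumber header column(s) {bad}")
    if not np.all(np.diff(wavenumbers) > 0):
        raise FormatError(f"{path}: wavenumber header not strictly increasing")

    raw = df[wn_cols].to_numpy()
    matrix = np.empty(raw.shape, dtype=float)
    for i in range(raw.shape[0]):
        try:
            matrix[i] = raw[i].astype(float)
        except (TypeError, ValueError):
            raise FormatError(f"{path}: non-numeric intensity in data row {i}")
        if np.isnan(matrix[i]).any():
            raise FormatError(f"{path}: missing intensity in data row {i}")

    try:
        labels = df["label"].astype(float).to_numpy()
    except ValueError:
        raise FormatError(f"{path}: non-numeric value in 'label' column")
    if not np.all(np.isin(labels, (0.0, 1.0))):
        bad_rows = np.where(~np.isin(labels, (0.0, 1.0)))[0]
        raise FormatError(f"{path}: non-binary label in row(s) {bad_rows.tolist()}")

    provenance = (
        df["provenance"].to_numpy(dtype=object)
        if has_prov
        else np.full(len(df), "real", dtype=object)
    )
    return SpectrumSet(
        matrix=matrix,
        labels=labels.astype(int),
        wavenumbers=wavenumbers,
        provenance=provenance,
        name=str(path),
    )


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def write_spectra_csv(spectra: SpectrumSet, path) -> None:
    """Write a :class:`SpectrumSet` to CSV with 9-significant-digit values."""
    if spectra.n_samples == 0:
        raise ValueError("refusing to write an empty SpectrumSet")
    buf = io.StringIO()
    header = [_fmt(w) for w in spectra.wavenumbers] + ["label", "provenance"]
    buf.write(",".join(header) + "\n")
    for i in range(spectra.n_samples):
        row = [_fmt(v) for v in spectra.matrix[i]]
        row.append(str(int(spectra.labels[i])))
        row.append(str(spectra.provenance[i]))
        buf.write(",".join(row) + "\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def _fmt(v: float) -> str:
    return format(float(v), ".9g")


def concat_sets(a: SpectrumSet, b: SpectrumSet) -> SpectrumSet:
    """Stack two sets row-wise; axes must match exactly."""
    if b.n_samples == 0:
        return a.select(np.arange(a.n_samples))
    if a.n_samples == 0:
        return b.select(np.arange(b.n_samples))
    if a.n_features != b.n_features or not np.array_equal(
        a.wavenumbers, b.wavenumbers
    ):
        raise ValueError("wavenumber axes differ; cannot concatenate")
    return SpectrumSet(
        matrix=np.vstack([a.matrix, b.matrix]),
        labels=np.concatenate([a.labels, b.labels]),
        wavenumbers=a.wavenumbers,
        provenance=np.concatenate([a.provenance, b.provenance]),
        name=a.name,
    )


def sample_rows(spectra: SpectrumSet, n: int, per_class="prior", seed: int = 0) -> SpectrumSet:
    """Draw ``n`` rows without replacement.

    ``per_class`` is either a ``{1: n_pos, 0: n_neg}`` map or the string
    ``"prior"`` (preserve the pool's class prior, rounding half-up toward the
    positive class) or ``"balanced"`` (equal split, extra sample to the
    positive class when ``n`` is odd).
    """
    if n == 0:
        return spectra.select(np.array([], dtype=int))
    counts = spectra.class_counts()
    if per_class == "prior":
        prior = counts[1] / spectra.n_samples
        n_pos = round_half_up(n * prior)
        want = {1: n_pos, 0: n - n_pos}
    elif per_class == "balanced":
        n_pos = round_half_up(n / 2)
        want = {1: n_pos, 0: n - n_pos}
    else:
        want = {int(k): int(v) for k, v in dict(per_class).items()}
        for c in (0, 1):
            want.setdefault(c, 0)
    for c in (0, 1):
        if want[c] > counts[c]:
            raise ValueError(
                f"requested {want[c]} samples of class {c} "
                f"but only {counts[c]} available"
            )
    rng = np.random.default_rng(seed)
    chosen = []
    for c in (1, 0):
        pool = np.where(spectra.labels == c)[0]
        if want[c] > 0:
            chosen.append(rng.choice(pool, size=want[c], replace=False))
    idx = np.sort(np.concatenate(chosen)) if chosen else np.array([], dtype=int)
    return spectra.select(idx)
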