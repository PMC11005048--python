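"""Synthetic Raman-like dataset generator.

Each simulated spectrum is a smooth polynomial baseline plus a sum of
Gaussian or Lorentzian bands plus i.i.d. Gaussian detector noise:

    y = baseline(x) + sum_p a_p (1 + jitter) f_p(x; c_p, w_p) + noise

Bands are split into *shared* peaks (present in every spectrum) and
*class* peaks (present only in one class), so the two classes differ in a
known, localised set of features — the structure a binary Raman
classification task actually presents after smoothing and baseline
correction.

Two ready-made profiles emulate the study conditions of the two datasets
the pipeline targets: a chlorinated-solvent-like profile (2473 features,
350-3500 cm^-1, 67/33 class prior, distinguishing bands below 1168 cm^-1,
intensities natively inside [0,1]) and a SARS-CoV-2-serum-like profile
(900 features, 600-1800 cm^-1, 51/49 prior, raw intensities spanning
(-0.1, 0.4) with 8 dead all-zero columns, exercising the preprocessing
path).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import SpectrumSet, round_half_up

__all__ = [
    "PeakSpec",
    "SimulationConfig",
    "generate_dataset",
    "make_chlorinated_like",
    "make_sars_like",
]


@dataclass(frozen=True)
class PeakSpec:
    """One vibrational band: centre and width in axis units, unit-free amplitude."""

    center: float
    width: float
    amplitude: float
    shape: str = "gaussian"

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("peak width must be positive")
        if self.amplitude <= 0:
            raise ValueError("peak amplitude must be positive")
        if self.shape not in ("gaussian", "lorentzian"):
            raise ValueError("shape must be 'gaussian' or 'lorentzian'")

    def profile(self, axis: np.ndarray) -> np.ndarray:
        t = (axis - self.center) / self.width
        if self.shape == "gaussian":
            return np.exp(-0.5 * t * t)
        return 1.0 / (1.0 + t * t)


@dataclass
class SimulationConfig:
    """Full description of one simulated dataset.

    ``baseline_coeffs`` are polynomial coefficients (highest power first, as
    for ``numpy.polyval``) evaluated on the axis rescaled to [0, 1], so they
    are directly interpretable as intensity offsets.  ``intensity_range``,
    when given, affinely rescales the finished matrix onto that range before
    the ``zero_columns`` are blanked — used to emulate data that needs
    min-max normalization downstream.
    """

    n_features: int
    axis_range: tuple
    shared_peaks: list
    class_peaks: dict
    baseline_coeffs: tuple = (0.05,)
    noise_sd: float = 0.01
    amplitude_jitter: float = 0.05
    class_prior: float = 0.5
    seed: int = 0
    intensity_range: tuple | None = None
    zero_columns: tuple = ()

    def __post_init__(self):
        if self.n_features < 8:
            raise ValueError("n_features must be at least 8")
        if self.noise_sd < 0 or self.amplitude_jitter < 0:
            raise ValueError("noise_sd and amplitude_jitter must be nonnegative")
        if not (0.0 < self.class_prior < 1.0):
            raise ValueError("class_prior must lie strictly between 0 and 1")
        lo, hi = self.axis_range
        if hi <= lo:
            raise ValueError("axis_range must be increasing")
        for c in (0, 1):
            self.class_peaks.setdefault(c, [])
        for p in list(self.shared_peaks) + self.class_peaks[0] + self.class_peaks[1]:
            if not (lo <= p.center <= hi):
                raise ValueError(f"peak center {p.center} outside axis range")

    @property
    def axis(self) -> np.ndarray:
        lo, hi = self.axis_range
        return np.linspace(lo, hi, self.n_features)


def generate_dataset(config: SimulationConfig, n: int) -> SpectrumSet:
    """Draw ``n`` labelled spectra from a :class:`SimulationConfig`.

    Labels match ``class_prior`` exactly (rounded half-up toward the positive
    class) and are shuffled, all deterministically under ``config.seed``.
    The rows are flagged ``real`` because simulated data stands in for the
    principal (measured) data downstream.
    """
    if n < 2:
        raise ValueError("need n >= 2 so both classes are represented")
    if not config.class_peaks[0] and not config.class_peaks[1]:
        raise ValueError("degenerate config: no class-distinguishing peaks")
    n_pos = round_half_up(n * config.class_prior)
    n_pos = min(max(n_pos, 1), n - 1)  # both classes get >= 1 sample
    rng = np.random.default_rng(config.seed)

    axis = config.axis
    t = (axis - axis[0]) / (axis[-1] - axis[0])
    baseline = np.polyval(config.baseline_coeffs, t)

    labels = np.concatenate([np.ones(n_pos, dtype=int), np.zeros(n - n_pos, dtype=int)])
    rng.shuffle(labels)

    matrix = np.empty((n, config.n_features))
    for i, lab in enumerate(labels):
        y = baseline.copy()
        for p in list(config.shared_peaks) + config.class_peaks[int(lab)]:
            amp = p.amplitude * (1.0 + rng.normal(0.0, config.amplitude_jitter))
            y = y + amp * p.profile(axis)
        if config.noise_sd > 0:
            y = y + rng.normal(0.0, config.noise_sd, size=config.n_features)
        matrix[i] = y

    if config.intensity_range is not None:
        lo, hi = config.intensity_range
        mmin, mmax = matrix.min(), matrix.max()
        if mmax > mmin:
            matrix = lo + (matrix - mmin) * (hi - lo) / (mmax - mmin)
    if config.zero_columns:
        matrix[:, list(config.zero_columns)] = 0.0

    return SpectrumSet(
        matrix=matrix,
        labels=labels,
        wavenumbers=axis,
        provenance=np.full(n, "real", dtype=object),
        name="simulated",
    )


def make_chlorinated_like(seed: int = 0) -> SimulationConfig:
    """Profile emulating the chlorinated-solvent dataset.

    2473 features over 350-3500 cm^-1, 67% positive prior, and the
    class-distinguishing C-Cl stretch/deformation bands placed in the
    350-1168 cm^-1 fingerprint region.  Amplitudes are chosen so raw
    intensities already sit inside [0, 1], mirroring data delivered
    pre-normalized.
    """
    shared = [
        PeakSpec(1450.0, 40.0, 0.30),
        PeakSpec(2950.0, 55.0, 0.45),
        PeakSpec(2100.0, 90.0, 0.12),
    ]
    class_peaks = {
        # positive = chlorinated: strong bands in the chlorinated region
        1: [
            PeakSpec(680.0, 18.0, 0.40),
            PeakSpec(760.0, 15.0, 0.30),
            PeakSpec(1050.0, 25.0, 0.22, shape="lorentzian"),
        ],
        # negative = nonchlorinated
        0: [
            PeakSpec(880.0, 20.0, 0.28),
            PeakSpec(1110.0, 22.0, 0.20),
        ],
    }
    return SimulationConfig(
        n_features=2473,
        axis_range=(350.0, 3500.0),
        shared_peaks=shared,
        class_peaks=class_peaks,
        baseline_coeffs=(0.05, -0.02, 0.08),
        noise_sd=0.008,
        amplitude_jitter=0.05,
        class_prior=0.67,
        seed=seed,
    )


def make_sars_like(seed: int = 0, n_features: int = 900) -> SimulationConfig:
    """Profile emulating the SARS-CoV-2 serum dataset.

    900 features (the true dimensionality is configurable) over
    600-1800 cm^-1, 51% positive prior, raw intensities spanning
    (-0.1, 0.4) and 8 dead (all-zero) feature columns, so the dead-column
    removal and min-max normalization stages are genuinely exercised.
    """
    shared = [
        PeakSpec(1004.0, 12.0, 0.30),   # phenylalanine ring breathing
        PeakSpec(1450.0, 25.0, 0.25),   # CH2 deformation
        PeakSpec(1655.0, 30.0, 0.35),   # amide I
    ]
    class_peaks = {
        1: [
            PeakSpec(830.0, 15.0, 0.22),
            PeakSpec(1240.0, 22.0, 0.18, shape="lorentzian"),
        ],
        0: [
            PeakSpec(940.0, 16.0, 0.20),
            PeakSpec(1340.0, 20.0, 0.16),
        ],
    }
    # 8 dead columns near the axis edges, clear of every band support
    zero_cols = tuple(int(i) for i in (0, 1, 2, 3, n_features - 4, n_features - 3,
                                       n_features - 2, n_features - 1))
    return SimulationConfig(
        n_features=n_features,
        axis_range=(600.0, 1800.0),
        shared_peaks=shared,
        class_peaks=class_peaks,
        baseline_coeffs=(-0.06, 0.02, 0.02),
        noise_sd=0.01,
        amplitude_jitter=0.05,
        class_prior=0.51,
        seed=seed,
        intensity_range=(-0.1, 0.4),
        zero_columns=zero_cols,
    )
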