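"""Variational Autoencoder synthesizer for [0,1]-normalized spectra.

Encoder and decoder are two-hidden-layer (500, 500) ELU networks; the
latent heads (mu-hat and gamma-hat, gamma = log sigma) are linear with 50
units.  Latent samples use the reparameterization z = mu + eps * exp(gamma)
with eps ~ N(0, 1).  The cost is summed binary cross-entropy reconstruction
(sigmoid decoder output, hence intensities must be min-max normalized)
plus the closed-form KL divergence of N(mu, sigma^2) from N(0, 1):

    KL = -1/2 * sum_d (1 + 2*gamma_d - mu_d^2 - exp(2*gamma_d))

Training uses Adam (lr 0.001, default betas).  Synthetic spectra are
generated by encoding a randomly chosen real training spectrum, drawing a
fresh eps, and decoding; the label is inherited from the source spectrum,
so one model serves both classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from . import nn
from .dataset import SpectrumSet

__all__ = [
    "VAEConfig",
    "SpectrumVAE",
    "reparameterize",
    "vae_loss",
    "train_vae",
    "generate_vae",
]


@dataclass(frozen=True)
class VAEConfig:
    hidden_sizes: tuple = (500, 500)
    latent_dim: int = 50
    epochs: int = 10000
    learning_rate: float = 0.001
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self):
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


def reparameterize(mu, gamma, eps):
    """z = mu + eps * exp(gamma), elementwise; eps = 0 returns mu exactly."""
    mu = np.asarray(mu, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    eps = np.asarray(eps, dtype=float)
    return mu + eps * np.exp(gamma)


def vae_loss(x, x_hat, mu, gamma):
    """Return (reconstruction, kl, total) for one sample or a batch.

    Reconstruction is binary cross-entropy summed over features; KL is the
    closed form above.  For 2-D inputs both terms are averaged over rows.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    x_hat = np.atleast_2d(np.asarray(x_hat, dtype=float))
    mu = np.atleast_2d(np.asarray(mu, dtype=float))
    gamma = np.atleast_2d(np.asarray(gamma, dtype=float))
    if x.min() < 0.0 or x.max() > 1.0:
        raise ValueError("targets must lie in [0, 1]; normalize first")
    eps = np.finfo(float).tiny
    xh = np.clip(x_hat, eps, 1.0 - 1e-15)
    recon = float(np.mean(np.sum(-(x * np.log(xh) + (1 - x) * np.log1p(-xh)), axis=1)))
    kl = float(np.mean(
        -0.5 * np.sum(1.0 + 2.0 * gamma - mu**2 - np.exp(2.0 * gamma), axis=1)
    ))
    return recon, kl, recon + kl


class SpectrumVAE(BaseEstimator):
    """VAE over normalized spectra, sklearn-style.

    Parameters mirror the training schedule: two 500-unit ELU hidden layers
    in encoder and decoder, a 50-dimensional latent space, Adam at lr 0.001.
    The headline schedule trains for 10,000 epochs; tests and demos pass a
    smaller ``epochs``.

    Fitted attributes: ``history_`` (per-epoch mean total loss per sample),
    ``X_``, ``y_`` (training data, used as generation sources),
    ``input_dim_``.
    """

    def __init__(self, hidden_sizes=(500, 500), latent_dim: int = 50,
                 epochs: int = 10000, learning_rate: float = 0.001,
                 batch_size: int = 32, seed: int = 0):
        self.hidden_sizes = hidden_sizes
        self.latent_dim = latent_dim
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.seed = seed

    # -- construction -----------------------------------------------------
    def _build(self, input_dim: int, rng: np.random.Generator):
        h1, h2 = self.hidden_sizes
        self._trunk = nn.Sequential([
            nn.Dense(input_dim, h1, rng), nn.ELU(),
            nn.Dense(h1, h2, rng), nn.ELU(),
        ])
        self._mu_head = nn.Dense(h2, self.latent_dim, rng)
        self._gamma_head = nn.Dense(h2, self.latent_dim, rng)
        self._decoder = nn.Sequential([
            nn.Dense(self.latent_dim, h2, rng), nn.ELU(),
            nn.Dense(h2, h1, rng), nn.ELU(),
            nn.Dense(h1, input_dim, rng),   # logits; sigmoid applied on decode
        ])
        self.input_dim_ = input_dim

    def _all_params(self):
        return (self._trunk.params() + self._mu_head.params()
                + self._gamma_head.params() + self._decoder.params())

    def _all_grads(self):
        return (self._trunk.grads() + self._mu_head.grads()
                + self._gamma_head.grads() + self._decoder.grads())

    # -- core passes -------------------------------------------------------
    def encode(self, X):
        """Latent parameters (mu, gamma) for a batch; deterministic."""
        X = self._check_X(X)
        h = self._trunk.forward(X, train=False)
        return self._mu_head.forward(h), self._gamma_head.forward(h)

    def decode(self, Z):
        """Decoder probabilities in (0, 1) for latent vectors."""
        logits = self._decoder.forward(np.atleast_2d(np.asarray(Z, float)),
                                       train=False)
        return nn.sigmoid(logits)

    def _check_X(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.input_dim_:
            raise ValueError(
                f"expected {self.input_dim_} features, got {X.shape[1]}"
            )
        return X

    # -- training ----------------------------------------------------------
    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("X must be 2-D with at least 2 samples")
        if X.min() < 0.0 or X.max() > 1.0:
            raise ValueError("inputs must lie in [0, 1]; normalize first")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        rng = np.random.default_rng(self.seed)
        self._build(X.shape[1], rng)
        self.X_ = X
        self.y_ = None if y is None else np.asarray(y, dtype=int)

        opt = nn.Adam(self._all_params(), lr=self.learning_rate)
        n = X.shape[0]
        bs = min(self.batch_size, n)
        self.history_ = []
        for epoch in range(self.epochs):
            perm = rng.permutation(n)
            total = 0.0
            for start in range(0, n, bs):
                xb = X[perm[start:start + bs]]
                b = xb.shape[0]
                h = self._trunk.forward(xb, train=True, rng=rng)
                mu = self._mu_head.forward(h)
                gamma = self._gamma_head.forward(h)
                eps = rng.standard_normal(mu.shape)
                z = mu + eps * np.exp(gamma)
                logits = self._decoder.forward(z, train=True, rng=rng)

                recon = np.sum(nn.bce_with_logits(logits, xb))
                kl = -0.5 * np.sum(1.0 + 2.0 * gamma - mu**2 - np.exp(2.0 * gamma))
                loss = (recon + kl) / b
                if not np.isfinite(loss):
                    raise RuntimeError(f"VAE training diverged at epoch {epoch}")
                total += loss * b

                dlogits = (nn.sigmoid(logits) - xb) / b
                dz = self._decoder.backward(dlogits)
                dmu = dz + mu / b
                dgamma = dz * eps * np.exp(gamma) + (np.exp(2.0 * gamma) - 1.0) / b
                dh = self._mu_head.backward(dmu) + self._gamma_head.backward(dgamma)
                self._trunk.backward(dh)
                opt.step(self._all_grads())
            self.history_.append(total / n)
        return self

    # -- generation ----------------------------------------------------------
    def sample(self, n_per_class: dict, seed: int = 0):
        """Generate synthetic spectra per class; returns (X_synth, y_synth).

        Source spectra are drawn with replacement (seeded) from the stored
        training set of the requested class, encoded, perturbed with fresh
        eps, and decoded; the label is inherited.
        """
        if self.y_ is None:
            raise ValueError("fit was called without labels; cannot sample per class")
        rng = np.random.default_rng(seed)
        xs, ys = [], []
        for c in sorted(int(k) for k in n_per_class):
            n = int(n_per_class[c])
            if n == 0:
                continue
            pool = np.where(self.y_ == c)[0]
            if pool.size == 0:
                raise ValueError(f"class {c} absent from the training data")
            src = rng.choice(pool, size=n, replace=True)
            mu, gamma = self.encode(self.X_[src])
            eps = rng.standard_normal(mu.shape)
            xs.append(self.decode(reparameterize(mu, gamma, eps)))
            ys.append(np.full(n, c, dtype=int))
        if not xs:
            return (np.empty((0, self.input_dim_)), np.empty(0, dtype=int))
        return np.vstack(xs), np.concatenate(ys)


def train_vae(train: SpectrumSet, config: VAEConfig = VAEConfig()) -> SpectrumVAE:
    """Fit a :class:`SpectrumVAE` on a normalized :class:`SpectrumSet`."""
    model = SpectrumVAE(
        hidden_sizes=tuple(config.hidden_sizes),
        latent_dim=config.latent_dim,
        epochs=config.epochs,
        learning_rate=config.learning_rate,
        batch_size=config.batch_size,
        seed=config.seed,
    )
    model.fit(train.matrix, train.labels)
    model.wavenumbers_ = train.wavenumbers
    return model


def generate_vae(model: SpectrumVAE, n_per_class: dict, seed: int = 0) -> SpectrumSet:
    """Wrap :meth:`SpectrumVAE.sample` into a provenance-tagged SpectrumSet."""
    X, y = model.sample(n_per_class, seed=seed)
    wn = getattr(model, "wavenumbers_", np.arange(model.input_dim_, dtype=float))
    return SpectrumSet(
        matrix=X,
        labels=y,
        wavenumbers=wn,
        provenance=np.full(X.shape[0], "vae", dtype=object),
        name="vae",
    )
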