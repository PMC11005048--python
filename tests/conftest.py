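import numpy as np
import pytest

import ramanblend as rb


@pytest.fixture(scope="session")
def sars_small():
    """Preprocessed SARS-like simulated dataset at reduced dimensionality."""
    cfg = rb.make_sars_like(seed=11, n_features=120)
    data = rb.generate_dataset(cfg, 60)
    data, removed, _ = rb.preprocess_set(data)
    return data


@pytest.fixture(scope="session")
def sars_fold(sars_small):
    """(train, holdout) pair from the first inverted fold of sars_small."""
    splits = rb.stratified_inverted_kfold(sars_small.labels, k=3, seed=0)
    s = splits[0]
    return sars_small.select(s.train_idx), sars_small.select(s.holdout_idx)


@pytest.fixture
def tiny_set():
    """3 x 5 hand-written SpectrumSet."""
    return rb.SpectrumSet(
        matrix=np.array([[0.1, 0.2, 0.3, 0.4, 0.5],
                         [0.5, 0.4, 0.3, 0.2, 0.1],
                         [0.0, 1.0, 0.0, 1.0, 0.0]]),
        labels=np.array([1, 0, 1]),
        wavenumbers=np.array([100.0, 200.0, 300.0, 400.0, 500.0]),
    )


def random_spectrum_set(rng, n, d, provenance="real"):
    return rb.SpectrumSet(
        matrix=rng.random((n, d)),
        labels=rng.integers(0, 2, size=n),
        wavenumbers=np.sort(rng.choice(np.arange(1.0, 100.0), size=d, replace=False)),
        provenance=np.full(n, provenance, dtype=object),
    )
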