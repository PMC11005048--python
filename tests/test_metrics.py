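"""Confusion metrics, mean spectra, discrete Fréchet distance, PCA scores."""

import itertools

import numpy as np
import pytest

import ramanblend as rb
from ramanblend.metrics import ConfusionCounts, sensitivity, specificity

from conftest import random_spectrum_set


def brute_frechet(p, q):
    """Oracle: exhaustive minimization over all monotone couplings."""
    p, q = np.atleast_2d(p.T).T, np.atleast_2d(q.T).T
    if p.ndim == 1:
        p = p[:, None]
    if q.ndim == 1:
        q = q[:, None]
    d = np.sqrt(((p[:, None, :] - q[None, :, :]) ** 2).sum(axis=2))
    n, m = d.shape
    best = [np.inf]

    def walk(i, j, cur):
        cur = max(cur, d[i, j])
        if cur >= best[0]:
            return
        if i == n - 1 and j == m - 1:
            best[0] = cur
            return
        if i + 1 < n:
            walk(i + 1, j, cur)
        if j + 1 < m:
            walk(i, j + 1, cur)
        if i + 1 < n and j + 1 < m:
            walk(i + 1, j + 1, cur)

    walk(0, 0, 0.0)
    return best[0]


class TestConfusion:
    def test_hand_tally(self):
        c = rb.confusion([1, 1, 0], [1, 0, 0])
        assert (c.tp, c.fn, c.tn, c.fp) == (1, 1, 1, 0)

    def test_perfect_prediction(self):
        c = rb.confusion([1, 0, 1], [1, 0, 1])
        assert c.fp == c.fn == 0

    def test_all_positive_prediction(self):
        c = rb.confusion([1, 1, 0, 0, 0], [1, 1, 1, 1, 1])
        assert (c.tp, c.fp) == (2, 3)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            rb.confusion([1, 0], [1])


class TestBalancedAccuracy:
    def test_direct_arithmetic(self):
        c = ConfusionCounts(tp=9, fn=1, tn=4, fp=1)
        assert sensitivity(c) == pytest.approx(0.9)
        assert specificity(c) == pytest.approx(0.8)
        assert rb.balanced_accuracy(c) == pytest.approx(0.85)

    def test_perfect(self):
        assert rb.balanced_accuracy(ConfusionCounts(5, 0, 3, 0)) == 1.0

    def test_constant_predictor_is_half(self):
        y = np.r_[np.ones(90, int), np.zeros(10, int)]
        c = rb.confusion(y, np.ones_like(y))
        assert rb.balanced_accuracy(c) == 0.5

    def test_absent_class_raises(self):
        with pytest.raises(ValueError, match="undefined|positive|negative"):
            rb.balanced_accuracy(rb.confusion([1, 1], [1, 0]))

    def test_permuted_predictions_average_half(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, size=60)
        pred = rng.integers(0, 2, size=60)
        vals = []
        for _ in range(1000):
            vals.append(rb.balanced_accuracy(rb.confusion(y, rng.permutation(pred))))
        assert np.mean(vals) == pytest.approx(0.5, abs=0.05)


class TestMeanSpectrum:
    def test_single_spectrum_is_itself(self, tiny_set):
        one = tiny_set.select([0])
        curve = rb.mean_spectrum(one)
        assert np.array_equal(curve[:, 1], one.matrix[0])
        assert np.array_equal(curve[:, 0], np.arange(5.0))

    def test_two_spectra_average(self):
        s = rb.SpectrumSet([[0.0, 0.0], [1.0, 1.0]], [0, 1], [1.0, 2.0])
        assert np.array_equal(rb.mean_spectrum(s, x_mode="none"), [0.5, 0.5])

    def test_blend_mean_symmetry(self):
        # with a symmetric weight set the pool mean equals the pairwise
        # parent midpoints averaged over pairs
        rng = np.random.default_rng(4)
        parents = rng.random((6, 6))
        labels = np.array([0, 0, 0, 1, 1, 1])
        train = rb.SpectrumSet(parents, labels, np.arange(6.0))
        pool = rb.generate_blended(train, rb.BlendConfig(weights=(0.25, 0.5, 0.75)))
        pair_mids = np.array([(parents[i] + parents[j]) / 2
                              for c in (0, 1)
                              for i, j in itertools.combinations(
                                  np.where(labels == c)[0], 2)])
        assert np.allclose(pool.matrix.mean(axis=0), pair_mids.mean(axis=0))

    def test_wavenumber_mode(self, tiny_set):
        curve = rb.mean_spectrum(tiny_set, x_mode="wavenumber")
        assert np.array_equal(curve[:, 0], tiny_set.wavenumbers)


class TestDiscreteFrechet:
    def test_identical_curves_zero(self):
        p = np.array([[0.0, 0.0], [1.0, 2.0], [2.0, 1.0]])
        assert rb.discrete_frechet(p, p) == 0.0

    def test_offset_horizontal_lines(self):
        p = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        q = p + [0.0, 1.0]
        assert rb.discrete_frechet(p, q) == pytest.approx(1.0)

    def test_unequal_length_example(self):
        p = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        q = np.array([[0.0, 0.0], [2.0, 2.0]])
        assert rb.discrete_frechet(p, q) == pytest.approx(np.sqrt(2.0))
        assert brute_frechet(p, q) == pytest.approx(np.sqrt(2.0))

    def test_matches_brute_force_on_random_pairs(self):
        rng = np.random.default_rng(12)
        for _ in range(200):
            p = rng.random((rng.integers(1, 8), 2))
            q = rng.random((rng.integers(1, 8), 2))
            assert rb.discrete_frechet(p, q) == pytest.approx(brute_frechet(p, q))

    def test_symmetry_and_endpoint_lower_bound(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            p = rng.random((rng.integers(2, 7), 2))
            q = rng.random((rng.integers(2, 7), 2))
            d = rb.discrete_frechet(p, q)
            assert d == pytest.approx(rb.discrete_frechet(q, p))
            assert d >= max(np.linalg.norm(p[0] - q[0]),
                            np.linalg.norm(p[-1] - q[-1])) - 1e-12

    def test_one_dimensional_curves(self):
        assert rb.discrete_frechet([0.0, 0.5], [0.25, 0.5]) == pytest.approx(0.25)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rb.discrete_frechet(np.empty((0, 2)), np.ones((2, 2)))


class TestPCAScores:
    def test_variance_ordering(self):
        rng = np.random.default_rng(3)
        scores = rb.pca_scores(rng.normal(size=(30, 8)))
        assert scores[:, 0].var() >= scores[:, 1].var()

    def test_rank_one_data(self):
        t = np.linspace(0, 1, 20)
        x = np.column_stack([t, 2 * t])
        scores = rb.pca_scores(x)
        assert np.abs(scores[:, 1]).max() < 1e-10

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(9)
        x = rng.random((5, 4))
        xc = x - x.mean(axis=0)
        evals, evecs = np.linalg.eigh(xc.T @ xc / (len(x) - 1))
        order = np.argsort(evals)[::-1][:2]
        ref = xc @ evecs[:, order]
        got = rb.pca_scores(x)
        for k in range(2):
            # sign is a convention; compare up to it
            same = np.allclose(got[:, k], ref[:, k], atol=1e-9)
            flipped = np.allclose(got[:, k], -ref[:, k], atol=1e-9)
            assert same or flipped

    def test_too_few_rows(self):
        with pytest.raises(ValueError):
            rb.pca_scores(np.ones((1, 3)))
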