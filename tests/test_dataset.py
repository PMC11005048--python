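"""Core SpectrumSet container, CSV round-trips, concatenation, sampling."""

import numpy as np
import pytest

import ramanblend as rb
from ramanblend.dataset import FormatError, round_half_up

from conftest import random_spectrum_set


def quantize(spectra):
    """Quantize a set to the 9-significant-digit on-disk precision."""
    q = np.vectorize(lambda v: float(format(v, ".9g")))(spectra.matrix)
    return rb.SpectrumSet(q, spectra.labels, spectra.wavenumbers,
                          spectra.provenance, spectra.name)


class TestCSV:
    def test_read_simple(self, tiny_set, tmp_path):
        path = tmp_path / "t.csv"
        rb.write_spectra_csv(tiny_set, path)
        got = rb.read_spectra_csv(path)
        assert got.matrix.shape == (3, 5)
        assert np.array_equal(got.labels, tiny_set.labels)
        assert list(got.provenance) == ["real"] * 3

    def test_round_trip_random_sets(self, tmp_path):
        rng = np.random.default_rng(42)
        for i in range(100):
            s = quantize(random_spectrum_set(rng, rng.integers(1, 6),
                                             rng.integers(2, 8)))
            path = tmp_path / f"r{i}.csv"
            rb.write_spectra_csv(s, path)
            assert rb.read_spectra_csv(path) == s

    def test_provenance_column_optional(self, tmp_path):
        path = tmp_path / "noprov.csv"
        path.write_text("100,200,label\n0.1,0.2,1\n")
        got = rb.read_spectra_csv(path)
        assert list(got.provenance) == ["real"]

    def test_non_numeric_cell_cites_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("100,200,label\n0.1,0.2,1\n0.3,oops,0\n")
        with pytest.raises(FormatError, match="row 1"):
            rb.read_spectra_csv(path)

    def test_non_binary_label_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("100,200,label\n0.1,0.2,2\n")
        with pytest.raises(FormatError, match="non-binary"):
            rb.read_spectra_csv(path)

    def test_malformed_header_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("abc,200,label\n0.1,0.2,1\n")
        with pytest.raises(FormatError, match="header"):
            rb.read_spectra_csv(path)

    def test_write_empty_refused(self, tiny_set, tmp_path):
        empty = tiny_set.select([])
        with pytest.raises(ValueError):
            rb.write_spectra_csv(empty, tmp_path / "e.csv")
        assert not (tmp_path / "e.csv").exists()

    def test_fold_scale_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        s = quantize(random_spectrum_set(rng, 103, 90))
        path = tmp_path / "fold.csv"
        rb.write_spectra_csv(s, path)
        got = rb.read_spectra_csv(path)
        assert got.matrix.shape == (103, 90)
        assert got == s


class TestConcat:
    def test_row_counts_add(self, tiny_set):
        out = rb.concat_sets(tiny_set, tiny_set.select([0, 1]))
        assert out.n_samples == 5

    def test_empty_identity(self, tiny_set):
        out = rb.concat_sets(tiny_set, tiny_set.select([]))
        assert out == tiny_set

    def test_axis_mismatch_rejected(self, tiny_set):
        other = rb.SpectrumSet(tiny_set.matrix, tiny_set.labels,
                               tiny_set.wavenumbers + 1.0)
        with pytest.raises(ValueError, match="axes"):
            rb.concat_sets(tiny_set, other)

    def test_associative(self):
        rng = np.random.default_rng(7)
        wn = np.arange(4.0)
        parts = [rb.SpectrumSet(rng.random((n, 4)), rng.integers(0, 2, n), wn)
                 for n in (2, 3, 4)]
        a = rb.concat_sets(rb.concat_sets(parts[0], parts[1]), parts[2])
        b = rb.concat_sets(parts[0], rb.concat_sets(parts[1], parts[2]))
        assert a == b

    def test_provenance_preserved(self, tiny_set):
        rng = np.random.default_rng(1)
        synth = random_spectrum_set(rng, 4, 5, provenance="blend")
        synth.wavenumbers = tiny_set.wavenumbers
        out = rb.concat_sets(tiny_set, synth)
        assert out.provenance_counts() == {"real": 3, "blend": 4}


class TestSampleRows:
    @pytest.fixture
    def pool_67_33(self):
        rng = np.random.default_rng(3)
        labels = np.r_[np.ones(670, int), np.zeros(330, int)]
        return rb.SpectrumSet(rng.random((1000, 6)), labels, np.arange(6.0))

    def test_zero_gives_empty(self, pool_67_33):
        assert rb.sample_rows(pool_67_33, 0, seed=0).n_samples == 0

    def test_seed_reproducible(self, pool_67_33):
        a = rb.sample_rows(pool_67_33, 50, seed=5)
        b = rb.sample_rows(pool_67_33, 50, seed=5)
        assert a == b

    def test_prior_preserving_counts(self, pool_67_33):
        out = rb.sample_rows(pool_67_33, 400, per_class="prior", seed=0)
        assert out.class_counts() == {1: 268, 0: 132}

    def test_without_replacement(self, pool_67_33):
        out = rb.sample_rows(pool_67_33, 600, seed=2)
        assert len(np.unique(out.matrix, axis=0)) == 600

    def test_explicit_per_class(self, pool_67_33):
        out = rb.sample_rows(pool_67_33, 30, per_class={1: 10, 0: 20}, seed=0)
        assert out.class_counts() == {1: 10, 0: 20}

    def test_capacity_error_names_class(self, pool_67_33):
        with pytest.raises(ValueError, match="class 0"):
            rb.sample_rows(pool_67_33, 900, per_class={1: 500, 0: 400}, seed=0)


def test_round_half_up():
    assert round_half_up(268.0) == 268
    assert round_half_up(2.5) == 3
    assert round_half_up(154.1) == 154
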