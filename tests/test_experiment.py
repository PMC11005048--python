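"""Study orchestration: pools, leakage guard, aggregation, dFid reports."""

import numpy as np
import pytest

import ramanblend as rb
from ramanblend.classifiers import TrainConfig
from ramanblend.experiment import (ExperimentConfig, LeakageError, SynthPool,
                                   build_blend_pools, build_vae_pools,
                                   dfid_report, fingerprint, format_mean_std,
                                   load_folds, run_augmentation_sweep,
                                   run_baseline)


@pytest.fixture(scope="module")
def fold_dir(tmp_path_factory):
    cfg = rb.make_sars_like(seed=41, n_features=100)
    data = rb.generate_dataset(cfg, 60)
    data, _, _ = rb.preprocess_set(data)
    splits = rb.stratified_inverted_kfold(data.labels, k=3, seed=2)
    out = tmp_path_factory.mktemp("folds")
    rb.persist_folds(splits, data, out, dataset_name="toy", seed=2)
    return out


@pytest.fixture(scope="module")
def folds(fold_dir):
    return load_folds(fold_dir, "toy")[0]


@pytest.fixture(scope="module")
def blend_pools(folds):
    return build_blend_pools(folds, rb.BlendConfig())


class TestFingerprint:
    def test_stable(self, folds):
        train, _ = folds[0]
        assert fingerprint(train) == fingerprint(train)

    def test_sensitive_to_intensity_change(self, folds):
        train, _ = folds[0]
        bumped = rb.SpectrumSet(train.matrix + 1e-6, train.labels,
                                train.wavenumbers)
        assert fingerprint(bumped) != fingerprint(train)

    def test_sensitive_to_label_change(self, folds):
        train, _ = folds[0]
        flipped = rb.SpectrumSet(train.matrix, 1 - train.labels,
                                 train.wavenumbers)
        assert fingerprint(flipped) != fingerprint(train)


class TestPools:
    def test_one_blend_pool_per_fold(self, folds, blend_pools):
        assert [p.fold_index for p in blend_pools] == [1, 2, 3]
        for (train, _), pool in zip(folds, blend_pools):
            assert pool.source_fingerprint == fingerprint(train)
            counts = train.class_counts()
            expected = rb.count_unique(counts, 9)
            assert pool.data.n_samples == expected

    def test_vae_pools_sized_and_traced(self, folds):
        pools = build_vae_pools(folds[:1], rb.VAEConfig(epochs=2, seed=0),
                                pool_per_class=12)
        assert pools[0].data.n_samples == 24
        assert pools[0].source_fingerprint == fingerprint(folds[0][0])
        assert set(pools[0].data.provenance) == {"vae"}


class TestConfig:
    def test_unsorted_steps_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            ExperimentConfig(steps=(800, 400))

    def test_duplicate_seeds_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            ExperimentConfig(seeds=(1, 1))

    def test_unknown_synthesis_rejected(self):
        with pytest.raises(ValueError, match="synthesis"):
            ExperimentConfig(synthesis="gan")


class TestBaseline:
    def test_aggregation_shape_and_counts(self, fold_dir):
        cfg = ExperimentConfig(seeds=(0, 1), model="fcnn",
                               train=TrainConfig(epochs=2))
        table = run_baseline(fold_dir, cfg, "toy")
        assert len(table) == 1
        row = table.iloc[0]
        assert row["model"] == "fcnn" and row["synthesis"] == "none"
        assert row["step"] == 0
        assert row["n_runs"] == 6          # 3 folds x 2 seeds
        assert 0.0 <= row["mean"] <= 1.0 and row["std"] >= 0.0

    def test_single_run_has_zero_std(self, fold_dir):
        cfg = ExperimentConfig(seeds=(0,), k_folds=3, model="fcnn",
                               train=TrainConfig(epochs=1))
        table = run_baseline(fold_dir, cfg, "toy")
        # three folds, one seed: std over three runs, rarely zero -- but a
        # deterministic repeat of the whole call must agree exactly
        again = run_baseline(fold_dir, cfg, "toy")
        assert table.equals(again)

    def test_baseline_learns_separable_data(self, fold_dir):
        cfg = ExperimentConfig(seeds=(0,), model="fcnn",
                               train=TrainConfig(epochs=15))
        table = run_baseline(fold_dir, cfg, "toy")
        assert table.iloc[0]["mean"] >= 0.9


class TestSweep:
    def test_sweep_shape_and_determinism(self, fold_dir, blend_pools):
        cfg = ExperimentConfig(steps=(6, 12), seeds=(0,), synthesis="blend",
                               model="fcnn", train=TrainConfig(epochs=2))
        table = run_augmentation_sweep(fold_dir, blend_pools, cfg, "toy")
        assert list(table["step"]) == [6, 12]
        assert (table["n_runs"] == 3).all()
        again = run_augmentation_sweep(fold_dir, blend_pools, cfg, "toy")
        assert table.equals(again)

    def test_pool_count_mismatch(self, fold_dir, blend_pools):
        cfg = ExperimentConfig(steps=(6,), seeds=(0,), synthesis="blend",
                               model="fcnn", train=TrainConfig(epochs=1))
        with pytest.raises(ValueError, match="per fold"):
            run_augmentation_sweep(fold_dir, blend_pools[:2], cfg, "toy")

    def test_leakage_guard_trips_on_swapped_pools(self, fold_dir, blend_pools):
        cfg = ExperimentConfig(steps=(6,), seeds=(0,), synthesis="blend",
                               model="fcnn", train=TrainConfig(epochs=1))
        swapped = [
            SynthPool(blend_pools[1].data, 1, blend_pools[1].source_fingerprint),
            SynthPool(blend_pools[0].data, 2, blend_pools[0].source_fingerprint),
            blend_pools[2],
        ]
        with pytest.raises(LeakageError, match="fold 1"):
            run_augmentation_sweep(fold_dir, swapped, cfg, "toy")

    def test_leakage_guard_trips_on_tampered_data(self, fold_dir, blend_pools):
        cfg = ExperimentConfig(steps=(6,), seeds=(0,), synthesis="blend",
                               model="fcnn", train=TrainConfig(epochs=1))
        tampered = list(blend_pools)
        tampered[0] = SynthPool(tampered[0].data, 1, "0" * 64)
        with pytest.raises(LeakageError):
            run_augmentation_sweep(fold_dir, tampered, cfg, "toy")


class TestDfidReport:
    def test_blend_report_deterministic_with_average_row(self, fold_dir):
        a = dfid_report(fold_dir, "blend", dataset_name="toy")
        b = dfid_report(fold_dir, "blend", dataset_name="toy")
        assert a.equals(b)
        assert list(a["fold"]) == ["1", "2", "3", "average"]
        folds_only = a["dfid"][:3]
        assert a["dfid"].iloc[3] == pytest.approx(folds_only.mean())
        assert (a["dfid"] >= 0.0).all()

    def test_unknown_synthesis(self, fold_dir):
        with pytest.raises(ValueError, match="blend|vae"):
            dfid_report(fold_dir, "gan", dataset_name="toy")


class TestFormatting:
    def test_format_mean_std(self):
        assert format_mean_std(0.8504, 0.0151) == "0.850 ± 0.015"
        assert format_mean_std(1.0, 0.0) == "1.000 ± 0.000"
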