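"""Study orchestration: baselines, stepwise augmentation sweeps, dFid reports.

The protocol: per dataset, folds are split once and persisted; per fold a
synthetic pool (blend or VAE) is generated from that fold's training data
only; then for each augmentation step s, fold f, and seed, a fresh model is
trained on (train fold + s sampled synthetic spectra) and evaluated on the
fold's holdout.  Cells of the result table aggregate mean and standard
deviation of balanced accuracy over seeds x folds (15 runs with the default
5 seeds and 3 folds).  Training-set accuracy is also recorded, computed in
evaluation mode (dropout off).

A leakage guard fingerprints each pool's source training fold; a pool whose
fingerprint does not match the fold it is used with aborts the sweep.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .blend import BlendConfig, generate_blended
from .classifiers import TrainConfig, build_classifier, predict
from .dataset import SpectrumSet, concat_sets, read_spectra_csv, sample_rows, _fmt
from .folds import load_fold_manifest
from .metrics import balanced_accuracy, confusion, discrete_frechet, mean_spectrum, pca_scores
from .vae import VAEConfig, generate_vae, train_vae

logger = logging.getLogger(__name__)

__all__ = [
    "ExperimentConfig",
    "SynthPool",
    "LeakageError",
    "fingerprint",
    "load_folds",
    "build_blend_pools",
    "build_vae_pools",
    "run_baseline",
    "run_augmentation_sweep",
    "dfid_report",
    "render_report",
    "pca_overlay",
    "format_mean_std",
]


class LeakageError(RuntimeError):
    """A synthetic pool does not trace back to the fold it is used with."""


@dataclass(frozen=True)
class ExperimentConfig:
    steps: tuple = (400, 800, 1200, 1600, 2000)
    seeds: tuple = (0, 1, 2, 3, 4)
    k_folds: int = 3
    synthesis: str = "none"
    augment_policy: str = "prior"     # or "balanced"
    model: str = "cnn"
    train: TrainConfig = field(default_factory=TrainConfig)

    def __post_init__(self):
        if list(self.steps) != sorted(set(self.steps)):
            raise ValueError("steps must be strictly increasing")
        if len(set(self.seeds)) != len(self.seeds):
            raise ValueError("seeds must be distinct")
        if self.synthesis not in ("none", "blend", "vae"):
            raise ValueError("synthesis must be none, blend, or vae")


@dataclass
class SynthPool:
    data: SpectrumSet
    fold_index: int
    source_fingerprint: str


def fingerprint(spectra: SpectrumSet) -> str:
    """Stable content hash of a SpectrumSet at CSV (9 sig. digit) precision."""
    h = hashlib.sha256()
    for i in range(spectra.n_samples):
        h.update(",".join(_fmt(v) for v in spectra.matrix[i]).encode())
        h.update(f"|{int(spectra.labels[i])}\n".encode())
    return h.hexdigest()


def load_folds(data_dir, dataset_name: str = "data"):
    """Load persisted (train, holdout) SpectrumSet pairs from a fold directory."""
    data_dir = Path(data_dir)
    manifest = load_fold_manifest(data_dir, dataset_name)
    folds = []
    for entry in manifest["folds"]:
        train = read_spectra_csv(data_dir / entry["train_file"])
        holdout = read_spectra_csv(data_dir / entry["holdout_file"])
        folds.append((train, holdout))
    return folds, manifest


def build_blend_pools(folds, blend_config: BlendConfig = BlendConfig()):
    """One deterministic blend pool per fold, generated from its train data."""
    pools = []
    for f, (train, _) in enumerate(folds, start=1):
        pool = generate_blended(train, blend_config)
        pools.append(SynthPool(pool, f, fingerprint(train)))
    return pools


def build_vae_pools(folds, vae_config: VAEConfig = VAEConfig(),
                    pool_per_class: int = 1200):
    """One VAE pool per fold: train a fold-local VAE, pregenerate the pool.

    A single pool per fold serves every augmentation step, so step size is
    isolated from generator stochasticity.
    """
    pools = []
    for f, (train, _) in enumerate(folds, start=1):
        model = train_vae(train, vae_config)
        pool = generate_vae(model, {0: pool_per_class, 1: pool_per_class},
                            seed=vae_config.seed + f)
        pools.append(SynthPool(pool, f, fingerprint(train)))
    return pools


def _evaluate(model, spectra: SpectrumSet) -> float:
    labels, _ = predict(model, spectra)
    return balanced_accuracy(confusion(spectra.labels, labels))


def _run_cell(train: SpectrumSet, holdout: SpectrumSet, arch: str, seed: int,
              train_config: TrainConfig):
    model = build_classifier(arch, seed=seed, config=train_config)
    model.fit(train.matrix, train.labels)
    return _evaluate(model, holdout), _evaluate(model, train)


def _aggregate(rows) -> pd.DataFrame:
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["model", "synthesis", "step"], as_index=False)
        .agg(mean=("test_ba", "mean"), std=("test_ba", lambda s: float(np.std(s))),
             train_mean=("train_ba", "mean"),
             train_std=("train_ba", lambda s: float(np.std(s))),
             n_runs=("test_ba", "size"))
    )
    return out


def run_baseline(data_dir, config: ExperimentConfig, dataset_name: str = "data") -> pd.DataFrame:
    """Train on the raw training folds only (no synthetic data)."""
    folds, _ = load_folds(data_dir, dataset_name)
    rows = []
    for f, (train, holdout) in enumerate(folds, start=1):
        for seed in config.seeds:
            test_ba, train_ba = _run_cell(train, holdout, config.model, seed,
                                          config.train)
            logger.info("baseline model=%s fold=%d seed=%d test=%.3f train=%.3f",
                        config.model, f, seed, test_ba, train_ba)
            rows.append(dict(model=config.model, synthesis="none", step=0,
                             fold=f, seed=seed, test_ba=test_ba, train_ba=train_ba))
    return _aggregate(rows)


def run_augmentation_sweep(data_dir, pools, config: ExperimentConfig,
                           dataset_name: str = "data") -> pd.DataFrame:
    """Stepwise augmentation: train on fold train + sampled synthetic rows."""
    folds, _ = load_folds(data_dir, dataset_name)
    if len(pools) != len(folds):
        raise ValueError("need exactly one synthetic pool per fold")
    for f, ((train, _), pool) in enumerate(zip(folds, pools), start=1):
        if pool.fold_index != f or pool.source_fingerprint != fingerprint(train):
            raise LeakageError(
                f"pool for fold {f} does not trace to that fold's training data"
            )
    policy = "prior" if config.augment_policy == "prior" else "balanced"
    rows = []
    for f, ((train, holdout), pool) in enumerate(zip(folds, pools), start=1):
        for step in config.steps:
            for seed in config.seeds:
                synth = sample_rows(pool.data, step, per_class=policy, seed=seed)
                augmented = concat_sets(train, synth)
                test_ba, train_ba = _run_cell(augmented, holdout, config.model,
                                              seed, config.train)
                logger.info(
                    "sweep model=%s synth=%s fold=%d step=%d seed=%d test=%.3f",
                    config.model, config.synthesis, f, step, seed, test_ba)
                rows.append(dict(model=config.model, synthesis=config.synthesis,
                                 step=step, fold=f, seed=seed,
                                 test_ba=test_ba, train_ba=train_ba))
    return _aggregate(rows)


def dfid_report(data_dir, synthesis: str, reps: int = 5,
                dataset_name: str = "data",
                blend_config: BlendConfig = BlendConfig(),
                vae_config: VAEConfig = VAEConfig(),
                synth_per_class: int | None = None,
                x_mode: str = "index", seed: int = 0) -> pd.DataFrame:
    """Per-fold discrete Fréchet distance between real and synthetic means.

    Blending is deterministic, so one generation per fold suffices; the VAE
    is stochastic, so ``reps`` fresh generations are averaged per fold.
    The final row is the average over folds.
    """
    folds, _ = load_folds(data_dir, dataset_name)
    records = []
    for f, (train, _) in enumerate(folds, start=1):
        real_mean = mean_spectrum(train, x_mode=x_mode)
        if synthesis == "blend":
            pool = generate_blended(train, blend_config)
            val = discrete_frechet(real_mean, mean_spectrum(pool, x_mode=x_mode))
        elif synthesis == "vae":
            model = train_vae(train, vae_config)
            n = synth_per_class or 3 * train.n_samples // 2
            vals = []
            for r in range(reps):
                synth = generate_vae(model, {0: n, 1: n}, seed=seed + 1000 * f + r)
                vals.append(discrete_frechet(real_mean,
                                             mean_spectrum(synth, x_mode=x_mode)))
            val = float(np.mean(vals))
        else:
            raise ValueError("synthesis must be 'blend' or 'vae'")
        records.append({"fold": str(f), "dfid": val})
    records.append({"fold": "average",
                    "dfid": float(np.mean([r["dfid"] for r in records]))})
    return pd.DataFrame(records)


def format_mean_std(mean: float, std: float) -> str:
    return f"{mean:.3f} ± {std:.3f}"


def render_report(tables, out_dir, pca_data=None, seed: int = 0) -> list:
    """Write result tables as CSV and aligned text, plus PCA overlay figures.

    ``tables`` is a list of result DataFrames (concatenated before writing).
    ``pca_data``, when given, is a list of ``(fold_index, train_set,
    {method: synth_set})`` tuples; each produces one PNG overlaying the real
    scores with synthetic scores subsampled at three times the real count.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    df = pd.concat(list(tables), ignore_index=True)
    csv_path = out_dir / "results.csv"
    df.to_csv(csv_path, index=False)
    written.append(csv_path)

    txt_path = out_dir / "results.txt"
    with open(txt_path, "w") as fh:
        fh.write(f"{'model':<6} {'synthesis':<10} {'step':>6} "
                 f"{'balanced accuracy':<18} {'train accuracy':<18}\n")
        for _, row in df.iterrows():
            fh.write(f"{row['model']:<6} {row['synthesis']:<10} {row['step']:>6} "
                     f"{format_mean_std(row['mean'], row['std']):<18} "
                     f"{format_mean_std(row['train_mean'], row['train_std']):<18}\n")
    written.append(txt_path)

    if pca_data:
        for fold_index, train, synth_sets in pca_data:
            written.append(
                pca_overlay(train, synth_sets,
                            out_dir / f"pca_fold{fold_index}.png", seed=seed)
            )
    return written


def run_study(cfg: dict, out_dir) -> pd.DataFrame:
    """Drive the whole comparative study from a plain config mapping.

    Steps: obtain the dataset (a CSV path under ``csv`` or a simulation
    ``profile``), preprocess, split and persist folds, build one synthetic
    pool per fold and method, run the baseline and the augmentation sweep
    for every model, write result tables, dFid reports, and first-fold PCA
    overlays.  Returns the combined result table.
    """
    from .folds import persist_folds, stratified_inverted_kfold
    from .preprocess import preprocess_set
    from .simulate import generate_dataset, make_chlorinated_like, make_sars_like

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    name = cfg.get("name", "data")

    if "csv" in cfg:
        data = read_spectra_csv(cfg["csv"])
    else:
        profile = cfg.get("profile", "sars")
        sim_seed = int(cfg.get("sim_seed", 0))
        if profile == "chlorinated":
            sim = make_chlorinated_like(seed=sim_seed)
        elif profile == "sars":
            sim = make_sars_like(seed=sim_seed,
                                 n_features=int(cfg.get("n_features", 900)))
        else:
            raise ValueError(f"unknown profile {profile!r}")
        data = generate_dataset(sim, int(cfg.get("n", 309)))
    data, removed, _ = preprocess_set(data)
    logger.info("dataset %s: %d x %d (%d dead columns removed)",
                name, data.n_samples, data.n_features, len(removed))

    split_seed = int(cfg.get("split_seed", 0))
    splits = stratified_inverted_kfold(data.labels, k=int(cfg.get("k_folds", 3)),
                                       seed=split_seed)
    fold_dir = out_dir / "folds"
    persist_folds(splits, data, fold_dir, dataset_name=name, seed=split_seed)
    folds, _ = load_folds(fold_dir, name)

    train_cfg = TrainConfig(
        epochs=int(cfg.get("epochs", 100)),
        learning_rate=float(cfg.get("learning_rate", 1e-4)),
        batch_size=int(cfg.get("batch_size", 1)),
        seed=0,
    )
    steps = tuple(cfg.get("steps", (400, 800, 1200, 1600, 2000)))
    seeds = tuple(cfg.get("seeds", (0, 1, 2, 3, 4)))
    models = list(cfg.get("models", ("cnn", "fcnn")))
    methods = list(cfg.get("synthesis", ("blend",)))
    policy = cfg.get("augment_policy", "prior")

    blend_cfg = BlendConfig(weights=tuple(cfg.get("blend_weights",
                                                  BlendConfig().weights)))
    vae_opts = dict(cfg.get("vae", {}))
    vae_cfg = VAEConfig(
        epochs=int(vae_opts.get("epochs", 10000)),
        latent_dim=int(vae_opts.get("latent_dim", 50)),
        learning_rate=float(vae_opts.get("learning_rate", 0.001)),
        batch_size=int(vae_opts.get("batch_size", 32)),
        seed=int(vae_opts.get("seed", 0)),
    )
    pool_per_class = int(vae_opts.get("pool_per_class",
                                      max(steps) if steps else 100))

    pools_by_method = {}
    if "blend" in methods:
        pools_by_method["blend"] = build_blend_pools(folds, blend_cfg)
    if "vae" in methods:
        pools_by_method["vae"] = build_vae_pools(folds, vae_cfg,
                                                 pool_per_class=pool_per_class)

    tables = []
    for model in models:
        base_cfg = ExperimentConfig(steps=steps, seeds=seeds,
                                    k_folds=len(folds), synthesis="none",
                                    augment_policy=policy, model=model,
                                    train=train_cfg)
        tables.append(run_baseline(fold_dir, base_cfg, name))
        for method in methods:
            sweep_cfg = ExperimentConfig(steps=steps, seeds=seeds,
                                         k_folds=len(folds), synthesis=method,
                                         augment_policy=policy, model=model,
                                         train=train_cfg)
            tables.append(run_augmentation_sweep(fold_dir,
                                                 pools_by_method[method],
                                                 sweep_cfg, name))

    for method in methods:
        rep = dfid_report(fold_dir, method, reps=int(cfg.get("dfid_reps", 5)),
                          dataset_name=name, blend_config=blend_cfg,
                          vae_config=vae_cfg)
        rep.to_csv(out_dir / f"dfid_{method}.csv", index=False)

    pca_data = None
    if cfg.get("pca", True) and pools_by_method:
        train1 = folds[0][0]
        pca_data = [(1, train1,
                     {m: pools_by_method[m][0].data for m in pools_by_method})]
    render_report(tables, out_dir, pca_data=pca_data, seed=seeds[0] if seeds else 0)
    return pd.concat(tables, ignore_index=True)


def pca_overlay(train: SpectrumSet, synth_sets: dict, out_path, seed: int = 0):
    """Scatter the 2-component PCA scores of real vs synthetic spectra.

    Synthetic sets are subsampled (seeded) at three times the real count to
    avoid oversaturating the plot.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    blocks = [train.matrix]
    tags = ["real"] * train.n_samples
    for method in sorted(synth_sets):
        synth = synth_sets[method]
        n = min(3 * train.n_samples, synth.n_samples)
        sub = sample_rows(synth, n, per_class="prior", seed=seed)
        blocks.append(sub.matrix)
        tags.extend([method] * sub.n_samples)
    scores = pca_scores(np.vstack(blocks), n_components=2)
    tags = np.array(tags)
    fig, ax = plt.subplots(figsize=(6, 5))
    for tag, marker in zip(["real", "blend", "vae"], ["o", "x", "^"]):
        mask = tags == tag
        if mask.any():
            ax.scatter(scores[mask, 0], scores[mask, 1], s=12, marker=marker,
                       label=tag, alpha=0.6)
    ax.set_xlabel("PC1 score")
    ax.set_ylabel("PC2 score")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_path, dpi=100)
    plt.close(fig)
    return Path(out_path)
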