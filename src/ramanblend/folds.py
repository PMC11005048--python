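"""Inverted stratified k-fold cross-validation.

Each fold trains on a *small* stratified partition (1/k of the data,
33.3% for k=3) and evaluates on the large complement (66.6%), stressing the
small-sample regime the study targets.  When a class count is not divisible
by k, ``count mod k`` samples of that class are randomly dropped (seeded)
so every training fold has exactly equal per-class counts; dropped samples
are never trained on but remain in every fold's holdout, so evaluation uses
all real spectra the fold did not train on.  With 154/76 labels this
reproduces the one-per-class drop, 51+25 training folds and 154-sample
holdouts; with 159/150 labels, 53+50 training folds and 206-sample
holdouts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .dataset import SpectrumSet, write_spectra_csv

__all__ = ["FoldSplit", "stratified_inverted_kfold", "persist_folds", "load_fold_manifest"]


@dataclass(frozen=True)
class FoldSplit:
    fold_index: int          # 1-based
    train_idx: np.ndarray
    holdout_idx: np.ndarray
    dropped_idx: np.ndarray  # global, identical across folds


def stratified_inverted_kfold(labels, k: int = 3, seed: int = 0) -> list:
    """Split binary labels into k inverted stratified folds.

    Per class: seeded shuffle, drop ``count mod k`` samples, then chunk the
    remainder into k contiguous equal blocks; block f of each class forms
    the training set of fold f, and every index not trained on (including
    the dropped ones) forms its holdout.
    """
    labels = np.asarray(labels, dtype=int)
    if k < 2:
        raise ValueError("k must be at least 2")
    n = labels.size
    rng = np.random.default_rng(seed)
    train_chunks = [[] for _ in range(k)]
    dropped = []
    for c in (0, 1):
        idx = np.where(labels == c)[0]
        if idx.size < k:
            raise ValueError(f"class {c} has {idx.size} samples, fewer than k={k}")
        idx = idx[rng.permutation(idx.size)]
        r = idx.size % k
        if r:
            dropped.extend(idx[:r].tolist())
            idx = idx[r:]
        per = idx.size // k
        for f in range(k):
            train_chunks[f].extend(idx[f * per:(f + 1) * per].tolist())
    dropped = np.sort(np.array(dropped, dtype=int))
    splits = []
    for f in range(k):
        train = np.sort(np.array(train_chunks[f], dtype=int))
        mask = np.ones(n, dtype=bool)
        mask[train] = False
        holdout = np.where(mask)[0]
        splits.append(FoldSplit(f + 1, train, holdout, dropped))
    return splits


def persist_folds(splits, spectra: SpectrumSet, out_dir, dataset_name: str = "data",
                  seed: int | None = None) -> None:
    """Write one train + one holdout CSV per fold plus an index manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "dataset": dataset_name,
        "seed": seed,
        "k": len(splits),
        "n_samples": spectra.n_samples,
        "dropped": splits[0].dropped_idx.tolist() if splits else [],
        "folds": [],
    }
    for s in splits:
        train_path = out_dir / f"{dataset_name}_fold{s.fold_index}_train.csv"
        hold_path = out_dir / f"{dataset_name}_fold{s.fold_index}_holdout.csv"
        write_spectra_csv(spectra.select(s.train_idx), train_path)
        write_spectra_csv(spectra.select(s.holdout_idx), hold_path)
        manifest["folds"].append(
            {"fold": s.fold_index,
             "train": s.train_idx.tolist(),
             "holdout": s.holdout_idx.tolist(),
             "train_file": train_path.name,
             "holdout_file": hold_path.name}
        )
    with open(out_dir / f"{dataset_name}_folds.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)


def load_fold_manifest(out_dir, dataset_name: str = "data") -> dict:
    path = Path(out_dir) / f"{dataset_name}_folds.json"
    if not path.exists():
        raise FileNotFoundError(f"fold manifest not found: {path}")
    with open(path) as fh:
        return json.load(fh)
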