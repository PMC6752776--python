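"""Shared fixtures: a desk-scale synthetic dataset and self-adaptively trained models.

The desk-scale study conditions used throughout: 400 clean synthetic images
on a 256x192 canvas, CLAHE preprocessing at input side 64, tiny backbone,
20 epochs, three training seeds.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from fundus_laterality.classifier import TrainConfig, build, fit, predict
from fundus_laterality.pipeline import load_manifest_images, split_dataset
from fundus_laterality.preprocess import PreprocessConfig, enhance, normalize
from fundus_laterality.synth_fundus import SynthConfig, disc_center_for, generate_dataset

SIDE = 64
CANVAS = (256, 192)
N_IMAGES = 400
TRAIN_SEEDS = (0, 1, 2)


def disc_center_after_preprocess(laterality, canvas, side: int = SIDE) -> tuple[float, float]:
    """Ground-truth disc center mapped from canvas to preprocessed coordinates."""
    dx, dy = disc_center_for(laterality, canvas)
    w, h = canvas
    bar = (w - h) / 2.0
    scale = side / h
    return ((dx - bar) * scale, dy * scale)


@pytest.fixture(scope="session")
def desk_dataset(tmp_path_factory):
    """(manifest, X_uint8[N,64,64,3] CLAHE-preprocessed, labels)."""
    out = tmp_path_factory.mktemp("desk_data")
    cfg = SynthConfig(n_images=N_IMAGES, canvas_sizes=(CANVAS,), seed=0)
    manifest = generate_dataset(cfg, out)
    images = load_manifest_images(manifest, out)
    pcfg = PreprocessConfig(target_side=SIDE, method="clahe")
    processed = [enhance(normalize(im, pcfg), pcfg) for im in images]
    X = np.stack([im.pixels for im in processed])
    y = manifest["laterality"].to_numpy()
    return manifest, X, y


@pytest.fixture(scope="session")
def trained_runs(desk_dataset):
    """One self-adaptive training run per seed: list of dicts with model and data."""
    manifest, X, y = desk_dataset
    runs = []
    for seed in TRAIN_SEEDS:
        train_df, val_df = split_dataset(manifest, 0.8, seed)
        ti, vi = train_df.index.to_numpy(), val_df.index.to_numpy()
        tcfg = TrainConfig(backbone="tiny", input_side=SIDE, seed=seed, max_epochs=20)
        model = build("tiny", SIDE, seed=seed)
        model, log, pool = fit(
            model, (X[ti], y[ti]), (X[vi], y[vi]), tcfg,
            controller=tcfg.controller_config(),
        )
        preds = [predict(model, X[i]).label for i in vi]
        val_acc = float(np.mean(np.asarray(preds) == y[vi]))
        runs.append(
            {"seed": seed, "model": model, "log": log, "pool": pool,
             "val_idx": vi, "val_acc": val_acc}
        )
    return runs


@pytest.fixture(scope="session")
def best_run(trained_runs):
    """The first training run reaching the 95% validation-accuracy bar."""
    for run in trained_runs:
        if run["val_acc"] >= 0.95:
            return run
    pytest.fail("no training run reached 95% validation accuracy")
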