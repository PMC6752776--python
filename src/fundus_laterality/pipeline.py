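"""End-to-end orchestration: data -> preprocess -> split -> train -> evaluate.

Two experiment drivers are provided.  ``compare_preprocessing`` trains one
fresh model per enhancement method at a fixed learning rate with no
self-adaptive control (the adaptive strategy belongs to the laterality
model only), holding the split and the initial weights identical across
methods so the curves differ only by preprocessing.  ``run_training``
executes the full self-adaptive run and writes a self-contained run
directory (config copy, per-epoch curve, best-model snapshot, evaluation
report, log).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import adaptive_controller as ac
from .classifier import CurveLog, TrainConfig, build, fit, save_model
from .evaluation import evaluate_model
from .preprocess import METHODS, PreprocessConfig, enhance, normalize, with_method
from .synth_fundus import (
    LEFT,
    RIGHT,
    FundusImage,
    ImageMeta,
    SynthConfig,
    generate_dataset,
    is_poor_quality,
    load_image,
)

logger = logging.getLogger("fundus_laterality")


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclass
class RunConfig:
    output_dir: str = "run"
    manifest: str | None = None       # directory containing manifest.csv + PNGs
    synth: SynthConfig = field(default_factory=lambda: SynthConfig(
        n_images=400, canvas_sizes=((256, 192),), seed=0))
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    split: float = 0.8
    log_level: str = "INFO"

    def __post_init__(self):
        if not (0.0 < self.split < 1.0):
            raise ValueError("split must lie in (0, 1)")


def split_dataset(
    manifest: pd.DataFrame, fraction: float, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Disjoint, exhaustive train/validation split stratified by laterality."""
    if manifest.empty:
        raise ValueError("manifest is empty")
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    train_parts, val_parts = [], []
    for _, group in manifest.groupby("laterality", sort=True):
        order = rng.permutation(len(group))
        n_train = int(round(fraction * len(group)))
        train_parts.append(group.iloc[order[:n_train]])
        val_parts.append(group.iloc[order[n_train:]])
    train_df = pd.concat(train_parts).sort_index()
    val_df = pd.concat(val_parts).sort_index()
    if train_df.empty or val_df.empty:
        raise ValueError("split fraction leaves one side empty")
    return train_df, val_df


def load_manifest_images(
    manifest: pd.DataFrame, image_dir: str | Path
) -> list[FundusImage]:
    image_dir = Path(image_dir)
    images = []
    for row in manifest.itertuples():
        meta = ImageMeta(
            laterality=row.laterality,
            obscured_fraction=float(row.obscured_fraction),
            disc_visible_fraction=float(row.disc_visible_fraction),
            canvas_size=(int(row.width), int(row.height)),
            disc_center=(float("nan"), float("nan")),
            seed=int(row.seed),
        )
        images.append(load_image(image_dir / row.filename, meta))
    return images


def exclude_poor_quality(manifest: pd.DataFrame) -> pd.DataFrame:
    """Apply the quality exclusion rule (>=50% obscured or disc partly visible)."""
    keep = [
        not is_poor_quality(
            ImageMeta(
                laterality=row.laterality,
                obscured_fraction=float(row.obscured_fraction),
                disc_visible_fraction=float(row.disc_visible_fraction),
                canvas_size=(int(row.width), int(row.height)),
                disc_center=(0.0, 0.0),
                seed=int(row.seed),
            )
        )
        for row in manifest.itertuples()
    ]
    return manifest[np.asarray(keep)]


def _to_arrays(
    images: list[FundusImage], labels: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    return np.stack([im.pixels for im in images]), np.asarray(labels)


def compare_preprocessing(
    manifest: pd.DataFrame,
    image_dir: str | Path,
    methods: list[str],
    epochs: int,
    preprocess_config: PreprocessConfig | None = None,
    train_config: TrainConfig | None = None,
    fixed_lr: float = 0.01,
) -> dict[str, CurveLog]:
    """Train one model per enhancement method at a fixed learning rate.

    The split, the augmentation stream, and the initial weights are
    identical across methods (same seeds), so curves differ only through
    the preprocessing applied.
    """
    if not methods:
        raise ValueError("at least one method is required")
    seen, unique = set(), []
    for m in methods:
        ml = m.lower()
        if ml not in METHODS:
            raise ValueError(f"unknown method {m!r}; expected one of {METHODS}")
        if ml in seen:
            warnings.warn(f"duplicate method {m!r} ignored", stacklevel=2)
        else:
            seen.add(ml)
            unique.append(ml)

    tcfg = train_config or TrainConfig(backbone="tiny", input_side=64)
    tcfg = dataclasses.replace(tcfg, initial_lr=fixed_lr, max_epochs=epochs)
    pcfg = preprocess_config or PreprocessConfig(target_side=tcfg.input_side)

    images = load_manifest_images(manifest, image_dir)
    normalized = [normalize(im, pcfg) for im in images]
    manifest = manifest.reset_index(drop=True)
    train_df, val_df = split_dataset(manifest, 0.8, tcfg.seed)

    curves: dict[str, CurveLog] = {}
    for method in unique:
        mcfg = with_method(pcfg, method)
        enhanced = [enhance(im, mcfg) for im in normalized]
        X = np.stack([im.pixels for im in enhanced])
        y = manifest["laterality"].to_numpy()
        model = build(tcfg.backbone, tcfg.input_side, seed=tcfg.seed)
        _, log, _ = fit(
            model,
            (X[train_df.index.to_numpy()], y[train_df.index.to_numpy()]),
            (X[val_df.index.to_numpy()], y[val_df.index.to_numpy()]),
            tcfg,
            controller=None,
        )
        curves[method] = log
    return curves


def _setup_run_logging(run_dir: Path, level: str) -> logging.Handler:
    handler = logging.FileHandler(run_dir / "run.log")
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s",
                          datefmt="%Y-%m-%dT%H:%M:%S")
    )
    logger.addHandler(handler)
    logger.setLevel(level.upper())
    if not any(isinstance(h, logging.StreamHandler) and h.stream is sys.stderr
               for h in logger.handlers):
        stream = logging.StreamHandler(sys.stderr)
        stream.setFormatter(handler.formatter)
        logger.addHandler(stream)
    return handler


def run_training(config: RunConfig) -> Path:
    """Full self-adaptive run; returns the populated run directory."""
    run_dir = Path(config.output_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    handler = _setup_run_logging(run_dir, config.log_level)
    try:
        # stage: data
        try:
            if config.manifest is not None:
                data_dir = Path(config.manifest)
                manifest = pd.read_csv(data_dir / "manifest.csv")
            else:
                data_dir = run_dir / "data"
                logger.info("synthesizing %d images", config.synth.n_images)
                manifest = generate_dataset(config.synth, data_dir)
            n_all = len(manifest)
            manifest = exclude_poor_quality(manifest).reset_index(drop=True)
            logger.info("data: %d images (%d excluded as poor quality)",
                        len(manifest), n_all - len(manifest))
        except Exception as e:
            raise PipelineStageError("data", e) from e

        # stage: preprocess
        try:
            pcfg = dataclasses.replace(
                config.preprocess, target_side=config.train.input_side
            )
            images = load_manifest_images(manifest, data_dir)
            processed = [enhance(normalize(im, pcfg), pcfg) for im in images]
            X = np.stack([im.pixels for im in processed])
            y = manifest["laterality"].to_numpy()
            logger.info("preprocess: method=%s side=%d", pcfg.method, pcfg.target_side)
        except Exception as e:
            raise PipelineStageError("preprocess", e) from e

        # stage: split
        try:
            train_df, val_df = split_dataset(manifest, config.split, config.train.seed)
            tr_idx = train_df.index.to_numpy()
            va_idx = val_df.index.to_numpy()
            logger.info("split: %d train / %d validation", len(tr_idx), len(va_idx))
        except Exception as e:
            raise PipelineStageError("split", e) from e

        # stage: train
        try:
            model = build(config.train.backbone, config.train.input_side,
                          seed=config.train.seed)
            model, curve, pool = fit(
                model,
                (X[tr_idx], y[tr_idx]),
                (X[va_idx], y[va_idx]),
                config.train,
                controller=config.train.controller_config(),
            )
            curve.to_csv(run_dir / "curve.csv")
            sidecar = {}
            if pool is not None:
                sidecar = {
                    "epoch": pool.metrics.epoch,
                    "accuracy": pool.metrics.accuracy,
                    "loss": pool.metrics.loss,
                    "monitor": pool.metrics.monitor,
                }
                logger.info("train: pooled best model from epoch %d (M=%.5f)",
                            pool.metrics.epoch, pool.metrics.monitor)
            else:
                logger.info("train: pool empty; keeping last-epoch model")
            save_model(model, run_dir / "model_best.npz", sidecar)
        except Exception as e:
            raise PipelineStageError("train", e) from e

        # stage: evaluate
        try:
            report = evaluate_model(
                model, X[va_idx], y[va_idx],
                out_csv=run_dir / "predictions.csv",
                filenames=manifest["filename"].to_numpy()[va_idx],
            )
            report.to_json(run_dir / "report.json")
            logger.info(
                "evaluate: acc=%.4f sens=%.4f spec=%.4f auc=%.4f",
                report.accuracy.value, report.sensitivity.value,
                report.specificity.value, report.auc.value,
            )
        except Exception as e:
            raise PipelineStageError("evaluate", e) from e

        (run_dir / "config.yaml").write_text(
            yaml.safe_dump(_config_to_dict(config), sort_keys=False)
        )
        return run_dir
    finally:
        logger.removeHandler(handler)
        handler.close()


def _config_to_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d["synth"]["canvas_sizes"] = [list(c) for c in d["synth"]["canvas_sizes"]]
    return d


def config_from_dict(d: dict) -> RunConfig:
    """Build a RunConfig from a (YAML/JSON-loaded) nested mapping."""
    kwargs = dict(d)
    if "synth" in kwargs and isinstance(kwargs["synth"], dict):
        s = dict(kwargs["synth"])
        if "canvas_sizes" in s:
            s["canvas_sizes"] = tuple(tuple(c) for c in s["canvas_sizes"])
        kwargs["synth"] = SynthConfig(**s)
    if "preprocess" in kwargs and isinstance(kwargs["preprocess"], dict):
        kwargs["preprocess"] = PreprocessConfig(**kwargs["preprocess"])
    if "train" in kwargs and isinstance(kwargs["train"], dict):
        kwargs["train"] = TrainConfig(**kwargs["train"])
    return RunConfig(**kwargs)
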