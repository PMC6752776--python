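"""Two-way eye-laterality classifier: backbones, augmentation, loss, training.

The model maps a normalized fundus image to a probability vector
``(P1, P2)`` — P1 for the left eye, P2 for the right — through a
convolutional feature extractor, global average pooling, and a single
affine layer with softmax.  Training is mini-batch SGD with momentum on
cross-entropy with L2 weight decay; per-image augmentation applies a
random horizontal shift of 0-10 pixels and a random rotation bounded by
30 degrees.  All epoch-level adaptation (learning rate, best-model pool,
reloads) is delegated to :mod:`fundus_laterality.adaptive_controller`.

Two backbones are available: ``tiny`` (four conv/pool blocks, desk
scale) and ``inception_v3`` (the standard topology at 299 px).
"""

from __future__ import annotations

import dataclasses
import io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from . import _nn, adaptive_controller as ac
from .synth_fundus import LEFT, RIGHT, FundusImage

_EPS = 1e-7
_LABEL_INDEX = {LEFT: 0, RIGHT: 1}

CURVE_COLUMNS = ["epoch", "train_loss", "val_loss", "val_acc", "monitor", "lr", "actions"]


@dataclass(frozen=True)
class TrainConfig:
    backbone: str = "tiny"
    input_side: int = 299
    initial_lr: float = 0.1
    momentum: float = 0.9
    l2_lambda: float = 1e-4
    batch_size: int = 32
    max_epochs: int = 20
    k: int = 5
    alpha: float = 0.5
    m_threshold: float = 0.005
    acc_gate: float = 0.95
    loss_gate: float = 0.1
    reload_period: int = 10
    min_lr: float = 1e-5
    shift_max: int = 10
    rot_max: float = 30.0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError("alpha must lie in (0, 1]")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.acc_gate <= 0 or self.loss_gate <= 0 or self.m_threshold <= 0:
            raise ValueError("gates must be positive")
        if self.shift_max < 0 or self.rot_max < 0:
            raise ValueError("augmentation bounds must be nonnegative")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be positive")

    def controller_config(self) -> ac.ControllerConfig:
        return ac.ControllerConfig(
            l0=self.initial_lr,
            alpha=self.alpha,
            k=self.k,
            m_threshold=self.m_threshold,
            acc_gate=self.acc_gate,
            loss_gate=self.loss_gate,
            reload_period=self.reload_period,
            min_lr=self.min_lr,
        )


@dataclass(frozen=True)
class PredictionResult:
    p_left: float
    p_right: float
    label: str

    def __post_init__(self):
        if abs(self.p_left + self.p_right - 1.0) > 1e-6:
            raise ValueError("probabilities must sum to 1")


@dataclass
class CurveLog:
    """Per-epoch training record (the real-time accuracy-loss curve)."""

    rows: list[dict] = field(default_factory=list)

    def append(self, **row) -> None:
        self.rows.append({c: row[c] for c in CURVE_COLUMNS})

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=CURVE_COLUMNS)

    def to_csv(self, path: str | Path | io.IOBase) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @property
    def learning_rates(self) -> list[float]:
        return [r["lr"] for r in self.rows]


def label_index(label) -> int:
    if isinstance(label, str):
        return _LABEL_INDEX[label]
    return int(label)


def build(backbone: str, input_side: int, seed: int = 0) -> _nn.Network:
    """Construct a GAP-headed convolutional classifier emitting 2 logits."""
    rng = np.random.default_rng(seed)
    if backbone == "tiny":
        return _nn.build_tiny(input_side, rng)
    if backbone == "inception_v3":
        return _nn.build_inception_v3(input_side, rng)
    raise ValueError(f"unknown backbone {backbone!r}; expected 'tiny' or 'inception_v3'")


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------


def sample_augmentation(rng: np.random.Generator, config: TrainConfig) -> tuple[int, float]:
    """Draw (horizontal shift in pixels, rotation angle in degrees).

    Shift magnitude is uniform on {0..shift_max} with a random sign; the
    angle is uniform on [-rot_max, +rot_max].
    """
    magnitude = int(rng.integers(0, config.shift_max + 1))
    sign = 1 if rng.random() < 0.5 else -1
    angle = float(rng.uniform(-config.rot_max, config.rot_max)) if config.rot_max > 0 else 0.0
    return magnitude * sign, angle


def apply_augmentation(pixels: np.ndarray, shift: int, angle: float) -> np.ndarray:
    """Rotate about the image center, then shift horizontally; vacated pixels black."""
    out = pixels.astype(np.float32)
    if angle != 0.0:
        out = ndimage.rotate(
            out, angle, axes=(1, 0), reshape=False, order=1, mode="constant", cval=0.0
        )
    if shift != 0:
        shifted = np.zeros_like(out)
        if shift > 0:
            shifted[:, shift:] = out[:, :-shift]
        else:
            shifted[:, :shift] = out[:, -shift:]
        out = shifted
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def augment(image: FundusImage, rng: np.random.Generator, config: TrainConfig) -> FundusImage:
    shift, angle = sample_augmentation(rng, config)
    return FundusImage(pixels=apply_augmentation(image.pixels, shift, angle), meta=image.meta)


# ---------------------------------------------------------------------------
# Loss
# ---------------------------------------------------------------------------


def loss(
    probabilities: np.ndarray,
    labels,
    weights: list[np.ndarray] | None = None,
    l2_lambda: float = 0.0,
) -> float:
    """Mean categorical cross-entropy plus ``l2_lambda * sum(w^2)``.

    ``probabilities`` is an (N, 2) array of (P1, P2) rows; true-class
    probabilities are clamped at 1e-7 so certain-but-wrong predictions
    yield a large finite loss.
    """
    p = np.asarray(probabilities, dtype=np.float64)
    if p.ndim != 2 or p.shape[0] == 0:
        raise ValueError("probabilities must be a nonempty (N, 2) array")
    idx = np.array([label_index(l) for l in np.asarray(labels).ravel()])
    if idx.size != p.shape[0]:
        raise ValueError("labels must match the probability batch")
    p_true = np.clip(p[np.arange(idx.size), idx], _EPS, 1.0)
    ce = float(-np.log(p_true).mean())
    reg = 0.0
    if weights is not None and l2_lambda:
        reg = l2_lambda * float(sum(np.sum(np.square(w)) for w in weights))
    return ce + reg


def _decay_weights(model: _nn.Network) -> list[np.ndarray]:
    return [p.value for p in model.params() if p.decay]


def _to_batch(images: np.ndarray) -> np.ndarray:
    """uint8 (N, H, W, 3) -> float32 NCHW scaled to [0, 1]."""
    return np.ascontiguousarray(images.transpose(0, 3, 1, 2), dtype=np.float32) / 255.0


def _forward_probs(model: _nn.Network, images: np.ndarray, batch_size: int = 64) -> np.ndarray:
    model.set_training(False)
    probs = []
    for start in range(0, images.shape[0], batch_size):
        logits = model.forward(_to_batch(images[start : start + batch_size]))
        probs.append(_nn.softmax(logits))
    return np.concatenate(probs, axis=0)


def predict(model: _nn.Network, image: FundusImage | np.ndarray) -> PredictionResult:
    """Softmax probabilities and the argmax label (LEFT wins ties)."""
    pixels = image.pixels if isinstance(image, FundusImage) else np.asarray(image)
    if pixels.shape[:2] != (model.input_side, model.input_side):
        raise ValueError(
            f"image side {pixels.shape[:2]} does not match model input "
            f"{model.input_side}"
        )
    p = _forward_probs(model, pixels[None])[0]
    label = LEFT if p[0] >= p[1] else RIGHT
    return PredictionResult(p_left=float(p[0]), p_right=float(p[1]), label=label)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def _validate_dataset(X: np.ndarray, y: np.ndarray, side: int, name: str) -> np.ndarray:
    if X.shape[0] != y.shape[0] or X.shape[0] == 0:
        raise ValueError(f"{name} set must be nonempty with matching labels")
    if X.shape[1:3] != (side, side):
        raise ValueError(f"{name} images must be {side}x{side}")
    return np.array([label_index(l) for l in y])


def fit(
    model: _nn.Network,
    train_data: tuple[np.ndarray, np.ndarray],
    val_data: tuple[np.ndarray, np.ndarray],
    config: TrainConfig,
    controller: ac.ControllerConfig | None = None,
) -> tuple[_nn.Network, CurveLog, ac.ModelSnapshot | None]:
    """Mini-batch SGD with momentum under optional self-adaptive control.

    After each epoch the validation accuracy and loss are formed into
    :class:`~fundus_laterality.adaptive_controller.EpochMetrics`, passed to
    the controller, and the returned actions applied (learning-rate change,
    best-weights snapshot, snapshot reload; a reload restores weights only
    and resets optimizer momentum).  Returns the pool's best snapshot as
    the final model when the pool is nonempty, else the last-epoch model.

    With ``controller=None`` the learning rate stays fixed at
    ``config.initial_lr`` and no pool is kept (the regime used for the
    preprocessing-methods comparison).
    """
    X_tr, y_tr = train_data
    X_va, y_va = val_data
    yi_tr = _validate_dataset(X_tr, y_tr, model.input_side, "training")
    yi_va = _validate_dataset(X_va, y_va, model.input_side, "validation")
    if np.unique(yi_tr).size < 2:
        raise ValueError("training set must contain both classes")

    rng = np.random.default_rng(config.seed)
    lam = config.l2_lambda
    velocity = {id(p): np.zeros_like(p.value) for p in model.params()}
    state = ac.init(controller) if controller is not None else None
    lr = state.lr if state is not None else config.initial_lr
    best_weights: list[np.ndarray] | None = None
    best_ref: int | None = None
    log = CurveLog()

    n = X_tr.shape[0]
    for epoch in range(1, config.max_epochs + 1):
        model.set_training(True)
        perm = rng.permutation(n)
        batch_losses = []
        for start in range(0, n, config.batch_size):
            idx = perm[start : start + config.batch_size]
            batch = np.stack(
                [
                    apply_augmentation(X_tr[i], *sample_augmentation(rng, config))
                    for i in idx
                ]
            )
            xb = _to_batch(batch)
            yb = yi_tr[idx]
            logits = model.forward(xb)
            p = _nn.softmax(logits)
            p_true = np.clip(p[np.arange(yb.size), yb], _EPS, 1.0)
            data_loss = float(-np.log(p_true).mean())
            reg = lam * sum(float(np.sum(np.square(w))) for w in _decay_weights(model))
            batch_losses.append(data_loss + reg)

            model.zero_grad()
            dlogits = p.astype(np.float32)
            dlogits[np.arange(yb.size), yb] -= 1.0
            dlogits /= yb.size
            model.backward(dlogits)
            for prm in model.params():
                g = prm.grad
                if prm.decay and lam:
                    g = g + (2.0 * lam) * prm.value
                v = velocity[id(prm)]
                v *= config.momentum
                v -= lr * g
                prm.value += v

        # validation metrics at the end of the epoch
        probs = _forward_probs(model, X_va, config.batch_size)
        val_acc = float((probs.argmax(axis=1) == yi_va).mean())
        val_loss = loss(probs, yi_va, _decay_weights(model), lam)
        metrics = ac.EpochMetrics(epoch=epoch, accuracy=val_acc, loss=val_loss)

        tokens = []
        if state is not None:
            state, actions = ac.observe(state, metrics)
            for action in actions:
                tokens.append(action.token())
                if action.kind == ac.SAVE_BEST:
                    best_weights = model.get_weights()
                    best_ref = action.snapshot.ref
                elif action.kind == ac.REDUCE_LR:
                    lr = action.new_lr
                elif action.kind == ac.RELOAD_BEST:
                    if action.snapshot.ref != best_ref:  # pragma: no cover
                        raise RuntimeError("pool reference does not match stored weights")
                    model.set_weights(best_weights)
                    for v in velocity.values():
                        v.fill(0.0)

        log.append(
            epoch=epoch,
            train_loss=float(np.mean(batch_losses)),
            val_loss=val_loss,
            val_acc=val_acc,
            monitor=metrics.monitor,
            lr=lr,
            actions=";".join(tokens),
        )

    pool = ac.best_snapshot(state) if state is not None else None
    if pool is not None:
        model.set_weights(best_weights)
    return model, log, pool


# ---------------------------------------------------------------------------
# Snapshot store
# ---------------------------------------------------------------------------


def save_model(model: _nn.Network, path: str | Path, sidecar: dict | None = None) -> None:
    """Write weights (``.npz``) plus a JSON sidecar describing the run."""
    path = Path(path)
    np.savez(path, *model.get_weights())
    meta = {"backbone": model.name, "input_side": model.input_side}
    meta.update(sidecar or {})
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_model(path: str | Path) -> _nn.Network:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    model = build(meta["backbone"], meta["input_side"], seed=0)
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as data:
        model.set_weights([data[k] for k in data.files])
    return model
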