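"""Backbones, augmentation, loss arithmetic, and the training loop."""

import numpy as np
import pytest

from fundus_laterality.classifier import (
    CurveLog,
    TrainConfig,
    apply_augmentation,
    augment,
    build,
    fit,
    loss,
    predict,
    sample_augmentation,
)
from fundus_laterality.synth_fundus import LEFT, RIGHT, FundusImage


def _toy_data(n=40, side=32, seed=0):
    """Trivially separable images: bright blob on the class side."""
    rng = np.random.default_rng(seed)
    X = np.zeros((n, side, side, 3), dtype=np.uint8)
    y = np.array([LEFT, RIGHT] * (n // 2))
    for i in range(n):
        x0 = side // 8 if y[i] == LEFT else 5 * side // 8
        X[i, side // 4 : 3 * side // 4, x0 : x0 + side // 4] = 200
        X[i] = np.clip(
            X[i].astype(int) + rng.integers(-20, 20, X[i].shape), 0, 255
        ).astype(np.uint8)
    return X, y


class TestBuild:
    def test_tiny_interface(self):
        model = build("tiny", 96, seed=0)
        result = predict(model, np.zeros((96, 96, 3), dtype=np.uint8))
        assert result.p_left + result.p_right == pytest.approx(1.0, abs=1e-6)

    def test_inception_v3_accepts_299(self):
        model = build("inception_v3", 299, seed=0)
        x = np.random.default_rng(0).integers(0, 255, (299, 299, 3), dtype=np.uint8)
        result = predict(model, x)
        assert result.p_left + result.p_right == pytest.approx(1.0, abs=1e-6)
        assert result.label in (LEFT, RIGHT)

    def test_zeroed_head_gives_uniform_and_left_tie(self):
        model = build("tiny", 32, seed=0)
        model.head.w.value[...] = 0.0
        model.head.b.value[...] = 0.0
        result = predict(model, np.full((32, 32, 3), 50, dtype=np.uint8))
        assert result.p_left == pytest.approx(0.5, abs=1e-6)
        assert result.label == LEFT

    def test_unknown_backbone(self):
        with pytest.raises(ValueError):
            build("resnet", 64)

    def test_wrong_input_size_rejected(self):
        model = build("tiny", 64, seed=0)
        with pytest.raises(ValueError):
            predict(model, np.zeros((32, 32, 3), dtype=np.uint8))


class TestAugmentation:
    def test_bounds_over_many_samples(self):
        cfg = TrainConfig(shift_max=10, rot_max=30.0)
        rng = np.random.default_rng(0)
        shifts, angles = zip(*(sample_augmentation(rng, cfg) for _ in range(10_000)))
        assert max(abs(s) for s in shifts) <= 10
        assert max(abs(a) for a in angles) <= 30.0
        # both extremes actually get exercised
        assert max(abs(s) for s in shifts) == 10
        assert max(abs(a) for a in angles) > 29.9

    def test_deterministic_given_rng_state(self):
        cfg = TrainConfig()
        img = FundusImage(
            pixels=np.random.default_rng(1).integers(0, 255, (32, 32, 3), dtype=np.uint8)
        )
        a = augment(img, np.random.default_rng(7), cfg)
        b = augment(img, np.random.default_rng(7), cfg)
        assert np.array_equal(a.pixels, b.pixels)

    def test_degenerate_bounds_are_identity(self):
        cfg = TrainConfig(shift_max=0, rot_max=0.0)
        px = np.random.default_rng(2).integers(0, 255, (16, 16, 3), dtype=np.uint8)
        out = augment(FundusImage(pixels=px), np.random.default_rng(0), cfg)
        assert np.array_equal(out.pixels, px)

    def test_shift_fills_black(self):
        px = np.full((8, 8, 3), 200, dtype=np.uint8)
        out = apply_augmentation(px, 3, 0.0)
        assert np.all(out[:, :3] == 0)
        assert np.all(out[:, 3:] == 200)


class TestLoss:
    def test_perfect_predictions_zero(self):
        p = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert loss(p, [LEFT, RIGHT]) == pytest.approx(0.0, abs=1e-6)

    def test_uniform_predictions_ln2(self):
        p = np.full((4, 2), 0.5)
        assert loss(p, [LEFT, RIGHT, LEFT, RIGHT]) == pytest.approx(np.log(2), rel=1e-6)

    def test_l2_term_arithmetic(self):
        p = np.array([[1.0, 0.0]])
        assert loss(p, [LEFT], weights=[np.array([2.0])], l2_lambda=0.01) == pytest.approx(
            0.04, abs=1e-9
        )

    def test_l2_decomposition_exact(self):
        rng = np.random.default_rng(3)
        p = rng.dirichlet((1, 1), size=10)
        y = [LEFT] * 5 + [RIGHT] * 5
        ws = [rng.normal(size=(4, 3)), rng.normal(size=7)]
        lam = 1e-3
        expected = lam * sum(np.sum(w**2) for w in ws)
        assert loss(p, y, ws, lam) - loss(p, y) == pytest.approx(expected, rel=1e-9)

    def test_clamped_zero_probability(self):
        p = np.array([[0.0, 1.0]])
        assert loss(p, [LEFT]) == pytest.approx(-np.log(1e-7))

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            loss(np.zeros((0, 2)), [])


class TestFit:
    def test_learns_separable_toy_data(self):
        X, y = _toy_data(n=60, side=32)
        cfg = TrainConfig(
            backbone="tiny", input_side=32, seed=0, max_epochs=6,
            shift_max=2, rot_max=10.0, batch_size=16,
        )
        model = build("tiny", 32, seed=0)
        model, log, _ = fit(model, (X[:40], y[:40]), (X[40:], y[40:]), cfg)
        assert log.rows[-1]["val_acc"] >= 0.9

    def test_reproducible_curve(self):
        X, y = _toy_data(n=24, side=32)
        cfg = TrainConfig(backbone="tiny", input_side=32, seed=5, max_epochs=3,
                          batch_size=8)
        logs = []
        for _ in range(2):
            model = build("tiny", 32, seed=5)
            _, log, _ = fit(model, (X[:16], y[:16]), (X[16:], y[16:]), cfg,
                            controller=cfg.controller_config())
            logs.append(log.to_dataframe())
        assert logs[0].equals(logs[1])

    def test_lr_column_non_increasing(self, trained_runs):
        for run in trained_runs:
            lrs = run["log"].learning_rates
            assert all(b <= a for a, b in zip(lrs, lrs[1:]))

    def test_epoch1_metrics_independent_of_controller(self):
        X, y = _toy_data(n=24, side=32)
        cfg = TrainConfig(backbone="tiny", input_side=32, seed=4, max_epochs=1,
                          batch_size=8)
        rows = []
        for ctrl in (None, cfg.controller_config()):
            model = build("tiny", 32, seed=4)
            _, log, _ = fit(model, (X[:16], y[:16]), (X[16:], y[16:]), cfg,
                            controller=ctrl)
            rows.append((log.rows[0]["val_acc"], log.rows[0]["val_loss"]))
        assert rows[0] == rows[1]

    def test_single_class_training_rejected(self):
        X, y = _toy_data(n=20, side=32)
        only_left = np.array([LEFT] * 10)
        with pytest.raises(ValueError):
            fit(
                build("tiny", 32, seed=0),
                (X[:10], only_left),
                (X[10:], y[10:]),
                TrainConfig(backbone="tiny", input_side=32, max_epochs=1),
            )


class TestCurveLog:
    def test_csv_round_trip(self, tmp_path):
        log = CurveLog()
        log.append(epoch=1, train_loss=0.5, val_loss=0.4, val_acc=0.9,
                   monitor=0.04, lr=0.1, actions="save")
        path = tmp_path / "curve.csv"
        log.to_csv(path)
        import pandas as pd

        df = pd.read_csv(path)
        assert df.loc[0, "actions"] == "save"
        assert df.loc[0, "monitor"] == pytest.approx(0.04)
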