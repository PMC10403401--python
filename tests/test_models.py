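import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mfcbod as m
from mfcbod import models
from mfcbod.models import _backward, _forward, _init_weights


def tiny_config(**kw):
    defaults = dict(
        n_input=5, hidden=(8, 8, 4), dropout=(0.0, 0.0, 0.0), n_output=2,
        learning_rate=1e-3, loss="mse_indirect", epochs=10, seed=0,
    )
    defaults.update(kw)
    return models.MLPConfig(**defaults)


class TestRegistry:
    def test_24h_direct(self):
        cfg = models.registry_config(m.WindowSpec(24), "direct")
        assert cfg.n_input == 289
        assert cfg.hidden == (128, 128, 64)
        assert cfg.dropout == (0.10, 0.10, 0.30)
        assert cfg.n_output == 1
        assert cfg.learning_rate == 1e-3
        assert cfg.loss == "mse_direct"

    def test_2h_indirect(self):
        cfg = models.registry_config(m.WindowSpec(2), "indirect")
        assert cfg.n_input == 25
        assert cfg.hidden == (128, 128, 64)
        assert cfg.dropout == (0.30, 0.30, 0.50)
        assert cfg.n_output == 1486
        assert cfg.learning_rate == 1e-4

    def test_12h_direct(self):
        cfg = models.registry_config(m.WindowSpec(12), "direct")
        assert cfg.hidden == (96, 96, 64)
        assert cfg.dropout == (0.10, 0.10, 0.40)
        assert cfg.n_output == 1

    @pytest.mark.parametrize("hours", m.WINDOW_HOURS)
    @pytest.mark.parametrize("approach", ["direct", "indirect"])
    def test_all_twelve_entries_valid(self, hours, approach):
        w = m.WindowSpec(hours)
        cfg = models.registry_config(w, approach)
        assert all(h in (64, 96, 128) for h in cfg.hidden)
        assert all(d in (0.10, 0.20, 0.25, 0.30, 0.40, 0.50) for d in cfg.dropout)
        if approach == "direct":
            assert (cfg.n_output, cfg.learning_rate) == (1, 1e-3)
        else:
            assert cfg.n_output == 1511 - cfg.n_input
            assert cfg.learning_rate == 1e-4

    def test_unknown_approach(self):
        with pytest.raises(ValueError):
            models.registry_config(m.WindowSpec(24), "sideways")


class TestTrain:
    def test_same_seed_identical_weights(self, rng):
        x = rng.normal(size=(6, 5))
        y = rng.normal(size=(6, 2))
        cfg = tiny_config(dropout=(0.2, 0.2, 0.2), epochs=50)
        a = models.train(cfg, x, y, seed=3)
        b = models.train(cfg, x, y, seed=3)
        for (wa, ba), (wb, bb) in zip(a.weights, b.weights):
            np.testing.assert_array_equal(wa, wb)
            np.testing.assert_array_equal(ba, bb)

    def test_zero_epochs_keeps_initial_weights(self, rng):
        x = rng.normal(size=(4, 5))
        y = rng.normal(size=(4, 2))
        cfg = tiny_config(epochs=0)
        model = models.train(cfg, x, y, seed=1)
        init = _init_weights(cfg, np.random.default_rng(1))
        for (w, b), (wi, bi) in zip(model.weights, init):
            np.testing.assert_array_equal(w, wi)
            np.testing.assert_array_equal(b, bi)
        assert model.training_log == []

    def test_overfit_tiny_dataset(self):
        # capacity sanity: 4 experiments, dropout off, long training
        ds = m.generate_dataset(4, seed=11, params=m.CurveParams())
        w = m.WindowSpec(2)
        x = np.stack([m.truncate_window(m.pad_to_canonical(t), w) for t in ds])
        y = np.array([t.bod5_mass for t in ds])[:, None]
        base = models.registry_config(w, "direct", epochs=2500, seed=0)
        cfg = dataclasses.replace(base, dropout=(0.0, 0.0, 0.0))
        model = models.train(cfg, x, y, seed=0)
        assert model.training_log[-1] < 1e-4 * float(np.var(y))

    def test_loss_trend_decreasing(self, rng):
        x = rng.normal(size=(10, 5))
        y = x[:, :2] * 2.0
        model = models.train(tiny_config(epochs=200), x, y, seed=0)
        log = np.asarray(model.training_log)
        assert log[-20:].mean() < log[:20].mean()

    @pytest.mark.parametrize("shape_kw", [
        {"x": (5, 4), "y": (5, 2)},   # wrong input width
        {"x": (5, 5), "y": (5, 3)},   # wrong output width
        {"x": (5, 5), "y": (4, 2)},   # row mismatch
    ])
    def test_shape_errors(self, rng, shape_kw):
        x = rng.normal(size=shape_kw["x"])
        y = rng.normal(size=shape_kw["y"])
        with pytest.raises(ValueError):
            models.train(tiny_config(), x, y, seed=0)

    def test_nonfinite_rejected(self, rng):
        x = rng.normal(size=(4, 5))
        x[0, 0] = np.nan
        with pytest.raises(ValueError):
            models.train(tiny_config(), x, np.zeros((4, 2)), seed=0)


class TestGradients:
    def test_backprop_matches_finite_differences(self, rng):
        cfg = tiny_config(hidden=(4, 3, 3), n_input=3, n_output=2)
        weights = _init_weights(cfg, rng)
        # zero-init biases put dead units exactly on the ReLU kink, where the
        # central difference is ill-defined; jitter them off it
        weights = [(w, b + rng.normal(scale=0.1, size=b.shape)) for w, b in weights]
        x = rng.normal(size=(5, 3))
        y = rng.normal(size=(5, 2))

        def loss_at(ws):
            out, _ = _forward(ws, x, cfg.dropout, rng=None)
            return float(np.mean((out - y) ** 2))

        pred, caches = _forward(weights, x, cfg.dropout, rng=None)
        grads = _backward(weights, caches, cfg.dropout, 2.0 * (pred - y) / y.size)

        eps = 1e-6
        for li in range(len(weights)):
            w, b = weights[li]
            for idx in [(0, 0), (w.shape[0] - 1, w.shape[1] - 1)]:
                ws_hi = [(wi.copy(), bi.copy()) for wi, bi in weights]
                ws_lo = [(wi.copy(), bi.copy()) for wi, bi in weights]
                ws_hi[li][0][idx] += eps
                ws_lo[li][0][idx] -= eps
                numeric = (loss_at(ws_hi) - loss_at(ws_lo)) / (2 * eps)
                assert grads[li][0][idx] == pytest.approx(numeric, rel=1e-4, abs=1e-8)
            ws_hi = [(wi.copy(), bi.copy()) for wi, bi in weights]
            ws_lo = [(wi.copy(), bi.copy()) for wi, bi in weights]
            ws_hi[li][1][0] += eps
            ws_lo[li][1][0] -= eps
            numeric = (loss_at(ws_hi) - loss_at(ws_lo)) / (2 * eps)
            assert grads[li][1][0] == pytest.approx(numeric, rel=1e-4, abs=1e-8)


class TestPredict:
    def _direct_model(self, epochs=20):
        ds = m.generate_dataset(6, seed=1)
        w = m.WindowSpec(2)
        x = np.stack([m.truncate_window(m.pad_to_canonical(t), w) for t in ds])
        y = np.array([t.bod5_mass for t in ds])[:, None]
        cfg = models.registry_config(w, "direct", epochs=epochs, seed=0)
        return models.train(cfg, x, y, seed=0), x

    def test_direct_output_is_scalar_and_clamped(self):
        model, x = self._direct_model()
        pred = models.predict_direct(model, x[0])
        assert isinstance(pred, float) and pred >= 0.0

    def test_negative_output_clamps_to_zero(self):
        model, x = self._direct_model(epochs=0)
        # force a negative raw output through the final bias
        w_last, _ = model.weights[-1]
        model.weights[-1] = (np.zeros_like(w_last), np.array([-0.3]))
        assert models.predict_direct(model, x[0]) == 0.0

    def test_inference_deterministic_despite_dropout(self):
        model, x = self._direct_model()
        assert model.config.dropout != (0.0, 0.0, 0.0)
        a = model.predict(x)
        b = model.predict(x)
        np.testing.assert_array_equal(a, b)

    @pytest.mark.parametrize("hours,n_out", [(24, 1222), (16, 1318), (2, 1486)])
    def test_continuation_lengths(self, hours, n_out):
        w = m.WindowSpec(hours)
        cfg = models.registry_config(w, "indirect", epochs=0, seed=0)
        model = models.train(cfg, np.zeros((2, w.n_input)), np.zeros((2, n_out)), seed=0)
        out = models.predict_continuation(model, np.random.default_rng(0).uniform(size=w.n_input))
        assert out.shape == (n_out,)
        assert np.all(np.isfinite(out))

    def test_wrong_approach_rejected(self):
        model, x = self._direct_model(epochs=0)
        with pytest.raises(ValueError):
            models.predict_continuation(model, x[0])

    def test_wrong_input_length_rejected(self):
        model, _ = self._direct_model(epochs=0)
        with pytest.raises(ValueError):
            models.predict_direct(model, np.zeros(26))


class TestFoldPlan:
    def test_40_into_5_blocks_of_8(self):
        plan = models.plan_folds(40, k=5)
        assert plan.k == 5
        assert all(len(b) == 8 for b in plan.blocks)
        assert sorted(i for b in plan.blocks for i in b) == list(range(40))

    def test_indivisible_rejected(self):
        with pytest.raises(ValueError):
            models.plan_folds(41, k=5)

    def test_unequal_blocks_rejected(self):
        with pytest.raises(ValueError):
            models.FoldPlan(blocks=((0, 1), (2,)))

    def test_overlapping_blocks_rejected(self):
        with pytest.raises(ValueError):
            models.FoldPlan(blocks=((0, 1), (1, 2)))


@pytest.fixture(scope="module")
def cv_setup():
    rng = np.random.default_rng(3)
    x = rng.normal(size=(10, 5))
    y = (x[:, :1] @ np.ones((1, 2))) + rng.normal(scale=0.05, size=(10, 2))
    plan = models.plan_folds(10, k=5)
    cfg = tiny_config(epochs=40)
    result = models.cross_validate([cfg], x, y, plan, seed=0, max_epochs=40)
    return x, y, plan, cfg, result


class TestCrossValidate:
    def test_each_block_validated_once(self, cv_setup):
        *_, result = cv_setup
        assert len(result.fold_losses[0]) == 5

    def test_mean_curve_is_mean_of_folds(self, cv_setup):
        *_, result = cv_setup
        manual = np.mean(np.asarray(result.fold_losses[0]), axis=0)
        np.testing.assert_allclose(result.mean_curves[0], manual)

    def test_selected_epoch_minimises_mean(self, cv_setup):
        *_, result = cv_setup
        curve = result.mean_curves[0]
        assert result.selected.epochs == int(np.argmin(curve)) + 1
        assert result.best_mean_loss == pytest.approx(float(curve.min()))

    def test_fold_training_reproducible(self, cv_setup):
        x, y, plan, cfg, result = cv_setup
        again = models.cross_validate([cfg], x, y, plan, seed=0, max_epochs=40)
        np.testing.assert_array_equal(result.mean_curves[0], again.mean_curves[0])

    def test_plan_must_cover_rows(self):
        with pytest.raises(ValueError):
            models.cross_validate(
                [tiny_config()], np.zeros((10, 5)), np.zeros((10, 2)),
                models.plan_folds(5, k=5), seed=0,
            )


class TestLossEquivalence:
    @settings(max_examples=50, deadline=None)
    @given(seed=st.integers(0, 2**31), n=st.integers(1, 8), p=st.integers(1, 6))
    def test_training_loss_equals_metric_mse(self, seed, n, p):
        # the loss minimised by train() must agree with the metric-module MSE
        rng = np.random.default_rng(seed)
        true = rng.normal(size=(n, p))
        pred = rng.normal(size=(n, p))
        manual = sum(
            (true[j, i] - pred[j, i]) ** 2 for j in range(n) for i in range(p)
        ) / (n * p)
        assert m.mse_indirect(true, pred) == pytest.approx(manual)
        if p == 1:
            assert m.mse_direct(true[:, 0], pred[:, 0]) == pytest.approx(manual)


class TestNormalization:
    def test_round_trip(self, rng):
        x = rng.uniform(0, 0.6, size=100)
        z = models.minimax_normalize(x, 0.01, 0.55)
        np.testing.assert_allclose(models.minimax_denormalize(z, 0.01, 0.55), x)

    def test_degenerate_bounds_rejected(self):
        with pytest.raises(ValueError):
            models.minimax_normalize(np.zeros(3), 0.5, 0.5)
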