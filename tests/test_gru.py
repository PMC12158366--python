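"""GRU regressor: parameter accounting, exact gradients, training
behaviour, metrics, and the sensor-ablation scaffold."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import emg2press as ep
from emg2press.gru import GRUModel, load_model, save_model


def toy_data(t_len=40, d=3, o=2, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.random((t_len, d))
    # smooth deterministic target so tiny models can fit it
    Y = np.column_stack([np.convolve(X[:, k % d], np.ones(5) / 5, "same")
                         for k in range(o)])
    return X, Y


def toy_dataset(t_len=40, d=4, o=4, seed=0):
    X, Y = toy_data(t_len, d, o, seed)
    return ep.WindowedDataset(X=X, Y=Y, window_times=np.arange(t_len, dtype=float),
                              feature_channels=tuple(ep.EMG_CHANNELS[:d]))


class TestParamCount:
    def test_reference_architecture(self):
        pc = ep.count_params(ep.GRUConfig())
        assert (pc.gru, pc.dense, pc.total) == (13_440, 260, 13_700)

    def test_hand_evaluated_small_configs(self):
        pc = ep.count_params(ep.GRUConfig(input_dim=1, units=1, output_dim=1))
        assert (pc.gru, pc.dense, pc.total) == (12, 2, 14)
        pc = ep.count_params(ep.GRUConfig(input_dim=1, units=64, output_dim=4))
        assert pc.gru == 12_864 and pc.dense == 260

    def test_dropout_contributes_no_parameters(self):
        with_do = ep.count_params(ep.GRUConfig(dropout=0.4))
        without = ep.count_params(ep.GRUConfig(dropout=0.0))
        assert with_do.total == without.total == 13_700

    @given(st.integers(1, 8), st.integers(1, 48), st.integers(1, 6),
           st.integers(0, 10_000))
    @settings(max_examples=20)
    def test_allocated_parameters_match_formula(self, d, h, o, seed):
        cfg = ep.GRUConfig(input_dim=d, units=h, output_dim=o, seed=seed)
        model = GRUModel(cfg)
        assert model.n_params().gru == ep.count_params(cfg).gru
        assert model.n_params().dense == ep.count_params(cfg).dense
        assert model.n_params().total == sum(p.size for p in model.params.values())


class TestForwardBackward:
    def test_output_shape_contract(self):
        model = GRUModel(ep.GRUConfig())
        X = np.random.default_rng(0).random((37, 4))
        yhat, _ = model.forward(X)
        assert yhat.shape == (37, 4)

    def test_wrong_input_dim_rejected(self):
        model = GRUModel(ep.GRUConfig())
        with pytest.raises(ValueError, match="shape"):
            model.forward(np.zeros((10, 3)))

    def test_gradients_match_finite_differences(self):
        """BPTT oracle: central finite differences on every parameter."""
        cfg = ep.GRUConfig(input_dim=3, units=5, dropout=0.0, output_dim=2, seed=3)
        model = GRUModel(cfg)
        X, Y = toy_data(t_len=9, d=3, o=2, seed=1)

        yhat, cache = model.forward(X)
        grads = model.backward(cache, 2.0 * (yhat - Y) / yhat.size)

        def loss():
            out, _ = model.forward(X)
            return float(np.mean((out - Y) ** 2))

        eps = 1e-6
        for name, p in model.params.items():
            it = np.nditer(p, flags=["multi_index"])
            for _ in it:
                i = it.multi_index
                orig = p[i]
                p[i] = orig + eps
                up = loss()
                p[i] = orig - eps
                down = loss()
                p[i] = orig
                num = (up - down) / (2 * eps)
                assert num == pytest.approx(grads[name][i], rel=1e-4, abs=1e-8), name

    def test_dropout_only_active_in_training(self):
        cfg = ep.GRUConfig(input_dim=4, units=8, dropout=0.5, output_dim=4, seed=0)
        model = GRUModel(cfg)
        X = np.random.default_rng(1).random((20, 4))
        a, _ = model.forward(X, training=False)
        b, _ = model.forward(X, training=False)
        np.testing.assert_array_equal(a, b)
        c, _ = model.forward(X, training=True)
        assert not np.allclose(a, c)


class TestMetrics:
    def test_perfect_predictor_scores_zero(self):
        _, Y = toy_data()
        m = ep.compute_metrics(Y, Y)
        assert m.mse == 0.0 and m.mae == 0.0

    def test_constant_half_on_uniform_targets(self):
        rng = np.random.default_rng(4)
        y = rng.random((50_000, 1))
        m = ep.compute_metrics(y, np.full_like(y, 0.5))
        assert m.mae == pytest.approx(0.25, abs=0.01)
        assert m.mse == pytest.approx(1 / 12, abs=0.01)

    def test_jensen_inequality_on_random_evaluations(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            y = rng.random((200, 4))
            yhat = y + rng.normal(0, rng.random(), (200, 4))
            m = ep.compute_metrics(y, yhat)
            assert m.mae ** 2 <= m.mse + 1e-12


class TestTraining:
    def test_loss_decreases_and_curves_have_epoch_length(self):
        ds = toy_dataset(seed=2)
        cfg = ep.GRUConfig(units=12, epochs=25, dropout=0.0, seed=1,
                           learning_rate=0.01)
        res = ep.train(GRUModel(cfg), [ds], None, cfg)
        assert len(res.loss_curve) == len(res.mae_curve) == 25
        assert res.loss_curve[-1] <= res.loss_curve[0]
        assert res.final_train.mae ** 2 <= res.final_train.mse + 1e-12

    def test_same_seed_reproduces_training_exactly(self):
        ds = toy_dataset(seed=3)
        cfg = ep.GRUConfig(units=10, epochs=8, seed=11)
        r1 = ep.train(GRUModel(cfg), [ds], [ds], cfg)
        r2 = ep.train(GRUModel(cfg), [ds], [ds], cfg)
        np.testing.assert_array_equal(r1.loss_curve, r2.loss_curve)
        assert r1.final_val.mae == r2.final_val.mae

    def test_memorizes_tiny_noiseless_recording(self):
        """One 5-cycle noiseless recording, full training: near-perfect fit.

        Dropout is disabled — this is a capacity/optimization sanity check,
        and regularization deliberately fights single-sequence memorization.
        """
        from conftest import noiseless_params
        rec = ep.simulate_recording(noiseless_params(n_cycles=5, seed=2))
        env = ep.preprocess_recording(rec)
        table, _ = ep.compatibility_report(env, search_halfwidth=0.9)
        ds = ep.build_dataset(env, table, ep.WindowConfig())
        cfg = ep.GRUConfig(epochs=200, seed=0, dropout=0.0)
        res = ep.train(GRUModel(cfg), [ds], None, cfg)
        assert res.final_train.mae < 0.05

    def test_empty_training_set_rejected(self):
        cfg = ep.GRUConfig()
        with pytest.raises(ValueError, match="empty"):
            ep.train(GRUModel(cfg), [], None, cfg)

    def test_dimension_mismatch_rejected(self):
        cfg = ep.GRUConfig(input_dim=4)
        ds = toy_dataset(d=2, o=4)
        with pytest.raises(ValueError, match="dims"):
            ep.train(GRUModel(cfg), [ds], None, cfg)

    def test_predict_is_clipped_to_unit_interval(self):
        model = GRUModel(ep.GRUConfig(units=8, seed=0))
        X = 5.0 * np.random.default_rng(0).random((30, 4))
        yhat = ep.predict(model, X)
        assert yhat.min() >= 0.0 and yhat.max() <= 1.0

    def test_save_load_roundtrip(self, tmp_path):
        model = GRUModel(ep.GRUConfig(units=6, seed=4))
        path = str(tmp_path / "w.npz")
        save_model(model, path)
        back = load_model(path)
        X = np.random.default_rng(2).random((15, 4))
        np.testing.assert_array_equal(back.forward(X)[0], model.forward(X)[0])


class TestSensorAblation:
    def test_one_row_per_subset_with_baseline(self):
        train_ds = toy_dataset(seed=6)
        val_ds = toy_dataset(seed=7)
        cfg = ep.GRUConfig(units=8, epochs=5, seed=2)
        subsets = [tuple(ep.EMG_CHANNELS), ("GA",), ("TA", "GA")]
        rows = ep.sensor_ablation([train_ds], [val_ds], subsets, cfg)
        assert [r["subset"] for r in rows] == subsets
        assert all("mae" in r for r in rows)
        baseline = rows[0]
        assert baseline["rel_change_vs_baseline"] == pytest.approx(0.0)

    def test_failed_subset_reported_not_fatal(self):
        train_ds = toy_dataset(seed=8)
        rows = ep.sensor_ablation([train_ds], [train_ds],
                                  [("GA",), ("nope",)],
                                  ep.GRUConfig(units=4, epochs=2, seed=0))
        by_subset = {r["subset"]: r for r in rows}
        assert "error" in by_subset[("nope",)]
        assert "mae" in by_subset[("GA",)]
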