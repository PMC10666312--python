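"""The CNN regressor: architecture contracts, gradients, training loop and
early stopping."""

import numpy as np
import pytest

from mirex._nn import Net
from mirex.encoding import Batch, ModelData
from mirex.model import ExpressionCNN, ModelConfig, TrainConfig


def _small_data(n_train=24, n_val=8, n_test=8, width=60, k=0, seed=0):
    rng = np.random.default_rng(seed)

    def batch(n, prefix):
        ids = [f"{prefix}{i}" for i in range(n)]
        X = np.zeros((n, width, 4), dtype=np.float32)
        codes = rng.integers(0, 4, size=(n, width))
        X[np.arange(n)[:, None], np.arange(width)[None, :], codes] = 1.0
        H = rng.standard_normal((n, 8)).astype(np.float32)
        M = rng.random((n, k)).astype(np.float32)
        y = (H @ np.linspace(0.5, -0.5, 8) + (M.sum(axis=1) if k else 0)).astype(np.float32)
        return Batch(ids, X, H, M, y)

    return ModelData(batch(n_train, "tr"), batch(n_val, "va"), batch(n_test, "te"),
                     [f"m{i}" for i in range(k)])


def _cfg(width=60, k=0, **kw):
    kw.setdefault("conv_blocks", ((4, 5, 1, 8),))
    kw.setdefault("dense_units", 8)
    return ModelConfig(window=width, k_mirnas=k, **kw)


class TestArchitecture:
    def test_forward_returns_finite_scalar_per_gene(self):
        data = _small_data(k=3)
        model = ExpressionCNN(data.subset_mirnas(["m0", "m1", "m2"]), _cfg(k=3))
        res = model.fit(TrainConfig(batch_size=8, learning_rate=0.01, max_epochs=2, patience=1, seed=0))
        pred = res.predict(data.test)
        assert pred.shape == (8,) and np.isfinite(pred).all()

    def test_zero_mirnas_is_baseline_parameter_count(self):
        rng = np.random.default_rng(0)
        n0 = Net(60, ((4, 5, 1, 8),), 8, 0.0, 0, rng).n_params
        n0b = Net(60, ((4, 5, 1, 8),), 8, 0.0, 0, np.random.default_rng(1)).n_params
        assert n0 == n0b

    def test_mirna_columns_widen_first_dense_layer_only(self):
        # adding K miRNA inputs adds exactly K * dense_units parameters
        rng = np.random.default_rng(0)
        for dense in (8, 16):
            n0 = Net(60, ((4, 5, 1, 8),), dense, 0.0, 0, rng).n_params
            n10 = Net(60, ((4, 5, 1, 8),), dense, 0.0, 10, rng).n_params
            assert n10 - n0 == 10 * dense

    def test_pool_wider_than_sequence_is_config_error(self):
        with pytest.raises(ValueError):
            ModelConfig(window=20, conv_blocks=((4, 5, 1, 30),))

    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(3)
        net = Net(40, ((3, 5, 1, 4), (2, 3, 2, 2)), 5, 0.0, 2, rng)
        X = rng.random((4, 40, 4)).astype(np.float32)
        H = rng.standard_normal((4, 8)).astype(np.float32)
        M = rng.standard_normal((4, 2)).astype(np.float32)
        y = rng.standard_normal(4).astype(np.float32)
        out, cache = net.forward(X, H, M)
        grads = net.backward(cache, (2.0 / 4) * (out - y))

        def loss():
            o, _ = net.forward(X, H, M)
            return float(np.mean((o - y) ** 2))

        eps = 1e-3
        checked = 0
        for pi, p in enumerate(net.params):
            flat = p.reshape(-1)
            for j in range(0, flat.size, max(1, flat.size // 3)):
                old = flat[j]
                flat[j] = old + eps
                lp = loss()
                flat[j] = old - eps
                lm = loss()
                flat[j] = old
                num = (lp - lm) / (2 * eps)
                ana = grads[pi].reshape(-1)[j]
                assert abs(num - ana) <= 1e-2 * max(1.0, abs(num)), (pi, j)
                checked += 1
        assert checked >= 10


class TestTraining:
    def test_forced_worsening_stops_after_patience_extra_epochs(self, monkeypatch):
        data = _small_data()
        model = ExpressionCNN(data, _cfg())
        losses = iter(float(i) for i in range(1, 1000))  # strictly worsening
        monkeypatch.setattr(model, "_validation_loss", lambda net: next(losses))
        res = model.fit(TrainConfig(batch_size=8, learning_rate=0.001, max_epochs=50, patience=7, seed=0))
        assert res.epochs_run == 1 + 7
        assert res.best_epoch == 1

    def test_always_improving_runs_all_epochs(self, monkeypatch):
        data = _small_data()
        model = ExpressionCNN(data, _cfg())
        losses = iter(1.0 / i for i in range(1, 1000))  # strictly improving
        monkeypatch.setattr(model, "_validation_loss", lambda net: next(losses))
        res = model.fit(TrainConfig(batch_size=8, learning_rate=0.001, max_epochs=12, patience=5, seed=0))
        assert res.epochs_run == 12
        assert res.best_epoch == 12

    def test_same_seed_is_bit_identical(self):
        data = _small_data()
        tcfg = TrainConfig(batch_size=8, learning_rate=0.01, max_epochs=6, patience=5, seed=42)
        a = ExpressionCNN(data, _cfg()).fit(tcfg)
        b = ExpressionCNN(data, _cfg()).fit(tcfg)
        assert a.val_loss_curve == b.val_loss_curve
        assert a.predictions == b.predictions

    def test_residual_identity_holds_exactly(self):
        data = _small_data()
        res = ExpressionCNN(data, _cfg()).fit(
            TrainConfig(batch_size=8, learning_rate=0.01, max_epochs=4, patience=3, seed=1)
        )
        y_true = {g: float(v) for b in (data.train, data.val, data.test) for g, v in zip(b.gene_ids, b.y)}
        for g, r in res.residuals.items():
            assert r == y_true[g] - res.predictions[g]

    def test_early_stop_bound(self):
        data = _small_data()
        res = ExpressionCNN(data, _cfg()).fit(
            TrainConfig(batch_size=8, learning_rate=0.01, max_epochs=30, patience=4, seed=2)
        )
        assert res.epochs_run - res.best_epoch <= 4

    def test_divergent_learning_rate_aborts_with_diagnostic(self):
        data = _small_data()
        with pytest.raises(FloatingPointError, match="learning rate"):
            ExpressionCNN(data, _cfg()).fit(
                TrainConfig(batch_size=8, learning_rate=1e4, max_epochs=5, patience=3, seed=0)
            )

    def test_empty_validation_set_rejected(self):
        data = _small_data()
        empty = Batch([], np.zeros((0, 60, 4), np.float32), np.zeros((0, 8), np.float32),
                      np.zeros((0, 0), np.float32), np.zeros(0, np.float32))
        with pytest.raises(ValueError, match="validation"):
            ExpressionCNN(ModelData(data.train, empty, data.test, []), _cfg())


@pytest.fixture(scope="module")
def trained():
    data = _small_data(k=2)
    res = ExpressionCNN(data, _cfg(k=2, dropout=0.2)).fit(
        TrainConfig(batch_size=8, learning_rate=0.01, max_epochs=15, patience=10, seed=0)
    )
    return data, res


class TestPredict:

    def test_single_row_batch(self, trained):
        data, res = trained
        one = Batch(data.test.gene_ids[:1], data.test.X[:1], data.test.H[:1],
                    data.test.M[:1], data.test.y[:1])
        assert res.predict(one).shape == (1,)

    def test_batching_invariance(self, trained):
        data, res = trained
        full = res.predict(data.test)
        halves = np.concatenate([
            res.predict(Batch(data.test.gene_ids[:4], data.test.X[:4], data.test.H[:4],
                              data.test.M[:4], data.test.y[:4])),
            res.predict(Batch(data.test.gene_ids[4:], data.test.X[4:], data.test.H[4:],
                              data.test.M[4:], data.test.y[4:])),
        ])
        assert np.allclose(full, halves)

    def test_dropout_disabled_at_prediction(self, trained):
        data, res = trained
        assert np.array_equal(res.predict(data.test), res.predict(data.test))

    def test_mirna_inputs_affect_trained_model(self, trained):
        data, res = trained
        perturbed = Batch(data.test.gene_ids, data.test.X, data.test.H,
                          data.test.M + 1.0, data.test.y)
        assert not np.allclose(res.predict(data.test), res.predict(perturbed))

    def test_baseline_cannot_see_mirna_inputs(self):
        data = _small_data(k=0)
        res = ExpressionCNN(data, _cfg(k=0)).fit(
            TrainConfig(batch_size=8, learning_rate=0.01, max_epochs=3, patience=2, seed=0)
        )
        assert res.predict(data.test).shape == (8,)  # no M block to perturb
        with pytest.raises(ValueError, match="miRNA"):
            res.predict(Batch(data.test.gene_ids, data.test.X, data.test.H,
                              np.ones((8, 3), np.float32), data.test.y))

    def test_shape_mismatch_rejected(self, trained):
        data, res = trained
        with pytest.raises(ValueError, match="shape"):
            res.predict(Batch(["x"], np.zeros((1, 10, 4), np.float32),
                              np.zeros((1, 8), np.float32), np.zeros((1, 2), np.float32),
                              np.zeros(1, np.float32)))


def test_summary_reports_fit_metrics():
    data = _small_data()
    res = ExpressionCNN(data, _cfg()).fit(
        TrainConfig(batch_size=8, learning_rate=0.01, max_epochs=4, patience=3, seed=0)
    )
    text = res.summary()
    assert "test R2" in text and "best epoch" in text


def test_results_json_round_trip(tmp_path):
    from mirex.model import CNNResults

    data = _small_data()
    res = ExpressionCNN(data, _cfg()).fit(
        TrainConfig(batch_size=8, learning_rate=0.01, max_epochs=4, patience=3, seed=0)
    )
    path = tmp_path / "run.json"
    res.to_json(path)
    loaded = CNNResults.from_json(path)
    assert loaded.predictions == res.predictions
    assert loaded.val_loss_curve == res.val_loss_curve
    assert loaded.r2_test == res.r2_test
    assert loaded.residual_map() == res.residual_map()
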