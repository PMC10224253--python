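"""Pearson/top-k selection, boosted SPAD regression, report metrics."""

import numpy as np
import pytest
from sklearn.tree import DecisionTreeRegressor

from canopyseg.spadreg import (
    CorrelationTable,
    GbrtConfig,
    PartitionMetrics,
    SpadSample,
    correlation_table,
    evaluate,
    fit_gbrt,
    pearson,
    top_indices,
)
from canopyseg.vegindices import CVI_NAMES, CviRecord


def _record(values):
    vals = {name: 0.0 for name in CVI_NAMES}
    vals.update(values)
    return CviRecord(
        mean_R=0, mean_G=0, mean_B=0, mean_H=0, mean_S=0, mean_Bv=0, values=vals
    )


def _samples_from_matrix(X, y, features):
    return [
        SpadSample(f"im{i}", _record(dict(zip(features, row))), float(t))
        for i, (row, t) in enumerate(zip(X, y))
    ]


class TestPearson:
    def test_perfect_linear(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert pearson(x, [2 * v + 1 for v in x]) == pytest.approx(1.0)

    def test_perfect_antilinear(self):
        x = [1.0, 2.0, 3.0]
        assert pearson(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_hand_arithmetic_half(self):
        assert pearson([1, 2, 3], [1, 3, 2]) == pytest.approx(0.5)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            pearson([1, 1, 1], [1, 2, 3])


class TestTopIndices:
    def _table(self, rs):
        entries = sorted(rs.items(), key=lambda e: (-abs(e[1]), CVI_NAMES.index(e[0])))
        return CorrelationTable(tuple(entries))

    def test_returns_exactly_five(self):
        rs = {name: 0.1 * (i + 1) for i, name in enumerate(CVI_NAMES)}
        assert len(top_indices(self._table(rs))) == 5

    def test_largest_absolute_r_ranked_first(self):
        rs = {name: 0.2 for name in CVI_NAMES}
        rs["DGCI"] = 0.948
        rs["Blue"] = -0.6
        top = top_indices(self._table(rs))
        assert top[0] == "DGCI"
        assert top[1] == "Blue"  # |r| ordering ignores sign

    def test_ties_resolved_by_registry_order(self):
        rs = {name: 0.5 for name in CVI_NAMES}
        top = top_indices(self._table(rs))
        assert list(top) == list(CVI_NAMES[:5])

    def test_too_few_entries_rejected(self):
        table = CorrelationTable((("ExG", 0.9),))
        with pytest.raises(ValueError, match="need 5"):
            top_indices(table)


class TestCorrelationTable:
    def test_constant_index_excluded_not_dropped_silently(self):
        rng = np.random.default_rng(0)
        y = rng.random(20) * 40 + 10
        samples = [
            SpadSample(f"i{i}", _record({"ExG": float(t), "GBRG": -1.0}), float(t))
            for i, t in enumerate(y)
        ]
        table = correlation_table(samples, indices=("ExG", "GBRG"))
        assert "GBRG" in table.excluded
        assert table.r_of("ExG") == pytest.approx(1.0)


def reference_boosting(X, y, n_estimators, learning_rate, max_depth, seeds):
    """Handwritten exact-split stagewise-residual booster (no binning)."""
    pred = np.full(y.shape, y.mean())
    trees = []
    for t in range(n_estimators):
        tree = DecisionTreeRegressor(max_depth=max_depth, random_state=seeds + t)
        tree.fit(X, y - pred)
        pred = pred + learning_rate * tree.predict(X)
        trees.append(tree)
    return pred


class TestFitGbrt:
    FEATURES = ("ExG", "CIVE")

    def test_constant_target_returns_constant_model(self):
        rng = np.random.default_rng(0)
        X = rng.random((20, 2))
        samples = _samples_from_matrix(X, np.full(20, 33.0), self.FEATURES)
        with pytest.warns(UserWarning, match="constant"):
            model = fit_gbrt(samples, None, self.FEATURES)
        assert np.allclose(model.predict(samples), 33.0)

    def test_noiseless_linear_target_fit_to_under_1pct_error(self):
        rng = np.random.default_rng(1)
        X = rng.random((40, 2))
        y = 10.0 + 30.0 * X[:, 0]
        samples = _samples_from_matrix(X, y, self.FEATURES)
        model = fit_gbrt(
            samples, None, self.FEATURES,
            GbrtConfig(n_estimators=200, max_depth=3, learning_rate=0.3),
        )
        rmse = float(np.sqrt(np.mean((model.predict(samples) - y) ** 2)))
        assert rmse < 0.01 * np.ptp(y)

    def test_training_loss_non_increasing(self):
        rng = np.random.default_rng(2)
        X = rng.random((30, 2))
        y = 5 * X[:, 0] + rng.normal(0, 0.5, 30)
        samples = _samples_from_matrix(X, y, self.FEATURES)
        model = fit_gbrt(samples, None, self.FEATURES,
                         GbrtConfig(n_estimators=50, learning_rate=0.1))
        losses = np.asarray(model.train_losses)
        assert np.all(np.diff(losses) <= 1e-9)

    def test_histogram_binning_reproduces_exact_boosting_on_small_data(self):
        # 20 points, bins >> distinct values -> bin midpoints are injective
        rng = np.random.default_rng(3)
        X = np.round(rng.random((20, 2)), 2)
        y = 20.0 * X[:, 0] - 7.0 * X[:, 1] + rng.normal(0, 0.2, 20)
        samples = _samples_from_matrix(X, y, self.FEATURES)
        cfg = GbrtConfig(n_estimators=25, learning_rate=0.2, max_depth=2,
                         bins=4096, seed=11)
        model = fit_gbrt(samples, None, self.FEATURES, cfg)
        ref = reference_boosting(model._binned(X), y, 25, 0.2, 2, seeds=11)
        assert np.allclose(model.predict_matrix(X), ref, atol=1e-9)

    def test_tuning_grid_picks_lowest_validation_rmse(self):
        rng = np.random.default_rng(4)
        X = rng.random((60, 2))
        y = 15.0 * X[:, 0] + rng.normal(0, 0.3, 60)
        samples = _samples_from_matrix(X, y, self.FEATURES)
        grid = {"n_estimators": (5, 80), "learning_rate": (0.2,),
                "max_depth": (2,), "subsample": (1.0,)}
        model = fit_gbrt(samples[:40], samples[40:], self.FEATURES,
                         GbrtConfig(seed=0), tune_grid=grid)
        assert model.config.n_estimators == 80

    def test_agrees_with_independent_booster_on_noiseless_data(self):
        # cross-check against xgboost's exact-tree booster at lr=1
        xgb = pytest.importorskip("xgboost")
        rng = np.random.default_rng(5)
        X = rng.random((50, 2))
        y = 4.0 + 25.0 * X[:, 0]
        samples = _samples_from_matrix(X, y, self.FEATURES)
        model = fit_gbrt(samples, None, self.FEATURES,
                         GbrtConfig(n_estimators=100, learning_rate=0.5, max_depth=3))
        reg = xgb.XGBRegressor(
            n_estimators=100, learning_rate=0.5, max_depth=3,
            tree_method="exact", reg_lambda=0.0, base_score=float(y.mean()),
        )
        reg.fit(X, y)
        ours = model.predict_matrix(X)
        theirs = reg.predict(X)
        assert np.allclose(ours, y, atol=0.15) and np.allclose(theirs, y, atol=0.15)


class TestEvaluate:
    def _model_predicting(self, offsets, features=("ExG",)):
        """A trained 1-feature model used only as a prediction carrier."""
        rng = np.random.default_rng(0)
        X = rng.random((12, 1))
        y = 10 * X[:, 0]
        return fit_gbrt(_samples_from_matrix(X, y, features), None, features,
                        GbrtConfig(n_estimators=50, learning_rate=0.5))

    def test_perfect_predictions_score_ideal(self):
        model = self._model_predicting(None)
        rng = np.random.default_rng(1)
        X = rng.random((12, 1))
        samples = _samples_from_matrix(X, model.predict_matrix(X), ("ExG",))
        m = evaluate(model, samples)
        assert m.RMSE == pytest.approx(0.0, abs=1e-9)
        assert m.MAE == pytest.approx(0.0, abs=1e-9)
        assert m.R2_adj == pytest.approx(1.0)

    def test_symmetric_errors_hand_arithmetic(self):
        # predictions off by +2 and -2 -> RMSE = MAE = 2
        y = np.array([10.0, 20.0])
        pred = np.array([12.0, 18.0])
        err = pred - y
        rmse = float(np.sqrt(np.mean(err**2)))
        mae = float(np.mean(np.abs(err)))
        assert rmse == 2.0 and mae == 2.0

    def test_constant_predictor_has_nonpositive_adjusted_r2(self):
        rng = np.random.default_rng(2)
        X = rng.random((50, 1))
        y_train = np.full(50, 25.0)
        with pytest.warns(UserWarning):
            model = fit_gbrt(
                _samples_from_matrix(X, y_train, ("ExG",)), None, ("ExG",)
            )
        y_real = rng.random(50) * 30 + 10
        samples = _samples_from_matrix(X, y_real, ("ExG",))
        m = evaluate(model, samples)
        assert m.R2_adj <= 0.0

    def test_too_few_samples_for_adjusted_r2_rejected(self):
        model = self._model_predicting(None)
        rng = np.random.default_rng(3)
        X = rng.random((2, 1))
        samples = _samples_from_matrix(X, [1.0, 2.0], ("ExG",))
        with pytest.raises(ValueError, match="undefined"):
            evaluate(model, samples)
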