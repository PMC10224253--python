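"""MLP forward/backward consistency, RF/SVM defaults, image segmentation."""

import math

import numpy as np
import pytest

from canopyseg.dataset import PixelDataset, SplitSpec, split
from canopyseg.evalmetrics import classification_metrics
from canopyseg.segmenters import (
    MlpModel,
    TrainConfig,
    grid_search_neurons,
    load_model,
    repeat_train,
    save_model,
    segment_image,
    train_mlp,
    train_rf,
    train_svm,
)

FAST = TrainConfig(epochs=15, patience=0, seed=0)


def _split(ds, seed=0):
    return split(ds, SplitSpec((3, 1, 1), seed=seed))


def literal_forward(model, x):
    """Triple-loop evaluation of the perceptron output formula."""
    hidden = []
    for j in range(model.m):
        s = model.W_jb[j]
        for i in range(model.n_inputs):
            s += model.W_ji[i, j] * x[i]
        hidden.append(max(s, 0.0))
    z = model.W_kb
    for j in range(model.m):
        z += model.W_kj[j] * hidden[j]
    return 1.0 / (1.0 + math.exp(-z))


class TestMlpForward:
    def test_literal_formula_matches_predictions(self, separable_pixels):
        tr, va, _ = _split(separable_pixels)
        model, _ = train_mlp(tr, va, FAST)
        rng = np.random.default_rng(0)
        X = rng.random((100, 2))
        p_model = model.predict_proba(X)
        for k in range(100):
            assert abs(literal_forward(model, X[k]) - p_model[k]) < 1e-9

    def test_one_sgd_step_matches_hand_computed_update(self):
        # 1-input / 1-hidden / 1-output network, one sample (x=0.5, y=1)
        model = MlpModel(
            W_ji=np.array([[0.8]]), W_jb=np.array([0.1]),
            W_kj=np.array([-0.4]), W_kb=0.2,
        )
        x, y, lr = 0.5, 1.0, 0.1
        a1 = 0.8 * x + 0.1          # hidden pre-activation (positive)
        h = a1
        p = 1.0 / (1.0 + math.exp(-(-0.4 * h + 0.2)))
        d_out = p - y               # dE/dz for logistic + cross-entropy
        exp_Wkj = -0.4 - lr * (d_out * h)
        exp_Wkb = 0.2 - lr * d_out
        d_h = d_out * -0.4          # times ReLU'(a1) = 1
        exp_Wji = 0.8 - lr * (d_h * x)
        exp_Wjb = 0.1 - lr * d_h

        model.sgd_step(np.array([[x]]), np.array([y]), lr)
        assert abs(model.W_kj[0] - exp_Wkj) < 1e-9
        assert abs(model.W_kb - exp_Wkb) < 1e-9
        assert abs(model.W_ji[0, 0] - exp_Wji) < 1e-9
        assert abs(model.W_jb[0] - exp_Wjb) < 1e-9


class TestMlpTraining:
    def test_separable_clusters_reach_perfect_validation_accuracy(
        self, separable_pixels
    ):
        tr, va, _ = _split(separable_pixels)
        _, report = train_mlp(tr, va, FAST)
        assert report.accuracy == 1.0

    def test_shuffled_labels_give_chance_accuracy(self, separable_pixels):
        rng = np.random.default_rng(0)
        shuffled = PixelDataset(
            separable_pixels.X, rng.permutation(separable_pixels.y),
            separable_pixels.channel_names,
        )
        tr, va, _ = _split(shuffled)
        _, report = train_mlp(tr, va, FAST)
        # binomial 3-sigma band around 0.5 on the validation rows
        sigma = math.sqrt(0.25 / va.n_rows)
        assert abs(report.accuracy - 0.5) < 3 * sigma

    def test_same_seed_reproduces_identical_weights(self, separable_pixels):
        tr, va, _ = _split(separable_pixels)
        m1, _ = train_mlp(tr, va, FAST)
        m2, _ = train_mlp(tr, va, FAST)
        assert np.array_equal(m1.W_ji, m2.W_ji)
        assert np.array_equal(m1.W_kj, m2.W_kj)
        assert m1.W_kb == m2.W_kb

    def test_single_class_training_rejected(self, separable_pixels):
        tr, va, _ = _split(separable_pixels)
        mono = PixelDataset(tr.X, np.zeros_like(tr.y), tr.channel_names)
        with pytest.raises(ValueError, match="both classes"):
            train_mlp(mono, va, FAST)


class TestGridSearch:
    def test_singleton_candidate_returned_directly(self, separable_pixels):
        tr, va, _ = _split(separable_pixels)
        assert grid_search_neurons(tr, va, [20]) == 20

    def test_tie_broken_toward_smaller_count(self, separable_pixels):
        # both widths solve the separable problem -> identical CV accuracy
        tr, va, _ = _split(separable_pixels)
        cfg = TrainConfig(epochs=8, patience=0, seed=0)
        chosen = grid_search_neurons(tr, va, [35, 20], k=5, config=cfg)
        assert chosen == 20

    def test_k_larger_than_class_count_rejected(self, separable_pixels):
        take = np.r_[np.arange(4), np.arange(-4, 0)]  # 4 rows per class
        small = PixelDataset(
            separable_pixels.X[take], separable_pixels.y[take],
            separable_pixels.channel_names,
        )
        tr = va = small
        with pytest.raises(ValueError, match="class count"):
            grid_search_neurons(tr, va, [12, 20], k=10)


class TestRfSvm:
    def test_rf_perfect_on_separable_clusters_with_200_trees(
        self, separable_pixels
    ):
        tr, va, _ = _split(separable_pixels)
        model, report = train_rf(tr, va, seed=0)
        assert report.accuracy == 1.0
        assert len(model.clf.estimators_) == 200
        assert model.clf.max_depth == 20
        assert model.clf.min_samples_leaf == 4

    def test_svm_defaults_echo_tuned_hyperparameters(self, separable_pixels):
        tr, va, _ = _split(separable_pixels)
        model, _ = train_svm(tr, va, seed=0)
        assert model.clf.C == 0.001
        assert model.clf.gamma == 1.0
        assert model.clf.kernel == "rbf"

    def test_svm_subsamples_oversized_training_sets(self, separable_pixels):
        tr, va, _ = _split(separable_pixels)
        with pytest.warns(UserWarning, match="subsampled"):
            train_svm(tr, va, seed=0, max_rows=100)


class TestRepeatTrain:
    def test_single_seed_equals_one_run(self, separable_pixels):
        trainer = lambda tr, va, seed: train_rf(tr, va, seed, n_estimators=20)
        agg = repeat_train(trainer, separable_pixels, seeds=[0])
        tr, va, te = _split(separable_pixels, seed=0)
        model, _ = train_rf(tr, va, 0, n_estimators=20)
        rep = classification_metrics(model.predict(te.X), te.y)
        assert agg["accuracy"] == (rep.accuracy, 0.0)

    def test_separable_fixture_mean_perfect_sd_zero(self, separable_pixels):
        trainer = lambda tr, va, seed: train_rf(tr, va, seed, n_estimators=20)
        agg = repeat_train(trainer, separable_pixels, seeds=[0, 1, 2])
        assert agg["accuracy"] == (1.0, 0.0)

    def test_noisy_fixture_has_seed_variation(self):
        rng = np.random.default_rng(0)
        n = 300
        X = np.clip(rng.normal([[0.45]] * n + [[0.55]] * n, 0.15), 0, 1)
        y = np.r_[np.zeros(n, np.uint8), np.ones(n, np.uint8)]
        ds = PixelDataset(X, y, ("rgb.G",))
        trainer = lambda tr, va, seed: train_rf(tr, va, seed, n_estimators=10)
        agg = repeat_train(trainer, ds, seeds=range(5))
        assert agg["accuracy"][1] > 0.0


@pytest.fixture(scope="module")
def color_model():
    """MLP trained on RGB features of green-plant vs brown-soil clusters."""
    rng = np.random.default_rng(0)
    n = 500
    fg = np.array([40, 160, 50]) / 255 + rng.normal(0, 0.02, (n, 3))
    bg = np.array([80, 60, 40]) / 255 + rng.normal(0, 0.02, (n, 3))
    ds = PixelDataset(
        np.clip(np.vstack([fg, bg]), 0, 1),
        np.r_[np.ones(n, np.uint8), np.zeros(n, np.uint8)],
        ("rgb.R", "rgb.G", "rgb.B"),
    )
    tr, va, _ = _split(ds)
    model, report = train_mlp(
        tr, va, TrainConfig(epochs=150, learning_rate=0.05, patience=0, seed=0)
    )
    assert report.accuracy == 1.0
    return model


class TestSegmentImage:
    def test_foreground_color_image_fully_segmented(self, color_model):
        img = np.zeros((5, 6, 3), dtype=np.uint8)
        img[:] = (40, 160, 50)
        mask = segment_image(color_model, img, ("rgb.R", "rgb.G", "rgb.B"))
        assert mask.shape == (5, 6)
        assert np.all(mask == 255)

    def test_background_color_image_fully_rejected(self, color_model):
        img = np.zeros((4, 4, 3), dtype=np.uint8)
        img[:] = (80, 60, 40)
        mask = segment_image(color_model, img, ("rgb.R", "rgb.G", "rgb.B"))
        assert np.all(mask == 0)

    def test_channel_mismatch_rejected(self, color_model):
        img = np.zeros((2, 2, 3), dtype=np.uint8)
        with pytest.raises(ValueError, match="trained on channels"):
            segment_image(color_model, img, ("hsv.H",))

    def test_model_persistence_round_trip(self, color_model, tmp_path):
        path = tmp_path / "model.bin"
        save_model(color_model, path)
        back = load_model(path)
        img = np.zeros((3, 3, 3), dtype=np.uint8)
        img[:] = (40, 160, 50)
        assert np.array_equal(
            segment_image(back, img, ("rgb.R", "rgb.G", "rgb.B")),
            segment_image(color_model, img, ("rgb.R", "rgb.G", "rgb.B")),
        )
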