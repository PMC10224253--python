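"""Pixel classifiers: a back-propagation MLP plus RF and SVM references.

The central segmenter is a single-hidden-layer perceptron operating on the
selected color channels of each pixel.  Its forward pass is

    P = alpha_0 [ sum_j W_kj * alpha_h( sum_i W_ji * X_i + W_jb ) + W_kb ]

with ReLU as the hidden activation ``alpha_h`` and a logistic output
``alpha_0`` thresholded at 0.5.  Training minimises binary cross-entropy by
mini-batch stochastic gradient descent, updating every weight as
``W <- W - a * dError/dW`` with learning rate ``a``.  The implementation is
plain NumPy so that the update rule is exactly the stated one (no momentum,
no adaptive scaling), and a fixed seed yields bit-identical models.

Random forest and support-vector classifiers (scikit-learn) are provided
with the tuned hyperparameters used for comparison: RF with 200 trees,
max depth 20, min samples per leaf 4, final label from the averaged class
probability; SVM with an RBF kernel, C = 0.001, gamma = 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .colorspaces import to_feature_stack
from .dataset import PixelDataset, SplitSpec, split
from .evalmetrics import ClassificationReport, classification_metrics
from .featsel import SelectedChannels

__all__ = [
    "TrainConfig",
    "MlpModel",
    "RfSegmenter",
    "SvmSegmenter",
    "train_mlp",
    "train_rf",
    "train_svm",
    "grid_search_neurons",
    "repeat_train",
    "segment_image",
    "save_model",
    "load_model",
    "SVM_MAX_TRAIN_ROWS",
]

#: Training-set cap for the SVM (kernel fits scale quadratically in rows).
SVM_MAX_TRAIN_ROWS = 100_000

DEFAULT_NEURON_CANDIDATES = (12, 20, 35, 60, 100)


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of the SGD loop."""

    learning_rate: float = 0.01
    epochs: int = 50
    batch_size: int = 256
    seed: int = 0
    patience: int = 5  # early-stop patience on validation loss; 0 disables
    hidden_neurons: int = 20

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class MlpModel:
    """Single-hidden-layer perceptron for binary pixel classification.

    Weight layout: ``W_ji`` (n_inputs, m) input-to-hidden, ``W_jb`` (m,)
    hidden biases, ``W_kj`` (m,) hidden-to-output, ``W_kb`` scalar output
    bias.  Hidden activation ReLU, output activation logistic.
    """

    W_ji: np.ndarray
    W_jb: np.ndarray
    W_kj: np.ndarray
    W_kb: float
    channel_names: tuple[str, ...] = ()

    kind = "mlp"

    @property
    def n_inputs(self) -> int:
        return self.W_ji.shape[0]

    @property
    def m(self) -> int:
        return self.W_ji.shape[1]

    @classmethod
    def initialise(
        cls, n_inputs: int, m: int, seed: int, channel_names: Sequence[str] = ()
    ) -> "MlpModel":
        rng = np.random.default_rng(seed)
        # He scaling for the ReLU layer, Xavier for the logistic output
        w1 = rng.normal(0.0, np.sqrt(2.0 / n_inputs), size=(n_inputs, m))
        w2 = rng.normal(0.0, np.sqrt(1.0 / m), size=m)
        return cls(w1, np.zeros(m), w2, 0.0, tuple(channel_names))

    def hidden(self, X: np.ndarray) -> np.ndarray:
        return np.maximum(X @ self.W_ji + self.W_jb, 0.0)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        z = self.hidden(X) @ self.W_kj + self.W_kb
        return 1.0 / (1.0 + np.exp(-z))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X) >= 0.5).astype(np.uint8)

    def loss(self, X: np.ndarray, y: np.ndarray) -> float:
        p = np.clip(self.predict_proba(X), 1e-12, 1.0 - 1e-12)
        return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))

    def sgd_step(self, X: np.ndarray, y: np.ndarray, learning_rate: float) -> None:
        """One in-place gradient-descent update on a mini-batch.

        Error is the mean binary cross-entropy of the batch; the ReLU
        subgradient at 0 is taken as 0.
        """
        n = X.shape[0]
        a1 = X @ self.W_ji + self.W_jb
        h = np.maximum(a1, 0.0)
        p = 1.0 / (1.0 + np.exp(-(h @ self.W_kj + self.W_kb)))

        delta_out = (p - y) / n            # dE/dz_out, logistic + BCE
        grad_Wkj = h.T @ delta_out
        grad_Wkb = float(delta_out.sum())
        delta_h = np.outer(delta_out, self.W_kj) * (a1 > 0)
        grad_Wji = X.T @ delta_h
        grad_Wjb = delta_h.sum(axis=0)

        self.W_ji -= learning_rate * grad_Wji
        self.W_jb -= learning_rate * grad_Wjb
        self.W_kj -= learning_rate * grad_Wkj
        self.W_kb -= learning_rate * grad_Wkb

    def copy(self) -> "MlpModel":
        return MlpModel(
            self.W_ji.copy(), self.W_jb.copy(), self.W_kj.copy(), self.W_kb,
            self.channel_names,
        )


def train_mlp(
    train: PixelDataset,
    val: PixelDataset,
    config: TrainConfig = TrainConfig(),
) -> tuple[MlpModel, ClassificationReport]:
    """Train the MLP by mini-batch SGD with validation-based early stopping.

    The model state with the lowest validation loss is kept; the returned
    report scores that model on the validation partition.  Deterministic
    for a fixed config seed.
    """
    if np.unique(train.y).size < 2:
        raise ValueError("training data must contain both classes")
    if train.channel_names != val.channel_names:
        raise ValueError("train and validation channel sets differ")

    rng = np.random.default_rng(config.seed)
    model = MlpModel.initialise(
        len(train.channel_names), config.hidden_neurons, config.seed,
        train.channel_names,
    )
    y = train.y.astype(np.float64)

    best = model.copy()
    best_loss = np.inf
    stall = 0
    for _epoch in range(config.epochs):
        order = rng.permutation(train.n_rows)
        for start in range(0, train.n_rows, config.batch_size):
            idx = order[start:start + config.batch_size]
            model.sgd_step(train.X[idx], y[idx], config.learning_rate)
        val_loss = model.loss(val.X, val.y.astype(np.float64))
        if not np.isfinite(val_loss):
            raise ArithmeticError(
                f"training diverged (non-finite validation loss); "
                f"reduce learning_rate={config.learning_rate}"
            )
        if val_loss < best_loss - 1e-12:
            best_loss = val_loss
            best = model.copy()
            stall = 0
        else:
            stall += 1
            if config.patience and stall >= config.patience:
                break
    report = classification_metrics(best.predict(val.X), val.y)
    return best, report


def grid_search_neurons(
    train: PixelDataset,
    val: PixelDataset,
    candidates: Sequence[int] = DEFAULT_NEURON_CANDIDATES,
    *,
    k: int = 10,
    config: TrainConfig = TrainConfig(),
) -> int:
    """Choose the hidden-layer width by k-fold cross-validated accuracy.

    The train and validation partitions are pooled, each candidate neuron
    count is scored by stratified k-fold CV, and the candidate with the
    highest mean accuracy wins; ties go to the smallest count.
    """
    if not candidates:
        raise ValueError("candidate list must be nonempty")
    if len(candidates) == 1:
        return int(candidates[0])
    X = np.vstack([train.X, val.X])
    y = np.concatenate([train.y, val.y])
    counts = np.bincount(y)
    if k > counts[counts > 0].min():
        raise ValueError(f"k={k} exceeds the smallest class count")

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=config.seed)
    folds = list(skf.split(X, y))
    best_m, best_acc = None, -1.0
    for m in sorted(candidates):
        accs = []
        for tr_idx, te_idx in folds:
            ds_tr = PixelDataset(X[tr_idx], y[tr_idx], train.channel_names)
            ds_te = PixelDataset(X[te_idx], y[te_idx], train.channel_names)
            cfg = TrainConfig(
                learning_rate=config.learning_rate, epochs=config.epochs,
                batch_size=config.batch_size, seed=config.seed,
                patience=config.patience, hidden_neurons=m,
            )
            mdl, _ = train_mlp(ds_tr, ds_te, cfg)
            accs.append(classification_metrics(mdl.predict(ds_te.X), ds_te.y).accuracy)
        mean_acc = float(np.mean(accs))
        if mean_acc > best_acc + 1e-12:  # strict: ties keep the smaller count
            best_acc, best_m = mean_acc, m
    return int(best_m)


@dataclass
class RfSegmenter:
    """Random-forest pixel classifier (averaged tree probabilities)."""

    clf: RandomForestClassifier
    channel_names: tuple[str, ...] = ()
    kind = "rf"

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.clf.predict_proba(X)[:, 1]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X) >= 0.5).astype(np.uint8)


@dataclass
class SvmSegmenter:
    """RBF-kernel SVM pixel classifier."""

    clf: SVC
    channel_names: tuple[str, ...] = ()
    kind = "svm"

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.clf.predict(X).astype(np.uint8)


def train_rf(
    train: PixelDataset,
    val: PixelDataset,
    seed: int = 0,
    *,
    n_estimators: int = 200,
    max_depth: int = 20,
    min_samples_leaf: int = 4,
) -> tuple[RfSegmenter, ClassificationReport]:
    """Train the random-forest classifier (defaults: 200 trees, depth 20,
    min leaf 4); final labels threshold the averaged class probability at 0.5."""
    if np.unique(train.y).size < 2:
        raise ValueError("training data must contain both classes")
    clf = RandomForestClassifier(
        n_estimators=n_estimators, max_depth=max_depth,
        min_samples_leaf=min_samples_leaf, random_state=seed, n_jobs=1,
    )
    clf.fit(train.X, train.y)
    model = RfSegmenter(clf, train.channel_names)
    return model, classification_metrics(model.predict(val.X), val.y)


def train_svm(
    train: PixelDataset,
    val: PixelDataset,
    seed: int = 0,
    *,
    C: float = 0.001,
    gamma: float = 1.0,
    max_rows: int = SVM_MAX_TRAIN_ROWS,
) -> tuple[SvmSegmenter, ClassificationReport]:
    """Train the RBF-kernel SVM classifier (defaults C = 0.001, gamma = 1).

    Training sets larger than ``max_rows`` are stratified-subsampled first
    (kernel training is quadratic in rows); a warning reports the reduction.
    """
    if np.unique(train.y).size < 2:
        raise ValueError("training data must contain both classes")
    X, y = train.X, train.y
    if X.shape[0] > max_rows:
        rng = np.random.default_rng(seed)
        keep = []
        for c in np.unique(y):
            idx = np.flatnonzero(y == c)
            n_keep = int(round(max_rows * idx.size / y.size))
            keep.append(rng.choice(idx, size=n_keep, replace=False))
        keep = np.sort(np.concatenate(keep))
        warnings.warn(
            f"SVM training subsampled from {X.shape[0]} to {keep.size} rows "
            f"(cap {max_rows})"
        )
        X, y = X[keep], y[keep]
    clf = SVC(kernel="rbf", C=C, gamma=gamma, random_state=seed)
    clf.fit(X, y)
    model = SvmSegmenter(clf, train.channel_names)
    return model, classification_metrics(model.predict(val.X), val.y)


def repeat_train(
    trainer: Callable[[PixelDataset, PixelDataset, int], tuple[object, ClassificationReport]],
    dataset: PixelDataset,
    seeds: Sequence[int] = tuple(range(100)),
    *,
    ratios: tuple[float, ...] = (3, 1, 1),
) -> dict[str, tuple[float, float]]:
    """Repeat split-train-test over seeds and aggregate the test metrics.

    For each seed the dataset is re-split (stratified, ``ratios``), the
    trainer is rerun, and the model is scored on the held-out test part.
    Returns mean and population sd of accuracy, F-score and recall.
    """
    if not seeds:
        raise ValueError("seed list must be nonempty")
    acc, fsc, rec = [], [], []
    for seed in seeds:
        tr, va, te = split(dataset, SplitSpec(ratios, seed=seed, stratified=True))
        model, _ = trainer(tr, va, seed)
        rep = classification_metrics(model.predict(te.X), te.y)
        acc.append(rep.accuracy)
        fsc.append(rep.f_score)
        rec.append(rep.recall)
    agg = {}
    for name, vals in (("accuracy", acc), ("f_score", fsc), ("recall", rec)):
        v = np.asarray(vals)
        agg[name] = (float(v.mean()), float(v.std(ddof=0)))
    return agg


def segment_image(
    model,
    image: np.ndarray,
    channels: SelectedChannels | Sequence[str],
) -> np.ndarray:
    """Classify every pixel of an RGB image into a {0, 255} plant mask."""
    names = tuple(channels.names if isinstance(channels, SelectedChannels) else channels)
    if tuple(model.channel_names) and tuple(model.channel_names) != names:
        raise ValueError(
            f"model was trained on channels {model.channel_names}, "
            f"segmentation requested {names}"
        )
    stack = to_feature_stack(image).restrict(names)
    labels = model.predict(stack.as_matrix())
    return (labels.reshape(stack.height, stack.width) * 255).astype(np.uint8)


_MODEL_FORMAT = "canopyseg-model"
_MODEL_VERSION = 1


def save_model(model, path) -> None:
    """Persist a trained segmenter to a single versioned file."""
    joblib.dump(
        {"format": _MODEL_FORMAT, "version": _MODEL_VERSION,
         "kind": model.kind, "model": model},
        path,
    )


def load_model(path):
    payload = joblib.load(path)
    if not isinstance(payload, dict) or payload.get("format") != _MODEL_FORMAT:
        raise ValueError(f"{path} is not a canopyseg model file")
    if payload.get("version") != _MODEL_VERSION:
        raise ValueError(f"unsupported model version {payload.get('version')}")
    return payload["model"]
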