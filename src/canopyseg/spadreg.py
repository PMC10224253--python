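"""SPAD (leaf greenness) regression from region color vegetation indices.

Region CVIs extracted from segmented plant images are Pearson-correlated
with measured SPAD values; the five indices with the largest |r| become the
predictors of a gradient-boosted regression-tree (GBRT) model.  The booster
is stagewise least squares: the initial model is the target mean, and each
regression tree is fitted to the residuals of the running ensemble, whose
prediction advances by ``learning_rate`` times the new tree.  Split finding
is histogram-based — every feature is discretised onto uniform bins and
trees see only the bin midpoints — which bounds the split-search cost on
large cohorts and reproduces exact-split boosting whenever the bin count
exceeds the number of distinct feature values.

Model quality is reported as RMSE, MAE and the adjusted determination
coefficient ``R2_adj = 1 - (1 - R^2)(n - 1)/(n - p - 1)`` with p predictors.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as _stats
from sklearn.tree import DecisionTreeRegressor

from .vegindices import CVI_NAMES, CviRecord

__all__ = [
    "SpadSample",
    "CorrelationTable",
    "GbrtConfig",
    "GbrtModel",
    "PartitionMetrics",
    "RegressionReport",
    "pearson",
    "correlation_table",
    "top_indices",
    "fit_gbrt",
    "evaluate",
    "DEFAULT_TUNING_GRID",
]


@dataclass(frozen=True)
class SpadSample:
    """One image's CVI vector paired with its measured SPAD value."""

    image_id: str
    cvi: CviRecord
    spad: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.spad):
            raise ValueError(f"sample {self.image_id}: SPAD value must be finite")


@dataclass(frozen=True)
class CorrelationTable:
    """Index -> Pearson r, sorted by |r| descending; excluded indices listed."""

    entries: tuple[tuple[str, float], ...]
    excluded: tuple[str, ...] = ()

    def r_of(self, name: str) -> float:
        for n, r in self.entries:
            if n == name:
                return r
        raise KeyError(name)


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation coefficient."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    if xa.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("undefined correlation: zero variance")
    return float(_stats.pearsonr(xa, ya).statistic)


def correlation_table(
    samples: Sequence[SpadSample],
    indices: Sequence[str] = CVI_NAMES,
) -> CorrelationTable:
    """Correlate every region CVI with SPAD across a cohort.

    Indices that are undefined for any sample (vanishing denominator) or
    constant across the cohort cannot be correlated; they are reported in
    ``excluded`` rather than silently dropped.
    """
    if len(samples) < 3:
        raise ValueError("need at least 3 samples to correlate")
    spad = [s.spad for s in samples]
    entries = []
    excluded = []
    for name in indices:
        if any(not s.cvi.defined(name) for s in samples):
            excluded.append(name)
            continue
        vals = [s.cvi.values[name] for s in samples]
        if np.ptp(vals) == 0:
            excluded.append(name)
            continue
        entries.append((name, pearson(vals, spad)))
    order = {name: i for i, name in enumerate(indices)}
    entries.sort(key=lambda e: (-abs(e[1]), order[e[0]]))
    return CorrelationTable(tuple(entries), tuple(excluded))


def top_indices(table: CorrelationTable, k: int = 5) -> tuple[str, ...]:
    """The k indices with the largest |r|; ties resolved by registry order."""
    if len(table.entries) < k:
        raise ValueError(f"only {len(table.entries)} correlated indices, need {k}")
    return tuple(name for name, _ in table.entries[:k])


# ---------------------------------------------------------------------------
# Gradient-boosted regression trees with histogram split finding
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GbrtConfig:
    n_estimators: int = 100
    learning_rate: float = 0.1
    max_depth: int = 3
    subsample: float = 1.0
    bins: int = 256
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_estimators < 1 or not 0 < self.subsample <= 1:
            raise ValueError("invalid boosting configuration")
        if self.bins < 2:
            raise ValueError("need at least 2 histogram bins")


#: Hyperparameter grid searched on the validation partition.
DEFAULT_TUNING_GRID: dict[str, tuple] = {
    "n_estimators": (100, 300),
    "max_depth": (2, 3, 4),
    "learning_rate": (0.05, 0.1),
    "subsample": (0.8, 1.0),
}


@dataclass
class GbrtModel:
    """Stagewise boosted regression trees over histogram-binned features."""

    kind = "gbrt"

    feature_names: tuple[str, ...]
    bin_edges: tuple[np.ndarray, ...]  # per feature, len bins+1
    init: float  # stage-0 prediction: the training-target mean
    trees: list = field(default_factory=list)
    learning_rate: float = 0.1
    train_losses: tuple[float, ...] = ()  # MSE after each stage
    config: GbrtConfig = GbrtConfig()

    def _binned(self, X: np.ndarray) -> np.ndarray:
        out = np.empty_like(X, dtype=np.float64)
        for j, edges in enumerate(self.bin_edges):
            mids = (edges[:-1] + edges[1:]) / 2.0
            idx = np.clip(np.searchsorted(edges, X[:, j], side="right") - 1,
                          0, len(mids) - 1)
            out[:, j] = mids[idx]
        return out

    def predict_matrix(self, X: np.ndarray) -> np.ndarray:
        Xb = self._binned(np.asarray(X, dtype=np.float64))
        pred = np.full(Xb.shape[0], self.init)
        for tree in self.trees:
            pred += self.learning_rate * tree.predict(Xb)
        return pred

    def predict(self, samples: Sequence[SpadSample]) -> np.ndarray:
        return self.predict_matrix(feature_matrix(samples, self.feature_names))


def feature_matrix(
    samples: Sequence[SpadSample], features: Sequence[str]
) -> np.ndarray:
    """Stack the chosen CVI values of a cohort into an (n, p) matrix."""
    rows = []
    for s in samples:
        row = []
        for name in features:
            if not s.cvi.defined(name):
                raise ValueError(f"sample {s.image_id}: index {name} is undefined")
            row.append(s.cvi.values[name])
        rows.append(row)
    return np.asarray(rows, dtype=np.float64)


def _fit_single(
    X: np.ndarray, y: np.ndarray, features: Sequence[str], config: GbrtConfig
) -> GbrtModel:
    rng = np.random.default_rng(config.seed)
    edges = []
    for j in range(X.shape[1]):
        lo, hi = float(X[:, j].min()), float(X[:, j].max())
        if lo == hi:
            hi = lo + 1.0  # constant feature: single effective bin
        edges.append(np.linspace(lo, hi, config.bins + 1))
    model = GbrtModel(
        tuple(features), tuple(edges), init=float(y.mean()),
        learning_rate=config.learning_rate, config=config,
    )
    Xb = model._binned(X)
    pred = np.full(y.shape, model.init)
    losses = []
    n = y.size
    for t in range(config.n_estimators):
        residual = y - pred
        if config.subsample < 1.0:
            take = rng.choice(n, size=max(2, int(round(config.subsample * n))),
                              replace=False)
        else:
            take = slice(None)
        tree = DecisionTreeRegressor(max_depth=config.max_depth,
                                     random_state=config.seed + t)
        tree.fit(Xb[take], residual[take])
        pred = pred + config.learning_rate * tree.predict(Xb)
        model.trees.append(tree)
        losses.append(float(np.mean((y - pred) ** 2)))
    model.train_losses = tuple(losses)
    return model


def fit_gbrt(
    train: Sequence[SpadSample],
    val: Sequence[SpadSample] | None,
    features: Sequence[str],
    config: GbrtConfig = GbrtConfig(),
    *,
    tune_grid: Mapping[str, tuple] | None = None,
) -> GbrtModel:
    """Fit the boosted SPAD regressor, optionally tuning on validation RMSE.

    With ``tune_grid`` given (e.g. ``DEFAULT_TUNING_GRID``) every grid
    combination is trained on ``train`` and scored by RMSE on ``val``; the
    best configuration's model is returned.  Without a grid, ``config`` is
    used as-is.  A constant training target yields a constant model with a
    warning.
    """
    if len(train) < 10:
        raise ValueError("need at least 10 training samples")
    X = feature_matrix(train, features)
    y = np.asarray([s.spad for s in train], dtype=np.float64)
    if np.ptp(y) == 0:
        warnings.warn("constant SPAD target: returning a constant model")
        return _fit_single(X, y, features, GbrtConfig(n_estimators=1, max_depth=1,
                                                      seed=config.seed))
    if tune_grid is None:
        return _fit_single(X, y, features, config)

    if val is None or len(val) == 0:
        raise ValueError("tuning requires a validation partition")
    Xv = feature_matrix(val, features)
    yv = np.asarray([s.spad for s in val], dtype=np.float64)
    keys = sorted(tune_grid)
    best_model, best_rmse = None, np.inf
    for combo in itertools.product(*(tune_grid[k] for k in keys)):
        params = dict(zip(keys, combo))
        cfg = GbrtConfig(seed=config.seed, bins=config.bins, **params)
        model = _fit_single(X, y, features, cfg)
        rmse = float(np.sqrt(np.mean((model.predict_matrix(Xv) - yv) ** 2)))
        if rmse < best_rmse - 1e-12:
            best_rmse, best_model = rmse, model
    return best_model


@dataclass(frozen=True)
class PartitionMetrics:
    R2_adj: float
    RMSE: float
    MAE: float
    n: int


@dataclass(frozen=True)
class RegressionReport:
    train: PartitionMetrics
    test: PartitionMetrics


def evaluate(
    model: GbrtModel,
    samples: Sequence[SpadSample],
    n_features: int | None = None,
) -> PartitionMetrics:
    """Score predictions on a cohort partition.

    ``R2_adj`` adjusts the determination coefficient for the number of
    predictors p: ``1 - (1 - R^2)(n - 1)/(n - p - 1)``; it requires
    n > p + 1 observations.
    """
    if not samples:
        raise ValueError("empty sample list")
    p = n_features if n_features is not None else len(model.feature_names)
    n = len(samples)
    if n <= p + 1:
        raise ValueError(f"adjusted R^2 undefined for n={n} <= p+1={p + 1}")
    y = np.asarray([s.spad for s in samples], dtype=np.float64)
    pred = model.predict(samples)
    err = pred - y
    rmse = float(np.sqrt(np.mean(err**2)))
    mae = float(np.mean(np.abs(err)))
    ss_res = float(np.sum(err**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -np.inf)
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    return PartitionMetrics(R2_adj=r2_adj, RMSE=rmse, MAE=mae, n=n)
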