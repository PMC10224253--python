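"""Segmentation quality scores and binary classification metrics.

A candidate mask S is compared with a reference mask R pixel-by-pixel using
three quality factors:

* ``Qseg = |S AND R| / |S OR R|`` — foreground intersection-over-union;
* ``Sr   = |S AND R| / |R|``     — fraction of reference plant recovered;
* ``Es   = |S AND NOT R| / |R|`` — false positives relative to the
  reference plant size (may exceed 1 for grossly over-segmented masks).

A perfect segmentation scores (1, 1, 0).  Pixel-label classifiers are scored
with the usual confusion-matrix metrics (accuracy, precision, recall,
F-score).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "QualityScores",
    "ClassificationReport",
    "quality",
    "classification_metrics",
    "aggregate",
]


@dataclass(frozen=True)
class QualityScores:
    Qseg: float
    Sr: float
    Es: float
    height: int
    width: int


@dataclass(frozen=True)
class ClassificationReport:
    TP: int
    TN: int
    FP: int
    FN: int
    accuracy: float
    precision: float
    recall: float
    f_score: float
    degenerate_f: bool = False  # True when P + R = 0 and F was defined as 0


def _as_bool_mask(mask: np.ndarray) -> np.ndarray:
    m = np.asarray(mask)
    if m.ndim != 2:
        raise ValueError("mask must be 2-D")
    return m > 0


def quality(S: np.ndarray, R: np.ndarray) -> QualityScores:
    """Score a segmentation mask S against a reference mask R.

    Both masks are {0, 255} images of identical dimensions; any nonzero
    pixel counts as foreground.  R must contain at least one foreground
    pixel (Sr and Es are undefined otherwise).
    """
    s = _as_bool_mask(S)
    r = _as_bool_mask(R)
    if s.shape != r.shape:
        raise ValueError(f"mask dimensions differ: {s.shape} vs {r.shape}")
    n_ref = int(r.sum())
    if n_ref == 0:
        raise ValueError("reference mask has no foreground: Sr/Es undefined")

    inter = int(np.logical_and(s, r).sum())
    union = int(np.logical_or(s, r).sum())
    false_pos = int(np.logical_and(s, np.logical_not(r)).sum())

    return QualityScores(
        Qseg=inter / union,  # union >= n_ref >= 1
        Sr=inter / n_ref,
        Es=false_pos / n_ref,
        height=s.shape[0],
        width=s.shape[1],
    )


def classification_metrics(
    predicted: Sequence[int], true: Sequence[int]
) -> ClassificationReport:
    """Confusion-matrix metrics for binary pixel labels.

    accuracy = (TP+TN)/(TP+TN+FP+FN); recall R = TP/(TP+FN);
    precision P = TP/(TP+FP); F = 2PR/(P+R).  When P + R = 0 (no positive
    predictions and none recovered) F is reported as 0 with
    ``degenerate_f=True``.
    """
    p = np.asarray(predicted).ravel()
    t = np.asarray(true).ravel()
    if p.size == 0:
        raise ValueError("empty input")
    if p.shape != t.shape:
        raise ValueError("predicted and true labels must have equal length")
    p = (p > 0).astype(np.int8)
    t = (t > 0).astype(np.int8)

    tp = int(np.sum((p == 1) & (t == 1)))
    tn = int(np.sum((p == 0) & (t == 0)))
    fp = int(np.sum((p == 1) & (t == 0)))
    fn = int(np.sum((p == 0) & (t == 1)))

    accuracy = (tp + tn) / (tp + tn + fp + fn)
    precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    recall = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    degenerate = (precision + recall) == 0.0
    f_score = 0.0 if degenerate else 2 * precision * recall / (precision + recall)
    return ClassificationReport(
        TP=tp, TN=tn, FP=fp, FN=fn,
        accuracy=accuracy, precision=precision, recall=recall,
        f_score=f_score, degenerate_f=degenerate,
    )


def aggregate(scores: Iterable[QualityScores]) -> dict[str, tuple[float, float]]:
    """Mean and population standard deviation of each quality metric.

    Returns ``{"Qseg": (mean, sd), "Sr": ..., "Es": ...}``.  The standard
    deviation divides by N (population), matching how per-image quality
    means are summarised.
    """
    items = list(scores)
    if not items:
        raise ValueError("empty score list")
    out = {}
    for metric in ("Qseg", "Sr", "Es"):
        vals = np.asarray([getattr(s, metric) for s in items], dtype=float)
        out[metric] = (float(vals.mean()), float(vals.std(ddof=0)))
    return out


def filter_scoreable(
    pairs: Iterable[tuple[np.ndarray, np.ndarray]],
) -> list[QualityScores]:
    """Score (S, R) mask pairs, skipping empty-reference pairs with a warning."""
    out = []
    for i, (s, r) in enumerate(pairs):
        if not (np.asarray(r) > 0).any():
            warnings.warn(f"pair {i}: reference mask empty, excluded from aggregation")
            continue
        out.append(quality(s, r))
    return out
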