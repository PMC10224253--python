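"""Decision-tree recursive feature elimination (DT-RFE) over color channels.

A single bounded-depth decision tree is fitted to the labeled pixel table
and its Gini impurity-decrease importances are recorded; the lowest-ranked
channels are then removed and the tree refitted, repeating until one channel
survives.  The elimination order gives each channel a rank (1 = last
survivor), while the reported importance scores come from the initial
full-feature fit so they are comparable across channels.

Channels whose initial importance exceeds a threshold (0.04 by default) form
the selected subset used to train the pixel classifiers.  The packaged
default subset — the 12 channels R, G (RGB), H, S (HSV), L, a (Lab),
v (Luv), Y (YCbCr), U (YUV) and h, l, s (HLS) — is what that selection
yields on glasshouse+field patch data, and is used whenever no computed
ranking is supplied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "DEFAULT_SELECTED_CHANNELS",
    "DEFAULT_IMPORTANCE_THRESHOLD",
    "RankedChannel",
    "FeatureRanking",
    "SelectedChannels",
    "rank_dtrfe",
    "select",
]

#: Channel subset shipped as the package default (12 channels).
DEFAULT_SELECTED_CHANNELS: tuple[str, ...] = (
    "rgb.R", "rgb.G",
    "hsv.H", "hsv.S",
    "lab.L", "lab.a",
    "luv.v",
    "ycbcr.Y",
    "yuv.U",
    "hls.h", "hls.l", "hls.s",
)

DEFAULT_IMPORTANCE_THRESHOLD = 0.04


@dataclass(frozen=True)
class RankedChannel:
    name: str
    importance: float  # from the initial full-feature fit, sums to 1
    elimination_rank: int  # 1 = eliminated last (most important)


@dataclass(frozen=True)
class FeatureRanking:
    """Result of DT-RFE: one entry per channel, ordered best-first."""

    entries: tuple[RankedChannel, ...]

    def __post_init__(self) -> None:
        ranks = sorted(e.elimination_rank for e in self.entries)
        if ranks != list(range(1, len(self.entries) + 1)):
            raise ValueError("elimination ranks must be a permutation of 1..n")

    def importance_of(self, name: str) -> float:
        for e in self.entries:
            if e.name == name:
                return e.importance
        raise KeyError(name)


@dataclass(frozen=True)
class SelectedChannels:
    """An ordered channel subset with provenance."""

    names: tuple[str, ...]
    origin: str = "default"  # "default" | "computed"
    threshold_used: float = DEFAULT_IMPORTANCE_THRESHOLD

    def __post_init__(self) -> None:
        if not self.names:
            raise ValueError("selected channel set must be nonempty")

    @classmethod
    def default(cls) -> "SelectedChannels":
        return cls(DEFAULT_SELECTED_CHANNELS, origin="default")

    @classmethod
    def from_file(cls, path) -> "SelectedChannels":
        names = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line and not line.startswith("#"):
                    names.append(line)
        return cls(tuple(names), origin="computed")

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for name in self.names:
                fh.write(name + "\n")


def _fit_tree(X: np.ndarray, y: np.ndarray, max_depth: int, seed: int) -> np.ndarray:
    tree = DecisionTreeClassifier(max_depth=max_depth, random_state=seed)
    tree.fit(X, y)
    return tree.feature_importances_


def rank_dtrfe(
    dataset,
    *,
    step: int = 1,
    seed: int = 0,
    max_depth: int = 12,
) -> FeatureRanking:
    """Rank channels by decision-tree recursive feature elimination.

    Per iteration, a decision tree (Gini impurity, depth <= ``max_depth``)
    is fitted on the surviving channels and the ``step`` channels with the
    lowest importances are eliminated; ties are broken by canonical channel
    order so a fixed seed gives a reproducible ranking.  The scores reported
    in the result come from the first (all-channel) fit.
    """
    X, y = dataset.X, dataset.y
    names = list(dataset.channel_names)
    if len(names) < 2:
        raise ValueError("need at least 2 channels to rank")
    if np.unique(y).size < 2:
        raise ValueError("degenerate labels: both classes must be present")
    if step < 1:
        raise ValueError("step must be >= 1")

    initial_importances = _fit_tree(X, y, max_depth, seed)
    initial = dict(zip(names, initial_importances))

    surviving = list(range(len(names)))
    elimination_order: list[int] = []  # column indices, first eliminated first
    while len(surviving) > 1:
        imp = _fit_tree(X[:, surviving], y, max_depth, seed)
        # lowest importance first; ties resolved by canonical column order
        order = sorted(range(len(surviving)), key=lambda i: (imp[i], surviving[i]))
        n_drop = min(step, len(surviving) - 1)
        for i in sorted(order[:n_drop], reverse=True):
            elimination_order.append(surviving[i])
            del surviving[i]
    elimination_order.extend(surviving)

    n = len(names)
    entries = []
    for pos, col in enumerate(elimination_order):
        rank = n - pos  # eliminated first -> rank n; survivor -> rank 1
        entries.append(RankedChannel(names[col], float(initial[names[col]]), rank))
    entries.sort(key=lambda e: e.elimination_rank)
    return FeatureRanking(tuple(entries))


def select(
    ranking: FeatureRanking,
    threshold: float = DEFAULT_IMPORTANCE_THRESHOLD,
    k: int | None = None,
) -> SelectedChannels:
    """Select channels above an importance threshold (or exactly top-k).

    Channels are ordered by descending importance (elimination rank breaking
    ties).  With ``k`` given, exactly the top-k channels are returned and
    the threshold is ignored.
    """
    if not ranking.entries:
        raise ValueError("empty ranking")
    by_importance = sorted(
        ranking.entries, key=lambda e: (-e.importance, e.elimination_rank)
    )
    if k is not None:
        if not 1 <= k <= len(by_importance):
            raise ValueError(f"k must be in [1, {len(by_importance)}]")
        chosen = by_importance[:k]
        return SelectedChannels(
            tuple(e.name for e in chosen), origin="computed", threshold_used=float("nan")
        )
    chosen = [e for e in by_importance if e.importance > threshold]
    if not chosen:
        raise ValueError(
            f"no channel has importance > {threshold}; "
            "use k=<count> to force a fixed-size selection"
        )
    return SelectedChannels(
        tuple(e.name for e in chosen), origin="computed", threshold_used=threshold
    )
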