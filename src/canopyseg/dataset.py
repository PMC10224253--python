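"""Annotated patches and the per-pixel labeled feature table.

Foreground (plant) and background (soil/compost/clutter) training examples
arrive as small image crops.  Each crop is standardised to 20 x 20 pixels,
expanded into the 24-channel color feature stack, and flattened so that
every pixel contributes one labeled row — a patch therefore yields exactly
400 rows of 24 features.  The resulting table is what the pixel classifiers
train on, after an optional restriction to a selected channel subset and a
seeded stratified split (3:1:1 by default, after the train/validation/test
protocol used throughout the package).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from skimage.transform import resize as _sk_resize

from .colorspaces import CHANNEL_NAMES, to_feature_stack, validate_rgb_image

__all__ = [
    "PATCH_SIZE",
    "Patch",
    "PixelDataset",
    "SplitSpec",
    "standardize_patch",
    "assemble",
    "split",
    "restrict",
    "load_patch_dirs",
]

PATCH_SIZE = 20  # side length of a standardised patch, pixels


@dataclass(frozen=True)
class Patch:
    """One annotated image crop with a binary label."""

    crop: np.ndarray  # (h, w, 3) uint8
    label: int  # 1 = foreground (plant), 0 = background
    source: str = "glasshouse"  # or "field"
    patch_id: str = ""

    def __post_init__(self) -> None:
        validate_rgb_image(self.crop)
        if self.label not in (0, 1):
            raise ValueError("label must be 0 (background) or 1 (foreground)")


@dataclass(frozen=True)
class PixelDataset:
    """Flat table of per-pixel feature vectors with binary labels.

    ``X`` is (n_rows, n_channels) float in [0, 1]; ``y`` is {0, 1};
    ``row_ids`` are stable integer identifiers used to verify that splits
    are disjoint and exhaustive.
    """

    X: np.ndarray
    y: np.ndarray
    channel_names: tuple[str, ...]
    row_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.X.ndim != 2 or self.X.shape[1] != len(self.channel_names):
            raise ValueError("X must be (n_rows, n_channels) matching channel_names")
        if self.y.shape != (self.X.shape[0],):
            raise ValueError("y must have one label per row")
        if self.row_ids is None:
            object.__setattr__(self, "row_ids", np.arange(self.X.shape[0], dtype=np.int64))
        elif self.row_ids.shape != (self.X.shape[0],):
            raise ValueError("row_ids must have one id per row")

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    @property
    def n_scalar_features(self) -> int:
        """Total scalar feature count (rows x channels)."""
        return self.X.shape[0] * self.X.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=list(self.channel_names))
        df["label"] = self.y
        return df

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            fh.write("# canopyseg pixel dataset, schema v1\n")
            self.to_frame().to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PixelDataset":
        df = pd.read_csv(path, comment="#")
        if "label" not in df.columns:
            raise ValueError("dataset CSV must contain a 'label' column")
        y = df.pop("label").to_numpy(dtype=np.uint8)
        return cls(df.to_numpy(dtype=np.float64), y, tuple(df.columns))


@dataclass(frozen=True)
class SplitSpec:
    """Ordered split ratios plus a seed; e.g. (3, 1, 1) or (70, 15, 15)."""

    ratios: tuple[float, ...]
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.ratios):
            raise ValueError("all split ratios must be positive")

    @property
    def fractions(self) -> tuple[float, ...]:
        total = sum(self.ratios)
        fr = tuple(r / total for r in self.ratios)
        if abs(sum(fr) - 1.0) > 1e-9:
            raise ValueError("ratios do not normalise to 1")
        return fr


def standardize_patch(patch: Patch) -> Patch:
    """Bilinearly resize a patch crop to 20 x 20 pixels.

    Crops already at the target size are returned unchanged; label and
    metadata are always preserved.
    """
    h, w = patch.crop.shape[:2]
    if h < 1 or w < 1:
        raise ValueError("empty crop")
    if (h, w) == (PATCH_SIZE, PATCH_SIZE):
        return patch
    out = _sk_resize(
        patch.crop, (PATCH_SIZE, PATCH_SIZE), order=1, anti_aliasing=False,
        preserve_range=True,
    )
    return replace(patch, crop=np.clip(np.rint(out), 0, 255).astype(np.uint8))


def assemble(patches: Iterable[Patch], *, log=None) -> PixelDataset:
    """Build the per-pixel labeled feature table from standardised patches.

    Every patch contributes 400 rows (one per pixel) of 24 channel features;
    the label of each row is the patch label.  The total scalar-feature
    count (rows x 24) is reported through ``log`` when given.
    """
    feats: list[np.ndarray] = []
    labels: list[np.ndarray] = []
    n_patches = 0
    for patch in patches:
        h, w = patch.crop.shape[:2]
        if (h, w) != (PATCH_SIZE, PATCH_SIZE):
            raise ValueError(
                f"patch {patch.patch_id or n_patches} is {h}x{w}; "
                f"standardise to {PATCH_SIZE}x{PATCH_SIZE} first"
            )
        stack = to_feature_stack(patch.crop)
        feats.append(stack.as_matrix())
        labels.append(np.full(PATCH_SIZE * PATCH_SIZE, patch.label, dtype=np.uint8))
        n_patches += 1
    if n_patches == 0:
        raise ValueError("no patches to assemble")
    X = np.vstack(feats)
    y = np.concatenate(labels)
    ds = PixelDataset(X, y, CHANNEL_NAMES)
    if log is not None:
        log(
            f"assembled {n_patches} patches -> {ds.n_rows} pixel rows, "
            f"{ds.n_scalar_features} scalar features "
            f"(foreground {int((y == 1).sum()) * len(CHANNEL_NAMES)}, "
            f"background {int((y == 0).sum()) * len(CHANNEL_NAMES)})"
        )
    return ds


def _largest_remainder(n: int, fractions: Sequence[float]) -> list[int]:
    """Integer part sizes that always sum to ``n`` (largest-remainder rule)."""
    exact = [n * f for f in fractions]
    sizes = [int(np.floor(e)) for e in exact]
    remainder = n - sum(sizes)
    order = np.argsort([-(e - s) for e, s in zip(exact, sizes)], kind="stable")
    for i in range(remainder):
        sizes[order[i]] += 1
    return sizes


def split(dataset: PixelDataset, spec: SplitSpec) -> tuple[PixelDataset, ...]:
    """Seeded disjoint split of a pixel dataset into len(ratios) parts.

    With ``stratified=True`` each class is partitioned separately so the
    class balance of every part matches the whole to within one row.
    Identical seeds give identical splits.
    """
    fractions = spec.fractions
    n_parts = len(fractions)
    if dataset.n_rows < n_parts:
        raise ValueError("fewer rows than split parts")
    rng = np.random.default_rng(spec.seed)

    part_indices: list[list[np.ndarray]] = [[] for _ in range(n_parts)]
    if spec.stratified:
        groups = [np.flatnonzero(dataset.y == c) for c in np.unique(dataset.y)]
    else:
        groups = [np.arange(dataset.n_rows)]
    for idx in groups:
        perm = rng.permutation(idx)
        sizes = _largest_remainder(len(perm), fractions)
        start = 0
        for p, size in enumerate(sizes):
            part_indices[p].append(perm[start:start + size])
            start += size

    parts = []
    for chunks in part_indices:
        take = np.sort(np.concatenate(chunks))
        parts.append(
            PixelDataset(
                dataset.X[take], dataset.y[take], dataset.channel_names,
                dataset.row_ids[take],
            )
        )
    return tuple(parts)


def restrict(dataset: PixelDataset, channels: Sequence[str]) -> PixelDataset:
    """Subset/reorder the feature columns to ``channels``; labels untouched."""
    names = list(channels)
    idx = []
    for name in names:
        if name not in dataset.channel_names:
            raise KeyError(f"unknown channel {name!r}")
        idx.append(dataset.channel_names.index(name))
    return PixelDataset(dataset.X[:, idx], dataset.y, tuple(names), dataset.row_ids)


def load_patch_dirs(fg_dir: str | Path, bg_dir: str | Path) -> list[Patch]:
    """Load labelled patch crops from ``fg/`` and ``bg/`` directories of PNGs."""
    from .colorspaces import load_rgb_image

    patches = []
    for label, directory in ((1, Path(fg_dir)), (0, Path(bg_dir))):
        for path in sorted(directory.glob("*.png")) + sorted(directory.glob("*.jpg")):
            crop = load_rgb_image(path)
            patches.append(
                standardize_patch(Patch(crop=crop, label=label, patch_id=path.stem))
            )
    return patches
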