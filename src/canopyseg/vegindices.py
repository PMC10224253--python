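"""Color vegetation indices (CVIs) and index+Otsu baseline segmentation.

Two kinds of quantity live here:

* **index images** — per-pixel evaluation of ExG (excess green, 2G - R - B)
  and ExGR (excess green minus excess red), used with automatic Otsu
  thresholding as the classical baselines against which the learned pixel
  classifiers are compared;
* **region CVIs** — scalar indices of a segmented plant region, computed
  from the region's mean R, G, B values (and the HSV of that mean color),
  used downstream as predictors of SPAD greenness.

All index formulas operate on raw 8-bit channel values.  An optional
chromatic-coordinate mode (r = R/(R+G+B) etc.) is available for sensitivity
analysis but is off by default.
"""

from __future__ import annotations

import colorsys
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .colorspaces import validate_rgb_image

__all__ = [
    "INDEX_IMAGE_NAMES",
    "CVI_NAMES",
    "IndexImage",
    "CviRecord",
    "index_image",
    "otsu_threshold",
    "otsu_mask",
    "cvi_from_region",
]

#: Indices available as per-pixel images (the segmentation baselines).
INDEX_IMAGE_NAMES = ("ExG", "ExGR")

#: Region-level CVI registry, in canonical (tie-breaking) order.
CVI_NAMES = (
    "Green", "Blue", "ExG", "ExR", "CIVE", "ERI", "DGCI", "GR", "COM1", "GBRG", "EGI",
)


@dataclass(frozen=True)
class IndexImage:
    """Per-pixel scalar vegetation-index image."""

    index_name: str
    values: np.ndarray  # (H, W) float

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]


def index_image(image: np.ndarray, name: str, *, chromatic: bool = False) -> IndexImage:
    """Evaluate a per-pixel vegetation index over an RGB image.

    ``chromatic=True`` replaces the raw 8-bit channels with chromatic
    coordinates R/(R+G+B) etc. before evaluating the formula.
    """
    if name not in INDEX_IMAGE_NAMES:
        raise KeyError(f"unknown index image {name!r}; available: {INDEX_IMAGE_NAMES}")
    img = validate_rgb_image(image).astype(np.float64)
    r, g, b = img[..., 0], img[..., 1], img[..., 2]
    if chromatic:
        total = r + g + b
        total[total == 0] = 1.0
        r, g, b = r / total, g / total, b / total
    exg = 2.0 * g - r - b
    if name == "ExG":
        values = exg
    else:  # ExGR = ExG - ExR = ExG - (1.4 R - G)
        values = exg - (1.4 * r - g)
    return IndexImage(name, values)


def otsu_threshold(values: np.ndarray) -> tuple[float, np.ndarray]:
    """Otsu's threshold on an index image.

    The values are linearly rescaled onto 256 integer bins, and the bin
    threshold maximising the between-class variance is found by evaluating
    all 256 candidates.  Returns ``(threshold_in_bin_units, binned_values)``
    so callers can build the mask consistently; foreground is
    ``binned > threshold``.
    """
    v = np.asarray(values, dtype=np.float64)
    vmin, vmax = float(v.min()), float(v.max())
    if vmin == vmax:
        raise ValueError("degenerate histogram: index image is constant")
    binned = np.rint((v - vmin) / (vmax - vmin) * 255.0).astype(np.int64)

    hist = np.bincount(binned.ravel(), minlength=256).astype(np.float64)
    p = hist / hist.sum()
    omega = np.cumsum(p)                      # class-0 probability up to t
    mu = np.cumsum(p * np.arange(256))        # first moment up to t
    mu_total = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_total * omega - mu) ** 2 / (omega * (1.0 - omega))
    sigma_b[~np.isfinite(sigma_b)] = 0.0
    threshold = int(np.argmax(sigma_b))
    return float(threshold), binned


def otsu_mask(index: IndexImage) -> np.ndarray:
    """Binarise an index image with Otsu's method.

    Pixels above the threshold become foreground (255); the rest 0.
    """
    threshold, binned = otsu_threshold(index.values)
    return np.where(binned > threshold, 255, 0).astype(np.uint8)


@dataclass(frozen=True)
class CviRecord:
    """Region-level color vegetation indices of a segmented plant.

    ``values`` maps each registry name to a float; indices with a vanishing
    denominator (GBRG at R = G, EGI at G = B, DGCI for an achromatic mean
    color when evaluated literally) appear in ``undefined`` instead of being
    silently dropped.
    """

    mean_R: float
    mean_G: float
    mean_B: float
    mean_H: float  # degrees in [0, 360)
    mean_S: float  # [0, 1]
    mean_Bv: float  # HSV value ("brightness") in [0, 1]
    values: Mapping[str, float]
    undefined: frozenset[str] = frozenset()

    def defined(self, name: str) -> bool:
        return name not in self.undefined


def cvi_from_region(
    image: np.ndarray,
    mask: np.ndarray,
    *,
    dgci_literal: bool = False,
    per_pixel_mean: bool = False,
) -> CviRecord:
    """Compute the 11 region CVIs of a segmented plant.

    The canonical mode evaluates every formula on the region's *mean*
    channel values (mean R, G, B over foreground pixels, plus the HSV of the
    mean color).  ``per_pixel_mean=True`` instead averages per-pixel index
    values over the region, for sensitivity checks.

    DGCI defaults to the established dark-green color index
    ``[(H - 60)/60 + (1 - S) + (1 - Bv)] / 3``; ``dgci_literal=True``
    evaluates the alternative parenthesisation
    ``(H - 60) / [60 + (1 - S) + (1 - Bv)] / 3`` instead.
    """
    img = validate_rgb_image(image).astype(np.float64)
    m = np.asarray(mask)
    if m.shape[:2] != img.shape[:2]:
        raise ValueError("mask dimensions must match the image")
    fg = m > 0
    if not fg.any():
        raise ValueError("empty region: mask has no foreground pixels")

    mean_r = float(img[..., 0][fg].mean())
    mean_g = float(img[..., 1][fg].mean())
    mean_b = float(img[..., 2][fg].mean())
    h01, s, bv = colorsys.rgb_to_hsv(mean_r / 255.0, mean_g / 255.0, mean_b / 255.0)
    mean_h = h01 * 360.0

    if per_pixel_mean:
        r = img[..., 0][fg]
        g = img[..., 1][fg]
        b = img[..., 2][fg]
    else:
        r, g, b = mean_r, mean_g, mean_b

    values: dict[str, float] = {}
    undefined: set[str] = set()

    def _mean(x) -> float:
        return float(np.mean(x))

    exg = _mean(2.0 * g - r - b)
    exr = _mean(1.4 * r - g)
    cive = _mean(0.441 * r - 0.811 * g + 0.385 * b + 18.78)
    values["Green"] = mean_g
    values["Blue"] = mean_b
    values["ExG"] = exg
    values["ExR"] = exr
    values["CIVE"] = cive
    values["ERI"] = _mean((r - g) * (r - b))
    values["GR"] = _mean(g - r)
    values["COM1"] = exg + cive + (exg - exr)

    if dgci_literal:
        denom = 60.0 + (1.0 - s) + (1.0 - bv)
        values["DGCI"] = ((mean_h - 60.0) / denom) / 3.0
    else:
        values["DGCI"] = ((mean_h - 60.0) / 60.0 + (1.0 - s) + (1.0 - bv)) / 3.0

    # Ratio indices are evaluated on the region means even in per-pixel mode:
    # a single pixel with R = G would otherwise poison the whole region.
    if math.isclose(mean_r, mean_g, abs_tol=1e-12):
        values["GBRG"] = float("nan")
        undefined.add("GBRG")
    else:
        values["GBRG"] = (mean_g - mean_r) / (mean_r - mean_g)
    if math.isclose(mean_g, mean_b, abs_tol=1e-12):
        values["EGI"] = float("nan")
        undefined.add("EGI")
    else:
        values["EGI"] = (mean_g - mean_r) / (mean_g - mean_b)

    return CviRecord(
        mean_R=mean_r,
        mean_G=mean_g,
        mean_B=mean_b,
        mean_H=mean_h,
        mean_S=s,
        mean_Bv=bv,
        values=values,
        undefined=frozenset(undefined),
    )
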