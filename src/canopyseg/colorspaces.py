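"""Color-space feature extraction and color-checker correction.

Every pixel of an 8-bit RGB image is expanded into a 24-dimensional feature
vector by transforming the image into eight color spaces (RGB, HSV, YCbCr,
CIELAB, YUV, CIELUV, HLS, CIEXYZ) and stacking the three channels of each.
All channels are rescaled to [0, 1] so that downstream classifiers see
bounded, comparable magnitudes.

Conventions (chosen once, for bit-stable results):

* all conversions start from 8-bit sRGB;
* hue channels (``hsv.H``, ``hls.h``) map the full 360-degree circle to [0, 1];
* CIELAB / CIELUV use the D65 white point;
* YCbCr uses the ITU-R BT.601 full-range (JPEG) matrix;
* signed chroma axes (a, b, U, V, u, v, Cb, Cr) are shifted/scaled so the
  neutral axis sits near 0.5.

The module also implements the color-checker workflow used on glasshouse and
field images: per-channel linear white balance from the neutral (gray)
patches, and additive hue correction per color group (green / brown / yellow
tiles) against target hue angles.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from skimage import color as _skcolor

__all__ = [
    "CHANNEL_NAMES",
    "ColorFeatureStack",
    "ColorCheckerReference",
    "HueGroup",
    "to_feature_stack",
    "white_balance",
    "hue_correct",
    "load_rgb_image",
    "validate_rgb_image",
]

#: Canonical channel ordering.  This list *defines* the feature-vector layout
#: used everywhere in the package; do not reorder.
CHANNEL_NAMES: tuple[str, ...] = (
    "rgb.R", "rgb.G", "rgb.B",
    "hsv.H", "hsv.S", "hsv.V",
    "ycbcr.Y", "ycbcr.Cb", "ycbcr.Cr",
    "lab.L", "lab.a", "lab.b",
    "yuv.Y", "yuv.U", "yuv.V",
    "luv.L", "luv.u", "luv.v",
    "hls.h", "hls.l", "hls.s",
    "xyz.X", "xyz.Y", "xyz.Z",
)

# Normalisation extents for the signed / non-unit color axes.  The Lab a/b
# axes use the conventional [-128, 127] byte encoding; Luv uses the extreme
# u'v' values reachable from the sRGB gamut under D65; XYZ is divided by the
# D65 white point so a white pixel maps to (1, 1, 1).
_LUV_U_RANGE = (-134.0, 220.0)
_LUV_V_RANGE = (-140.0, 122.0)
_D65_XYZ = (0.95047, 1.0, 1.08883)


def validate_rgb_image(image: np.ndarray) -> np.ndarray:
    """Check that ``image`` is a non-empty H x W x 3 8-bit RGB array."""
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB array, got shape {arr.shape}")
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError("empty image: height and width must be >= 1")
    if arr.dtype != np.uint8:
        if np.issubdtype(arr.dtype, np.integer) and arr.min() >= 0 and arr.max() <= 255:
            arr = arr.astype(np.uint8)
        else:
            raise ValueError("RGB image must be 8-bit (uint8, values in [0, 255])")
    return arr


@dataclass(frozen=True)
class ColorFeatureStack:
    """Per-pixel multi-channel feature tensor.

    ``values`` has shape (height, width, n_channels) with every entry in
    [0, 1]; ``channel_names`` gives the meaning and order of the last axis.
    """

    values: np.ndarray
    channel_names: tuple[str, ...]

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def n_channels(self) -> int:
        return self.values.shape[2]

    def __post_init__(self) -> None:
        if self.values.ndim != 3:
            raise ValueError("feature stack must be (H, W, C)")
        if self.values.shape[2] != len(self.channel_names):
            raise ValueError("channel_names length must match the channel axis")

    def channel(self, name: str) -> np.ndarray:
        """Return one channel plane by canonical name."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"unknown channel {name!r}") from None
        return self.values[:, :, idx]

    def restrict(self, names: Sequence[str]) -> "ColorFeatureStack":
        """Return a stack containing only ``names``, in the order given."""
        idx = []
        for name in names:
            if name not in self.channel_names:
                raise KeyError(f"unknown channel {name!r}")
            idx.append(self.channel_names.index(name))
        return ColorFeatureStack(self.values[:, :, idx], tuple(names))

    def as_matrix(self) -> np.ndarray:
        """Flatten to an (n_pixels, n_channels) feature matrix (row-major)."""
        return self.values.reshape(-1, self.n_channels)


def _rgb_to_hls(rgb01: np.ndarray) -> np.ndarray:
    """Vectorised RGB -> HLS with all three channels in [0, 1].

    Hue matches the HSV hue; lightness is (max+min)/2; saturation follows the
    standard bi-conic definition (chroma over 1-|2L-1|).
    """
    maxc = rgb01.max(axis=-1)
    minc = rgb01.min(axis=-1)
    chroma = maxc - minc
    light = (maxc + minc) / 2.0

    hue = _skcolor.rgb2hsv(rgb01)[..., 0]  # already the HSL hue, in [0, 1)

    sat = np.zeros_like(light)
    denom = 1.0 - np.abs(2.0 * light - 1.0)
    nz = (chroma > 0) & (denom > 0)
    sat[nz] = chroma[nz] / denom[nz]
    return np.stack([hue, light, np.clip(sat, 0.0, 1.0)], axis=-1)


def _rgb_to_ycbcr_full(rgb01: np.ndarray) -> np.ndarray:
    """BT.601 full-range YCbCr, each channel rescaled to [0, 1]."""
    r, g, b = rgb01[..., 0], rgb01[..., 1], rgb01[..., 2]
    y = 0.299 * r + 0.587 * g + 0.114 * b
    cb = 0.5 - 0.168736 * r - 0.331264 * g + 0.5 * b
    cr = 0.5 + 0.5 * r - 0.418688 * g - 0.081312 * b
    return np.stack([y, cb, cr], axis=-1)


def to_feature_stack(image: np.ndarray) -> ColorFeatureStack:
    """Expand an 8-bit RGB image into the canonical 24-channel stack.

    Deterministic; the ``rgb.*`` planes, multiplied back by 255, reproduce
    the input exactly.
    """
    img = validate_rgb_image(image)
    rgb01 = img.astype(np.float64) / 255.0

    hsv = _skcolor.rgb2hsv(rgb01)
    ycbcr = _rgb_to_ycbcr_full(rgb01)

    lab = _skcolor.rgb2lab(rgb01)  # D65 / 2-deg observer
    lab_n = np.stack(
        [lab[..., 0] / 100.0, (lab[..., 1] + 128.0) / 255.0, (lab[..., 2] + 128.0) / 255.0],
        axis=-1,
    )

    yuv = _skcolor.rgb2yuv(rgb01)
    yuv_n = np.stack(
        [yuv[..., 0], yuv[..., 1] / (2 * 0.436) + 0.5, yuv[..., 2] / (2 * 0.615) + 0.5],
        axis=-1,
    )

    luv = _skcolor.rgb2luv(rgb01)
    u_lo, u_hi = _LUV_U_RANGE
    v_lo, v_hi = _LUV_V_RANGE
    luv_n = np.stack(
        [
            luv[..., 0] / 100.0,
            (luv[..., 1] - u_lo) / (u_hi - u_lo),
            (luv[..., 2] - v_lo) / (v_hi - v_lo),
        ],
        axis=-1,
    )

    hls = _rgb_to_hls(rgb01)

    xyz = _skcolor.rgb2xyz(rgb01)
    xyz_n = xyz / np.asarray(_D65_XYZ)

    stack = np.concatenate([rgb01, hsv, ycbcr, lab_n, yuv_n, luv_n, hls, xyz_n], axis=-1)
    np.clip(stack, 0.0, 1.0, out=stack)
    return ColorFeatureStack(stack, CHANNEL_NAMES)


# ---------------------------------------------------------------------------
# Color-checker correction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HueGroup:
    """A named group of checker tiles with a target hue angle.

    ``band`` is the half-open angular interval [lo, hi) of hues (degrees)
    that the group's correction applies to; bands wrapping through 0 are
    expressed with lo > hi.
    """

    name: str
    target_hue_deg: float
    band: tuple[float, float]

    def contains(self, hue_deg: np.ndarray) -> np.ndarray:
        lo, hi = self.band
        if lo <= hi:
            return (hue_deg >= lo) & (hue_deg < hi)
        return (hue_deg >= lo) | (hue_deg < hi)


@dataclass(frozen=True)
class ColorCheckerReference:
    """Reference values of a 24-tile color checker.

    ``patch_rgbs`` holds the published (R, G, B) triplet of every tile;
    ``gray_indices`` picks out the neutral tiles used for white balance;
    ``hue_groups`` names the chromatic tile groups (green, brown, yellow)
    used for hue calibration.
    """

    patch_rgbs: tuple[tuple[int, int, int], ...]
    gray_indices: tuple[int, ...]
    hue_groups: tuple[HueGroup, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if len(self.patch_rgbs) != 24:
            raise ValueError("a color checker has exactly 24 tiles")
        if not self.gray_indices:
            raise ValueError("gray_indices must be nonempty")
        for grp in self.hue_groups:
            if not 0.0 <= grp.target_hue_deg < 360.0:
                raise ValueError(f"target hue of group {grp.name!r} outside [0, 360)")

    @property
    def mean_gray(self) -> np.ndarray:
        grays = np.asarray([self.patch_rgbs[i] for i in self.gray_indices], dtype=float)
        return grays.mean(axis=0)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ColorCheckerReference":
        """Load a 24-row CSV ``index,R,G,B,group`` (group may be empty).

        Rows whose group is ``gray`` populate ``gray_indices``.  Chromatic
        groups get their target hue from the mean hue of their member tiles
        and a band of +/-30 degrees around it.
        """
        rows: list[tuple[int, int, int, int, str]] = []
        with open(path, newline="") as fh:
            for rec in csv.reader(fh):
                if not rec or rec[0].startswith("#") or rec[0].lower() == "index":
                    continue
                idx, r, g, b = int(rec[0]), int(rec[1]), int(rec[2]), int(rec[3])
                group = rec[4].strip().lower() if len(rec) > 4 else ""
                rows.append((idx, r, g, b, group))
        rows.sort()
        patch_rgbs = tuple((r, g, b) for _, r, g, b, _ in rows)
        gray_indices = tuple(i for i, (_, _, _, _, grp) in enumerate(rows) if grp == "gray")

        groups: dict[str, list[int]] = {}
        for i, (_, _, _, _, grp) in enumerate(rows):
            if grp and grp != "gray":
                groups.setdefault(grp, []).append(i)
        hue_groups = []
        for name, members in sorted(groups.items()):
            hues = [_hue_of_rgb(patch_rgbs[i]) for i in members]
            target = float(np.mean(hues))
            lo, hi = (target - 30.0) % 360.0, (target + 30.0) % 360.0
            hue_groups.append(HueGroup(name, target % 360.0, (lo, hi)))
        return cls(patch_rgbs, gray_indices, tuple(hue_groups))


def _hue_of_rgb(rgb: Sequence[float]) -> float:
    arr = np.asarray(rgb, dtype=np.float64).reshape(1, 1, 3) / 255.0
    return float(_skcolor.rgb2hsv(arr)[0, 0, 0] * 360.0)


def white_balance(
    image: np.ndarray,
    observed_grays: Sequence[Sequence[float]],
    reference: ColorCheckerReference,
) -> np.ndarray:
    """Linear per-channel white balance from neutral checker tiles.

    The gain on each channel maps the mean observed gray onto the mean
    reference gray; the corrected image is clipped back to [0, 255].
    """
    img = validate_rgb_image(image)
    obs = np.asarray(observed_grays, dtype=np.float64)
    if obs.ndim != 2 or obs.shape[1] != 3 or obs.shape[0] < 1:
        raise ValueError("observed_grays must be a nonempty list of RGB triplets")
    obs_mean = obs.mean(axis=0)
    if np.any(obs_mean <= 0):
        raise ValueError("degenerate gain: observed gray has a zero channel")
    gains = reference.mean_gray / obs_mean
    out = img.astype(np.float64) * gains
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def hue_correct(
    image: np.ndarray,
    observed_hues: Mapping[str, float],
    reference: ColorCheckerReference,
) -> np.ndarray:
    """Shift pixel hues per checker group so observed hues meet their targets.

    For each hue group (e.g. the green tiles) the offset ``target - observed``
    is added, modulo 360, to the hue of every chromatic pixel whose hue lies
    in that group's angular band.  Saturation and value are untouched, and
    achromatic pixels (S = 0) are left alone because their hue is undefined.
    """
    img = validate_rgb_image(image)
    for name, hue in observed_hues.items():
        if not 0.0 <= hue < 360.0:
            raise ValueError(f"observed hue for group {name!r} outside [0, 360)")
    covered = {g.name for g in reference.hue_groups}
    missing = covered - set(observed_hues)
    if missing:
        raise ValueError(f"observed hues missing for groups: {sorted(missing)}")

    hsv = _skcolor.rgb2hsv(img.astype(np.float64) / 255.0)
    hue_deg = hsv[..., 0] * 360.0
    sat = hsv[..., 1]

    new_hue = hue_deg.copy()
    for grp in reference.hue_groups:
        offset = grp.target_hue_deg - observed_hues[grp.name]
        mask = grp.contains(hue_deg) & (sat > 0)
        new_hue[mask] = (hue_deg[mask] + offset) % 360.0

    hsv_out = hsv.copy()
    hsv_out[..., 0] = new_hue / 360.0
    rgb = _skcolor.hsv2rgb(hsv_out)
    return np.clip(np.rint(rgb * 255.0), 0, 255).astype(np.uint8)


def load_rgb_image(path: str | Path) -> np.ndarray:
    """Read a JPEG/PNG file as an 8-bit RGB array (alpha dropped)."""
    from PIL import Image

    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"), dtype=np.uint8)
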