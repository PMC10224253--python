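"""Seeded synthetic plant scenes with exact ground-truth masks.

The generator emulates the two imaging situations the pipeline targets:

* **glasshouse** — plant rosettes photographed from above against a fairly
  plain compost background;
* **field** — a canopy over cluttered soil scattered with straw-yellow and
  stone-gray debris.

Plants are unions of rotated elliptical leaf lobes around randomly placed
centers.  Leaf hue is drawn from a configurable normal distribution whose
mean tracks nutrient status: healthy plants sit in the green band
(roughly 100-140 degrees) and nutrient-deficient ones drift through yellow
toward brown (30-60 degrees).  A smooth linear illumination gradient and
additive Gaussian pixel noise are applied after rendering; the ground-truth
mask records exactly the pre-noise leaf pixels.

SPAD cohorts pair each scene with a greenness-linked SPAD value,
``spad = a + b * greenness + N(0, sigma^2)`` where greenness is the mean
excess-green index of the true plant pixels rescaled to [0, 1].  All
randomness flows through a single integer seed.
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from skimage.draw import ellipse as _sk_ellipse

from .dataset import PATCH_SIZE, Patch
from .vegindices import index_image

__all__ = [
    "SceneConfig",
    "SyntheticScene",
    "GLASSHOUSE",
    "FIELD",
    "generate_scene",
    "generate_patchset",
    "generate_spad_cohort",
    "scene_greenness",
]

# ExG on 8-bit channels spans [-510, 510]; used to rescale greenness to [0, 1].
_EXG_SPAN = (-510.0, 510.0)


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of a rendered scene.

    ``foreground_hue_mean`` encodes nutrient status: ~115 degrees for a
    healthy green canopy, sliding toward ~45 degrees (yellow-brown) under
    deficiency.  ``spad_link = (a, b, sigma)`` defines the SPAD response
    to rendered greenness; the defaults map the renderer's greenness span
    onto a realistic SPAD working range (~15-50 meter units) with a
    repeatability noise of 1.5 units.
    """

    height: int = 192
    width: int = 192
    scene_type: str = "glasshouse"  # or "field"
    n_plants: int = 3
    leaves_per_plant: int = 8
    leaf_axis_range: tuple[int, int] = (10, 26)
    foreground_hue_mean: float = 115.0  # degrees
    foreground_hue_sd: float = 8.0
    deficient_hue_mean: float = 45.0  # hue at the most depleted nutrient level
    illumination_gradient_amplitude: float = 0.10
    pixel_noise_sd: float = 4.0  # 8-bit units
    clutter_density: float = 0.0  # clutter ellipses per pixel (field scenes)
    spad_link: tuple[float, float, float] = (-190.0, 350.0, 1.5)

    def __post_init__(self) -> None:
        if not 0.0 <= self.foreground_hue_mean < 360.0:
            raise ValueError("foreground hue mean must lie in [0, 360)")
        if self.pixel_noise_sd < 0:
            raise ValueError("pixel noise sd must be >= 0")
        if self.leaf_axis_range[0] < 2:
            raise ValueError("leaf axes must be >= 2 px")
        if self.spad_link[2] < 0:
            raise ValueError("SPAD noise sigma must be >= 0")


#: Preset configurations for the two imaging situations.
GLASSHOUSE = SceneConfig()
FIELD = SceneConfig(
    scene_type="field", n_plants=4, leaves_per_plant=7,
    foreground_hue_mean=80.0, foreground_hue_sd=26.0,
    illumination_gradient_amplitude=0.18, pixel_noise_sd=8.0,
    clutter_density=0.0025,
)


@dataclass(frozen=True)
class SyntheticScene:
    image: np.ndarray  # (H, W, 3) uint8
    truth: np.ndarray  # (H, W) uint8, {0, 255}; exactly the rendered leaf pixels
    nutrient_level: float  # 1 = healthy, 0 = fully deficient
    spad_true: float
    seed: int


def _hsv_to_rgb255(h_deg: float, s: float, v: float) -> np.ndarray:
    r, g, b = colorsys.hsv_to_rgb((h_deg % 360.0) / 360.0, s, v)
    return np.array([r, g, b]) * 255.0


def _smooth_texture(rng: np.random.Generator, shape: tuple[int, int], scale: float) -> np.ndarray:
    """Low-frequency multiplicative texture in [1-scale, 1+scale]."""
    coarse = rng.uniform(-1.0, 1.0, size=(max(shape[0] // 16, 2), max(shape[1] // 16, 2)))
    from skimage.transform import resize

    fine = resize(coarse, shape, order=1, anti_aliasing=False)
    return 1.0 + scale * fine


_BACKGROUND_BASE = {
    "glasshouse": (72.0, 54.0, 38.0),   # moist compost brown
    "field": (108.0, 86.0, 62.0),       # drier field soil
}
_CLUTTER_COLORS = (
    (205.0, 178.0, 110.0),  # straw
    (142.0, 140.0, 134.0),  # stone
)


def generate_scene(config: SceneConfig, seed: int) -> SyntheticScene:
    """Render one scene; identical config+seed gives a byte-identical result."""
    if config.scene_type not in _BACKGROUND_BASE:
        raise ValueError(f"unknown scene type {config.scene_type!r}")
    rng = np.random.default_rng(seed)
    h, w = config.height, config.width

    base = np.asarray(_BACKGROUND_BASE[config.scene_type])
    img = np.empty((h, w, 3), dtype=np.float64)
    texture = _smooth_texture(rng, (h, w), 0.25)
    img[:] = base
    img *= texture[..., None]

    if config.scene_type == "field" and config.clutter_density > 0:
        n_clutter = rng.poisson(config.clutter_density * h * w)
        for _ in range(n_clutter):
            cy, cx = rng.uniform(0, h), rng.uniform(0, w)
            ry, rx = rng.uniform(2, 7), rng.uniform(2, 7)
            rot = rng.uniform(0, np.pi)
            rr, cc = _sk_ellipse(cy, cx, ry, rx, shape=(h, w), rotation=rot)
            color = np.asarray(_CLUTTER_COLORS[rng.integers(len(_CLUTTER_COLORS))])
            img[rr, cc] = color * rng.uniform(0.85, 1.15)

    # plants: overlapping elliptical leaf lobes around each center
    truth = np.zeros((h, w), dtype=bool)
    lo, hi = config.leaf_axis_range
    margin = hi + 2
    if 2 * margin >= min(h, w) and config.n_plants > 0:
        raise ValueError(
            f"plants with leaf axes up to {hi} px cannot fit a {h}x{w} canvas"
        )
    for _ in range(config.n_plants):
        py = rng.uniform(margin, h - margin)
        px = rng.uniform(margin, w - margin)
        for _ in range(config.leaves_per_plant):
            angle = rng.uniform(0, 2 * np.pi)
            major = rng.uniform(lo, hi)
            minor = major * rng.uniform(0.35, 0.6)
            dist = major * rng.uniform(0.5, 0.9)
            cy = py + dist * np.sin(angle)
            cx = px + dist * np.cos(angle)
            hue = rng.normal(config.foreground_hue_mean, config.foreground_hue_sd)
            sat = rng.uniform(0.55, 0.85)
            val = rng.uniform(0.45, 0.75)
            rr, cc = _sk_ellipse(cy, cx, minor, major, shape=(h, w), rotation=angle)
            img[rr, cc] = _hsv_to_rgb255(hue, sat, val)
            truth[rr, cc] = True

    if config.illumination_gradient_amplitude > 0:
        theta = rng.uniform(0, 2 * np.pi)
        yy, xx = np.mgrid[0:h, 0:w]
        t = ((yy / max(h - 1, 1) - 0.5) * np.sin(theta)
             + (xx / max(w - 1, 1) - 0.5) * np.cos(theta)) * 2.0
        img *= (1.0 + config.illumination_gradient_amplitude * t)[..., None]

    if config.pixel_noise_sd > 0:
        img += rng.normal(0.0, config.pixel_noise_sd, size=img.shape)

    image = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    truth_mask = np.where(truth, 255, 0).astype(np.uint8)

    scene = SyntheticScene(image, truth_mask, nutrient_level=1.0,
                           spad_true=float("nan"), seed=seed)
    a, b, sigma = config.spad_link
    spad = a + b * scene_greenness(scene)
    if sigma > 0:
        spad += rng.normal(0.0, sigma)
    return replace(scene, spad_true=float(spad))


def scene_greenness(scene: SyntheticScene) -> float:
    """Mean excess-green of the true plant pixels, rescaled to [0, 1]."""
    fg = scene.truth > 0
    if not fg.any():
        return 0.0
    exg = index_image(scene.image, "ExG").values[fg]
    lo, hi = _EXG_SPAN
    return float((exg.mean() - lo) / (hi - lo))


def _pure_windows(region: np.ndarray, size: int) -> np.ndarray:
    """Top-left corners of size x size windows entirely inside ``region``."""
    from numpy.lib.stride_tricks import sliding_window_view

    if region.shape[0] < size or region.shape[1] < size:
        return np.empty((0, 2), dtype=np.int64)
    win = sliding_window_view(region.astype(np.uint8), (size, size))
    pure = win.sum(axis=(2, 3)) == size * size
    return np.argwhere(pure)


def generate_patchset(
    config: SceneConfig,
    n_fg: int,
    n_bg: int,
    seed: int,
    *,
    max_scenes: int = 200,
) -> list[Patch]:
    """Sample pure 20x20 foreground/background patches from fresh scenes.

    Foreground patches lie entirely inside the truth mask, background
    patches entirely outside it, so patch labels are guaranteed correct.
    Raises if the requested counts cannot be met within ``max_scenes``
    freshly generated scenes.
    """
    seeds = np.random.SeedSequence(seed).generate_state(max_scenes + 1)
    rng = np.random.default_rng(seeds[0])
    label_of = {1: "fg", 0: "bg"}
    needed = {1: n_fg, 0: n_bg}
    patches: list[Patch] = []
    source = config.scene_type

    for scene_i in range(max_scenes):
        if all(v <= 0 for v in needed.values()):
            break
        scene = generate_scene(config, int(seeds[scene_i + 1] % (2**31)))
        fg = scene.truth > 0
        for label, region in ((1, fg), (0, ~fg)):
            if needed[label] <= 0:
                continue
            corners = _pure_windows(region, PATCH_SIZE)
            if corners.shape[0] == 0:
                continue
            # cap per scene so patches come from many independent scenes
            take = min(needed[label], max(1, corners.shape[0] // 50), 50)
            chosen = corners[rng.choice(corners.shape[0], size=take, replace=False)]
            for y, x in chosen:
                crop = scene.image[y:y + PATCH_SIZE, x:x + PATCH_SIZE].copy()
                patches.append(
                    Patch(
                        crop=crop, label=label, source=source,
                        patch_id=f"{label_of[label]}-{scene_i}-{y}-{x}",
                    )
                )
            needed[label] -= take
    if any(v > 0 for v in needed.values()):
        raise RuntimeError(
            f"could not sample enough pure patches within {max_scenes} scenes "
            f"(missing fg={max(needed[1], 0)}, bg={max(needed[0], 0)})"
        )
    return patches


def generate_spad_cohort(
    config: SceneConfig,
    n: int,
    seed: int,
) -> list[SyntheticScene]:
    """Generate ``n`` scenes whose nutrient levels span deficient..healthy.

    Nutrient level i/(n-1) linearly interpolates the leaf hue mean between
    ``deficient_hue_mean`` and ``foreground_hue_mean``; each scene carries
    its greenness-linked ``spad_true``.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    seeds = np.random.SeedSequence(seed).generate_state(n)
    cohort = []
    for i in range(n):
        level = 1.0 if n == 1 else i / (n - 1)
        hue = config.deficient_hue_mean + level * (
            config.foreground_hue_mean - config.deficient_hue_mean
        )
        cfg = replace(config, foreground_hue_mean=hue % 360.0)
        scene = generate_scene(cfg, int(seeds[i] % (2**31)))
        cohort.append(replace(scene, nutrient_level=level))
    return cohort
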