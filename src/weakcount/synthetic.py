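"""Seeded synthetic plant scenes with exact ground truth.

Generates RGB images of bright, roughly convex "boll" blobs on darker
textured backgrounds, together with per-blob point marks, per-blob masks
and the exact count. Every downstream stage (tiling, annotation I/O,
model training, evaluation) is testable on these scenes without any
external imagery.

Blobs are intensity-elevated ellipses with Gaussian-softened edges — a
learnable stand-in for sunlit cotton bolls against foliage. Occlusion is
painter's-algorithm: a later blob may cover part of an earlier one, but
placement is rejected unless every blob keeps at least 25% of its area
visible, and an occluded blob still contributes its point and its
(clipped) mask, mirroring how partially visible organs are still counted.

Coordinates are 0-based ``(x, y) = (column, row)`` with the origin at the
top-left, the convention used by every module in this package.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "SceneConfig",
    "Scene",
    "SceneGenerationError",
    "generate_scene",
    "generate_dataset",
    "benchmark_config",
    "BIN_RANGES",
]

# count-bin name -> inclusive count range; bin names shared with the
# annotations module (Table-2-style subitizing bins)
BIN_RANGES: dict[str, tuple[int, int]] = {
    "zero": (0, 0),
    "b1_5": (1, 5),
    "b6_10": (6, 10),
    "b11_15": (11, 15),
}

_MAX_PLACEMENT_TRIES = 300
_MIN_VISIBLE_FRACTION = 0.25

# fixed rendering constants (documented, not exposed): base canopy color,
# foliage-field smoothing relative to image side, shadow darkening factor
_BASE_GREEN = np.array([0.10, 0.18, 0.08], dtype=np.float64)
_FOLIAGE_SIGMA_FRACTION = 1 / 16
_FOLIAGE_AMPLITUDE = 0.35
_NOISE_SIGMA = 0.035
_SHADOW_FACTOR = 0.55


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one synthetic scene.

    Defaults emulate a 500×500 plant tile: up to 15 bolls of 18–45 px
    radius on a foliage-like background with occasional occlusion and
    shadows, matching the count range retained for training (tiles with
    more than 15 bolls are treated as not-countable downstream).
    """

    image_height_px: int = 500
    image_width_px: int = 500
    count_range: tuple[int, int] = (0, 15)
    blob_radius_range_px: tuple[float, float] = (18.0, 45.0)
    blob_eccentricity_range: tuple[float, float] = (0.0, 0.6)
    blob_intensity_range: tuple[float, float] = (0.75, 0.98)
    background_texture: str = "foliage-like"
    occlusion_probability: float = 0.3
    shadow_probability: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_height_px < 1 or self.image_width_px < 1:
            raise ValueError("image dimensions must be positive")
        lo, hi = self.count_range
        if lo < 0 or hi < lo:
            raise ValueError("count_range must satisfy 0 <= min <= max")
        rlo, rhi = self.blob_radius_range_px
        if rlo <= 0 or rhi < rlo:
            raise ValueError("blob_radius_range_px must be positive and ordered")
        elo, ehi = self.blob_eccentricity_range
        if not (0 <= elo <= ehi < 1):
            raise ValueError("blob_eccentricity_range must lie in [0, 1)")
        ilo, ihi = self.blob_intensity_range
        if not (0 <= ilo <= ihi <= 1):
            raise ValueError("blob_intensity_range must lie in [0, 1]")
        if self.background_texture not in ("flat", "noise", "foliage-like"):
            raise ValueError(
                "background_texture must be 'flat', 'noise' or 'foliage-like'"
            )
        for name in ("occlusion_probability", "shadow_probability"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class Scene:
    """A rendered scene plus its exact ground truth.

    ``count == len(points) == len(masks)``; every point (the blob center)
    lies inside its own mask; image values are in [0, 1].
    """

    image: np.ndarray
    points: list[tuple[float, float]]
    masks: list[np.ndarray]
    count: int
    config: SceneConfig = field(repr=False, default=None)

    def validate(self) -> None:
        if not (self.count == len(self.points) == len(self.masks)):
            raise AssertionError("count / points / masks disagree")
        if self.image.min() < 0 or self.image.max() > 1:
            raise AssertionError("image values outside [0, 1]")
        for (x, y), mask in zip(self.points, self.masks):
            if not mask[int(round(y)), int(round(x))]:
                raise AssertionError(f"point ({x}, {y}) outside its mask")


class SceneGenerationError(RuntimeError):
    """Raised when blob placement fails within the retry budget."""


def _ellipse_mask(
    h: int, w: int, cx: float, cy: float, a: float, b: float, theta: float
) -> np.ndarray:
    """Boolean mask of a rotated ellipse, clipped to the image."""
    r0 = max(int(np.floor(cy - a)) - 1, 0)
    r1 = min(int(np.ceil(cy + a)) + 2, h)
    c0 = max(int(np.floor(cx - a)) - 1, 0)
    c1 = min(int(np.ceil(cx + a)) + 2, w)
    mask = np.zeros((h, w), dtype=bool)
    if r0 >= r1 or c0 >= c1:
        return mask
    yy, xx = np.mgrid[r0:r1, c0:c1]
    dx, dy = xx - cx, yy - cy
    ct, st = np.cos(theta), np.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    mask[r0:r1, c0:c1] = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return mask


def _render_background(cfg: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    h, w = cfg.image_height_px, cfg.image_width_px
    img = np.broadcast_to(_BASE_GREEN, (h, w, 3)).copy()
    if cfg.background_texture == "noise":
        img = img + rng.normal(0.0, _NOISE_SIGMA, size=(h, w, 3))
    elif cfg.background_texture == "foliage-like":
        sigma = max(1.0, min(h, w) * _FOLIAGE_SIGMA_FRACTION)
        fld = gaussian_filter(rng.standard_normal((h, w)), sigma=sigma)
        std = fld.std()
        if std > 0:
            fld = fld / std
        img = img * (1.0 + _FOLIAGE_AMPLITUDE * fld[..., None])
        img = img + rng.normal(0.0, _NOISE_SIGMA / 2, size=(h, w, 3))
    return np.clip(img, 0.0, 1.0)


def generate_scene(config: SceneConfig) -> Scene:
    """Render one seeded scene; identical config ⇒ bit-identical output.

    The declared count is drawn uniformly from ``count_range``. Blob
    placement uses rejection sampling so every blob — including occluded
    ones — keeps at least 25% of its area visible; exhaustion of the
    retry budget raises :class:`SceneGenerationError` naming the config
    fields to loosen.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.image_height_px, cfg.image_width_px
    lo, hi = cfg.count_range
    count = int(rng.integers(lo, hi + 1))

    blobs: list[dict] = []  # cx, cy, a, b, theta, mask
    visible: list[np.ndarray] = []  # per-blob currently-visible region
    for _ in range(count):
        may_occlude = rng.random() < cfg.occlusion_probability
        placed = False
        for _attempt in range(_MAX_PLACEMENT_TRIES):
            a = rng.uniform(*cfg.blob_radius_range_px)
            ecc = rng.uniform(*cfg.blob_eccentricity_range)
            b = a * np.sqrt(1.0 - ecc**2)
            theta = rng.uniform(0.0, np.pi)
            margin = min(a, (min(h, w) - 1) / 2)
            cx = rng.uniform(margin, w - 1 - margin)
            cy = rng.uniform(margin, h - 1 - margin)
            mask = _ellipse_mask(h, w, cx, cy, a, b, theta)
            if not mask[int(round(cy)), int(round(cx))]:
                continue  # degenerate raster; retry
            overlaps = [i for i, vis in enumerate(visible) if (mask & vis).any()]
            if overlaps and not may_occlude:
                continue
            if overlaps:
                ok = True
                for i in overlaps:
                    remaining = visible[i] & ~mask
                    if remaining.sum() < _MIN_VISIBLE_FRACTION * blobs[i]["mask"].sum():
                        ok = False
                        break
                if not ok:
                    continue
            for i in overlaps:
                visible[i] = visible[i] & ~mask
            blobs.append({"cx": cx, "cy": cy, "a": a, "b": b, "theta": theta, "mask": mask})
            visible.append(mask.copy())
            placed = True
            break
        if not placed:
            raise SceneGenerationError(
                f"could not place blob {len(blobs) + 1}/{count} after "
                f"{_MAX_PLACEMENT_TRIES} tries; loosen count_range or "
                "blob_radius_range_px (or raise occlusion_probability)"
            )

    img = _render_background(cfg, rng)

    # shadows first, so they never cover a boll
    for blob in blobs:
        if rng.random() < cfg.shadow_probability:
            ang = rng.uniform(0.0, 2 * np.pi)
            off = 0.8 * blob["a"]
            sh = _ellipse_mask(
                h,
                w,
                blob["cx"] + off * np.cos(ang),
                blob["cy"] + off * np.sin(ang),
                blob["a"],
                blob["b"],
                blob["theta"],
            )
            img[sh] *= _SHADOW_FACTOR

    for blob in blobs:
        intensity = rng.uniform(*cfg.blob_intensity_range)
        color = np.array([intensity, intensity * 0.98, intensity * 0.93])
        alpha = gaussian_filter(
            blob["mask"].astype(np.float64), sigma=max(0.7, blob["a"] / 8)
        )
        amax = alpha.max()
        if amax > 0:
            alpha /= amax
        img = img * (1.0 - alpha[..., None]) + color * alpha[..., None]

    scene = Scene(
        image=np.clip(img, 0.0, 1.0),
        points=[(blob["cx"], blob["cy"]) for blob in blobs],
        masks=[blob["mask"] for blob in blobs],
        count=count,
        config=cfg,
    )
    scene.validate()
    return scene


def generate_dataset(
    n_scenes: int,
    bin_weights: dict[str, float],
    config: SceneConfig,
) -> list[Scene]:
    """Draw scenes whose counts follow a count-bin distribution.

    ``bin_weights`` maps bin names (``zero``, ``b1_5``, ``b6_10``,
    ``b11_15``) to nonnegative weights; weights are normalized and each
    scene's bin is drawn multinomially, then its count uniformly within
    the bin. This reproduces the count-bin imbalance of real tile
    datasets, where small counts dominate.
    """
    if n_scenes <= 0:
        raise ValueError("n_scenes must be positive")
    names = []
    weights = []
    for name, wt in bin_weights.items():
        key = getattr(name, "value", name)  # accept CountBin enums
        if key not in BIN_RANGES:
            raise ValueError(f"unknown count bin {name!r}")
        if wt < 0:
            raise ValueError("bin weights must be nonnegative")
        names.append(key)
        weights.append(float(wt))
    total = sum(weights)
    if total == 0:
        raise ValueError("bin weights must not all be zero")
    probs = np.asarray(weights) / total

    rng = np.random.default_rng(config.seed)
    scenes = []
    for _ in range(n_scenes):
        name = names[int(rng.choice(len(names), p=probs))]
        blo, bhi = BIN_RANGES[name]
        count = int(rng.integers(blo, bhi + 1))
        child = int(rng.integers(0, 2**31 - 1))
        scenes.append(
            generate_scene(
                dataclasses.replace(config, count_range=(count, count), seed=child)
            )
        )
    return scenes


def benchmark_config(seed: int = 0, tile_px: int = 64) -> SceneConfig:
    """Desk-scale benchmark conditions: small tiles, counts 0–5,
    well-separated blobs (no occlusion or shadows), noisy background.

    This is the fixed setting used by the package's training sanity
    checks and the scaled-down evaluation scripts.
    """
    return SceneConfig(
        image_height_px=tile_px,
        image_width_px=tile_px,
        count_range=(0, 5),
        blob_radius_range_px=(4.0, 7.0),
        blob_eccentricity_range=(0.0, 0.5),
        blob_intensity_range=(0.8, 0.98),
        background_texture="noise",
        occlusion_probability=0.0,
        shadow_probability=0.0,
        seed=seed,
    )
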