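"""Seeded synthetic greenhouse scenes with ground truth.

Real greenhouse imagery of ripening tomatoes is dominated by three strata —
red quasi-circular fruit, green elongated foliage and stems, and brown/grey
soil or structure — photographed under two illumination regimes (sunny and
shadow).  The generator emulates exactly those features: it rasterises
fruit as shaded ellipses, overlays elongated foliage strokes that partially
occlude fruit boundaries, applies a global illumination gain plus a linear
gradient, and adds Gaussian pixel noise.  Visible (non-occluded) fruit
pixels define the ground-truth mask.

Everything is driven by one integer seed, so calibration, training,
weighting, classification and fusion are all testable end to end with
bit-identical reruns and no external data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import draw

from .features import (
    FEATURE_NAMES,
    FeatureConfig,
    NormalizationStats,
    apply_normalization,
    fit_normalization,
    image_feature_table,
)
from .imaging import as_mask, as_rgb_image, tile_blocks

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ColourModel:
    """Per-channel Gaussian colour model (mean, sd) on the 0-255 scale."""

    mean: tuple[float, float, float]
    sd: float


#: Default stratum colours: red-dominant fruit, green-dominant foliage,
#: neutral brown/grey background.  Chosen so the chromatic discriminant
#: separates fruit cleanly while leaving enough overlap (via noise and
#: shading) that the learned second layer still has work to do.
FRUIT_COLOUR = ColourModel((190.0, 60.0, 50.0), 15.0)
FOLIAGE_COLOUR = ColourModel((60.0, 140.0, 55.0), 15.0)
BACKGROUND_COLOUR = ColourModel((120.0, 110.0, 100.0), 20.0)

#: Illumination gains for the two regimes; the shadow side keeps the same
#: scene geometry but at roughly half the light.
SUNNY_GAIN = 1.0
SHADOW_GAIN = 0.45
GRADIENT_SPAN = 0.15  # +/- relative illumination across the image width

# stratum codes in the layer map
LAYER_BACKGROUND = 0
LAYER_FRUIT = 1
LAYER_FOLIAGE = 2


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic scene.

    Defaults describe a scaled-down greenhouse view: a few fruit of 18-30 px
    radius in a 192x256 frame with moderate foliage occlusion and sensor
    noise of 8 grey levels.
    """

    height: int = 192
    width: int = 256
    n_fruit: int = 4
    radius_range: tuple[int, int] = (18, 30)
    fruit_colour: ColourModel = FRUIT_COLOUR
    foliage_colour: ColourModel = FOLIAGE_COLOUR
    background_colour: ColourModel = BACKGROUND_COLOUR
    illumination: str = "sunny"  # {"sunny", "shadow"}
    occlusion_fraction: float = 0.15
    noise_sd: float = 8.0
    n_background_strokes: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.illumination not in ("sunny", "shadow"):
            raise ValueError("illumination must be 'sunny' or 'shadow'")
        if not 0.0 <= self.occlusion_fraction <= 1.0:
            raise ValueError("occlusion_fraction must lie in [0, 1]")
        if 2 * self.radius_range[1] >= min(self.height, self.width):
            raise ValueError("radius_range does not fit in the image")


@dataclass
class Scene:
    """A generated scene: image, ground truth and bookkeeping tables."""

    image: np.ndarray  # (H, W, 3) uint8
    truth_mask: np.ndarray  # (H, W) uint8, 255 = visible fruit
    fruit_table: pd.DataFrame  # centre/radii/visible pixel count per fruit
    layer_map: np.ndarray  # (H, W) stratum codes
    spec: SceneSpec

    def __iter__(self):  # allows  img, truth, table = scene
        return iter((self.image, self.truth_mask, self.fruit_table))


def _place_fruit(
    rng: np.random.Generator, spec: SceneSpec, max_retries: int = 200
) -> list[tuple[int, int, int, int, float]]:
    """Sample non-overlapping ellipse placements (cy, cx, ry, rx, angle)."""
    placements: list[tuple[int, int, int, int, float]] = []
    r_lo, r_hi = spec.radius_range
    for _ in range(spec.n_fruit):
        for attempt in range(max_retries):
            r_major = int(rng.integers(r_lo, r_hi + 1))
            r_minor = int(round(r_major * rng.uniform(0.85, 1.0)))  # quasi-circular
            cy = int(rng.integers(r_major + 1, spec.height - r_major - 1))
            cx = int(rng.integers(r_major + 1, spec.width - r_major - 1))
            ok = all(
                (cy - p[0]) ** 2 + (cx - p[1]) ** 2 > (r_major + p[2] + 2) ** 2
                for p in placements
            )
            if ok:
                placements.append((cy, cx, r_major, r_minor, rng.uniform(0, np.pi)))
                break
        else:
            raise RuntimeError(
                f"could not place {spec.n_fruit} non-overlapping fruit of radius "
                f"{spec.radius_range} in a {spec.height}x{spec.width} scene"
            )
    return placements


def _stroke_mask(
    rng: np.random.Generator,
    shape: tuple[int, int],
    start: tuple[float, float],
    angle: float,
    length: float,
    thickness: int,
) -> np.ndarray:
    """Rasterise one elongated foliage stroke as a thick line segment."""
    h, w = shape
    r0, c0 = start
    r1 = r0 + length * np.sin(angle)
    c1 = c0 + length * np.cos(angle)
    mask = np.zeros(shape, bool)
    rr, cc = draw.line(
        int(np.clip(r0, 0, h - 1)),
        int(np.clip(c0, 0, w - 1)),
        int(np.clip(r1, 0, h - 1)),
        int(np.clip(c1, 0, w - 1)),
    )
    mask[rr, cc] = True
    if thickness > 1:
        mask = ndimage.binary_dilation(mask, iterations=thickness // 2)
    return mask


def generate_scene(spec: SceneSpec) -> Scene:
    """Render one scene deterministically from its spec.

    Fruit are laid down first, then foliage strokes: background strokes
    anywhere, plus per-fruit occluding strokes that cross the fruit boundary
    and penetrate part-way (so a fruit is occluded but rarely bisected).
    Illumination (gain x horizontal gradient) and Gaussian noise are applied
    last and clipped to [0, 255].
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    layer = np.full((h, w), LAYER_BACKGROUND, dtype=np.uint8)

    placements = _place_fruit(rng, spec)
    fruit_ids = np.zeros((h, w), dtype=np.int32)
    rows = []
    for fid, (cy, cx, ra, rb, angle) in enumerate(placements, start=1):
        rr, cc = draw.ellipse(cy, cx, ra, rb, shape=(h, w), rotation=angle)
        layer[rr, cc] = LAYER_FRUIT
        fruit_ids[rr, cc] = fid
        rows.append(
            {"fruit_id": fid, "centre_row": cy, "centre_col": cx,
             "radius_major": ra, "radius_minor": rb, "angle": angle}
        )

    # free-standing foliage in the background
    for _ in range(spec.n_background_strokes):
        start = (rng.uniform(0, h), rng.uniform(0, w))
        stroke = _stroke_mask(
            rng, (h, w), start, rng.uniform(0, np.pi),
            rng.uniform(0.15, 0.45) * max(h, w), int(rng.integers(3, 7)),
        )
        layer[stroke & (layer != LAYER_FRUIT)] = LAYER_FOLIAGE

    # occluding strokes: radial segments that enter each fruit from outside
    # and stop well inside it, so the boundary is covered (about
    # occlusion_fraction of it on average, at ~4 px stroke thickness) but
    # the fruit is almost never cut in two; a stroke aimed at one fruit
    # never erases pixels of another
    occluded = np.zeros((h, w), bool)
    if spec.occlusion_fraction > 0:
        for fid, (cy, cx, ra, rb, _) in enumerate(placements, start=1):
            n_strokes = max(1, int(round(spec.occlusion_fraction * 2 * np.pi * ra / 8)))
            other_fruit = (fruit_ids > 0) & (fruit_ids != fid)
            # evenly spaced angles with jitter: two near-parallel strokes
            # merging at their inner ends would pinch off a wedge of fruit
            base = rng.uniform(0, 2 * np.pi)
            for k in range(n_strokes):
                theta = base + 2 * np.pi * k / n_strokes + rng.uniform(
                    -np.pi / (4 * n_strokes), np.pi / (4 * n_strokes)
                )
                dr, dc = np.sin(theta), np.cos(theta)
                start = (cy + 1.3 * ra * dr, cx + 1.3 * ra * dc)
                inward = np.arctan2(cy - start[0], cx - start[1])
                stroke = _stroke_mask(
                    rng, (h, w), start, inward, (1.3 - 0.42) * ra,
                    int(rng.integers(3, 6)),
                )
                occluded |= stroke & ~other_fruit
    layer[occluded] = LAYER_FOLIAGE

    models = {
        LAYER_BACKGROUND: spec.background_colour,
        LAYER_FRUIT: spec.fruit_colour,
        LAYER_FOLIAGE: spec.foliage_colour,
    }
    img = np.zeros((h, w, 3), dtype=np.float64)
    for code, cm in models.items():
        sel = layer == code
        n = int(sel.sum())
        if n:
            img[sel] = np.asarray(cm.mean) + rng.normal(0.0, cm.sd, size=(n, 3))

    # radial shading makes fruit look spherical rather than flat
    yy, xx = np.mgrid[0:h, 0:w]
    for cy, cx, ra, rb, _ in placements:
        sel = (fruit_ids > 0) & (layer == LAYER_FRUIT)
        dist = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2) / max(ra, rb)
        shade = np.clip(1.0 - 0.25 * dist, 0.7, 1.0)
        this = sel & (np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2) <= max(ra, rb) + 1)
        img[this] *= shade[this][:, None]

    gain = SUNNY_GAIN if spec.illumination == "sunny" else SHADOW_GAIN
    gradient = 1.0 + GRADIENT_SPAN * (2.0 * xx / max(w - 1, 1) - 1.0)
    img *= (gain * gradient)[:, :, None]

    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    image = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    visible = (layer == LAYER_FRUIT)
    truth = np.where(visible, 255, 0).astype(np.uint8)
    visible_counts = [
        int(np.sum(visible & (fruit_ids == row["fruit_id"]))) for row in rows
    ]
    table = pd.DataFrame(rows)
    if len(table):
        table["visible_pixels"] = visible_counts
    else:
        table = pd.DataFrame(
            columns=["fruit_id", "centre_row", "centre_col", "radius_major",
                     "radius_minor", "angle", "visible_pixels"]
        )
    return Scene(image=image, truth_mask=truth, fruit_table=table,
                 layer_map=layer, spec=spec)


def sunny_and_shadow_specs(
    n_sunny: int, n_shadow: int, base_seed: int, **overrides
) -> list[SceneSpec]:
    """Convenience: a batch of specs split across the two regimes."""
    specs = []
    for i in range(n_sunny):
        specs.append(SceneSpec(illumination="sunny", seed=base_seed + i, **overrides))
    for i in range(n_shadow):
        specs.append(
            SceneSpec(illumination="shadow", seed=base_seed + n_sunny + i, **overrides)
        )
    return specs


def sample_pixel_groups(
    img: np.ndarray,
    truth_mask: np.ndarray,
    n_per_group: int = 200,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Draw stratified calibration pixel samples (groups M, N, K).

    Strata: fruit pixels (truth mask), green-dominant non-fruit pixels
    (foliage, identified by G exceeding both R and B), and the remaining
    background.  Returns ``n_per_group`` seeded uniform draws per stratum as
    (R, G, B) rows, mirroring the three 200-pixel calibration sets used to
    fix the chromatic operating point.
    """
    rgb = as_rgb_image(img).astype(np.float64)
    truth = as_mask(truth_mask) > 0
    g_dom = (rgb[:, :, 1] > rgb[:, :, 0]) & (rgb[:, :, 1] > rgb[:, :, 2])
    strata = {
        "M": truth,
        "N": g_dom & ~truth,
        "K": ~g_dom & ~truth,
    }
    rng = np.random.default_rng(seed)
    groups: dict[str, np.ndarray] = {}
    for name, sel in strata.items():
        rr, cc = np.nonzero(sel)
        if rr.size < n_per_group:
            raise ValueError(
                f"stratum {name!r} has only {rr.size} pixels; "
                f"{n_per_group} requested"
            )
        idx = rng.choice(rr.size, size=n_per_group, replace=False)
        groups[name] = rgb[rr[idx], cc[idx]]
    return groups


def build_training_table(
    scenes: list[Scene] | list[tuple[np.ndarray, np.ndarray]],
    feature_config: FeatureConfig = FeatureConfig(),
    majority_fraction: float = 0.5,
) -> tuple[np.ndarray, np.ndarray, NormalizationStats]:
    """Blocks of every scene -> normalized labelled training samples.

    A block is labelled target (0) when at least ``majority_fraction`` of
    its pixels are ground-truth fruit, non-target (1) otherwise.  Raw
    features are extracted per block, min-max statistics are fitted on the
    pooled table and applied to it.  Returns ``(X, y, stats)``.
    """
    if not scenes:
        raise ValueError("need at least one scene")
    feats = []
    labels = []
    for scene in scenes:
        if isinstance(scene, Scene):
            img, truth = scene.image, scene.truth_mask
        else:
            img, truth = scene[0], scene[1]
        truth_b = as_mask(truth) > 0
        table = image_feature_table(img, feature_config)
        feats.append(table[list(FEATURE_NAMES)].to_numpy())
        for blk in tile_blocks(img):
            frac = float(truth_b[blk.slice()].mean())
            labels.append(0 if frac >= majority_fraction else 1)
    X_raw = np.vstack(feats)
    y = np.asarray(labels, dtype=np.int64)
    if np.unique(y).size < 2:
        raise ValueError("training scenes yield a single class; add fruit or background")
    stats = fit_normalization(X_raw)
    X = apply_normalization(X_raw, stats)
    return X, y, stats


def subsample_balanced(
    X: np.ndarray, y: np.ndarray, max_samples: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded class-balanced subsample used to cap classifier training cost."""
    if len(y) <= max_samples:
        return X, y
    rng = np.random.default_rng(seed)
    per_class = max_samples // 2
    keep: list[np.ndarray] = []
    for c in np.unique(y):
        idx = np.nonzero(y == c)[0]
        take = min(per_class, idx.size)
        keep.append(rng.choice(idx, size=take, replace=False))
    sel = np.sort(np.concatenate(keep))
    return X[sel], y[sel]
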