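"""Block-wise colour and texture features.

Each 9x9 block is summarised by an 11-dimensional feature vector in the
fixed order ``(R, G, B, H, S, I, Et, En, Cr, Im, Ls)``:

* ``R, G, B`` — block means of the colour channels;
* ``H, S, I`` — hue/saturation/intensity computed from those channel means
  (not the mean of per-pixel HSI);
* ``Et, En, Cr, Im, Ls`` — entropy, energy, correlation, inertia moment and
  local smoothing of the grey-level co-occurrence matrix (GLCM) of the
  block's red channel, quantized to ``k`` grey levels.

Features are min-max normalized to [0, 1] against statistics fitted on the
training set; out-of-range values at prediction time are clipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .imaging import Block, as_rgb_image, tile_blocks

log = logging.getLogger(__name__)

FEATURE_NAMES = ("R", "G", "B", "H", "S", "I", "Et", "En", "Cr", "Im", "Ls")
N_FEATURES = len(FEATURE_NAMES)

#: distance-1 offsets at 0, 45, 90 and 135 degrees, accumulated symmetrically
DEFAULT_OFFSETS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))
DEFAULT_GREY_LEVELS = 16
DEFAULT_LOG_BASE = 10.0


@dataclass(frozen=True)
class FeatureConfig:
    """Tunable feature-extraction parameters.

    ``grey_levels`` trades GLCM sparsity against grey resolution: 256 levels
    over an 81-pixel block would leave the matrix nearly empty, so the red
    channel is linearly binned to 16 levels by default.
    """

    grey_levels: int = DEFAULT_GREY_LEVELS
    offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS
    entropy_log_base: float = DEFAULT_LOG_BASE

    def to_dict(self) -> dict:
        return {
            "grey_levels": self.grey_levels,
            "offsets": [list(o) for o in self.offsets],
            "entropy_log_base": self.entropy_log_base,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureConfig":
        return cls(
            grey_levels=int(d["grey_levels"]),
            offsets=tuple(tuple(o) for o in d["offsets"]),
            entropy_log_base=float(d["entropy_log_base"]),
        )


def rgb_to_hsi(pixel_means: tuple[float, float, float] | np.ndarray) -> tuple[float, float, float]:
    """Convert mean (R, G, B) in [0, 255] to (H, S, I).

    I = (R+G+B)/3 and S = 1 - 3*min(R,G,B)/(R+G+B); hue is the arccos form

        H = arccos( 0.5*((R-G)+(R-B)) / sqrt((R-G)^2 + (R-B)(G-B)) )

    reflected to ``2*pi - arccos(...)`` when B > G so that H covers the full
    circle, reported in radians in [0, 2*pi).  Conventions for the degenerate
    cases: S = 0 when R+G+B = 0, H = 0 when the arccos denominator vanishes
    (achromatic pixels).
    """
    r, g, b = (float(v) for v in pixel_means)
    total = r + g + b
    i = total / 3.0
    s = 0.0 if total == 0 else 1.0 - 3.0 * min(r, g, b) / total
    denom_sq = (r - g) ** 2 + (r - b) * (g - b)
    if denom_sq <= 0:
        h = 0.0
    else:
        cosang = 0.5 * ((r - g) + (r - b)) / np.sqrt(denom_sq)
        ang = float(np.arccos(np.clip(cosang, -1.0, 1.0)))
        h = 2.0 * np.pi - ang if b > g else ang
        if h >= 2.0 * np.pi:
            h -= 2.0 * np.pi
    return h, s, i


def quantize_grey(
    channel: np.ndarray, k: int, lo: float = 0.0, hi: float = 255.0
) -> np.ndarray:
    """Linearly bin grey values in [lo, hi] to integer levels 0..k-1."""
    if k < 1:
        raise ValueError("grey-level count must be >= 1")
    if hi <= lo:
        raise ValueError("hi must exceed lo")
    scaled = (np.asarray(channel, dtype=np.float64) - lo) / (hi - lo)
    levels = np.floor(scaled * k).astype(np.intp)
    return np.clip(levels, 0, k - 1)


def glcm(
    block_levels: np.ndarray,
    k: int,
    offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS,
) -> np.ndarray:
    """Symmetric normalized grey-level co-occurrence matrix.

    Co-occurrences are counted over every offset and its opposite, summed
    into one k-by-k matrix and normalized to total mass 1.  Pairs reaching
    outside the block are skipped.  A block too small to contain any pair
    (e.g. a 1x1 edge block) degenerates to all mass at ``(g, g)`` of its
    single grey level.
    """
    levels = np.asarray(block_levels)
    if levels.size == 0:
        raise ValueError("empty block")
    if levels.min() < 0 or levels.max() >= k:
        raise ValueError(f"grey levels must already be quantized to [0, {k - 1}]")
    h, w = levels.shape
    mat = np.zeros((k, k), dtype=np.float64)
    for dr, dc in offsets:
        r0, r1 = max(0, -dr), min(h, h - dr)
        c0, c1 = max(0, -dc), min(w, w - dc)
        if r0 >= r1 or c0 >= c1:
            continue
        a = levels[r0:r1, c0:c1].ravel()
        b = levels[r0 + dr : r1 + dr, c0 + dc : c1 + dc].ravel()
        np.add.at(mat, (a, b), 1.0)
        np.add.at(mat, (b, a), 1.0)  # opposite offset => symmetric matrix
    total = mat.sum()
    if total == 0:
        g = int(levels.flat[0])
        log.debug("degenerate GLCM: no co-occurring pairs; mass at (%d,%d)", g, g)
        mat[g, g] = 1.0
        return mat
    return mat / total


def texture_features(G: np.ndarray, log_base: float = DEFAULT_LOG_BASE) -> tuple[float, float, float, float, float]:
    """Entropy, energy, correlation, inertia moment and local smoothing.

    Entropy uses the base-10 logarithm by default; zero-probability cells
    contribute nothing.  Correlation is defined as 0 when either marginal
    standard deviation vanishes (constant block).  Matrix indices run 1..k.
    """
    Gm = np.asarray(G, dtype=np.float64)
    k = Gm.shape[0]
    idx = np.arange(1, k + 1, dtype=np.float64)
    i = idx[:, None]
    j = idx[None, :]

    nz = Gm > 0
    et = float(-np.sum(Gm[nz] * (np.log(Gm[nz]) / np.log(log_base))))
    en = float(np.sum(Gm**2))
    u_i = float(np.sum(i * Gm))
    u_j = float(np.sum(j * Gm))
    s_i = float(np.sqrt(np.sum(Gm * (i - u_i) ** 2)))
    s_j = float(np.sqrt(np.sum(Gm * (j - u_j) ** 2)))
    if s_i * s_j == 0.0:
        cr = 0.0
        log.debug("constant-block GLCM: correlation set to 0 by convention")
    else:
        cr = float((np.sum(i * j * Gm) - u_i * u_j) / (s_i * s_j))
    im = float(np.sum((i - j) ** 2 * Gm))
    ls = float(np.sum(Gm / (1.0 + (i - j) ** 2)))
    return et, en, cr, im, ls


def block_feature_vector(
    img: np.ndarray, block: Block, config: FeatureConfig = FeatureConfig()
) -> np.ndarray:
    """Raw 11-feature vector of one block.

    Colour features are the block means of R, G, B plus the HSI transform of
    those means; texture features come from the GLCM of the quantized red
    channel.  Hue is rescaled by 2*pi so every raw feature lives on a
    comparable scale before min-max normalization.
    """
    rgb = as_rgb_image(img)
    win = rgb[block.slice()]
    r_mean = float(win[:, :, 0].mean())
    g_mean = float(win[:, :, 1].mean())
    b_mean = float(win[:, :, 2].mean())
    h, s, i = rgb_to_hsi((r_mean, g_mean, b_mean))
    levels = quantize_grey(win[:, :, 0], config.grey_levels)
    G = glcm(levels, config.grey_levels, config.offsets)
    et, en, cr, im, ls = texture_features(G, config.entropy_log_base)
    return np.array(
        [r_mean, g_mean, b_mean, h / (2.0 * np.pi), s, i, et, en, cr, im, ls],
        dtype=np.float64,
    )


def image_feature_table(
    img: np.ndarray, config: FeatureConfig = FeatureConfig()
) -> pd.DataFrame:
    """Raw feature vectors for every block of an image (row-major order)."""
    blocks = tile_blocks(img)
    rows = np.empty((len(blocks), N_FEATURES), dtype=np.float64)
    for n, blk in enumerate(blocks):
        rows[n] = block_feature_vector(img, blk, config)
    df = pd.DataFrame(rows, columns=list(FEATURE_NAMES))
    df.insert(0, "block_row", [b.row_index for b in blocks])
    df.insert(1, "block_col", [b.col_index for b in blocks])
    return df


@dataclass
class NormalizationStats:
    """Per-feature min/max fitted on the training set.

    Degenerate features (max == min on the training data) are flagged and
    given ``max = min + 1`` so their normalized value is identically 0.
    """

    minima: np.ndarray
    maxima: np.ndarray
    degenerate: np.ndarray = field(default_factory=lambda: np.zeros(N_FEATURES, bool))

    def to_dict(self) -> dict:
        return {
            "minima": self.minima.tolist(),
            "maxima": self.maxima.tolist(),
            "degenerate": self.degenerate.astype(int).tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationStats":
        return cls(
            minima=np.asarray(d["minima"], dtype=np.float64),
            maxima=np.asarray(d["maxima"], dtype=np.float64),
            degenerate=np.asarray(d["degenerate"], dtype=bool),
        )


def fit_normalization(vectors: np.ndarray) -> NormalizationStats:
    """Fit per-feature min-max statistics on raw training vectors."""
    X = np.asarray(vectors, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 feature vectors to fit normalization")
    mins = X.min(axis=0)
    maxs = X.max(axis=0)
    degenerate = maxs <= mins
    if degenerate.any():
        log.warning(
            "degenerate features (constant on training set): %s",
            [FEATURE_NAMES[i] for i in np.nonzero(degenerate)[0] if i < N_FEATURES],
        )
        maxs = np.where(degenerate, mins + 1.0, maxs)
    return NormalizationStats(minima=mins, maxima=maxs, degenerate=degenerate)


def apply_normalization(vectors: np.ndarray, stats: NormalizationStats) -> np.ndarray:
    """Min-max scale raw vectors to [0, 1], clipping out-of-range values."""
    X = np.asarray(vectors, dtype=np.float64)
    scaled = (X - stats.minima) / (stats.maxima - stats.minima)
    return np.clip(scaled, 0.0, 1.0)
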