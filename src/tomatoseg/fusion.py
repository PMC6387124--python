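"""Mask fusion, small-region filling, contour marking and evaluation.

The two layer masks are produced independently and then filter each other:
the default fusion keeps a pixel only when *both* strategies call it target
(pixelwise AND), which removes each layer's isolated false positives.  The
surviving mask is cleaned by the small-area rule — regions whose contour
length (boundary-point count) falls strictly below the mean over all regions
are deleted — and the remaining region contours are marked on the original
image.

A known failure mode is inherited by design: a fruit split into several
sub-mean fragments by occluding foliage can be deleted entirely by the
small-area rule.  The filling pass runs once (no fixed-point iteration).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import ndimage

from .chromatic import ChromaticParams, first_layer_mask
from .imaging import Region, as_mask, as_rgb_image, connected_components, overlay_regions
from .rvm import RvmModel, second_layer_mask

FusionMode = Literal["and", "or"]
FillCriterion = Literal["boundary_mean", "pixel_mean"]


def fuse_masks(m1: np.ndarray, m2: np.ndarray, mode: FusionMode = "and") -> np.ndarray:
    """Combine the two layer masks pixelwise.

    ``"and"`` (default) keeps pixels marked target by both layers; ``"or"``
    keeps pixels marked by either.  Pixels rejected by the rule are filled
    directly to background.
    """
    a = as_mask(m1)
    b = as_mask(m2)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    if mode == "and":
        out = (a > 0) & (b > 0)
    elif mode == "or":
        out = (a > 0) | (b > 0)
    else:
        raise ValueError(f"unknown fusion mode {mode!r}")
    return np.where(out, 255, 0).astype(np.uint8)


def fill_small_regions(
    mask: np.ndarray, criterion: FillCriterion = "boundary_mean"
) -> np.ndarray:
    """Delete regions strictly below the mean size over all regions.

    Under ``boundary_mean`` (default) a region's size is its boundary-point
    count; under ``pixel_mean`` it is its pixel count.  With one region or
    none the mask is returned unchanged — there is no mean to compare
    against.  Foreground is only ever removed, never added.
    """
    m = as_mask(mask)
    regions = connected_components(m)
    if len(regions) <= 1:
        return m.copy()
    if criterion == "boundary_mean":
        sizes = np.array([r.boundary_points for r in regions], dtype=np.float64)
    elif criterion == "pixel_mean":
        sizes = np.array([r.pixel_count for r in regions], dtype=np.float64)
    else:
        raise ValueError(f"unknown fill criterion {criterion!r}")
    mean = sizes.mean()
    out = m.copy()
    labels, _ = ndimage.label(m > 0, structure=np.ones((3, 3), bool))
    for r, size in zip(regions, sizes):
        if size < mean:
            out[labels == r.component_id] = 0
    return out


@dataclass
class DetectionResult:
    """Everything the full pipeline produces for one image."""

    final_mask: np.ndarray
    regions: list[Region]
    annotated: np.ndarray
    layer1_mask: np.ndarray
    layer2_mask: np.ndarray
    fused_mask: np.ndarray


def detect(
    img: np.ndarray,
    model: RvmModel,
    chromatic: ChromaticParams = ChromaticParams(),
    fusion_mode: FusionMode = "and",
    fill_criterion: FillCriterion = "boundary_mean",
    marker_colour: tuple[int, int, int] = (255, 255, 0),
) -> DetectionResult:
    """Run the bi-layer pipeline on one image.

    The chromatic and RVM masks are computed independently, fused, cleaned
    by the small-area rule; the surviving region contours are drawn on a
    copy of the input.  Zero detections is a valid result, not an error.
    """
    rgb = as_rgb_image(img)
    m1 = first_layer_mask(rgb, chromatic)
    m2 = second_layer_mask(rgb, model)
    fused = fuse_masks(m1, m2, fusion_mode)
    final = fill_small_regions(fused, fill_criterion)
    regions = connected_components(final)
    annotated = overlay_regions(rgb, regions, marker_colour)
    return DetectionResult(
        final_mask=final,
        regions=regions,
        annotated=annotated,
        layer1_mask=m1,
        layer2_mask=m2,
        fused_mask=fused,
    )


@dataclass
class EvalMetrics:
    """Pixel- and fruit-level agreement between prediction and truth."""

    pixel_precision: float
    pixel_recall: float
    pixel_iou: float
    fruit_precision: float
    fruit_recall: float
    n_truth: int
    n_pred: int
    n_matched: int

    def to_dict(self) -> dict:
        return {
            "pixel_precision": self.pixel_precision,
            "pixel_recall": self.pixel_recall,
            "pixel_iou": self.pixel_iou,
            "fruit_precision": self.fruit_precision,
            "fruit_recall": self.fruit_recall,
            "n_truth": self.n_truth,
            "n_pred": self.n_pred,
            "n_matched": self.n_matched,
        }


def evaluate(
    pred_mask: np.ndarray, truth_mask: np.ndarray, iou_threshold: float = 0.5
) -> EvalMetrics:
    """Score a predicted mask against ground truth.

    Pixel metrics are ordinary precision/recall/IoU of the 255 sets.
    Fruit-level matching is greedy one-to-one by descending IoU between
    predicted and truth connected components; a pair matches when its IoU
    reaches ``iou_threshold``.  An empty prediction against empty truth
    scores 1.0 everywhere by convention.
    """
    p = as_mask(pred_mask) > 0
    t = as_mask(truth_mask) > 0
    if p.shape != t.shape:
        raise ValueError(f"mask shapes differ: {p.shape} vs {t.shape}")

    inter = int(np.sum(p & t))
    union = int(np.sum(p | t))
    np_pix = int(p.sum())
    nt_pix = int(t.sum())
    if np_pix == 0 and nt_pix == 0:
        return EvalMetrics(1.0, 1.0, 1.0, 1.0, 1.0, 0, 0, 0)
    pixel_precision = inter / np_pix if np_pix else 0.0
    pixel_recall = inter / nt_pix if nt_pix else 1.0
    pixel_iou = inter / union if union else 1.0

    struct = np.ones((3, 3), bool)
    pl, n_pred = ndimage.label(p, structure=struct)
    tl, n_truth = ndimage.label(t, structure=struct)
    matched = 0
    if n_pred and n_truth:
        # joint label histogram gives all pairwise intersections at once
        joint = np.zeros((n_pred + 1, n_truth + 1), dtype=np.int64)
        np.add.at(joint, (pl.ravel(), tl.ravel()), 1)
        p_sizes = joint.sum(axis=1)
        t_sizes = joint.sum(axis=0)
        pairs = []
        for i in range(1, n_pred + 1):
            for j in range(1, n_truth + 1):
                ij = joint[i, j]
                if ij == 0:
                    continue
                iou = ij / (p_sizes[i] + t_sizes[j] - ij)
                if iou >= iou_threshold:
                    pairs.append((iou, i, j))
        pairs.sort(reverse=True)
        used_p: set[int] = set()
        used_t: set[int] = set()
        for _, i, j in pairs:
            if i in used_p or j in used_t:
                continue
            used_p.add(i)
            used_t.add(j)
            matched += 1
    fruit_recall = matched / n_truth if n_truth else 1.0
    fruit_precision = matched / n_pred if n_pred else (1.0 if n_truth == 0 else 0.0)
    return EvalMetrics(
        pixel_precision=pixel_precision,
        pixel_recall=pixel_recall,
        pixel_iou=pixel_iou,
        fruit_precision=fruit_precision,
        fruit_recall=fruit_recall,
        n_truth=n_truth,
        n_pred=n_pred,
        n_matched=matched,
    )
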