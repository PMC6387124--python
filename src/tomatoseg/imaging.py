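"""Image and mask I/O, block tiling, connected components and contours.

Images are plain numpy arrays throughout: an RGB image is a ``(H, W, 3)``
``uint8`` array and a mask is a ``(H, W)`` ``uint8`` array whose values are
exactly 0 or 255 (255 marks target pixels).  All pixel coordinates are
0-based ``(row, col)`` and pixel windows are half-open rectangles.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from PIL import Image, UnidentifiedImageError
from scipy import ndimage

BLOCK_SIZE = 9
MIN_IMAGE_SIDE = 9

# 8-connectivity structuring element shared by labelling and boundary tests
_STRUCT8 = np.ones((3, 3), bool)


class DimensionError(ValueError):
    """Input image smaller than the minimum 9x9 block."""


def as_rgb_image(arr: np.ndarray) -> np.ndarray:
    """Validate and coerce an array into the canonical RGB image layout."""
    a = np.asarray(arr)
    if a.ndim == 2:
        a = np.stack([a] * 3, axis=-1)
    if a.ndim != 3 or a.shape[2] < 3:
        raise ValueError(f"expected (H, W, 3) image, got shape {a.shape}")
    a = a[:, :, :3]
    if a.dtype != np.uint8:
        if np.any((a < 0) | (a > 255)):
            raise ValueError("channel values must lie in [0, 255]")
        a = a.astype(np.uint8)
    return np.ascontiguousarray(a)


def as_mask(arr: np.ndarray) -> np.ndarray:
    """Validate a binary {0, 255} mask."""
    a = np.asarray(arr)
    if a.ndim != 2:
        raise ValueError(f"expected (H, W) mask, got shape {a.shape}")
    vals = np.unique(a)
    if not np.all(np.isin(vals, (0, 255))):
        raise ValueError("mask values must be exactly 0 or 255")
    return a.astype(np.uint8)


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG/JPEG/BMP file as an 8-bit RGB array.

    Grayscale inputs are replicated to three channels; any alpha channel is
    dropped.  Images smaller than 9x9 are rejected because the pipeline's
    basic unit is a 9x9 pixel block.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            rgb = im.convert("RGB")
            arr = np.asarray(rgb, dtype=np.uint8)
    except (UnidentifiedImageError, OSError) as exc:
        raise IOError(f"cannot read image file {path!s}: {exc}") from exc
    if arr.shape[0] < MIN_IMAGE_SIDE or arr.shape[1] < MIN_IMAGE_SIDE:
        raise DimensionError(
            f"image {path!s} is {arr.shape[0]}x{arr.shape[1]}; "
            f"at least {MIN_IMAGE_SIDE}x{MIN_IMAGE_SIDE} required"
        )
    return arr


def write_image(img: np.ndarray, path: str | Path) -> None:
    """Write an RGB image to disk (format from file extension)."""
    Image.fromarray(as_rgb_image(img), mode="RGB").save(Path(path))


def read_mask(path: str | Path) -> np.ndarray:
    """Read a mask PNG; any nonzero pixel is treated as foreground (255)."""
    path = Path(path)
    try:
        with Image.open(path) as im:
            arr = np.asarray(im.convert("L"))
    except (UnidentifiedImageError, OSError) as exc:
        raise IOError(f"cannot read mask file {path!s}: {exc}") from exc
    return np.where(arr > 0, 255, 0).astype(np.uint8)


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    Image.fromarray(as_mask(mask), mode="L").save(Path(path))


@dataclass(frozen=True)
class Block:
    """One tile of the block decomposition.

    ``pixel_window`` is the half-open rectangle ``(top, left, height, width)``
    covered by the block; interior blocks are exactly 9x9, right/bottom edge
    blocks are truncated to the pixels that actually exist.
    """

    row_index: int
    col_index: int
    top: int
    left: int
    height: int
    width: int

    def slice(self) -> tuple[slice, slice]:
        return (
            slice(self.top, self.top + self.height),
            slice(self.left, self.left + self.width),
        )


def tile_blocks(img: np.ndarray, block_size: int = BLOCK_SIZE) -> list[Block]:
    """Tile an image into non-overlapping row-major blocks.

    Returns ``ceil(H/b) * ceil(W/b)`` blocks whose pixel windows partition the
    image exactly; edge blocks keep their true (smaller) extent rather than
    being padded, so no invented pixel values enter the texture statistics.
    """
    h, w = np.asarray(img).shape[:2]
    blocks: list[Block] = []
    n_rows = -(-h // block_size)
    n_cols = -(-w // block_size)
    for br in range(n_rows):
        top = br * block_size
        bh = min(block_size, h - top)
        for bc in range(n_cols):
            left = bc * block_size
            bw = min(block_size, w - left)
            blocks.append(Block(br, bc, top, left, bh, bw))
    return blocks


@dataclass
class Region:
    """A connected foreground component of a mask.

    ``boundary_points`` counts component pixels that touch (8-connectivity) a
    background pixel or the image border — the contour used both for the
    small-area filter and for marking detections.
    """

    component_id: int
    pixel_count: int
    boundary_points: int
    bounding_box: tuple[int, int, int, int]  # top, left, height, width
    centroid: tuple[float, float]  # (row, col)
    contour_rows: np.ndarray  # rows of boundary pixels
    contour_cols: np.ndarray


def connected_components(mask: np.ndarray) -> list[Region]:
    """Extract 8-connected foreground regions of a {0, 255} mask."""
    m = as_mask(mask) > 0
    labels, n = ndimage.label(m, structure=_STRUCT8)
    if n == 0:
        return []
    # interior = pixels whose full 8-neighbourhood is foreground; border
    # pixels of the image are never interior (border_value=0)
    interior = ndimage.binary_erosion(m, structure=_STRUCT8, border_value=0)
    boundary = m & ~interior
    regions: list[Region] = []
    objects = ndimage.find_objects(labels)
    for cid, slc in enumerate(objects, start=1):
        comp = labels[slc] == cid
        bnd = boundary[slc] & comp
        rr, cc = np.nonzero(comp)
        top, left = slc[0].start, slc[1].start
        br, bc = np.nonzero(bnd)
        regions.append(
            Region(
                component_id=cid,
                pixel_count=int(comp.sum()),
                boundary_points=int(bnd.sum()),
                bounding_box=(
                    top,
                    left,
                    slc[0].stop - slc[0].start,
                    slc[1].stop - slc[1].start,
                ),
                centroid=(float(rr.mean() + top), float(cc.mean() + left)),
                contour_rows=br + top,
                contour_cols=bc + left,
            )
        )
    return regions


def overlay_regions(
    img: np.ndarray,
    regions: Sequence[Region],
    colour: tuple[int, int, int] = (255, 255, 0),
) -> np.ndarray:
    """Draw each region's contour on a copy of the image.

    The input image is never modified; only contour pixels change, and they
    are set to ``colour``.
    """
    out = as_rgb_image(img).copy()
    h, w = out.shape[:2]
    for region in regions:
        if (
            region.contour_rows.size
            and (
                region.contour_rows.min() < 0
                or region.contour_rows.max() >= h
                or region.contour_cols.min() < 0
                or region.contour_cols.max() >= w
            )
        ):
            raise ValueError(
                f"region {region.component_id} lies outside a "
                f"{h}x{w} image"
            )
        out[region.contour_rows, region.contour_cols] = colour
    return out


REGION_CSV_COLUMNS = (
    "component_id",
    "pixel_count",
    "boundary_points",
    "top",
    "left",
    "height",
    "width",
    "centroid_row",
    "centroid_col",
)


def write_region_table(regions: Iterable[Region], path: str | Path) -> None:
    """Export regions as CSV with the documented column set."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(REGION_CSV_COLUMNS)
        for r in regions:
            top, left, height, width = r.bounding_box
            writer.writerow(
                [
                    r.component_id,
                    r.pixel_count,
                    r.boundary_points,
                    top,
                    left,
                    height,
                    width,
                    f"{r.centroid[0]:.4f}",
                    f"{r.centroid[1]:.4f}",
                ]
            )
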