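"""Foreground extraction for shoot images.

The chain mirrors a conveyor-imaging workflow: a rectangular region of
interest crops out visible hardware, pixels are labelled plant/background
by nearest-neighbour colour classification against small reference
palettes, morphological erosion + dilation remove speckle noise, and all
surviving components are composed into one plant object.  The resulting
binary mask can be overlaid onto co-registered near-infrared images to
read out a mean grey value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skimage.morphology import dilation, disk, erosion, remove_small_objects

logger = logging.getLogger(__name__)

VIEWS = ("top", "side0", "side90")

__all__ = [
    "VIEWS",
    "ColorClassifier",
    "PlantMask",
    "classify_pixels",
    "clean_and_compose",
    "overlay_nir",
    "overlay_nir_pair",
]


@dataclass(frozen=True)
class ColorClassifier:
    """Nearest-neighbour colour classifier.

    A pixel is foreground iff its nearest reference sample (squared
    Euclidean distance in RGB space) belongs to the foreground palette.
    Ties resolve to background: erring toward a smaller plant is the
    conservative choice when the goal is noise removal.
    """

    fg_palette: tuple
    bg_palette: tuple

    def __post_init__(self):
        fg = tuple(tuple(int(v) for v in c) for c in self.fg_palette)
        bg = tuple(tuple(int(v) for v in c) for c in self.bg_palette)
        if not fg or not bg:
            raise ValueError("both palettes must be non-empty")
        if set(fg) & set(bg):
            raise ValueError("foreground and background palettes must be disjoint")
        object.__setattr__(self, "fg_palette", fg)
        object.__setattr__(self, "bg_palette", bg)


@dataclass
class PlantMask:
    """Binary plant mask for one camera view.

    ``pixel_count`` and ``centroid_xy`` (x = column, y = row) are derived
    from the raster on construction; an empty mask is valid but flagged.
    """

    raster: np.ndarray
    view_label: str = "top"
    flagged_empty: bool = field(init=False)
    pixel_count: int = field(init=False)
    centroid_xy: tuple = field(init=False)

    def __post_init__(self):
        self.raster = np.asarray(self.raster, dtype=bool)
        if self.raster.ndim != 2:
            raise ValueError("mask raster must be 2-D")
        self.pixel_count = int(self.raster.sum())
        self.flagged_empty = self.pixel_count == 0
        if self.flagged_empty:
            self.centroid_xy = (float("nan"), float("nan"))
            logger.info("empty plant mask flagged (view=%s)", self.view_label)
        else:
            rows, cols = np.nonzero(self.raster)
            self.centroid_xy = (float(cols.mean()), float(rows.mean()))

    def coords_xy(self) -> np.ndarray:
        """Foreground pixel centres as (x, y) = (col, row) pairs."""
        rows, cols = np.nonzero(self.raster)
        return np.column_stack([cols, rows]).astype(float)


def _min_sq_dist(image: np.ndarray, palette) -> np.ndarray:
    img = image.astype(np.int64)
    best = None
    for color in palette:
        d = np.zeros(image.shape[:2], dtype=np.int64)
        for ch in range(3):
            diff = img[..., ch] - int(color[ch])
            d += diff * diff
        best = d if best is None else np.minimum(best, d)
    return best


def classify_pixels(image: np.ndarray, clf: ColorClassifier, roi=None) -> np.ndarray:
    """Label each pixel plant/background by nearest palette sample.

    Parameters
    ----------
    image : (H, W, 3) uint8 RGB raster.
    clf : ColorClassifier
    roi : optional (row_start, row_stop, col_start, col_stop) rectangle in
        half-open slice convention; pixels outside are always background.

    Ties (equal distance to nearest foreground and nearest background
    sample) resolve to background.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    h, w = image.shape[:2]
    if roi is None:
        roi = (0, h, 0, w)
    r0, r1, c0, c1 = (int(v) for v in roi)
    if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
        raise ValueError(f"empty or out-of-bounds ROI {roi!r} for image {h}x{w}")
    d_fg = _min_sq_dist(image, clf.fg_palette)
    d_bg = _min_sq_dist(image, clf.bg_palette)
    fg = d_fg < d_bg  # strict: tie -> background
    out = np.zeros((h, w), dtype=bool)
    out[r0:r1, c0:c1] = fg[r0:r1, c0:c1]
    return out


def clean_and_compose(
    binary: np.ndarray,
    erosion_radius: int = 1,
    dilation_radius: int = 1,
    min_component_px: int = 5,
    view_label: str = "top",
) -> PlantMask:
    """Morphological cleanup, then composition into one plant object.

    Erosion then dilation with disc structuring elements (radius 0 skips
    the step), removal of 8-connected components smaller than
    ``min_component_px``, and union of everything that survives.  The
    small-component filter is idempotent.  An empty result is returned as
    a valid, flagged mask rather than an error so a pipeline over many
    pots keeps running.
    """
    if erosion_radius < 0 or dilation_radius < 0:
        raise ValueError("structuring-element radii must be >= 0")
    mask = np.asarray(binary, dtype=bool)
    if erosion_radius > 0:
        mask = erosion(mask, disk(erosion_radius))
    if dilation_radius > 0:
        mask = dilation(mask, disk(dilation_radius))
    if min_component_px > 1:
        # components strictly below min_component_px are discarded
        mask = remove_small_objects(mask, max_size=int(min_component_px) - 1, connectivity=2)
    return PlantMask(mask, view_label=view_label)


def overlay_nir(nir: np.ndarray, mask: PlantMask) -> float:
    """Mean 8-bit grey value of the NIR raster under the plant mask.

    High values mean high reflectance, i.e. low shoot water content.
    Raises on an empty mask (the mean is undefined).
    """
    nir = np.asarray(nir)
    raster = mask.raster if isinstance(mask, PlantMask) else np.asarray(mask, dtype=bool)
    if nir.shape != raster.shape:
        raise ValueError("NIR raster and mask dimensions differ")
    if not raster.any():
        raise ValueError("mean NIR grey value is undefined for an empty mask")
    return float(nir[raster].mean())


def overlay_nir_pair(nir0: np.ndarray, mask0: PlantMask, nir90: np.ndarray, mask90: PlantMask) -> float:
    """Mean NIR grey value pooled over the two side views.

    The mean is taken over the union of both masked pixel sets (one pooled
    mean, not the mean of two per-view means).
    """
    r0 = mask0.raster if isinstance(mask0, PlantMask) else np.asarray(mask0, dtype=bool)
    r90 = mask90.raster if isinstance(mask90, PlantMask) else np.asarray(mask90, dtype=bool)
    if not (r0.any() or r90.any()):
        raise ValueError("mean NIR grey value is undefined for empty masks")
    values = np.concatenate([np.asarray(nir0)[r0].ravel(), np.asarray(nir90)[r90].ravel()])
    return float(values.mean())
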