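"""Pixel-to-physical calibration and geometric shoot traits.

Three views are captured per plant: one from above and two from the side
at a 90 deg rotation.  Side-view pixel areas convert to mm^2 with a fixed
factor (0.273 mm^2/px by default).  Top-view pixels convert with a factor
that depends on plant height, because a taller plant is nearer the
overhead camera: K_TV = slope * Y_ax + intercept, where Y_ax is the mean
centre-of-mass row of the two side-view masks (origin top-left, y down, so
taller plants have smaller Y_ax and a smaller per-pixel area).

Projected leaf area — the biomass proxy — is the calibrated pixel sum over
all three views.  The shape descriptors of the top-view canopy (convex
hull, calliper length, minimum enclosing circle, compactness, surface
coverage, eccentricity) are computed on the binary mask.

Unit conventions: the two published calibration constants are treated as
area factors (mm^2 per pixel); a separate linear factor (default
sqrt(0.273) mm/px) converts side-view pixel rows to heights.  Geometry
operations work on pixel centres; the ratio traits (compactness, surface
coverage) use hulls/circles over pixel corners so that the enclosing
region genuinely contains the pixel area and the ratios stay in (0, 1].
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import geometry
from .segmentation import PlantMask

logger = logging.getLogger(__name__)

__all__ = [
    "CameraCalibration",
    "ShootTraits",
    "topview_constant",
    "projected_leaf_area",
    "convex_hull",
    "min_enclosing_circle",
    "calliper_length",
    "compactness_and_coverage",
    "eccentricity",
    "heights",
    "compute_shoot_traits",
]

SIDE_AREA_FACTOR = 0.273  # mm^2 per side-view pixel
TV_SLOPE = 9.937e-5  # mm^2 per pixel per pixel of Y_ax
TV_INTERCEPT = 0.061936  # mm^2 per pixel at Y_ax = 0


@dataclass(frozen=True)
class CameraCalibration:
    """Published pixel-to-area calibration for a two-camera imaging cabinet.

    ``side_linear_factor`` defaults to sqrt(side_area_factor), consistent
    with the area reading of the side-view constant.
    """

    side_area_factor: float = SIDE_AREA_FACTOR
    tv_slope: float = TV_SLOPE
    tv_intercept: float = TV_INTERCEPT
    side_linear_factor: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.side_linear_factor is None:
            object.__setattr__(self, "side_linear_factor", math.sqrt(self.side_area_factor))
        for name in ("side_area_factor", "tv_slope", "tv_intercept", "side_linear_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"calibration factor {name} must be > 0")

    @classmethod
    def linear_side_constant(cls, side_constant: float = SIDE_AREA_FACTOR, **kw) -> "CameraCalibration":
        """Alternative reading: the side constant is mm per pixel (linear).

        The per-pixel area factor is then side_constant**2 and heights use
        the constant directly.
        """
        return cls(side_area_factor=side_constant**2, side_linear_factor=side_constant, **kw)


def _raster(mask) -> np.ndarray:
    return np.asarray(getattr(mask, "raster", mask), dtype=bool)


def _coords_xy(mask) -> np.ndarray:
    rows, cols = np.nonzero(_raster(mask))
    if rows.size == 0:
        raise ValueError("empty mask")
    return np.column_stack([cols, rows]).astype(float)


def _corner_points(points_xy: np.ndarray) -> np.ndarray:
    """Pixel-corner point set: hull-equivalent Minkowski sum with the unit square.

    conv(S + Q) = conv(conv(S) + Q), so padding only the hull vertices of
    the centres gives the exact corner hull at negligible cost.
    """
    hull = geometry.convex_hull(points_xy)
    offsets = np.array([[-0.5, -0.5], [-0.5, 0.5], [0.5, -0.5], [0.5, 0.5]])
    return (hull[:, None, :] + offsets[None, :, :]).reshape(-1, 2)


def topview_constant(y_ax: float, calib: CameraCalibration = CameraCalibration()) -> float:
    """Height-dependent top-view area factor K_TV (mm^2 per pixel).

    ``y_ax`` is the mean centre-of-mass row coordinate of the two side-view
    masks, in pixels from the top of the frame.
    """
    if y_ax < 0:
        raise ValueError("y_ax must be >= 0")
    return calib.tv_slope * float(y_ax) + calib.tv_intercept


def side_view_y_ax(side0: PlantMask, side90: PlantMask) -> float:
    """Mean centre-of-mass row of the two side views; 0 when both empty."""
    rows = [m.centroid_xy[1] for m in (side0, side90) if not getattr(m, "flagged_empty", not _raster(m).any())]
    if not rows:
        return 0.0
    return float(np.mean(rows))


def projected_leaf_area(
    top_mask: PlantMask,
    side0_mask: PlantMask,
    side90_mask: PlantMask,
    calib: CameraCalibration = CameraCalibration(),
) -> float:
    """Projected leaf area (mm^2): calibrated pixel sum over the three views.

    area = top_px * K_TV(Y_ax) + (side0_px + side90_px) * side_area_factor.
    All-empty masks give 0 with a warning.
    """
    top_px = int(_raster(top_mask).sum())
    s0_px = int(_raster(side0_mask).sum())
    s90_px = int(_raster(side90_mask).sum())
    if top_px + s0_px + s90_px == 0:
        warnings.warn("projected_leaf_area: all three masks are empty", stacklevel=2)
        return 0.0
    if isinstance(side0_mask, np.ndarray):
        side0_mask = PlantMask(side0_mask, "side0")
    if isinstance(side90_mask, np.ndarray):
        side90_mask = PlantMask(side90_mask, "side90")
    y_ax = side_view_y_ax(side0_mask, side90_mask)
    k_tv = topview_constant(y_ax, calib)
    return top_px * k_tv + (s0_px + s90_px) * calib.side_area_factor


def convex_hull(mask):
    """Convex hull of foreground pixel centres -> (polygon, area_px2).

    Degenerate (collinear) masks give area 0 with the polygon reduced to a
    segment or point.  Empty mask raises.
    """
    pts = _coords_xy(mask)
    hull = geometry.convex_hull(pts)
    return hull, geometry.polygon_area(hull)


def min_enclosing_circle(mask):
    """Smallest circle containing all foreground pixel centres -> ((cx, cy), r)."""
    return geometry.min_enclosing_circle(_coords_xy(mask))


def calliper_length(hull_or_mask) -> float:
    """Longest canopy dimension: max pairwise distance over hull vertices."""
    if isinstance(hull_or_mask, np.ndarray) and hull_or_mask.ndim == 2 and hull_or_mask.shape[1] == 2:
        pts = hull_or_mask.astype(float)
    else:
        pts = _coords_xy(hull_or_mask)
    return geometry.calliper_length(pts)


def compactness_and_coverage(mask, hull_area: float = None, circle_radius: float = None):
    """(compactness, surface_coverage) of a top-view mask.

    compactness = foreground area / convex-hull area; surface_coverage =
    foreground area / minimum-enclosing-circle area.  When the denominators
    are not supplied they are computed over pixel *corners*, which bounds
    both ratios by 1 for any mask.  A zero hull area (degenerate mask)
    yields NaN compactness with a warning.
    """
    fg_area = float(_raster(mask).sum())
    if fg_area == 0:
        raise ValueError("empty mask")
    pts = _coords_xy(mask)
    corners = None
    if hull_area is None:
        corners = _corner_points(pts)
        hull_area = geometry.polygon_area(geometry.convex_hull(corners))
    if circle_radius is None:
        corners = corners if corners is not None else _corner_points(pts)
        _, circle_radius = geometry.min_enclosing_circle(corners)
    if hull_area <= 0:
        warnings.warn("degenerate mask: hull area 0, compactness undefined", stacklevel=2)
        compact = float("nan")
    else:
        compact = fg_area / hull_area
    coverage = fg_area / (math.pi * circle_radius**2)
    return compact, coverage


def eccentricity(mask) -> float:
    """Departure from radial symmetry via second-order central moments.

    e = sqrt(1 - lambda2/lambda1) with lambda1 >= lambda2 the eigenvalues
    of the foreground-coordinate covariance; 0 for a radially symmetric
    canopy.  Requires a non-degenerate scatter (>= 3 pixels, nonzero
    variance in every direction).
    """
    pts = _coords_xy(mask)
    if len(pts) < 3:
        raise ValueError("eccentricity needs at least 3 foreground pixels")
    cov = np.cov(pts.T, bias=True)
    lam2, lam1 = np.sort(np.linalg.eigvalsh(cov))
    # exactly collinear scatter would give e = 1, outside the trait's [0, 1) domain
    if lam1 <= 0 or lam2 <= 0:
        raise ValueError("degenerate pixel scatter: eccentricity undefined")
    return float(math.sqrt(max(0.0, 1.0 - lam2 / lam1)))


def _row_widths(raster: np.ndarray):
    """Horizontal extent (max col - min col + 1) of each occupied row."""
    rows = np.nonzero(raster.any(axis=1))[0]
    widths = np.empty(rows.size, dtype=int)
    for i, r in enumerate(rows):
        cols = np.nonzero(raster[r])[0]
        widths[i] = cols[-1] - cols[0] + 1
    return rows, widths


def heights(
    side_masks,
    calib: CameraCalibration = CameraCalibration(),
    width_ratio: float = 2.5,
):
    """(max_height_mm, ligule_height_mm) from the side-view masks.

    Max height is the occupied row span of the taller of the two side
    views times the linear factor, measuring from the lowest foreground
    row (the pot rim is assumed cropped by the ROI) to the top of the
    plant.  The ligule — where the first leaf blade diverges from the stem
    — is located as the lowest row, scanning from the base upward, whose
    horizontal extent exceeds ``width_ratio`` times the stem width (taken
    as a low percentile of row extents, i.e. the width of stem-only rows).
    A leafless silhouette falls back to ligule = max height.
    """
    rasters = [_raster(m) for m in side_masks]
    rasters = [r for r in rasters if r.any()]
    if not rasters:
        raise ValueError("heights undefined: all side masks are empty")

    def _span(r):
        occ = np.nonzero(r.any(axis=1))[0]
        return int(occ[-1] - occ[0] + 1)

    best = max(rasters, key=_span)
    rows, widths = _row_widths(best)
    max_height_px = int(rows[-1] - rows[0] + 1)
    stem_width = max(1.0, float(np.percentile(widths, 10)))
    wide = widths > width_ratio * stem_width
    if wide.any():
        ligule_row = rows[wide][-1]  # lowest (largest row index) wide row
        ligule_px = int(rows[-1] - ligule_row + 1)
    else:
        ligule_px = max_height_px
    f = calib.side_linear_factor
    return max_height_px * f, ligule_px * f


@dataclass
class ShootTraits:
    """One plant x timepoint phenotype record (physical units)."""

    projected_leaf_area: float  # mm^2
    max_height: float  # mm
    ligule_height: float  # mm
    hull_area: float  # mm^2, top view
    compactness: float
    calliper_length: float  # mm
    min_circle_radius: float  # mm
    surface_coverage: float
    eccentricity: float
    mean_hue_deg: float
    senescent_fraction: float
    nir_mean_grey: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def compute_shoot_traits(
    top_mask: PlantMask,
    side0_mask: PlantMask,
    side90_mask: PlantMask,
    top_image: np.ndarray = None,
    nir_pair=None,
    calib: CameraCalibration = CameraCalibration(),
    bands=None,
    width_ratio: float = 2.5,
) -> ShootTraits:
    """Assemble the full trait record for one timepoint.

    Colour traits are read from the top view; the NIR mean from the two
    side views (``nir_pair`` = (nir0, nir90) grey rasters).  Missing
    optional inputs leave the corresponding traits NaN.
    """
    from . import spectral

    area = projected_leaf_area(top_mask, side0_mask, side90_mask, calib)
    y_ax = side_view_y_ax(side0_mask, side90_mask)
    k_tv = topview_constant(y_ax, calib)
    lin_tv = math.sqrt(k_tv)  # mm per top-view pixel

    nan = float("nan")
    hull_mm2 = compact = cal_mm = r_mm = cover = ecc = nan
    if top_mask.pixel_count > 0:
        pts = _coords_xy(top_mask)
        corners = _corner_points(pts)
        hull_px2 = geometry.polygon_area(geometry.convex_hull(corners))
        _, r_px = geometry.min_enclosing_circle(corners)
        compact, cover = compactness_and_coverage(top_mask, hull_area=hull_px2, circle_radius=r_px)
        hull_mm2 = hull_px2 * k_tv
        cal_mm = geometry.calliper_length(pts) * lin_tv
        r_mm = r_px * lin_tv
        try:
            ecc = eccentricity(top_mask)
        except ValueError:
            logger.info("degenerate top mask: eccentricity undefined")

    try:
        max_h, lig_h = heights((side0_mask, side90_mask), calib, width_ratio)
    except ValueError:
        max_h = lig_h = nan

    hue = sen = nan
    if top_image is not None and top_mask.pixel_count > 0:
        bands = bands if bands is not None else spectral.HueBands()
        try:
            hue = spectral.mean_hue(top_mask, top_image)
            sen = spectral.senescence_fraction(top_mask, top_image, bands)
        except ValueError:
            logger.info("no classifiable colour pixels under top mask")

    nir = nan
    if nir_pair is not None:
        from .segmentation import overlay_nir_pair

        try:
            nir = overlay_nir_pair(nir_pair[0], side0_mask, nir_pair[1], side90_mask)
        except ValueError:
            logger.info("empty side masks: NIR mean undefined")

    return ShootTraits(
        projected_leaf_area=area,
        max_height=max_h,
        ligule_height=lig_h,
        hull_area=hull_mm2,
        compactness=compact,
        calliper_length=cal_mm,
        min_circle_radius=r_mm,
        surface_coverage=cover,
        eccentricity=ecc,
        mean_hue_deg=hue,
        senescent_fraction=sen,
        nir_mean_grey=nir,
    )
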