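"""Synthetic glasshouse phenotyping data with exact ground truth.

No real conveyor-imaging dataset ships with this package, so every
downstream stage is exercised against a generator that emulates the
relevant structure of grass-architecture shoots:

* plants rendered as a stem plus strap-like leaf ribbons (optional
  tillers) on a uniform background, seen from the top and from two sides
  at a 90 deg rotation, with matching single-channel pseudo-NIR rasters;
* green -> yellow senescence gradients applied tip-first at an exact
  pixel fraction;
* exponential or sigmoidal leaf-area trajectories with multiplicative
  lognormal noise (scale-free CV, values stay positive);
* afternoon/pre-dawn image pairs in which leaf rolling shrinks the
  projected area by a known proportion;
* gravimetric pot-watering logs with empty-pot evaporation controls.

Geometry is deterministic given the spec: the seed drives only texture
noise, so the pixel-level ground truth (counts, heights, hue, NIR grey)
is identical across seeds.  All bookkeeping is exact — ground-truth
counts are taken from the rendered rasters themselves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.draw import disk as draw_disk
from skimage.draw import polygon as draw_polygon

from . import growth
from .spectral import hsi_to_rgb, rgb_to_hsi

__all__ = [
    "PlantSpec",
    "GroundTruth",
    "PlantImageSet",
    "TrajectorySpec",
    "GrowthSeries",
    "generate_plant_images",
    "generate_growth_series",
    "generate_diurnal_pair",
    "generate_diurnal_pairs",
    "generate_watering_log",
    "series_to_frame",
]

VIEWS = ("top", "side0", "side90")

_NIR_BACKGROUND = 12


@dataclass(frozen=True)
class PlantSpec:
    """Blueprint for one rendered plant.

    Lengths are in pixels; hues in degrees on the HSI circle; ``moisture``
    (0 dry .. 1 saturated) positions the NIR ground-truth grey linearly
    between ``nir_dry_grey`` and ``nir_wet_grey``; ``texture_noise`` is
    the relative amplitude of the seeded per-pixel intensity jitter (the
    only thing the seed influences).
    """

    n_leaves: int = 5
    leaf_length_px: int = 180
    leaf_width_px: int = 18
    stem_height_px: int = 140
    ligule_height_px: int = 60
    n_tillers: int = 0
    senescent_fraction: float = 0.04
    rolled: bool = False
    green_hue_deg: float = 110.0
    yellow_hue_deg: float = 60.0
    background_rgb: tuple = (210, 210, 230)
    nir_wet_grey: int = 108
    nir_dry_grey: int = 170
    moisture: float = 0.85
    texture_noise: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.senescent_fraction <= 1.0):
            raise ValueError("senescent_fraction must lie in [0, 1]")
        if self.ligule_height_px > self.stem_height_px:
            raise ValueError("ligule_height_px must not exceed stem_height_px")
        for name in ("green_hue_deg", "yellow_hue_deg"):
            if not (0.0 <= getattr(self, name) < 360.0):
                raise ValueError(f"{name} must lie in [0, 360)")
        for name in ("n_leaves", "leaf_length_px", "leaf_width_px", "stem_height_px", "ligule_height_px", "n_tillers"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 <= self.moisture <= 1.0):
            raise ValueError("moisture must lie in [0, 1]")
        if self.texture_noise < 0:
            raise ValueError("texture_noise must be >= 0")
        if len(self.background_rgb) != 3 or any(not (0 <= int(v) <= 255) for v in self.background_rgb):
            raise ValueError("background_rgb must be an 8-bit RGB triple")

    @property
    def is_empty(self) -> bool:
        return self.n_leaves == 0 and self.stem_height_px == 0


@dataclass
class GroundTruth:
    """Exact bookkeeping of what was rendered (the validation oracle)."""

    fg_pixels_per_view: dict
    senescent_pixels: int
    max_height_px: int
    ligule_height_px: int
    true_mean_hue_deg: float
    true_nir_grey: float

    def __post_init__(self):
        total = sum(self.fg_pixels_per_view.values())
        if self.senescent_pixels > total:
            raise ValueError("senescent pixels exceed total foreground")
        if any(v < 0 for v in self.fg_pixels_per_view.values()) or self.max_height_px < 0:
            raise ValueError("counts must be >= 0")


@dataclass
class PlantImageSet:
    """One timepoint's rendered views plus pseudo-NIR and palette metadata.

    ``true_masks`` carries the rendered foreground rasters (generator
    bookkeeping, used as the segmentation oracle); ``fg_palette`` /
    ``bg_palette`` are the exact base colours a nearest-neighbour
    classifier needs.
    """

    top: np.ndarray
    side0: np.ndarray
    side90: np.ndarray
    nir: dict
    true_masks: dict
    fg_palette: tuple
    bg_palette: tuple

    def rgb(self, view: str) -> np.ndarray:
        return {"top": self.top, "side0": self.side0, "side90": self.side90}[view]


# --- drawing ------------------------------------------------------------------


def _quad_bezier(p0, p1, p2, n):
    ts = np.linspace(0.0, 1.0, n)[:, None]
    p0, p1, p2 = (np.asarray(p, dtype=float)[None, :] for p in (p0, p1, p2))
    pts = (1 - ts) ** 2 * p0 + 2 * ts * (1 - ts) * p1 + ts**2 * p2
    tang = 2 * (1 - ts) * (p1 - p0) + 2 * ts * (p2 - p1)
    return pts, tang


def _fill_ribbon(mask, p0, p1, p2, w0, w2, n=30):
    """Fill a tapered quadratic-curve ribbon into a boolean raster.

    Points are (row, col); widths are full widths at base and tip.
    """
    pts, tang = _quad_bezier(p0, p1, p2, n)
    norm = np.linalg.norm(tang, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    unit = tang / norm
    perp = np.column_stack([-unit[:, 1], unit[:, 0]])
    hw = (w0 + (w2 - w0) * np.linspace(0, 1, n))[:, None] / 2.0
    left = pts + perp * hw
    right = pts - perp * hw
    poly = np.vstack([left, right[::-1]])
    rr, cc = draw_polygon(poly[:, 0], poly[:, 1], shape=mask.shape)
    mask[rr, cc] = True


def _leaf_plan(spec: PlantSpec):
    """Per-leaf azimuth (deg) and attachment height (px) for the main shoot."""
    if spec.n_leaves == 0:
        return []
    top_attach = max(spec.ligule_height_px, int(0.85 * spec.stem_height_px))
    if spec.n_leaves == 1:
        heights = [max(spec.ligule_height_px, 1)]
    else:
        heights = np.linspace(max(spec.ligule_height_px, 1), max(top_attach, spec.ligule_height_px, 1), spec.n_leaves)
        heights = [int(round(h)) for h in heights]
    az = [(360.0 * i / spec.n_leaves + 20.0) % 360.0 for i in range(spec.n_leaves)]
    return list(zip(az, heights))


def _stem_width(spec: PlantSpec) -> int:
    w = max(3, int(round(0.3 * spec.leaf_width_px)))
    return w if w % 2 == 1 else w + 1


def _draw_top(spec: PlantSpec):
    margin = 25
    L = spec.leaf_length_px
    size = max(64, 2 * (L + margin) + 1)
    mask = np.zeros((size, size), dtype=bool)
    c = size // 2
    width = spec.leaf_width_px * (0.5 if spec.rolled else 1.0)
    sw = _stem_width(spec)
    if spec.stem_height_px > 0:
        rr, cc = draw_disk((c, c), max(2, sw // 2 + 1), shape=mask.shape)
        mask[rr, cc] = True

    def _whorl(center, azimuths, length, w):
        for j, a in enumerate(azimuths):
            rad = math.radians(a)
            d = np.array([math.sin(rad), math.cos(rad)])
            perp = np.array([-d[1], d[0]])
            p0 = np.array(center, dtype=float) + d * 2.0
            p2 = np.array(center, dtype=float) + d * (2.0 + length)
            bend = perp * length * 0.10 * (1 if j % 2 == 0 else -1)
            p1 = np.array(center, dtype=float) + d * (2.0 + 0.5 * length) + bend
            if w >= 1 and length >= 2:
                _fill_ribbon(mask, p0, p1, p2, w, max(1.0, w * 0.35))

    _whorl((c, c), [a for a, _ in _leaf_plan(spec)], L, width)
    for k in range(1, spec.n_tillers + 1):
        dx = 14 * ((k + 1) // 2) * (1 if k % 2 else -1)
        azs = [(360.0 * j / 3 + 45.0 * k) % 360 for j in range(3)]
        _whorl((c, c + dx), azs, 0.5 * L, max(1.0, width * 0.6))
    return mask


def _draw_side(spec: PlantSpec, view_az_deg: float):
    L = spec.leaf_length_px
    sw = _stem_width(spec)
    plan = _leaf_plan(spec)
    rise = 0.45 * L
    top_needed = spec.stem_height_px
    if plan:
        top_needed = max(top_needed, max(h for _, h in plan) + rise)
    H = max(64, int(top_needed) + 40)
    W = max(64, int(2 * (L + 20) + sw + 2 + 28 * (spec.n_tillers + 1)))
    mask = np.zeros((H, W), dtype=bool)
    base_row = H - 15
    cx = W // 2

    def _stem(x, height, width):
        if height <= 0:
            return
        r0 = base_row - height + 1
        mask[r0 : base_row + 1, x - width // 2 : x + width // 2 + 1] = True

    def _leaves(x, leaf_plan, length, thickness, az_offset=0.0):
        for j, (az, h) in enumerate(leaf_plan):
            proj = math.cos(math.radians(az + az_offset - view_az_deg))
            sign = 1 if (proj > 0 or (proj == 0 and j % 2 == 0)) else -1
            d = length * sign * max(abs(proj), 0.15)
            attach_row = base_row - (h - 1)
            r = min(rise * max(abs(proj), 0.5), attach_row - 3)
            p0 = (float(attach_row), float(x + sign * (sw // 2)))
            p1 = (attach_row - 0.12 * r, x + 0.45 * d)
            p2 = (attach_row - r, x + d)
            _fill_ribbon(mask, p0, p1, p2, thickness, max(1.0, thickness * 0.5))

    thickness = max(2.0, 0.35 * spec.leaf_width_px) * (0.5 if spec.rolled else 1.0)
    _stem(cx, spec.stem_height_px, sw)
    _leaves(cx, plan, L, thickness)
    for k in range(1, spec.n_tillers + 1):
        dx = 26 * ((k + 1) // 2) * (1 if k % 2 else -1)
        t_stem = int(0.6 * spec.stem_height_px)
        t_plan = [((120 * j + 45.0 * k) % 360, max(1, int(0.35 * t_stem) + j * max(1, int(0.2 * t_stem)))) for j in range(2)]
        _stem(cx + dx, t_stem, max(3, sw - 2))
        if t_stem > 10:
            _leaves(cx + dx, t_plan, 0.5 * L, max(2.0, thickness * 0.6), az_offset=30.0 * k)
    return mask


def _paint_views(spec: PlantSpec, masks: dict, rng: np.random.Generator):
    """Colour the rendered masks; returns (rgb images, nir images, bookkeeping)."""
    green = np.round(hsi_to_rgb(spec.green_hue_deg, 0.65, 0.42)).astype(np.uint8)
    yellow = np.round(hsi_to_rgb(spec.yellow_hue_deg, 0.70, 0.50)).astype(np.uint8)
    bg = np.array(spec.background_rgb, dtype=np.uint8)
    nir_base = float(round(spec.nir_dry_grey + (spec.nir_wet_grey - spec.nir_dry_grey) * spec.moisture))

    images, nirs = {}, {}
    sen_total = 0
    hue_counts = {"green": 0, "yellow": 0}
    for view, mask in masks.items():
        h, w = mask.shape
        img = np.empty((h, w, 3), dtype=np.uint8)
        img[:] = bg
        nir = np.full((h, w), _NIR_BACKGROUND, dtype=np.uint8)
        rows, cols = np.nonzero(mask)
        n = rows.size
        if n:
            # senesce tip-first: order by distance from the plant base/centre
            if view == "top":
                ref = np.array([h // 2, w // 2])
            else:
                ref = np.array([h - 15, w // 2])
            d2 = (rows - ref[0]) ** 2 + (cols - ref[1]) ** 2
            order = np.argsort(-d2, kind="stable")
            k = int(round(spec.senescent_fraction * n))
            sen_idx = order[:k]
            colors = np.tile(green.astype(float), (n, 1))
            colors[sen_idx] = yellow.astype(float)
            if spec.texture_noise > 0:
                factors = 1.0 + spec.texture_noise * (2.0 * rng.random(n) - 1.0)
                colors *= factors[:, None]
            img[rows, cols] = np.clip(np.round(colors), 0, 255).astype(np.uint8)
            grey = np.full(n, nir_base)
            if spec.texture_noise > 0:
                grey = grey + rng.integers(-2, 3, size=n)
            nir[rows, cols] = np.clip(np.round(grey), 0, 255).astype(np.uint8)
            sen_total += k
            hue_counts["green"] += n - k
            hue_counts["yellow"] += k
        images[view] = img
        nirs[view] = nir

    # ground-truth hue: circular mean of the two quantised base-colour hues
    h_g = rgb_to_hsi(green.astype(float))[0]
    h_y = rgb_to_hsi(yellow.astype(float))[0]
    n_tot = hue_counts["green"] + hue_counts["yellow"]
    if n_tot == 0:
        true_hue = float("nan")
        nir_truth = float("nan")
    else:
        wg = hue_counts["green"] / n_tot
        wy = hue_counts["yellow"] / n_tot
        ang = np.radians([h_g, h_y])
        s = wg * np.sin(ang[0]) + wy * np.sin(ang[1])
        c = wg * np.cos(ang[0]) + wy * np.cos(ang[1])
        true_hue = float(np.mod(np.degrees(np.arctan2(s, c)), 360.0))
        nir_truth = nir_base
    palettes = ((tuple(int(v) for v in green), tuple(int(v) for v in yellow)), (tuple(int(v) for v in bg),))
    return images, nirs, sen_total, true_hue, nir_truth, palettes


def _mask_height_px(mask: np.ndarray) -> int:
    occ = np.nonzero(mask.any(axis=1))[0]
    return 0 if occ.size == 0 else int(occ[-1] - occ[0] + 1)


def generate_plant_images(spec: PlantSpec):
    """Render one plant -> (PlantImageSet, GroundTruth).

    Three RGB views (top, side 0, side 90) plus matching pseudo-NIR
    rasters.  Ground-truth counts are read off the rendered rasters, so
    they match exactly by construction; a degenerate spec (no leaves, no
    stem) yields a valid empty-plant result.
    """
    rng = np.random.default_rng(spec.seed)
    masks = {
        "top": _draw_top(spec),
        "side0": _draw_side(spec, 0.0),
        "side90": _draw_side(spec, 90.0),
    }
    images, nirs, sen_total, true_hue, nir_truth, (fg_pal, bg_pal) = _paint_views(spec, masks, rng)
    counts = {v: int(m.sum()) for v, m in masks.items()}
    max_h = max(_mask_height_px(masks["side0"]), _mask_height_px(masks["side90"]))
    if spec.is_empty:
        ligule = 0
    elif spec.n_leaves == 0:
        ligule = _mask_height_px(masks["side0"])  # leafless: no divergence point
    else:
        ligule = spec.ligule_height_px
    image_set = PlantImageSet(
        top=images["top"],
        side0=images["side0"],
        side90=images["side90"],
        nir=nirs,
        true_masks=masks,
        fg_palette=fg_pal,
        bg_palette=bg_pal,
    )
    truth = GroundTruth(
        fg_pixels_per_view=counts,
        senescent_pixels=sen_total,
        max_height_px=max_h,
        ligule_height_px=ligule,
        true_mean_hue_deg=true_hue,
        true_nir_grey=nir_truth,
    )
    return image_set, truth


# --- longitudinal trajectories ------------------------------------------------


@dataclass(frozen=True)
class TrajectorySpec:
    """Simulated leaf-area trajectory: model curve x lognormal noise.

    The noise factor has unit mean and coefficient of variation
    ``noise_cv`` exactly (sigma^2 = ln(1 + cv^2), mean offset -sigma^2/2),
    so the simulated areas are positive and mean-unbiased around the
    model curve.
    """

    model_name: str = "logistic3"
    params: dict = field(default_factory=lambda: {"Asym": 3000.0, "tmid": 35.0, "k": 5.0})
    times: tuple = tuple(range(18, 48))
    noise_cv: float = 0.05
    n_plants: int = 14
    seed: int = 0

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing with >= 2 points")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.n_plants < 1:
            raise ValueError("n_plants must be >= 1")
        growth.validate_params(self.model_name, self.params)
        growth.evaluate(self.model_name, self.params, t, strict=True)


@dataclass
class GrowthSeries:
    """Per-plant longitudinal trait trajectory."""

    plant_id: str
    times: np.ndarray
    values: np.ndarray
    variety: str = "sim"
    treatment: str = "sim"

    def endpoints(self):
        return (self.times[0], self.values[0]), (self.times[-1], self.values[-1])


def generate_growth_series(tspec: TrajectorySpec):
    """Simulate one plant cohort; returns a list of GrowthSeries."""
    rng = np.random.default_rng(tspec.seed)
    t = np.asarray(tspec.times, dtype=float)
    curve = np.asarray(growth.evaluate(tspec.model_name, tspec.params, t, strict=True), dtype=float)
    out = []
    sigma = math.sqrt(math.log(1.0 + tspec.noise_cv**2)) if tspec.noise_cv > 0 else 0.0
    for i in range(tspec.n_plants):
        if sigma > 0:
            factors = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=t.size)
        else:
            factors = np.ones(t.size)
        out.append(GrowthSeries(plant_id=f"plant_{i + 1:03d}", times=t.copy(), values=curve * factors))
    return out


def series_to_frame(series_list):
    """Long-format DataFrame (plant_id, variety, treatment, time, value)."""
    import pandas as pd

    rows = []
    for s in series_list:
        for t, v in zip(s.times, s.values):
            rows.append((s.plant_id, s.variety, s.treatment, float(t), float(v)))
    return pd.DataFrame(rows, columns=["plant_id", "variety", "treatment", "time", "value"])


# Canonical simulated trial designs -------------------------------------------
#
# Exponential-phase nutrient trial: six variety x nitrogen groups of six
# plants imaged three times a week from day 14; leaf area follows a
# near-exponential power law (RGR ~ 0.17 d^-1 declining only slightly with
# size, as in young well-fertilised cohorts).
NUTRIENT_TRIAL = dict(
    model_name="power_law",
    params={"M0": 160.0, "r": 0.222, "beta": 0.97},
    times=(14.0, 16.0, 18.0, 21.0, 23.0, 25.0, 28.0, 30.0),
    noise_cv=0.05,
    n_plants=6,
    n_groups=6,
)

# Sigmoidal watering trial: two varieties x two watering levels, fourteen
# plants each, imaged daily for thirty days; water limitation lowers the
# asymptote and advances the inflection by ~10 days.
WATERING_TRIAL_GROUPS = {
    "Sb:HighW": {"Asym": 1900.0, "tmid": 37.0, "k": 5.0},
    "Sb:LowW": {"Asym": 650.0, "tmid": 25.6, "k": 4.0},
    "HyA:HighW": {"Asym": 3100.0, "tmid": 35.9, "k": 5.0},
    "HyA:LowW": {"Asym": 1300.0, "tmid": 27.8, "k": 4.0},
}
WATERING_TRIAL = dict(model_name="logistic3", times=tuple(range(18, 48)), noise_cv=0.05, n_plants=14)


# --- diurnal leaf rolling -----------------------------------------------------


def generate_diurnal_pair(area_predawn: float, rolling_loss: float):
    """One afternoon/pre-dawn projected-area pair.

    Leaf rolling is realised as a proportional loss of projected area in
    the afternoon image: afternoon = predawn * (1 - rolling_loss).
    Returns (afternoon, predawn) in the input units.
    """
    if not (0.0 <= rolling_loss < 1.0):
        raise ValueError("rolling_loss must lie in [0, 1)")
    return area_predawn * (1.0 - rolling_loss), area_predawn


def generate_diurnal_pairs(
    n_pairs: int = 14,
    predawn_area: float = 1100.0,
    mean_loss: float = 0.22,
    sd_loss: float = 0.01,
    area_cv: float = 0.08,
    seed: int = 0,
):
    """Cohort of diurnal pairs with per-plant rolling loss ~ truncated normal.

    Defaults emulate a water-limited cohort (n = 14, mean loss 0.22) whose
    pre-dawn areas exceed the afternoon ones by ~28% on average.
    Returns a DataFrame (plant_id, la_afternoon, la_predawn).
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    losses = np.clip(rng.normal(mean_loss, sd_loss, size=n_pairs), 0.0, 0.9)
    sigma = math.sqrt(math.log(1.0 + area_cv**2)) if area_cv > 0 else 0.0
    areas = predawn_area * (rng.lognormal(-0.5 * sigma**2, sigma, size=n_pairs) if sigma > 0 else np.ones(n_pairs))
    rows = []
    for i, (a, loss) in enumerate(zip(areas, losses)):
        aft, pre = generate_diurnal_pair(float(a), float(loss))
        rows.append((f"plant_{i + 1:03d}", aft, pre))
    return pd.DataFrame(rows, columns=["plant_id", "la_afternoon", "la_predawn"])


# --- pot watering logs --------------------------------------------------------


def generate_watering_log(daily_transpiration, evaporation, n_days: int = None):
    """Gravimetric watering log for one planted pot and one empty control.

    Pots are weighed before and after each watering, so the daily water
    added equals the previous day's loss: transpiration + evaporation for
    the planted pot, evaporation only for the control.  Returns a
    DataFrame (day, pot_id, kind, water_added_g, cumulative_g).
    """
    import pandas as pd

    transp = np.atleast_1d(np.asarray(daily_transpiration, dtype=float))
    if n_days is None:
        n_days = transp.size
    if transp.size == 1:
        transp = np.full(n_days, transp[0])
    if transp.size != n_days:
        raise ValueError("daily_transpiration length must equal n_days")
    evap = np.atleast_1d(np.asarray(evaporation, dtype=float))
    if evap.size == 1:
        evap = np.full(n_days, evap[0])
    if evap.size != n_days:
        raise ValueError("evaporation length must equal n_days")
    if (transp < 0).any() or (evap < 0).any():
        raise ValueError("water losses must be non-negative")
    rows = []
    for day in range(1, n_days + 1):
        rows.append((day, "pot_plant", "planted", float(transp[day - 1] + evap[day - 1])))
        rows.append((day, "pot_control", "control", float(evap[day - 1])))
    df = pd.DataFrame(rows, columns=["day", "pot_id", "kind", "water_added_g"])
    df["cumulative_g"] = df.groupby("pot_id")["water_added_g"].cumsum()
    return df
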