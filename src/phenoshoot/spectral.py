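"""Colour-space traits: HSI hue angle and green/yellow senescence scoring.

Hue angle is the standard greenness index for visible-light phenotyping:
healthy leaves sit around 100-130 deg, senescing tissue drifts toward
yellow (~60 deg).  The transform used here is the classical
Hue-Saturation-Intensity decomposition (arccos form).  Hue is an angle, so
all averaging is circular; achromatic pixels (R = G = B) have no hue and
are excluded from means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "HueBands",
    "rgb_to_hsi",
    "hsi_to_rgb",
    "hue_angle",
    "mean_hue",
    "circular_mean_deg",
    "senescence_fraction",
]


@dataclass(frozen=True)
class HueBands:
    """Half-open hue intervals [low, high) classifying leaf condition.

    Defaults: green (healthy) [80, 160), yellow (senescent) [40, 80).
    Bands may wrap across 0/360 and must be disjoint.
    """

    green: tuple = (80.0, 160.0)
    yellow: tuple = (40.0, 80.0)

    def __post_init__(self):
        for name, (lo, hi) in (("green", self.green), ("yellow", self.yellow)):
            if not (0.0 <= lo < 360.0 and 0.0 <= hi <= 360.0):
                raise ValueError(f"{name} band bounds must lie in [0, 360)")
        g = self._band_set(self.green)
        y = self._band_set(self.yellow)
        if g & y:
            raise ValueError("green and yellow hue bands must be disjoint")

    @staticmethod
    def _band_set(band):
        lo, hi = band
        if lo < hi:
            return set(range(int(lo), int(np.ceil(hi))))
        return set(range(int(lo), 360)) | set(range(0, int(np.ceil(hi))))

    @staticmethod
    def _in_band(hue: np.ndarray, band) -> np.ndarray:
        lo, hi = band
        hue = np.mod(hue, 360.0)
        if lo < hi:
            return (hue >= lo) & (hue < hi)
        return (hue >= lo) | (hue < hi)

    def is_green(self, hue: np.ndarray) -> np.ndarray:
        return self._in_band(hue, self.green)

    def is_yellow(self, hue: np.ndarray) -> np.ndarray:
        return self._in_band(hue, self.yellow)


def rgb_to_hsi(rgb):
    """RGB (8-bit) -> (hue deg, saturation, intensity).

    Accepts a single triple or an (..., 3) array.  Hue is in [0, 360) and
    NaN for achromatic pixels; saturation in [0, 1]; intensity on [0, 1]
    (mean channel / 255).
    """
    arr = np.asarray(rgb, dtype=float)
    scalar = arr.ndim == 1
    arr = np.atleast_2d(arr)
    if arr.shape[-1] != 3:
        raise ValueError("expected RGB triples")
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("channels must lie in [0, 255]")
    r, g, b = arr[..., 0], arr[..., 1], arr[..., 2]
    num = 0.5 * ((r - g) + (r - b))
    den = np.sqrt((r - g) ** 2 + (r - b) * (g - b))
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.degrees(np.arccos(np.clip(num / den, -1.0, 1.0)))
    hue = np.where(b > g, 360.0 - theta, theta)
    hue = np.where(den == 0, np.nan, np.mod(hue, 360.0))
    total = r + g + b
    with np.errstate(invalid="ignore", divide="ignore"):
        sat = np.where(total > 0, 1.0 - 3.0 * np.minimum(np.minimum(r, g), b) / total, 0.0)
    intensity = total / (3.0 * 255.0)
    if scalar:
        return float(hue[0]), float(sat[0]), float(intensity[0])
    return hue, sat, intensity


def hsi_to_rgb(hue_deg: float, saturation: float, intensity: float):
    """Inverse HSI transform; returns float RGB on the 0-255 scale.

    Sector-based inverse of :func:`rgb_to_hsi`; round-trips hue exactly in
    real arithmetic (8-bit quantisation aside).
    """
    h = float(np.mod(hue_deg, 360.0))
    s = float(saturation)
    i = float(intensity)
    if not (0.0 <= s <= 1.0 and 0.0 <= i <= 1.0):
        raise ValueError("saturation and intensity must lie in [0, 1]")

    def _sector(hh):
        hr = np.radians(hh)
        c1 = i * (1.0 - s)
        c2 = i * (1.0 + s * np.cos(hr) / np.cos(np.radians(60.0) - hr))
        c3 = 3.0 * i - c1 - c2
        return c1, c2, c3

    if h < 120.0:
        b, r, g = _sector(h)
    elif h < 240.0:
        r, g, b = _sector(h - 120.0)
    else:
        g, b, r = _sector(h - 240.0)
    return tuple(float(np.clip(v, 0.0, 1.0)) * 255.0 for v in (r, g, b))


def hue_angle(image: np.ndarray) -> np.ndarray:
    """Per-pixel hue angle (deg, NaN where achromatic) of an RGB raster."""
    hue, _, _ = rgb_to_hsi(image)
    return hue


def circular_mean_deg(angles_deg: np.ndarray) -> float:
    """Circular mean of angles in degrees, result in [0, 360)."""
    a = np.radians(np.asarray(angles_deg, dtype=float))
    s, c = np.sin(a).mean(), np.cos(a).mean()
    if s == 0.0 and c == 0.0:
        raise ValueError("circular mean undefined (antipodal/empty angles)")
    return float(np.mod(np.degrees(np.arctan2(s, c)), 360.0))


def _masked_hues(image, mask) -> np.ndarray:
    raster = getattr(mask, "raster", mask)
    raster = np.asarray(raster, dtype=bool)
    image = np.asarray(image)
    if image.shape[:2] != raster.shape:
        raise ValueError("image and mask dimensions differ")
    if not raster.any():
        raise ValueError("mask is empty")
    hue = hue_angle(image[raster])
    return hue[np.isfinite(hue)]


def mean_hue(mask, image) -> float:
    """Circular mean hue angle over masked chromatic pixels."""
    hues = _masked_hues(image, mask)
    if hues.size == 0:
        raise ValueError("no chromatic pixels under the mask")
    return circular_mean_deg(hues)


def senescence_fraction(mask, image, bands: HueBands = HueBands()) -> float:
    """Proportion of classified leaf pixels that are senescent.

    yellow-band pixels / (green-band + yellow-band pixels); pixels in
    neither band (e.g. specular or soil-coloured) are excluded from both
    numerator and denominator.
    """
    hues = _masked_hues(image, mask)
    n_green = int(bands.is_green(hues).sum())
    n_yellow = int(bands.is_yellow(hues).sum())
    if n_green + n_yellow == 0:
        raise ValueError("no pixels fall in the green or yellow hue bands")
    return n_yellow / (n_green + n_yellow)
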