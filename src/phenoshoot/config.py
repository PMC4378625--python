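"""Run configuration: defaults, validation, YAML round-trip and hashing.

All tunables of the simulate -> extract -> fit -> report pipeline live in
one nested mapping with defaults matching the published calibration
(side-view constant 0.273 mm^2/px; top-view K_TV = 9.937e-5 * Y_ax +
0.061936) and documented fallbacks elsewhere.  Every source of
randomness flows from the declared seeds; there is no hidden entropy.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .growth import MODEL_NAMES
from .morphometrics import CameraCalibration
from .spectral import HueBands

DEFAULTS: dict = {
    "seed": 20110301,
    "simulate": {
        "n_plants": 4,
        "n_timepoints": 4,
        "plant": {
            "n_leaves": 5,
            "leaf_length_px": 180,
            "leaf_width_px": 18,
            "stem_height_px": 140,
            "ligule_height_px": 60,
            "n_tillers": 0,
            "senescent_fraction": 0.04,
            "rolled": False,
            "green_hue_deg": 110.0,
            "yellow_hue_deg": 60.0,
            "background_rgb": [210, 210, 230],
            "nir_wet_grey": 108,
            "nir_dry_grey": 170,
            "moisture": 0.85,
            "texture_noise": 0.05,
        },
        "growth": {
            "model": "logistic3",
            "params": {"Asym": 3000.0, "tmid": 35.0, "k": 5.0},
            "t_start": 18,
            "t_stop": 47,
            "noise_cv": 0.05,
        },
        "diurnal": {"n_pairs": 14, "predawn_area": 1100.0, "mean_loss": 0.22, "sd_loss": 0.01},
        "watering": {"n_days": 28, "transpiration_g": 45.0, "evaporation_g": 8.0, "final_biomass_g": 9.5},
    },
    "calibration": {
        "side_area_factor": 0.273,
        "tv_slope": 9.937e-5,
        "tv_intercept": 0.061936,
        "side_linear_factor": None,  # default sqrt(side_area_factor)
        "side_constant_is_area": True,
    },
    "segmentation": {"erosion_radius": 1, "dilation_radius": 1, "min_component_px": 5, "width_ratio": 2.5},
    "hue_bands": {"green": [80.0, 160.0], "yellow": [40.0, 80.0]},
    "models": {"candidates": ["logistic3", "gompertz", "exponential", "power_law"], "band_draws": 1000, "band_level": 0.95},
}


def _deep_merge(base: dict, extra: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in (extra or {}).items():
        if k in out and isinstance(out[k], dict) and isinstance(v, dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


@dataclass
class RunConfig:
    """Validated pipeline configuration (see DEFAULTS for the schema)."""

    data: dict = field(default_factory=lambda: copy.deepcopy(DEFAULTS))

    @classmethod
    def from_dict(cls, overrides: dict = None) -> "RunConfig":
        cfg = cls(_deep_merge(DEFAULTS, overrides or {}))
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            overrides = yaml.safe_load(fh) or {}
        return cls.from_dict(overrides)

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(self.data, fh, sort_keys=True)
        return path

    def validate(self):
        unknown = [m for m in self.data["models"]["candidates"] if m not in MODEL_NAMES]
        if unknown:
            raise ValueError(f"unknown growth model(s) in config: {unknown}; choose from {sorted(MODEL_NAMES)}")
        sim_model = self.data["simulate"]["growth"]["model"]
        if sim_model not in MODEL_NAMES:
            raise ValueError(f"unknown growth model in simulate.growth: {sim_model!r}")
        seg = self.data["segmentation"]
        if seg["erosion_radius"] < 0 or seg["dilation_radius"] < 0 or seg["min_component_px"] < 0:
            raise ValueError("segmentation parameters must be >= 0")
        if self.data["models"]["band_draws"] < 2:
            raise ValueError("band_draws must be >= 2")
        # constructing these validates their own invariants
        self.calibration()
        self.hue_bands()

    def calibration(self) -> CameraCalibration:
        c = self.data["calibration"]
        if c.get("side_constant_is_area", True):
            return CameraCalibration(
                side_area_factor=c["side_area_factor"],
                tv_slope=c["tv_slope"],
                tv_intercept=c["tv_intercept"],
                side_linear_factor=c.get("side_linear_factor"),
            )
        return CameraCalibration.linear_side_constant(
            side_constant=c["side_area_factor"], tv_slope=c["tv_slope"], tv_intercept=c["tv_intercept"]
        )

    def hue_bands(self) -> HueBands:
        hb = self.data["hue_bands"]
        return HueBands(green=tuple(hb["green"]), yellow=tuple(hb["yellow"]))

    @property
    def seed(self) -> int:
        return int(self.data["seed"])

    def hash(self) -> str:
        canon = json.dumps(self.data, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]
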