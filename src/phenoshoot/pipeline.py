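"""The simulate -> extract -> fit -> report pipeline.

Each stage reads the previous stage's CSV/PNG artifacts from the output
directory and writes its own, every table stamped with the config hash
and seed.  A stage failure halts the run with a stage-named error;
partial outputs are retained for inspection.  Re-running with the same
configuration and seeds reproduces the CSV outputs byte for byte.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import growth, io, morphometrics, phenostats, synthetic
from .config import RunConfig
from .segmentation import VIEWS, ColorClassifier, classify_pixels, clean_and_compose

logger = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, exc: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {exc}")
        self.stage = stage


def _plant_spec_at(cfg: RunConfig, plant_idx: int, rel_size: float) -> synthetic.PlantSpec:
    """Scale the base plant blueprint to a relative size in (0, 1]."""
    p = cfg.data["simulate"]["plant"]
    s = float(np.clip(np.sqrt(rel_size), 0.3, 1.0))
    return synthetic.PlantSpec(
        n_leaves=p["n_leaves"],
        leaf_length_px=max(8, int(round(p["leaf_length_px"] * s))),
        leaf_width_px=max(3, int(round(p["leaf_width_px"] * (0.6 + 0.4 * s)))),
        stem_height_px=max(4, int(round(p["stem_height_px"] * s))),
        ligule_height_px=min(max(2, int(round(p["ligule_height_px"] * s))), max(4, int(round(p["stem_height_px"] * s)))),
        n_tillers=p["n_tillers"],
        senescent_fraction=p["senescent_fraction"],
        rolled=p["rolled"],
        green_hue_deg=p["green_hue_deg"],
        yellow_hue_deg=p["yellow_hue_deg"],
        background_rgb=tuple(p["background_rgb"]),
        nir_wet_grey=p["nir_wet_grey"],
        nir_dry_grey=p["nir_dry_grey"],
        moisture=p["moisture"],
        texture_noise=p["texture_noise"],
        seed=cfg.seed + 1000 + plant_idx,
    )


def stage_simulate(cfg: RunConfig, out_dir: Path) -> dict:
    sim = cfg.data["simulate"]
    g = sim["growth"]
    times = tuple(range(int(g["t_start"]), int(g["t_stop"]) + 1))
    tspec = synthetic.TrajectorySpec(
        model_name=g["model"], params=g["params"], times=times, noise_cv=g["noise_cv"],
        n_plants=sim["n_plants"], seed=cfg.seed,
    )
    series = synthetic.generate_growth_series(tspec)
    io.write_table(synthetic.series_to_frame(series), out_dir / "series.csv", cfg.hash(), cfg.seed)

    # images at n_timepoints evenly spaced along each plant's trajectory
    n_tp = int(sim["n_timepoints"])
    tp_idx = np.linspace(0, len(times) - 1, n_tp).round().astype(int)
    img_dir = out_dir / "images"
    gt_rows = []
    for i, s in enumerate(series):
        final = s.values[-1]
        for j in tp_idx:
            rel = float(s.values[j] / final) if final > 0 else 1.0
            spec = _plant_spec_at(cfg, i * 100 + int(j), rel)
            image_set, truth = synthetic.generate_plant_images(spec)
            tag = f"{s.plant_id}_t{int(times[j]):03d}"
            for view in VIEWS:
                io.write_png(img_dir / f"{tag}_{view}.png", image_set.rgb(view))
                io.write_png(img_dir / f"{tag}_{view}_nir.png", image_set.nir[view])
            drawn_mm2 = morphometrics.projected_leaf_area(
                image_set.true_masks["top"], image_set.true_masks["side0"], image_set.true_masks["side90"],
                calib=cfg.calibration(),
            )
            gt_rows.append(
                dict(
                    plant_id=s.plant_id, time=float(times[j]),
                    drawn_area_mm2=drawn_mm2,
                    fg_top=truth.fg_pixels_per_view["top"],
                    fg_side0=truth.fg_pixels_per_view["side0"],
                    fg_side90=truth.fg_pixels_per_view["side90"],
                    senescent_pixels=truth.senescent_pixels,
                    max_height_px=truth.max_height_px,
                    ligule_height_px=truth.ligule_height_px,
                    true_mean_hue_deg=truth.true_mean_hue_deg,
                    true_nir_grey=truth.true_nir_grey,
                    fg_green=json.dumps(image_set.fg_palette[0]),
                    fg_yellow=json.dumps(image_set.fg_palette[1]),
                    bg=json.dumps(image_set.bg_palette[0]),
                )
            )
    io.write_table(pd.DataFrame(gt_rows), out_dir / "ground_truth.csv", cfg.hash(), cfg.seed)

    d = sim["diurnal"]
    pairs = synthetic.generate_diurnal_pairs(
        n_pairs=d["n_pairs"], predawn_area=d["predawn_area"], mean_loss=d["mean_loss"],
        sd_loss=d["sd_loss"], seed=cfg.seed + 7,
    )
    io.write_table(pairs, out_dir / "diurnal.csv", cfg.hash(), cfg.seed)

    w = sim["watering"]
    log = synthetic.generate_watering_log(w["transpiration_g"], w["evaporation_g"], int(w["n_days"]))
    io.write_table(log, out_dir / "watering.csv", cfg.hash(), cfg.seed)
    logger.info("simulate: %d plants, %d image timepoints", sim["n_plants"], n_tp)
    return {"series": out_dir / "series.csv", "images": img_dir, "ground_truth": out_dir / "ground_truth.csv"}


def stage_extract(cfg: RunConfig, out_dir: Path) -> dict:
    gt = io.read_table(out_dir / "ground_truth.csv")
    calib = cfg.calibration()
    bands = cfg.hue_bands()
    seg = cfg.data["segmentation"]
    img_dir = out_dir / "images"
    rows = []
    for _, rec in gt.iterrows():
        tag = f"{rec.plant_id}_t{int(rec.time):03d}"
        clf = ColorClassifier(
            fg_palette=(tuple(json.loads(rec.fg_green)), tuple(json.loads(rec.fg_yellow))),
            bg_palette=(tuple(json.loads(rec.bg)),),
        )
        masks, nirs, top_img = {}, {}, None
        for view in VIEWS:
            img = io.read_png(img_dir / f"{tag}_{view}.png")
            if view == "top":
                top_img = img
            raw = classify_pixels(img, clf)
            masks[view] = clean_and_compose(
                raw, seg["erosion_radius"], seg["dilation_radius"], seg["min_component_px"], view_label=view
            )
            nirs[view] = io.read_png(img_dir / f"{tag}_{view}_nir.png")
        traits = morphometrics.compute_shoot_traits(
            masks["top"], masks["side0"], masks["side90"], top_image=top_img,
            nir_pair=(nirs["side0"], nirs["side90"]), calib=calib, bands=bands,
            width_ratio=seg["width_ratio"],
        )
        rows.append(dict(plant_id=rec.plant_id, time=rec.time, **traits.as_dict()))
    df = pd.DataFrame(rows)
    io.write_table(df, out_dir / "traits.csv", cfg.hash(), cfg.seed)
    logger.info("extract: %d trait records", len(df))
    return {"traits": out_dir / "traits.csv"}


def stage_fit(cfg: RunConfig, out_dir: Path) -> dict:
    series = io.read_table(out_dir / "series.csv")
    groups = {}
    for (variety, treatment), sub in series.groupby(["variety", "treatment"]):
        groups[f"{variety}:{treatment}"] = (sub["time"].to_numpy(), sub["value"].to_numpy())
    sel = growth.select_model(groups, cfg.data["models"]["candidates"], seed=cfg.seed)
    io.write_table(sel.table, out_dir / "selection.csv", cfg.hash(), cfg.seed)

    fits_out = {}
    curve_rows = []
    draws = int(cfg.data["models"]["band_draws"])
    level = float(cfg.data["models"]["band_level"])
    for group in groups:
        f = sel.fits[(sel.best, group)]
        fits_out[group] = dict(
            model=f.model_name, estimates=f.estimates, stderr=f.stderr(), aic=f.aic, r2=f.r2,
            converged=f.converged, n_obs=f.n_obs,
        )
        t_grid = np.linspace(f.t_range[0], f.t_range[1], 60)
        gc = growth.growth_curves(f, t_grid, n_draws=draws, level=level, seed=cfg.seed)
        for tt, m, a, r, lo, up in zip(gc.times, gc.M, gc.AGR, gc.RGR, gc.lower, gc.upper):
            curve_rows.append(dict(group=group, time=tt, M=m, AGR=a, RGR=r, lower=lo, upper=up))
    with open(out_dir / "fits.json", "w") as fh:
        json.dump({"best_model": sel.best, "groups": fits_out}, fh, indent=2, sort_keys=True)
    io.write_table(pd.DataFrame(curve_rows), out_dir / "curves.csv", cfg.hash(), cfg.seed)
    logger.info("fit: best model %s across %d group(s)", sel.best, len(groups))
    return {"selection": out_dir / "selection.csv", "curves": out_dir / "curves.csv"}


def stage_report(cfg: RunConfig, out_dir: Path) -> dict:
    series = io.read_table(out_dir / "series.csv")
    by_plant = {pid: (sub["time"].to_numpy(), sub["value"].to_numpy()) for pid, sub in series.groupby("plant_id")}
    variants = phenostats.rgr_variants(by_plant)
    io.write_table(variants.reset_index(), out_dir / "rgr_variants.csv", cfg.hash(), cfg.seed)

    pairs = io.read_table(out_dir / "diurnal.csv")
    rolling = phenostats.leaf_rolling(pairs)

    log = io.read_table(out_dir / "watering.csv")
    biomass = float(cfg.data["simulate"]["watering"]["final_biomass_g"])
    wue_val = phenostats.wue(biomass, log)

    traits = io.read_table(out_dir / "traits.csv")
    gt = io.read_table(out_dir / "ground_truth.csv")
    merged = traits.merge(gt, on=["plant_id", "time"])
    reg = phenostats.validate_projection(merged["projected_leaf_area"], merged["drawn_area_mm2"])

    summary = [
        f"plants: {series['plant_id'].nunique()}  timepoints: {series['time'].nunique()}",
        f"RGR(individual) mean: {variants['rgr_individual'].mean():.4f} d^-1",
        f"RGR(leaf area)  mean: {variants['rgr_leaf_area'].mean():.4f} d^-1",
        f"leaf rolling: +{rolling.mean_pct_increase:.1f}% +/- {rolling.se:.1f}% (paired t p={rolling.p_value:.2e}, n={rolling.n})",
        f"WUE: {wue_val:.2f} g kg^-1",
        f"projected vs drawn area: slope {reg.slope:.3f}, R^2 {reg.r2:.3f} (n={reg.n})",
    ]
    (out_dir / "summary.txt").write_text("\n".join(summary) + "\n")
    report_df = pd.DataFrame(
        [
            dict(metric="rolling_mean_pct_increase", value=rolling.mean_pct_increase),
            dict(metric="rolling_se", value=rolling.se),
            dict(metric="rolling_p", value=rolling.p_value),
            dict(metric="wue_g_per_kg", value=wue_val),
            dict(metric="validation_slope", value=reg.slope),
            dict(metric="validation_r2", value=reg.r2),
        ]
    )
    io.write_table(report_df, out_dir / "report.csv", cfg.hash(), cfg.seed)
    logger.info("report: %s", "; ".join(summary))
    return {"report": out_dir / "report.csv", "summary": out_dir / "summary.txt"}


_STAGES = (
    ("simulate", stage_simulate),
    ("extract", stage_extract),
    ("fit", stage_fit),
    ("report", stage_report),
)


def run_pipeline(cfg: RunConfig, out_dir) -> dict:
    """Run all four stages; returns a mapping of artifact paths.

    The configuration is validated before any stage runs; a stage failure
    raises :class:`PipelineStageError` naming the stage, with earlier
    artifacts left on disk.
    """
    cfg.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out_dir / "config.yaml")
    artifacts: dict = {}
    for name, fn in _STAGES:
        try:
            artifacts.update(fn(cfg, out_dir))
        except Exception as exc:  # noqa: BLE001
            logger.error("stage %s failed: %s", name, exc)
            raise PipelineStageError(name, exc) from exc
    return artifacts
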