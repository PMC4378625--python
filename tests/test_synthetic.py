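"""Generator contracts: exact bookkeeping, determinism, noise calibration."""

import numpy as np
import pytest

from phenoshoot import growth, synthetic


class TestPlantImages:
    def test_pixel_count_conservation(self, default_plant):
        """Ground-truth counts equal the rendered non-background pixels exactly."""
        spec, images, truth = default_plant
        for view in ("top", "side0", "side90"):
            mask = images.true_masks[view]
            assert truth.fg_pixels_per_view[view] == int(mask.sum())
            img = images.rgb(view)
            non_bg = (img != np.array(spec.background_rgb, dtype=np.uint8)).any(axis=-1)
            assert truth.fg_pixels_per_view[view] == int(non_bg.sum())

    def test_byte_identical_given_seed(self):
        a, _ = synthetic.generate_plant_images(synthetic.PlantSpec(seed=5))
        b, _ = synthetic.generate_plant_images(synthetic.PlantSpec(seed=5))
        for view in ("top", "side0", "side90"):
            assert np.array_equal(a.rgb(view), b.rgb(view))
            assert np.array_equal(a.nir[view], b.nir[view])

    def test_geometry_independent_of_seed(self):
        """The seed drives only texture noise; the ground truth is identical."""
        _, t1 = synthetic.generate_plant_images(synthetic.PlantSpec(seed=1))
        _, t2 = synthetic.generate_plant_images(synthetic.PlantSpec(seed=99))
        assert t1.fg_pixels_per_view == t2.fg_pixels_per_view
        assert t1.senescent_pixels == t2.senescent_pixels
        assert t1.max_height_px == t2.max_height_px
        assert t1.true_mean_hue_deg == t2.true_mean_hue_deg

    def test_stem_only_plant(self):
        spec = synthetic.PlantSpec(n_leaves=0, stem_height_px=200, ligule_height_px=0, seed=0)
        images, truth = synthetic.generate_plant_images(spec)
        assert truth.max_height_px == 200
        # top view is just the stem cross-section: a small compact disc
        assert 0 < truth.fg_pixels_per_view["top"] < 100
        assert truth.ligule_height_px == 200  # leafless: no divergence point

    def test_empty_plant_is_valid(self):
        spec = synthetic.PlantSpec(n_leaves=0, stem_height_px=0, ligule_height_px=0, seed=0)
        images, truth = synthetic.generate_plant_images(spec)
        assert sum(truth.fg_pixels_per_view.values()) == 0
        assert truth.max_height_px == 0
        assert np.isnan(truth.true_mean_hue_deg)

    def test_senescent_fraction_exact(self):
        _, truth = synthetic.generate_plant_images(synthetic.PlantSpec(senescent_fraction=0.2, seed=1))
        total = sum(truth.fg_pixels_per_view.values())
        # per-view rounding: at most one pixel-rounding unit per view
        assert truth.senescent_pixels / total == pytest.approx(0.20, abs=3 / total)

    def test_rolled_reduces_projected_area(self):
        _, unrolled = synthetic.generate_plant_images(synthetic.PlantSpec(rolled=False, seed=2))
        _, rolled = synthetic.generate_plant_images(synthetic.PlantSpec(rolled=True, seed=2))
        for view in ("top", "side0", "side90"):
            assert rolled.fg_pixels_per_view[view] < unrolled.fg_pixels_per_view[view]

    @pytest.mark.parametrize(
        "bad",
        [
            dict(senescent_fraction=1.2),
            dict(ligule_height_px=300, stem_height_px=100),
            dict(green_hue_deg=400.0),
            dict(moisture=1.5),
            dict(n_leaves=-1),
        ],
    )
    def test_invalid_specs_rejected(self, bad):
        with pytest.raises(ValueError):
            synthetic.PlantSpec(**bad)


class TestGrowthSeries:
    def test_zero_noise_equals_curve(self):
        params = {"Asym": 3000.0, "tmid": 35.0, "k": 5.0}
        tspec = synthetic.TrajectorySpec("logistic3", params, tuple(range(18, 48)), 0.0, 3, seed=0)
        for s in synthetic.generate_growth_series(tspec):
            expected = params["Asym"] / (1 + np.exp((params["tmid"] - s.times) / params["k"]))
            np.testing.assert_allclose(s.values, expected, rtol=1e-12)

    def test_exponential_closed_form(self):
        tspec = synthetic.TrajectorySpec("exponential", {"M0": 10.0, "r": 0.1}, (0.0, 10.0), 0.0, 1, seed=0)
        (s,) = synthetic.generate_growth_series(tspec)
        assert s.values[-1] == pytest.approx(10 * np.e, rel=1e-12)

    def test_sample_cv_calibrated(self):
        """Monte-Carlo check: lognormal noise reproduces the requested CV."""
        tspec = synthetic.TrajectorySpec(noise_cv=0.05, n_plants=200, seed=21)
        series = synthetic.generate_growth_series(tspec)
        values = np.array([s.values for s in series])  # plants x times
        cvs = values.std(axis=0, ddof=1) / values.mean(axis=0)
        assert 0.04 <= cvs.mean() <= 0.06

    def test_mean_unbiased(self):
        """Sample mean at each t converges to the model curve (2 SE tolerance)."""
        params = {"Asym": 3000.0, "tmid": 35.0, "k": 5.0}
        tspec = synthetic.TrajectorySpec("logistic3", params, tuple(range(18, 48)), 0.1, 1000, seed=5)
        series = synthetic.generate_growth_series(tspec)
        values = np.array([s.values for s in series])
        curve = growth.evaluate("logistic3", params, np.asarray(tspec.times, float))
        se = values.std(axis=0, ddof=1) / np.sqrt(values.shape[0])
        assert (np.abs(values.mean(axis=0) - curve) <= 2 * se + 1e-9).mean() > 0.9

    @pytest.mark.parametrize(
        "bad",
        [
            dict(model_name="power_law", params={"M0": 10.0, "r": 0.1, "beta": 1.0}),
            dict(times=(3.0, 2.0, 1.0)),
            dict(noise_cv=-0.1),
            dict(model_name="nosuch"),
        ],
    )
    def test_invalid_trajectory_specs_rejected(self, bad):
        with pytest.raises(ValueError):
            synthetic.TrajectorySpec(**bad)


class TestDiurnalAndWatering:
    def test_diurnal_pair_construction(self):
        afternoon, predawn = synthetic.generate_diurnal_pair(1280.0, 0.21875)
        assert afternoon == pytest.approx(1000.0)
        assert 100 * (predawn - afternoon) / afternoon == pytest.approx(28.0)

    def test_no_rolling(self):
        assert synthetic.generate_diurnal_pair(500.0, 0.0) == (500.0, 500.0)

    def test_rolling_loss_bounds(self):
        with pytest.raises(ValueError):
            synthetic.generate_diurnal_pair(500.0, 1.0)

    def test_cohort_mean_increase(self):
        pairs = synthetic.generate_diurnal_pairs(n_pairs=500, mean_loss=0.22, sd_loss=0.01, seed=4)
        pct = 100 * (pairs.la_predawn - pairs.la_afternoon) / pairs.la_afternoon
        assert pct.mean() == pytest.approx(100 * (1 / 0.78 - 1), abs=0.5)

    def test_watering_cumulative_sum(self):
        log = synthetic.generate_watering_log(10.0, 0.0, 10)
        planted = log[log.kind == "planted"]
        assert planted.cumulative_g.iloc[-1] == pytest.approx(100.0)

    def test_zero_transpiration_matches_control(self):
        log = synthetic.generate_watering_log(0.0, 5.0, 7)
        planted = log[log.kind == "planted"].water_added_g.to_numpy()
        control = log[log.kind == "control"].water_added_g.to_numpy()
        np.testing.assert_array_equal(planted, control)

    def test_random_daily_values_match_running_sum(self, rng):
        transp = rng.uniform(5, 50, 20)
        evap = rng.uniform(1, 5, 20)
        log = synthetic.generate_watering_log(transp, evap, 20)
        planted = log[log.kind == "planted"]
        # independent running-sum oracle
        running = 0.0
        for day, add in zip(planted.day, planted.water_added_g):
            running += transp[day - 1] + evap[day - 1]
            assert planted[planted.day == day].cumulative_g.iloc[0] == pytest.approx(running)

    def test_negative_losses_rejected(self):
        with pytest.raises(ValueError):
            synthetic.generate_watering_log(-1.0, 0.0, 5)
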