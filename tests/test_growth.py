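"""Growth-model library: closed forms, rates, fitting, selection, bands."""

import numpy as np
import pytest

from phenoshoot import growth, synthetic
from phenoshoot.growth import agr, evaluate, fit, inflection_time, prediction_band, rgr, select_model, self_start

L3 = {"Asym": 3000.0, "tmid": 35.0, "k": 5.0}
T_DAILY = np.arange(18.0, 48.0)

_VALID_PARAMS = {
    "exponential": {"M0": 10.0, "r": 0.12},
    "power_law": {"M0": 10.0, "r": 0.4, "beta": 0.8},
    "logistic3": L3,
    "logistic4": {"A": 50.0, "Asym": 3000.0, "tmid": 35.0, "k": 5.0},
    "gompertz": {"Asym": 3000.0, "b2": 8.0, "b3": 0.88},
    "weibull": {"Asym": 3000.0, "Drop": 2900.0, "lrc": -8.0, "pwr": 2.5},
    "richards": {"Asym": 3000.0, "tmid": 35.0, "k": 5.0, "nu": 1.5},
    "beta": {"Mmax": 3000.0, "te": 45.0, "tm": 30.0},
}


class TestEvaluate:
    def test_power_law_beta_zero_is_linear(self):
        assert evaluate("power_law", {"M0": 1.0, "r": 2.0, "beta": 0.0}, 3.0) == pytest.approx(7.0)

    def test_logistic_midpoint_is_half_asymptote(self):
        assert evaluate("logistic3", L3, 35.0) == pytest.approx(1500.0)

    def test_power_law_approaches_exponential_as_beta_to_one(self):
        m_p = evaluate("power_law", {"M0": 10.0, "r": 0.1, "beta": 0.999}, 1.0)
        m_e = evaluate("exponential", {"M0": 10.0, "r": 0.1}, 1.0)
        assert abs(m_p - m_e) / m_e < 1e-3

    def test_power_law_domain_violation_names_time(self):
        # beta > 1: the base hits zero in finite time
        with pytest.raises(ValueError, match="t ="):
            evaluate("power_law", {"M0": 10.0, "r": 1.0, "beta": 2.0}, np.array([0.0, 50.0]))

    def test_beta_function_requires_tm_below_te(self):
        with pytest.raises(ValueError):
            evaluate("beta", {"Mmax": 100.0, "te": 10.0, "tm": 20.0}, 5.0)

    def test_unknown_model(self):
        with pytest.raises(ValueError):
            evaluate("nosuch", {}, 1.0)


class TestRates:
    def test_logistic_agr_maximum_at_tmid(self):
        assert agr("logistic3", L3, 35.0) == pytest.approx(3000.0 / (4 * 5.0))
        t = np.linspace(20, 50, 301)
        assert np.max(agr("logistic3", L3, t)) <= 3000.0 / 20.0 + 1e-9

    def test_logistic_rgr_vanishes_at_late_times(self):
        assert rgr("logistic3", L3, 200.0) < 1e-10

    def test_power_law_agr_matches_central_difference(self):
        p = {"M0": 10.0, "r": 0.4, "beta": 0.8}
        t = np.linspace(1.0, 30.0, 50)
        analytic = agr("power_law", p, t)
        h = 1e-4 * 30
        numeric = (evaluate("power_law", p, t + h) - evaluate("power_law", p, t - h)) / (2 * h)
        np.testing.assert_allclose(analytic, numeric, rtol=1e-6)

    @pytest.mark.parametrize("model", sorted(_VALID_PARAMS))
    def test_rgr_equals_agr_over_m(self, model):
        p = _VALID_PARAMS[model]
        t = np.linspace(5.0, 44.0, 14)
        M = evaluate(model, p, t, strict=False)
        np.testing.assert_allclose(rgr(model, p, t), np.asarray(agr(model, p, t)) / M, rtol=1e-12)

    def test_exponential_rgr_constant(self):
        t = np.linspace(0, 20, 10)
        np.testing.assert_allclose(rgr("exponential", {"M0": 5.0, "r": 0.13}, t), 0.13, rtol=1e-12)

    def test_power_law_rgr_monotone_in_m_with_sign_beta_minus_one(self):
        t = np.linspace(1, 30, 40)
        r_dec = rgr("power_law", {"M0": 10.0, "r": 0.4, "beta": 0.8}, t)
        assert np.all(np.diff(r_dec) < 0)  # beta < 1: RGR falls with size


class TestSelfStart:
    def test_noise_free_logistic_within_20pct(self):
        y = evaluate("logistic3", L3, T_DAILY)
        p0 = self_start("logistic3", T_DAILY, y)
        truth = np.array([3000.0, 35.0, 5.0])
        assert np.all(np.abs(p0 - truth) / truth < 0.20)

    def test_decreasing_series_rejected(self):
        with pytest.raises(ValueError, match="nondecreasing"):
            self_start("logistic3", T_DAILY[:5], np.array([5.0, 4.0, 3.0, 2.0, 1.0]))

    def test_constant_series_degenerate_flagged(self):
        with pytest.warns(UserWarning, match="constant"):
            p0 = self_start("logistic3", T_DAILY[:6], np.full(6, 100.0))
        assert p0[0] == pytest.approx(105.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            self_start("richards", np.array([1.0, 2.0]), np.array([1.0, 2.0]))


class TestFit:
    def test_noise_free_exact_recovery(self):
        y = evaluate("logistic3", L3, T_DAILY)
        f = fit("logistic3", T_DAILY, y)
        assert f.converged
        assert f.r2 == pytest.approx(1.0, abs=1e-12)
        for name, truth in L3.items():
            assert f.estimates[name] == pytest.approx(truth, rel=1e-6)

    def test_noisy_cohort_recovery_within_5pct(self):
        errs = []
        for seed in range(20):
            series = synthetic.generate_growth_series(synthetic.TrajectorySpec(seed=seed))
            t = np.concatenate([s.times for s in series])
            y = np.concatenate([s.values for s in series])
            f = fit("logistic3", t, y, variance="power")
            assert f.converged
            errs.append([abs(f.estimates[k] - L3[k]) / L3[k] for k in ("Asym", "tmid", "k")])
        assert np.median(errs, axis=0).max() < 0.05

    def test_ill_posed_richards_records_non_convergence(self):
        """An interpolating sigmoid on linear data is not a valid convergence."""
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        f = fit("richards", t, 10.0 + 2.0 * t)
        assert not f.converged
        assert not np.isfinite(f.aic)  # AIC finite iff converged
        assert f.message  # diagnosis recorded, no exception raised

    def test_time_origin_shift_invariance(self):
        y = evaluate("logistic3", L3, T_DAILY)
        f0 = fit("logistic3", T_DAILY, y)
        f1 = fit("logistic3", T_DAILY + 10.0, y)
        assert f1.estimates["tmid"] == pytest.approx(f0.estimates["tmid"] + 10.0, rel=1e-6)
        assert f1.estimates["Asym"] == pytest.approx(f0.estimates["Asym"], rel=1e-6)
        assert f1.estimates["k"] == pytest.approx(f0.estimates["k"], rel=1e-6)

    def test_aic_prefers_true_model_over_nesting_on_average(self):
        """logistic3 vs the 4-parameter logistic that nests it (n=30/series)."""
        diffs = []
        for seed in range(200):
            series = synthetic.generate_growth_series(
                synthetic.TrajectorySpec(noise_cv=0.05, n_plants=1, seed=seed)
            )
            t, y = series[0].times, series[0].values
            f3 = fit("logistic3", t, y)
            f4 = fit("logistic4", t, y)
            if f3.converged and f4.converged:
                diffs.append(f3.aic - f4.aic)
        assert len(diffs) > 100
        assert np.mean(diffs) <= 0.0

    def test_bad_weights_rejected(self):
        y = evaluate("logistic3", L3, T_DAILY)
        with pytest.raises(ValueError):
            fit("logistic3", T_DAILY, y, weights=np.zeros_like(y))


class TestPredictionBand:
    def _converged_fit(self, seed=0):
        series = synthetic.generate_growth_series(synthetic.TrajectorySpec(seed=seed))
        t = np.concatenate([s.times for s in series])
        y = np.concatenate([s.values for s in series])
        return fit("logistic3", t, y)

    def test_zero_covariance_collapses_onto_curve(self):
        f = self._converged_fit()
        f.covariance = np.zeros((3, 3))
        lo, up = prediction_band(f, T_DAILY, n_draws=200, seed=1)
        curve = evaluate("logistic3", f.params, T_DAILY)
        np.testing.assert_allclose(lo, curve, rtol=1e-12)
        np.testing.assert_allclose(up, curve, rtol=1e-12)

    def test_deterministic_given_seed(self):
        f = self._converged_fit()
        a = prediction_band(f, T_DAILY, n_draws=300, seed=42)
        b = prediction_band(f, T_DAILY, n_draws=300, seed=42)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_monte_carlo_stability(self):
        """A large-draw band contains most of a small-draw band's span."""
        f = self._converged_fit()
        lo_s, up_s = prediction_band(f, T_DAILY, n_draws=10, seed=3)
        lo_l, up_l = prediction_band(f, T_DAILY, n_draws=10_000, seed=4)
        overlap = np.minimum(up_s, up_l) - np.maximum(lo_s, lo_l)
        contained = overlap / (up_s - lo_s)
        assert contained.mean() >= 0.9

    def test_requires_convergence(self):
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        bad = fit("richards", t, 10.0 + 2.0 * t)
        with pytest.raises(ValueError):
            prediction_band(bad, T_DAILY)

    def test_non_psd_covariance_repaired_with_warning(self):
        f = self._converged_fit()
        f.covariance = np.array([[1.0, 2.0, 0.0], [2.0, 1.0, 0.0], [0.0, 0.0, 1.0]])  # indefinite
        with pytest.warns(UserWarning, match="PSD"):
            prediction_band(f, T_DAILY, n_draws=50, seed=0)


class TestInflection:
    def test_logistic3_exact(self):
        y = evaluate("logistic3", {"Asym": 3000.0, "tmid": 35.9, "k": 5.0}, T_DAILY)
        f = fit("logistic3", T_DAILY, y)
        assert inflection_time(f) == pytest.approx(35.9, rel=1e-6)

    def test_gompertz_matches_grid_argmax(self):
        p = {"Asym": 3000.0, "b2": 8.0, "b3": 0.88}
        t = np.arange(2.0, 50.0)
        f = fit("gompertz", t, evaluate("gompertz", p, t))
        found = inflection_time(f)
        grid = np.linspace(2.0, 50.0, 2_000_001)
        oracle = grid[np.argmax(agr("gompertz", f.params, grid))]
        assert found == pytest.approx(oracle, abs=0.01)

    def test_non_sigmoidal_raises(self):
        t = np.arange(0.0, 10.0)
        f = fit("exponential", t, evaluate("exponential", {"M0": 10.0, "r": 0.2}, t))
        with pytest.raises(ValueError):
            inflection_time(f)


class TestSelectModel:
    def test_true_model_wins_on_sigmoidal_groups(self):
        groups = {}
        for gi, (name, par) in enumerate(synthetic.WATERING_TRIAL_GROUPS.items()):
            series = synthetic.generate_growth_series(
                synthetic.TrajectorySpec("logistic3", par, tuple(range(18, 48)), 0.05, 14, seed=gi)
            )
            groups[name] = (np.concatenate([s.times for s in series]), np.concatenate([s.values for s in series]))
        sel = select_model(groups, ["logistic3", "gompertz", "exponential", "power_law"], seed=0)
        assert sel.best in ("logistic3", "gompertz")
        assert sel.table.iloc[-1]["mean_aic"] >= sel.table.iloc[0]["mean_aic"] or not sel.table.iloc[-1]["converged_on_all"]

    def test_disqualified_candidate_excluded_from_ranking(self, watering_cohort):
        """The robustness screen: fail on any group and you are out."""
        t, y = watering_cohort
        one_plant = synthetic.generate_growth_series(synthetic.TrajectorySpec(seed=8))[0]
        short = (one_plant.times[::4], one_plant.values[::4])  # 8 sparse points
        sel = select_model({"full": (t, y), "short": short}, ["logistic3", "gompertz", "weibull"], seed=0)
        assert "weibull" in sel.disqualified
        row = sel.table[sel.table.model == "weibull"].iloc[0]
        assert not row.converged_on_all and np.isnan(row["rank"])
        ranked = sel.table[sel.table.converged_on_all]
        assert set(ranked.model) == {"logistic3", "gompertz"}

    def test_all_disqualified_raises_with_diagnostics(self):
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        with pytest.raises(ValueError, match="disqualified"):
            select_model({"g": (t, 10.0 + 2.0 * t)}, ["richards"], seed=0)

    def test_parsimony_tie_break(self, watering_cohort):
        """Among near-tied candidates the one with fewer parameters ranks first."""
        t, y = watering_cohort
        sel = select_model({"g": (t, y)}, ["logistic3", "logistic4"], seed=0)
        f3 = sel.fits[("logistic3", "g")]
        f4 = sel.fits[("logistic4", "g")]
        if abs(f3.aic - f4.aic) < 2.0:
            assert sel.best == "logistic3"
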