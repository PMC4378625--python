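"""Derived growth and physiology statistics.

Classical relative growth rate from paired harvests,
R = (ln W2 - ln W1) / (t2 - t1)   [g g^-1 d^-1],
its image-based per-plant variants, diurnal leaf-rolling quantification
(pre-dawn vs late-afternoon projected area with a paired t-test),
gravimetric water-use efficiency, and the validation regressions that
benchmark projected traits against conventionally measured ones.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "HarvestRecord",
    "DiurnalRecord",
    "RollingResult",
    "RegressionResult",
    "NirRegression",
    "rgr_biomass",
    "rgr_variants",
    "leaf_rolling",
    "wue",
    "validate_projection",
    "nir_regression",
]


@dataclass(frozen=True)
class HarvestRecord:
    """Destructive-harvest record for one plant (masses in g, times in days)."""

    plant_id: str
    W1: float
    W2: float
    t1: float
    t2: float
    leaf_area: float = float("nan")  # cm^2
    leaf_mass: float = float("nan")  # g
    water_used: float = float("nan")  # kg

    def __post_init__(self):
        if self.W1 <= 0 or self.W2 <= 0:
            raise ValueError("harvest masses must be positive")
        if self.t2 <= self.t1:
            raise ValueError("harvest interval requires t2 > t1")


@dataclass(frozen=True)
class DiurnalRecord:
    """Afternoon (rolled) vs pre-dawn (unfolded) projected leaf area, mm^2."""

    plant_id: str
    la_afternoon: float
    la_predawn: float

    def __post_init__(self):
        if self.la_afternoon <= 0 or self.la_predawn <= 0:
            raise ValueError("leaf areas must be positive")

    @property
    def pct_increase(self) -> float:
        return 100.0 * (self.la_predawn - self.la_afternoon) / self.la_afternoon


def rgr_biomass(rec) -> float:
    """Classical RGR from initial/final biomass: (ln W2 - ln W1)/(t2 - t1).

    Positive iff the plant grew (W2 > W1).  Accepts a HarvestRecord or a
    (W1, W2, t1, t2) tuple.
    """
    if not isinstance(rec, HarvestRecord):
        W1, W2, t1, t2 = rec
        rec = HarvestRecord("anon", W1, W2, t1, t2)
    return (math.log(rec.W2) - math.log(rec.W1)) / (rec.t2 - rec.t1)


def _as_series_map(series_by_plant) -> dict:
    if isinstance(series_by_plant, dict):
        return {k: (np.asarray(t, float), np.asarray(v, float)) for k, (t, v) in series_by_plant.items()}
    out = {}
    for s in series_by_plant:  # GrowthSeries-like
        out[s.plant_id] = (np.asarray(s.times, float), np.asarray(s.values, float))
    return out


def rgr_variants(series_by_plant, group_initial: float = None):
    """Image-based RGR variants per plant.

    * ``rgr_leaf_area``: (ln LA_final,i - ln mean(LA_initial)) / dt —
      imitates destructive harvesting, where the initial size is
      necessarily a group average;
    * ``rgr_individual``: (ln LA_final,i - ln LA_initial,i) / dt — uses
      each plant's own initial area, possible only with repeated imaging.

    Returns a DataFrame indexed by plant id.  Plants lacking both
    endpoints are skipped with a warning.
    """
    import pandas as pd

    series = _as_series_map(series_by_plant)
    firsts, rows, skipped = {}, [], []
    for pid, (t, v) in series.items():
        if t.size < 2 or not (np.isfinite(v[0]) and np.isfinite(v[-1])) or v[0] <= 0 or v[-1] <= 0:
            skipped.append(pid)
            continue
        firsts[pid] = (t[0], v[0], t[-1], v[-1])
    if skipped:
        warnings.warn(f"skipped plants without usable endpoints: {skipped}", stacklevel=2)
    if not firsts:
        raise ValueError("no plant has both endpoint observations")
    if group_initial is None:
        group_initial = float(np.mean([v0 for (_, v0, _, _) in firsts.values()]))
    for pid, (t0, v0, t1, v1) in firsts.items():
        dt = t1 - t0
        rows.append(
            dict(
                plant_id=pid,
                rgr_leaf_area=(math.log(v1) - math.log(group_initial)) / dt,
                rgr_individual=(math.log(v1) - math.log(v0)) / dt,
            )
        )
    return pd.DataFrame(rows).set_index("plant_id")


@dataclass
class RollingResult:
    """Diurnal leaf-rolling summary: mean per-plant % LA increase +/- SE."""

    mean_pct_increase: float
    se: float
    p_value: float
    n: int


def _pairs_to_arrays(pairs):
    if hasattr(pairs, "columns"):  # DataFrame
        aft = np.asarray(pairs["la_afternoon"], dtype=float)
        pre = np.asarray(pairs["la_predawn"], dtype=float)
    else:
        recs = [p if isinstance(p, DiurnalRecord) else DiurnalRecord(f"p{i}", *p) for i, p in enumerate(pairs)]
        aft = np.array([r.la_afternoon for r in recs])
        pre = np.array([r.la_predawn for r in recs])
    if (aft <= 0).any() or (pre <= 0).any():
        raise ValueError("leaf areas must be positive")
    return aft, pre


def leaf_rolling(pairs) -> RollingResult:
    """Quantify diurnal leaf rolling from afternoon/pre-dawn area pairs.

    Per plant, pct = 100 (predawn - afternoon)/afternoon; the statistic is
    the mean of per-plant percentages (so it is invariant to area units),
    with its standard error and a two-sided paired t-test on the raw area
    differences.  With fewer than 2 pairs only the point estimate is
    reported; identical pairs (no rolling) give p = 1.
    """
    aft, pre = _pairs_to_arrays(pairs)
    pct = 100.0 * (pre - aft) / aft
    n = pct.size
    mean = float(pct.mean())
    if n < 2:
        return RollingResult(mean, float("nan"), float("nan"), n)
    se = float(pct.std(ddof=1) / math.sqrt(n))
    diffs = pre - aft
    if np.allclose(diffs, 0.0):
        return RollingResult(mean, se, 1.0, n)
    t_res = stats.ttest_rel(pre, aft)
    return RollingResult(mean, se, float(t_res.pvalue), n)


def wue(final_biomass_g: float, water_log, include_evaporation: bool = True) -> float:
    """Water-use efficiency: above-ground biomass per mass of water, g kg^-1.

    ``water_log`` is either a total water mass in grams or a watering-log
    DataFrame (kind in {planted, control}).  The default denominator is
    everything added to the planted pot — evaporation plus transpiration;
    ``include_evaporation=False`` subtracts the mean cumulative loss of
    the empty control pots instead.
    """
    if np.isscalar(water_log):
        total_g = float(water_log)
    else:
        planted = water_log[water_log["kind"] == "planted"]
        total_g = float(planted["water_added_g"].sum())
        if not include_evaporation:
            ctrl = water_log[water_log["kind"] == "control"]
            if len(ctrl):
                per_pot = ctrl.groupby("pot_id")["water_added_g"].sum()
                total_g -= float(per_pot.mean())
    if total_g <= 0:
        raise ValueError("cumulative water use must be positive")
    return final_biomass_g / (total_g / 1000.0)


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r2: float
    p_value: float
    n: int


def validate_projection(projected, measured) -> RegressionResult:
    """OLS of conventionally measured trait on its image-projected counterpart.

    The benchmark of imaging accuracy: a slope near 1 and high R^2 mean
    the projected trait tracks the real one.
    """
    import statsmodels.api as sm

    x = np.asarray(projected, dtype=float)
    y = np.asarray(measured, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("projected values have zero variance")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r2=float(model.rsquared),
        p_value=float(model.pvalues[1]),
        n=int(x.size),
    )


@dataclass
class NirRegression:
    """NIR ~ LMA + moisture multiple regression."""

    intercept: float
    lma_coef: float
    moisture_coef: float
    r2: float
    p_value: float
    collinear: bool
    dropped: tuple = ()


def nir_regression(nir_grey, lma, moisture_pct) -> NirRegression:
    """Two-predictor OLS: NIR grey ~ LMA (g m^-2) + moisture (%).

    NIR reflectance rises with leaf thickness (LMA) and falls with water
    content, so the expected signs are + and -.  Zero-variance predictors
    are dropped (their coefficient reported NaN); a near-collinear design
    is flagged.
    """
    import statsmodels.api as sm

    y = np.asarray(nir_grey, dtype=float)
    preds = {"lma": np.asarray(lma, dtype=float), "moisture": np.asarray(moisture_pct, dtype=float)}
    n = y.size
    if n < 4 or any(p.size != n for p in preds.values()):
        raise ValueError("need >= 4 complete observations")
    dropped = tuple(name for name, p in preds.items() if np.ptp(p) == 0)
    kept = [name for name in preds if name not in dropped]
    if not kept:
        raise ValueError("both predictors are constant")
    X = np.column_stack([preds[name] for name in kept])
    model = sm.OLS(y, sm.add_constant(X)).fit()
    coef = {name: float(model.params[i + 1]) for i, name in enumerate(kept)}
    collinear = bool(np.linalg.cond(np.column_stack([np.ones(n), X])) > 1e8) or bool(dropped)
    if collinear:
        warnings.warn("collinear or degenerate predictor design in NIR regression", stacklevel=2)
    return NirRegression(
        intercept=float(model.params[0]),
        lma_coef=coef.get("lma", float("nan")),
        moisture_coef=coef.get("moisture", float("nan")),
        r2=float(model.rsquared),
        p_value=float(model.f_pvalue),
        collinear=collinear,
        dropped=dropped,
    )
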