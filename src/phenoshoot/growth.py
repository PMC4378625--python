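"""Growth-curve models, nonlinear fitting, model selection and rate derivation.

Eight candidate models of shoot size M(t) (t in days after sowing):

================  =========================  ==================================
name              parameters                 form
================  =========================  ==================================
exponential       M0, r                      M0 * exp(r t)
power_law         M0, r, beta                (M0^(1-b) + r t (1-b))^(1/(1-b))
logistic3         Asym, tmid, k              Asym / (1 + exp((tmid - t)/k))
logistic4         A, Asym, tmid, k           A + (Asym - A)/(1 + exp((tmid-t)/k))
gompertz          Asym, b2, b3               Asym * exp(-b2 * b3^t)
weibull           Asym, Drop, lrc, pwr       Asym - Drop * exp(-exp(lrc) t^pwr)
richards          Asym, tmid, k, nu          Asym (1 + nu e^((tmid-t)/k))^(-1/nu)
beta              Mmax, te, tm               Yin beta growth function
================  =========================  ==================================

The power law generalises the exponential: beta tunes how relative growth
rate declines with size (beta -> 1 recovers exponential growth); the
logistic, Gompertz, Weibull, Richards and beta functions are asymptotic
(sigmoidal) alternatives.  Fitting is Gaussian nonlinear least squares
(bounded trust region) from heuristic self-start values.  Non-convergence
is a recorded state, never an exception: the model-selection rule
disqualifies any candidate that fails to converge on any group (the
robustness screen), ranks survivors by mean AIC, and breaks near-ties
(dAIC < 2) by parsimony and then by narrower population prediction bands.

Absolute growth rate AGR = dM/dt and relative growth rate RGR = AGR/M are
derived analytically where closed forms are simple (exponential, power
law, 3-parameter logistic) and by central differences otherwise.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

logger = logging.getLogger(__name__)

__all__ = [
    "MODELS",
    "ModelFit",
    "GrowthCurves",
    "SelectionResult",
    "validate_params",
    "evaluate",
    "agr",
    "rgr",
    "self_start",
    "fit",
    "select_model",
    "prediction_band",
    "inflection_time",
    "growth_curves",
]

_BIG = 1e30
_TINY = 1e-12


# --- model definitions --------------------------------------------------------


def _f_exponential(p, t):
    M0, r = p
    return M0 * np.exp(np.clip(r * t, -700, 700))


def _f_power_law(p, t, strict=False):
    M0, r, beta = p
    if strict and abs(beta - 1.0) < 1e-12:
        raise ValueError("power law undefined at beta = 1 (use the exponential model)")
    om = 1.0 - beta
    base = M0**om + r * t * om
    if strict:
        bad = np.atleast_1d(base) <= 0
        if bad.any():
            t_bad = np.atleast_1d(t)[bad][0]
            raise ValueError(f"power-law domain violation: non-positive base at t = {t_bad}")
    base = np.maximum(base, _TINY)
    with np.errstate(over="ignore"):
        return np.minimum(base ** (1.0 / om), _BIG)


def _f_logistic3(p, t):
    Asym, tmid, k = p
    return Asym / (1.0 + np.exp(np.clip((tmid - t) / k, -700, 700)))


def _f_logistic4(p, t):
    A, Asym, tmid, k = p
    return A + (Asym - A) / (1.0 + np.exp(np.clip((tmid - t) / k, -700, 700)))


def _f_gompertz(p, t):
    Asym, b2, b3 = p
    with np.errstate(over="ignore"):
        return Asym * np.exp(-b2 * np.minimum(b3**t, _BIG))


def _f_weibull(p, t, strict=False):
    Asym, Drop, lrc, pwr = p
    tt = np.asarray(t, dtype=float)
    if strict and (np.atleast_1d(tt) < 0).any():
        t_bad = np.atleast_1d(tt)[np.atleast_1d(tt) < 0][0]
        raise ValueError(f"weibull domain violation: negative time t = {t_bad}")
    tt = np.maximum(tt, 0.0)
    with np.errstate(over="ignore"):
        return Asym - Drop * np.exp(-np.exp(np.clip(lrc, -700, 700)) * tt**pwr)


def _f_richards(p, t):
    Asym, tmid, k, nu = p
    z = np.exp(np.clip((tmid - t) / k, -700, 700))
    with np.errstate(over="ignore"):
        return Asym * (1.0 + nu * z) ** (-1.0 / nu)


def _f_beta(p, t, strict=False):
    Mmax, te, tm = p
    if strict and not (0 < tm < te):
        raise ValueError("beta growth function requires 0 < tm < te")
    if tm >= te:  # lenient mode: push the optimizer away
        return np.full_like(np.asarray(t, dtype=float), _BIG)
    tt = np.clip(np.asarray(t, dtype=float), 0.0, te)
    with np.errstate(invalid="ignore"):
        out = Mmax * (1.0 + (te - tt) / (te - tm)) * (tt / te) ** (te / (te - tm))
    out = np.where(np.asarray(t, dtype=float) >= te, Mmax, out)
    return np.where(np.asarray(t, dtype=float) <= 0, 0.0, out)


def _agr_exponential(p, t, M):
    return p[1] * M


def _agr_power_law(p, t, M):
    _, r, beta = p
    return r * M**beta


def _agr_logistic3(p, t, M):
    Asym, _, k = p
    return (M / k) * (1.0 - M / Asym)


@dataclass(frozen=True)
class ModelDef:
    name: str
    param_names: tuple
    fn: callable
    lower: tuple
    upper: tuple
    sigmoidal: bool
    agr_fn: callable = None
    strict_fn: callable = None
    # bounds that are reparameterization limits (another model family):
    # an estimate pinned there means the optimizer diverged, not converged
    limit_bounds: tuple = ()

    @property
    def n_params(self) -> int:
        return len(self.param_names)


_INF = np.inf

MODELS = {
    "exponential": ModelDef(
        "exponential", ("M0", "r"), _f_exponential, (_TINY, -10.0), (_INF, 10.0), False, _agr_exponential
    ),
    "power_law": ModelDef(
        "power_law",
        ("M0", "r", "beta"),
        _f_power_law,
        (_TINY, 0.0, -5.0),
        (_INF, _INF, 0.999),
        False,
        _agr_power_law,
        strict_fn=lambda p, t: _f_power_law(p, t, strict=True),
        limit_bounds=((2, "upper"),),  # beta -> 1 is the exponential limit
    ),
    "logistic3": ModelDef(
        "logistic3", ("Asym", "tmid", "k"), _f_logistic3, (_TINY, -_INF, _TINY), (_INF, _INF, _INF), True, _agr_logistic3
    ),
    "logistic4": ModelDef(
        "logistic4", ("A", "Asym", "tmid", "k"), _f_logistic4, (-_INF, _TINY, -_INF, _TINY), (_INF, _INF, _INF, _INF), True
    ),
    "gompertz": ModelDef(
        "gompertz", ("Asym", "b2", "b3"), _f_gompertz, (_TINY, _TINY, 1e-8), (_INF, _INF, 0.999999), True,
        limit_bounds=((2, "upper"),),  # b3 -> 1 degenerates to a flat curve
    ),
    "weibull": ModelDef(
        "weibull",
        ("Asym", "Drop", "lrc", "pwr"),
        _f_weibull,
        (_TINY, _TINY, -_INF, 1e-8),
        (_INF, _INF, _INF, 10.0),
        True,
        strict_fn=lambda p, t: _f_weibull(p, t, strict=True),
    ),
    "richards": ModelDef(
        "richards", ("Asym", "tmid", "k", "nu"), _f_richards, (_TINY, -_INF, _TINY, 1e-3), (_INF, _INF, _INF, 20.0), True,
        limit_bounds=((3, "lower"), (3, "upper")),  # nu -> 0 is the Gompertz limit
    ),
    "beta": ModelDef(
        "beta",
        ("Mmax", "te", "tm"),
        _f_beta,
        (_TINY, _TINY, _TINY),
        (_INF, _INF, _INF),
        True,
        strict_fn=lambda p, t: _f_beta(p, t, strict=True),
    ),
}

MODEL_NAMES = tuple(MODELS)


def get_model(name: str) -> ModelDef:
    try:
        return MODELS[name]
    except KeyError:
        raise ValueError(f"unknown growth model {name!r}; choose from {sorted(MODELS)}") from None


def _param_array(md: ModelDef, params) -> np.ndarray:
    if isinstance(params, dict):
        missing = set(md.param_names) - set(params)
        if missing:
            raise ValueError(f"{md.name}: missing parameters {sorted(missing)}")
        return np.array([float(params[n]) for n in md.param_names])
    arr = np.asarray(params, dtype=float)
    if arr.shape != (md.n_params,):
        raise ValueError(f"{md.name} expects {md.n_params} parameters {md.param_names}")
    return arr


def validate_params(model_name: str, params) -> np.ndarray:
    """Check a parameter set against the model's domain; return the array."""
    md = get_model(model_name)
    p = _param_array(md, params)
    for v, name, lo, hi in zip(p, md.param_names, md.lower, md.upper):
        if not (lo <= v <= hi):
            raise ValueError(f"{md.name}: parameter {name}={v} outside domain [{lo}, {hi}]")
    if md.name == "power_law" and abs(p[2] - 1.0) < 1e-12:
        raise ValueError("power law requires beta != 1")
    if md.name == "beta" and not (0 < p[2] < p[1]):
        raise ValueError("beta growth function requires 0 < tm < te")
    return p


def evaluate(model_name: str, params, t, strict: bool = True):
    """Evaluate M(t).  ``strict`` enforces the model domain (raising with
    the offending t); the lenient mode clips, which the optimizer relies on."""
    md = get_model(model_name)
    p = _param_array(md, params)
    t = np.asarray(t, dtype=float)
    fn = md.strict_fn if (strict and md.strict_fn is not None) else md.fn
    out = fn(p, t)
    return float(out) if np.isscalar(t) or t.ndim == 0 else out


def _tscale(t) -> float:
    t = np.atleast_1d(np.asarray(t, dtype=float))
    span = float(t.max() - t.min()) if t.size > 1 else 0.0
    return max(span, float(np.abs(t).max()), 1.0)


def agr(model_name: str, params, t):
    """Absolute growth rate dM/dt (size units per day).

    Analytic for exponential (r M), power law (r M^beta) and logistic3
    (M/k (1 - M/Asym)); central differences with h = 1e-4 * time-scale for
    the remaining models.  Raises if M <= 0 anywhere requested.
    """
    md = get_model(model_name)
    p = _param_array(md, params)
    t_arr = np.asarray(t, dtype=float)
    M = md.fn(p, t_arr)
    if (np.atleast_1d(M) <= 0).any():
        raise ValueError(f"{model_name}: M <= 0 in the requested range; growth rates undefined")
    if md.agr_fn is not None:
        out = md.agr_fn(p, t_arr, M)
    else:
        h = 1e-4 * _tscale(t_arr)
        out = (md.fn(p, t_arr + h) - md.fn(p, t_arr - h)) / (2.0 * h)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def rgr(model_name: str, params, t):
    """Relative growth rate (1/M) dM/dt (per day); AGR/M pointwise."""
    md = get_model(model_name)
    p = _param_array(md, params)
    t_arr = np.asarray(t, dtype=float)
    M = md.fn(p, t_arr)
    if (np.atleast_1d(M) <= 0).any():
        raise ValueError(f"{model_name}: M <= 0 in the requested range; growth rates undefined")
    out = np.asarray(agr(model_name, p, t_arr)) / M
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


# --- self-start heuristics ----------------------------------------------------


def _series_checks(md: ModelDef, t: np.ndarray, y: np.ndarray):
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("series must be matching 1-D time and value arrays")
    if t.size < md.n_params + 1:
        raise ValueError(f"{md.name}: need at least {md.n_params + 1} observations, got {t.size}")
    if np.any(np.diff(t) < 0):
        order = np.argsort(t)
        t, y = t[order], y[order]
    scale = max(abs(float(y.max())), _TINY)
    if np.ptp(y) <= 1e-12 * scale:
        warnings.warn("constant series: degenerate self-start", stacklevel=3)
        return t, y, True
    # growth models assume a nondecreasing trend
    if np.all(np.diff(y) <= 0) and y[-1] < y[0]:
        raise ValueError("monotone-decreasing series: growth models assume a nondecreasing trend")
    return t, y, False


def _half_crossing(t, y, half):
    above = y >= half
    if above.all():
        return float(t[0])
    if not above.any():
        return float(t[-1])
    i = int(np.argmax(above))
    if i == 0:
        return float(t[0])
    t0, t1, y0, y1 = t[i - 1], t[i], y[i - 1], y[i]
    if y1 == y0:
        return float(t1)
    return float(t0 + (half - y0) * (t1 - t0) / (y1 - y0))


def _ss_logistic3(t, y, degenerate):
    Asym = 1.05 * float(y.max())
    if degenerate:
        return np.array([Asym, float(t.mean()), max(1.0, 0.25 * np.ptp(t))])
    tmid = _half_crossing(t, y, Asym / 2.0)
    yy = np.clip(y, 1e-9 * Asym, 0.999 * Asym)
    z = np.log(yy / (Asym - yy))
    slope = np.polyfit(t, z, 1)[0]
    k = 1.0 / slope if slope > 0 else max(1.0, 0.25 * np.ptp(t))
    return np.array([Asym, tmid, k])


def _ss_exponential(t, y, degenerate):
    yy = np.maximum(y, _TINY)
    slope, icpt = np.polyfit(t, np.log(yy), 1)
    return np.array([float(np.exp(icpt)), float(slope) if not degenerate else 0.0])


def _ss_power_law(t, y, degenerate):
    M0 = max(float(y[0]), _TINY)
    if degenerate:
        return np.array([M0, _TINY, 0.5])
    yy = np.maximum(y, _TINY)
    dln = np.diff(np.log(yy))
    dt = np.diff(t)
    mid_t = 0.5 * (t[:-1] + t[1:])
    local_rgr = dln / dt
    ln_m = np.interp(mid_t, t, np.log(yy))
    ok = local_rgr > 0
    if ok.sum() >= 2:
        # RGR = r M^(beta-1)  =>  ln RGR linear in ln M
        slope, icpt = np.polyfit(ln_m[ok], np.log(local_rgr[ok]), 1)
        beta = float(np.clip(1.0 + slope, -5.0, 0.99))
        r = float(np.exp(icpt))
    else:
        beta = 0.9
        om = 1.0 - beta
        r = max((yy[-1] ** om - M0**om) / (max(t[-1], _TINY) * om), _TINY)
    return np.array([M0, max(r, _TINY), beta])


def _ss_gompertz(t, y, degenerate):
    Asym = 1.05 * float(y.max())
    if degenerate:
        return np.array([Asym, 1.0, 0.9])
    yy = np.clip(y, 1e-9 * Asym, 0.999 * Asym)
    u = np.log(-np.log(yy / Asym))
    slope, icpt = np.polyfit(t, u, 1)
    b3 = float(np.clip(np.exp(slope), 1e-6, 0.999999))
    b2 = float(np.clip(np.exp(icpt), _TINY, 1e12))
    return np.array([Asym, b2, b3])


def _ss_logistic4(t, y, degenerate):
    rng_y = np.ptp(y)
    A = float(y.min()) - 0.05 * rng_y
    Asym = float(y.max()) + 0.05 * rng_y
    if degenerate:
        return np.array([A, Asym, float(t.mean()), max(1.0, 0.25 * np.ptp(t))])
    yy = np.clip((y - A) / (Asym - A), 1e-9, 1 - 1e-9)
    tmid = _half_crossing(t, yy, 0.5)
    z = np.log(yy / (1 - yy))
    slope = np.polyfit(t, z, 1)[0]
    k = 1.0 / slope if slope > 0 else max(1.0, 0.25 * np.ptp(t))
    return np.array([A, Asym, tmid, k])


def _ss_weibull(t, y, degenerate):
    Asym = 1.05 * float(y.max())
    Drop = max(Asym - float(y.min()), _TINY)
    pos = t > 0
    if degenerate or pos.sum() < 2:
        return np.array([Asym, Drop, -3.0, 1.0])
    v = np.clip((Asym - y[pos]) / Drop, 1e-9, 1 - 1e-9)
    u = np.log(-np.log(v))
    slope, icpt = np.polyfit(np.log(t[pos]), u, 1)
    return np.array([Asym, Drop, float(icpt), float(np.clip(slope, 0.1, 10.0))])


def _ss_richards(t, y, degenerate):
    ss = _ss_logistic3(t, y, degenerate)
    return np.append(ss, 1.0)


def _ss_beta(t, y, degenerate):
    Mmax = 1.05 * float(y.max())
    if degenerate:
        return np.array([Mmax, float(t.max()) * 1.1 + 1.0, float(t.mean()) + 0.5])
    near_max = t[y >= 0.99 * y.max()]
    te = float(near_max[0]) if near_max.size else 1.1 * float(t.max())
    te = max(te, float(t.min()) + _TINY)
    dy = np.diff(y) / np.diff(t)
    tm = float(0.5 * (t[:-1] + t[1:])[int(np.argmax(dy))])
    tm = float(np.clip(tm, 0.05 * te, 0.95 * te))
    return np.array([Mmax, te, tm])


_SELF_START = {
    "exponential": _ss_exponential,
    "power_law": _ss_power_law,
    "logistic3": _ss_logistic3,
    "logistic4": _ss_logistic4,
    "gompertz": _ss_gompertz,
    "weibull": _ss_weibull,
    "richards": _ss_richards,
    "beta": _ss_beta,
}


def self_start(model_name: str, times, values) -> np.ndarray:
    """Heuristic initial parameter values for the optimizer.

    Raises on series that are too short for the model or monotonically
    decreasing (these are growth models); warns and returns a degenerate
    initialisation for constant series.
    """
    md = get_model(model_name)
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    t, y, degenerate = _series_checks(md, t, y)
    # heuristics work on per-timepoint means: pooled cohorts replicate times
    ut, inv = np.unique(t, return_inverse=True)
    if ut.size < t.size:
        if ut.size < md.n_params + 1:
            raise ValueError(f"{md.name}: need at least {md.n_params + 1} distinct timepoints, got {ut.size}")
        ym = np.bincount(inv, weights=y) / np.bincount(inv)
        t, y = ut, ym
    p0 = _SELF_START[model_name](t, y, degenerate)
    return np.clip(p0, md.lower, md.upper)


# --- fitting ------------------------------------------------------------------


@dataclass
class ModelFit:
    """Result of a Gaussian nonlinear least-squares fit.

    ``converged`` is False (never an exception) when the optimizer fails
    or the Wald covariance is not estimable; AIC is finite iff converged.
    """

    model_name: str
    estimates: dict
    covariance: np.ndarray
    rss: float
    sigma2: float
    aic: float
    r2: float
    converged: bool
    n_obs: int
    message: str = ""
    t_range: tuple = (0.0, 1.0)
    params: np.ndarray = field(default=None, repr=False)

    @property
    def n_params(self) -> int:
        return len(get_model(self.model_name).param_names)

    def stderr(self) -> dict:
        md = get_model(self.model_name)
        if self.covariance is None:
            return {n: float("nan") for n in md.param_names}
        se = np.sqrt(np.maximum(np.diag(self.covariance), 0.0))
        return dict(zip(md.param_names, se.tolist()))

    def predict(self, t):
        return evaluate(self.model_name, self.params, t, strict=False)


def _failed_fit(md: ModelDef, n: int, t_range, msg: str) -> ModelFit:
    logger.info("fit(%s) did not converge: %s", md.name, msg)
    return ModelFit(
        model_name=md.name,
        estimates={k: float("nan") for k in md.param_names},
        covariance=None,
        rss=float("nan"),
        sigma2=float("nan"),
        aic=float("inf"),
        r2=float("nan"),
        converged=False,
        n_obs=n,
        message=msg,
        t_range=t_range,
        params=np.full(md.n_params, np.nan),
    )


_MAX_ITER = 400
_COND_LIMIT = 1e10


def fit(model_name: str, times, values, weights=None, variance: str = "constant") -> ModelFit:
    """Fit one growth model to a series by bounded trust-region least squares.

    AIC = n ln(RSS/n) + 2(p+1) (Gaussian homoscedastic likelihood, the +1
    counting the residual variance); R^2 = 1 - RSS/TSS.  ``weights``
    multiply residuals during optimisation; ``variance="power"`` instead
    derives them as 1/fitted (sd proportional to the mean, the right
    variance model for multiplicative noise) by one reweighting pass from
    the unweighted solution.  RSS/R^2/AIC are always reported on the
    unweighted scale.  Data problems (too few points, decreasing trend)
    raise as in :func:`self_start`; optimizer failure is recorded, not
    raised.
    """
    if variance not in ("constant", "power"):
        raise ValueError("variance must be 'constant' or 'power'")
    md = get_model(model_name)
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    order = np.argsort(t)
    t, y = t[order], y[order]
    t_range = (float(t.min()), float(t.max()))
    if variance == "power" and weights is None:
        pilot = fit(model_name, t, y)
        if not pilot.converged:
            return pilot
        fitted = np.maximum(md.fn(pilot.params, t), _TINY)
        w = 1.0 / fitted
        w /= w.mean()  # scale-free; sigma2 absorbs the level
    else:
        w = None
        if weights is not None:
            w = np.asarray(weights, dtype=float)[order]
            if w.shape != y.shape or (w <= 0).any():
                raise ValueError("weights must be positive and match the series length")
    p0 = self_start(model_name, t, y)

    def resid(p):
        r = md.fn(p, t) - y
        return r * w if w is not None else r

    lo = np.array(md.lower)
    hi = np.array(md.upper)
    p0 = np.clip(p0, lo + np.where(np.isfinite(lo), 1e-10, 0), hi - np.where(np.isfinite(hi), 1e-10, 0))
    try:
        res = optimize.least_squares(
            resid,
            p0,
            bounds=(lo, hi),
            method="trf",
            ftol=1e-10,
            xtol=1e-10,
            gtol=1e-10,
            max_nfev=_MAX_ITER * md.n_params,
            x_scale="jac",
        )
    except Exception as exc:  # noqa: BLE001 - non-convergence is a state
        return _failed_fit(md, t.size, t_range, f"optimizer error: {exc}")

    if not res.success or not np.isfinite(res.cost):
        return _failed_fit(md, t.size, t_range, res.message)

    p = res.x
    for idx, which in md.limit_bounds:
        bound = md.lower[idx] if which == "lower" else md.upper[idx]
        tol = 1e-3 * max(1e-3, abs(bound))
        if abs(p[idx] - bound) <= tol:
            return _failed_fit(
                md, t.size, t_range,
                f"parameter {md.param_names[idx]} pinned at its domain boundary ({bound})",
            )
    n = t.size
    fitted = md.fn(p, t)
    rss = float(np.sum((fitted - y) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else float("nan")
    dof = max(n - md.n_params, 1)
    fres = res.fun
    sigma2 = float(np.sum(fres**2)) / dof
    jtj = res.jac.T @ res.jac
    d = np.sqrt(np.maximum(np.diag(jtj), _TINY))
    corr = jtj / np.outer(d, d)
    if not np.all(np.isfinite(corr)) or np.linalg.cond(corr) > _COND_LIMIT:
        return _failed_fit(md, n, t_range, "parameter covariance not estimable (ill-conditioned fit)")
    cov = sigma2 * np.linalg.pinv(jtj)
    cov = 0.5 * (cov + cov.T)
    aic = n * np.log(max(rss, _TINY) / n) + 2.0 * (md.n_params + 1)
    return ModelFit(
        model_name=md.name,
        estimates=dict(zip(md.param_names, p.tolist())),
        covariance=cov,
        rss=rss,
        sigma2=sigma2,
        aic=float(aic),
        r2=r2,
        converged=True,
        n_obs=n,
        message=res.message,
        t_range=t_range,
        params=p,
    )


# --- prediction bands ---------------------------------------------------------


def _nearest_psd(cov: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(cov)
    if vals.min() < -1e-8 * max(vals.max(), _TINY):
        warnings.warn("covariance not positive semidefinite; nearest-PSD repair applied", stacklevel=3)
    vals = np.clip(vals, 0.0, None)
    return (vecs * vals) @ vecs.T


def prediction_band(fitres: ModelFit, times, n_draws: int = 1000, level: float = 0.95, seed: int = 20110301):
    """Population prediction interval for the fitted mean curve.

    Draws ``n_draws`` parameter vectors from N(estimates, covariance),
    evaluates the curve for each and takes pointwise quantiles at
    (1-level)/2 and 1-(1-level)/2.  Deterministic given ``seed``.  Draws
    are projected into the model's parameter domain before evaluation.
    Returns (lower, upper) arrays.
    """
    if not fitres.converged or fitres.covariance is None:
        raise ValueError("prediction band requires a converged fit")
    md = get_model(fitres.model_name)
    t = np.asarray(times, dtype=float)
    cov = _nearest_psd(np.asarray(fitres.covariance, dtype=float))
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(fitres.params, cov, size=int(n_draws), method="svd")
    lo = np.where(np.isfinite(md.lower), np.array(md.lower) + 1e-12, -np.inf)
    hi = np.where(np.isfinite(md.upper), np.array(md.upper) - 1e-12, np.inf)
    draws = np.clip(draws, lo, hi)
    curves = np.stack([md.fn(d, t) for d in draws])
    alpha = (1.0 - level) / 2.0
    lower = np.quantile(curves, alpha, axis=0)
    upper = np.quantile(curves, 1.0 - alpha, axis=0)
    return lower, upper


# --- model selection ----------------------------------------------------------


@dataclass
class SelectionResult:
    """Ranked model-selection report across groups."""

    table: "object"  # pandas DataFrame
    best: str
    fits: dict  # (model, group) -> ModelFit
    disqualified: dict  # model -> list of groups where it failed

    def __repr__(self):
        return f"SelectionResult(best={self.best!r}, ranked={list(self.table['model'])})"


def _band_width_score(model, fits_by_group, seed):
    widths = []
    for group, f in fits_by_group.items():
        t = np.linspace(f.t_range[0], f.t_range[1], 25)
        lo, up = prediction_band(f, t, n_draws=400, seed=seed)
        widths.append(float(np.mean(up - lo)))
    return float(np.mean(widths))


def select_model(series_by_group: dict, candidates=None, seed: int = 20110301):
    """Robustness-screened, parsimony-aware model selection.

    ``series_by_group`` maps group labels (e.g. variety x treatment) to
    ``(times, values)`` series.  Candidates that fail to converge on *any*
    group are disqualified (robustness rule).  Survivors are ranked by
    mean AIC across groups; near-ties (dAIC < 2) are broken by fewer
    parameters, then by narrower mean population-prediction-band width.
    Raises with per-group diagnostics if every candidate is disqualified.
    """
    import pandas as pd

    if not series_by_group:
        raise ValueError("need at least one group of series")
    candidates = list(candidates) if candidates is not None else list(MODEL_NAMES)
    for c in candidates:
        get_model(c)

    fits: dict = {}
    disqualified: dict = {}
    rows = []
    for model in candidates:
        by_group = {}
        failed = []
        for group, (t, y) in series_by_group.items():
            try:
                f = fit(model, t, y)
            except ValueError as exc:
                f = _failed_fit(get_model(model), len(np.atleast_1d(t)), (0, 1), str(exc))
            fits[(model, group)] = f
            by_group[group] = f
            if not f.converged:
                failed.append(group)
        if failed:
            disqualified[model] = failed
            logger.info("model %s disqualified (no convergence on %s)", model, failed)
            rows.append(
                dict(model=model, n_params=get_model(model).n_params, converged_on_all=False,
                     mean_aic=float("inf"), mean_r2=float("nan"), mean_band_width=float("nan"))
            )
            continue
        mean_aic = float(np.mean([f.aic for f in by_group.values()]))
        mean_r2 = float(np.mean([f.r2 for f in by_group.values()]))
        rows.append(
            dict(model=model, n_params=get_model(model).n_params, converged_on_all=True,
                 mean_aic=mean_aic, mean_r2=mean_r2, mean_band_width=float("nan"))
        )

    survivors = [r for r in rows if r["converged_on_all"]]
    if not survivors:
        detail = "; ".join(f"{m}: failed on {g}" for m, g in disqualified.items())
        raise ValueError(f"all candidate models were disqualified — {detail}")

    # band widths only needed to break near-ties, but cheap enough to report
    for r in survivors:
        if any(s is not r and abs(s["mean_aic"] - r["mean_aic"]) < 2.0 for s in survivors):
            by_group = {g: fits[(r["model"], g)] for g in series_by_group}
            r["mean_band_width"] = _band_width_score(r["model"], by_group, seed)

    def _better(a, b):
        if abs(a["mean_aic"] - b["mean_aic"]) < 2.0:
            if a["n_params"] != b["n_params"]:
                return a if a["n_params"] < b["n_params"] else b
            wa, wb = a["mean_band_width"], b["mean_band_width"]
            if np.isfinite(wa) and np.isfinite(wb) and wa != wb:
                return a if wa < wb else b
        return a if a["mean_aic"] <= b["mean_aic"] else b

    ranked = []
    pool = list(survivors)
    while pool:
        best = pool[0]
        for other in pool[1:]:
            best = _better(best, other)
        ranked.append(best)
        pool.remove(best)
    ranked += [r for r in rows if not r["converged_on_all"]]
    for i, r in enumerate(ranked):
        r["rank"] = i + 1 if r["converged_on_all"] else None
    table = pd.DataFrame(ranked, columns=["model", "rank", "n_params", "converged_on_all", "mean_aic", "mean_r2", "mean_band_width"])
    return SelectionResult(table=table, best=ranked[0]["model"], fits=fits, disqualified=disqualified)


# --- derived curve quantities -------------------------------------------------


_SIGMOIDAL = {"logistic3", "logistic4", "gompertz", "weibull", "richards", "beta"}


def inflection_time(fitres, t_lo: float = None, t_hi: float = None) -> float:
    """Time of maximum absolute growth rate (the inflection point).

    Exact (tmid) for the 3- and 4-parameter logistic; for the other
    sigmoidal models the AGR maximum is located by bounded golden-section/
    parabolic search over the fitted time range (extended by 50% on each
    side).  Non-sigmoidal models have no AGR maximum and raise.
    """
    name = fitres.model_name if isinstance(fitres, ModelFit) else fitres[0]
    params = fitres.params if isinstance(fitres, ModelFit) else np.asarray(fitres[1], dtype=float)
    if name not in _SIGMOIDAL:
        raise ValueError(f"{name} is not sigmoidal: AGR has no interior maximum")
    if name in ("logistic3", "logistic4"):
        md = get_model(name)
        return float(params[md.param_names.index("tmid")])
    if t_lo is None or t_hi is None:
        lo, hi = (fitres.t_range if isinstance(fitres, ModelFit) else (0.0, 1.0))
        span = hi - lo
        t_lo = lo - 0.5 * span if t_lo is None else t_lo
        t_hi = hi + 0.5 * span if t_hi is None else t_hi
    res = optimize.minimize_scalar(
        lambda tt: -agr(name, params, float(tt)),
        bounds=(t_lo, t_hi),
        method="bounded",
        options={"xatol": 1e-7},
    )
    return float(res.x)


@dataclass
class GrowthCurves:
    """Fitted curve with derived rates and a 95% population band."""

    times: np.ndarray
    M: np.ndarray
    AGR: np.ndarray
    RGR: np.ndarray
    lower: np.ndarray
    upper: np.ndarray


def growth_curves(fitres: ModelFit, times, n_draws: int = 1000, level: float = 0.95, seed: int = 20110301) -> GrowthCurves:
    t = np.asarray(times, dtype=float)
    M = np.asarray(evaluate(fitres.model_name, fitres.params, t, strict=False))
    A = np.asarray(agr(fitres.model_name, fitres.params, t))
    lower, upper = prediction_band(fitres, t, n_draws=n_draws, level=level, seed=seed)
    return GrowthCurves(times=t, M=M, AGR=A, RGR=A / M, lower=lower, upper=upper)
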