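"""Thermal performance curve (TPC) model registry.

A TPC describes a physiological rate as a unimodal function of temperature:
performance rises from cold temperatures to a maximum ``rmax`` at the thermal
optimum ``topt``, then falls, for many models reaching zero at a critical
thermal maximum ``ctmax``.  This module provides a registry of nine
commonly-used closed-form TPC models with vectorised evaluators, start-value
heuristics for nonlinear least squares, parameter bounds, and numeric
extraction of the derived biological parameters (topt, rmax, ctmax) for
models that do not expose them as explicit parameters.

Temperatures are degrees Celsius throughout; models formulated in Kelvin
(Sharpe–Schoolfield) convert internally with a 273.15 offset.  Evaluators
return 0 outside the temperature domain on which a model's formula is
defined (e.g. beyond ``ctmax`` for the O'Neill curve, where the power term
has a negative base); models defined on the whole line (quadratic, Gaussian)
are not truncated, so responses for which negative values are physical
(weight change, net photosynthesis) can be represented.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .errors import DegenerateDataError, RegistryError

BOLTZMANN_EV = 8.617333262e-5  # eV K^-1
SHARPE_TREF_C = 15.0  # reference temperature for the Sharpe-Schoolfield rate


@dataclass(frozen=True)
class TpcModelSpec:
    """One registered TPC model.

    ``explicit`` maps the derived-parameter names (``topt``, ``rmax``,
    ``ctmax``) to the model parameter that carries them directly, for models
    where the biology is an explicit parameter rather than a property of the
    fitted curve.
    """

    name: str
    param_names: tuple[str, ...]
    evaluator: Callable[[np.ndarray, np.ndarray], np.ndarray]
    explicit: dict[str, str] = field(default_factory=dict)
    start: Callable[["DatasetSummary"], np.ndarray] | None = None
    bounds: Callable[["DatasetSummary"], tuple[np.ndarray, np.ndarray]] | None = None
    accepts_truncate: bool = False  # evaluator has a controllable negative branch

    def rate(self, params_vec, temps: np.ndarray, truncate: bool = True) -> np.ndarray:
        if self.accepts_truncate:
            return self.evaluator(params_vec, temps, truncate)
        return self.evaluator(params_vec, temps)

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def params_dict(self, values: Sequence[float]) -> dict[str, float]:
        return dict(zip(self.param_names, (float(v) for v in values)))


@dataclass(frozen=True)
class DatasetSummary:
    """The features of a (temperature, rate) dataset that heuristics need."""

    tmin: float
    tmax: float
    rate_max: float
    t_at_rate_max: float
    monotone_increasing: bool = False

    @classmethod
    def from_points(cls, temps: Sequence[float], rates: Sequence[float]) -> "DatasetSummary":
        t = np.asarray(temps, dtype=float)
        r = np.asarray(rates, dtype=float)
        if t.size < 2 or np.unique(t).size < 2:
            raise DegenerateDataError("need >= 2 distinct temperatures")
        if not np.any(r != 0):
            raise DegenerateDataError("all rates zero; cannot place start values")
        i = int(np.argmax(r))
        order = np.argsort(t)
        # treatment means, to judge monotonicity robustly against replicates
        ut = np.unique(t)
        means = np.array([r[t == u].mean() for u in ut])
        mono = bool(np.all(np.diff(means) >= 0))
        return cls(
            tmin=float(t.min()),
            tmax=float(t.max()),
            rate_max=float(r[i]),
            t_at_rate_max=float(t[order][np.argmax(r[order])]),
            monotone_increasing=mono,
        )


# ---------------------------------------------------------------------------
# model formulas
# ---------------------------------------------------------------------------

def oneill_rate(params: Sequence[float], temp) -> np.ndarray:
    """O'Neill et al. (1972) curve.

    rate = rmax * ((ctmax - T)/(ctmax - topt))**x * exp(x*(T - topt)/(ctmax - topt))
    with w = (q10 - 1)*(ctmax - topt) and x = (w**2/400)*(1 + sqrt(1 + 40/w))**2.

    Explicit topt, rmax, ctmax; q10 sets the steepness of the rising limb.
    Zero for T > ctmax (curve truncated, the formula is undefined there).
    """
    rmax, topt, ctmax, q10 = (float(p) for p in params)
    t = np.asarray(temp, dtype=float)
    if not (topt < ctmax and q10 > 1 and rmax > 0):
        return np.full(t.shape, np.nan)
    w = (q10 - 1.0) * (ctmax - topt)
    x = (w * w / 400.0) * (1.0 + np.sqrt(1.0 + 40.0 / w)) ** 2
    base = (ctmax - t) / (ctmax - topt)
    out = np.zeros_like(t)
    ok = base > 0
    out[ok] = rmax * base[ok] ** x * np.exp(x * (t[ok] - topt) / (ctmax - topt))
    return out


def yanhunt_rate(params: Sequence[float], temp, truncate: bool = True) -> np.ndarray:
    """Yan & Hunt (1999) beta-type curve.

    rate = rmax * ((tmax - T)/(tmax - topt)) * (T/topt)**(topt/(tmax - topt))

    Explicit topt, rmax and tmax (the critical maximum); zero at T = 0 and
    T = tmax.  With ``truncate`` the rate is clipped to zero outside
    [0, tmax]; without it the formula's negative branch beyond tmax is kept
    — appropriate for responses where negative values are physical, such as
    percentage weight change (net tissue loss at supra-critical
    temperatures).
    """
    rmax, topt, tmax = (float(p) for p in params)
    t = np.asarray(temp, dtype=float)
    if not (0 < topt < tmax and rmax > 0):
        return np.full(t.shape, np.nan)
    out = np.zeros_like(t)
    ok = (t > 0) & (t < tmax) if truncate else (t > 0)
    out[ok] = (
        rmax
        * ((tmax - t[ok]) / (tmax - topt))
        * (t[ok] / topt) ** (topt / (tmax - topt))
    )
    return out


def quadratic_rate(params: Sequence[float], temp) -> np.ndarray:
    """Plain quadratic a + b*T + c*T**2; unimodal when c < 0. Not truncated."""
    a, b, c = (float(p) for p in params)
    t = np.asarray(temp, dtype=float)
    return a + b * t + c * t * t


def gaussian_rate(params: Sequence[float], temp) -> np.ndarray:
    """Gaussian curve rmax * exp(-0.5*((T - topt)/a)**2); explicit topt, rmax."""
    rmax, topt, a = (float(p) for p in params)
    t = np.asarray(temp, dtype=float)
    if not (rmax > 0 and a > 0):
        return np.full(t.shape, np.nan)
    return rmax * np.exp(-0.5 * ((t - topt) / a) ** 2)


def modified_gaussian_rate(params: Sequence[float], temp) -> np.ndarray:
    """Modified (Weibull-type) Gaussian rmax * exp(-0.5*(|T - topt|/a)**b)."""
    rmax, topt, a, b = (float(p) for p in params)
    t = np.asarray(temp, dtype=float)
    if not (rmax > 0 and a > 0 and b > 0):
        return np.full(t.shape, np.nan)
    return rmax * np.exp(-0.5 * (np.abs(t - topt) / a) ** b)


def sharpeschoolhigh_rate(params: Sequence[float], temp) -> np.ndarray:
    """Sharpe-Schoolfield model, high-temperature inactivation form.

    rate = r_tref * exp(e/k * (1/Tref - 1/T)) / (1 + exp(eh/k * (1/th - 1/T)))

    with temperatures in Kelvin inside the formula, Tref = 15 C. ``e`` is the
    activation energy (eV), ``eh`` the inactivation energy (eV), ``th`` the
    temperature (C) at which half the enzyme pool is inactivated. No explicit
    topt/rmax/ctmax; the rate is positive for all finite T.
    """
    r_tref, e, eh, th = (float(p) for p in params)
    t = np.asarray(temp, dtype=float)
    if not (r_tref > 0 and 0 < e < eh):
        return np.full(t.shape, np.nan)
    tk = t + 273.15
    tref = SHARPE_TREF_C + 273.15
    thk = th + 273.15
    boltz = np.exp(e / BOLTZMANN_EV * (1.0 / tref - 1.0 / tk))
    inact = 1.0 + np.exp(eh / BOLTZMANN_EV * (1.0 / thk - 1.0 / tk))
    return r_tref * boltz / inact


def ratkowsky_rate(params: Sequence[float], temp) -> np.ndarray:
    """Ratkowsky (1983) square-root model.

    rate = (a*(T - tmin) * (1 - exp(b*(T - tmax))))**2 on (tmin, tmax), else 0.
    Explicit ctmax (= tmax).
    """
    a, b, tmin, tmax = (float(p) for p in params)
    t = np.asarray(temp, dtype=float)
    if not (tmin < tmax and a != 0 and b > 0):
        return np.full(t.shape, np.nan)
    out = np.zeros_like(t)
    ok = (t > tmin) & (t < tmax)
    out[ok] = (a * (t[ok] - tmin) * (1.0 - np.exp(b * (t[ok] - tmax)))) ** 2
    return out


def briere2_rate(params: Sequence[float], temp) -> np.ndarray:
    """Briere-2 (1999) model: rate = a*T*(T - tmin)*(tmax - T)**(1/b) on
    [tmin, tmax], else 0. Explicit ctmax (= tmax)."""
    a, tmin, tmax, b = (float(p) for p in params)
    t = np.asarray(temp, dtype=float)
    if not (tmin < tmax and a > 0 and b > 0):
        return np.full(t.shape, np.nan)
    out = np.zeros_like(t)
    ok = (t > tmin) & (t < tmax)
    out[ok] = a * t[ok] * (t[ok] - tmin) * (tmax - t[ok]) ** (1.0 / b)
    return out


def thomas_rate(params: Sequence[float], temp) -> np.ndarray:
    """Thomas et al. (2012) model.

    rate = a * exp(b*T) * (1 - ((T - tm)/(c/2))**2), clipped at 0.

    ``tm`` centres the quadratic envelope but is NOT the realised optimum
    (the exponential skews the curve), so no parameter is marked explicit.
    """
    a, b, c, tm = (float(p) for p in params)
    t = np.asarray(temp, dtype=float)
    if not (a > 0 and c > 0):
        return np.full(t.shape, np.nan)
    out = a * np.exp(b * t) * (1.0 - ((t - tm) / (c / 2.0)) ** 2)
    return np.maximum(out, 0.0)


# ---------------------------------------------------------------------------
# start values and bounds
# ---------------------------------------------------------------------------

def _rmax_scale(d: DatasetSummary) -> float:
    return max(abs(d.rate_max), 1e-6)


def _oneill_start(d: DatasetSummary) -> np.ndarray:
    return np.array([d.rate_max, d.t_at_rate_max, d.tmax + 5.0, 2.0])


def _oneill_bounds(d: DatasetSummary):
    lo = np.array([1e-10, d.tmin - 5.0, d.tmin, 1.0 + 1e-6])
    hi = np.array([1e4 * _rmax_scale(d), d.tmax + 5.0, d.tmax + 15.0, 10.0])
    return lo, hi


def _yanhunt_start(d: DatasetSummary) -> np.ndarray:
    return np.array([d.rate_max, max(d.t_at_rate_max, 1.0), d.tmax + 5.0])


def _yanhunt_bounds(d: DatasetSummary):
    lo = np.array([1e-10, max(d.tmin - 5.0, 0.5), d.tmin])
    hi = np.array([1e4 * _rmax_scale(d), d.tmax + 5.0, d.tmax + 15.0])
    return lo, hi


def _quadratic_start(d: DatasetSummary) -> np.ndarray:
    # closed-form least squares is done in fit_quadratic; a crude concave
    # start is enough for the generic NLS path
    c = -d.rate_max / max((d.tmax - d.tmin) ** 2, 1.0)
    b = -2.0 * c * d.t_at_rate_max
    a = d.rate_max - b * d.t_at_rate_max - c * d.t_at_rate_max**2
    return np.array([a, b, c])


def _quadratic_bounds(d: DatasetSummary):
    big = 1e6 * max(_rmax_scale(d), 1.0)
    return np.array([-big, -big, -big]), np.array([big, big, big])


def _gaussian_start(d: DatasetSummary) -> np.ndarray:
    return np.array([d.rate_max, d.t_at_rate_max, (d.tmax - d.tmin) / 4.0])


def _gaussian_bounds(d: DatasetSummary):
    lo = np.array([1e-10, d.tmin - 5.0, 0.1])
    hi = np.array([1e4 * _rmax_scale(d), d.tmax + 5.0, 100.0])
    return lo, hi


def _modgauss_start(d: DatasetSummary) -> np.ndarray:
    return np.array([d.rate_max, d.t_at_rate_max, (d.tmax - d.tmin) / 4.0, 2.0])


def _modgauss_bounds(d: DatasetSummary):
    lo = np.array([1e-10, d.tmin - 5.0, 0.1, 0.5])
    hi = np.array([1e4 * _rmax_scale(d), d.tmax + 5.0, 100.0, 10.0])
    return lo, hi


def _sharpe_start(d: DatasetSummary) -> np.ndarray:
    return np.array([0.6 * d.rate_max, 0.6, 3.0, d.t_at_rate_max + 3.0])


def _sharpe_bounds(d: DatasetSummary):
    lo = np.array([1e-10, 0.01, 0.02, d.tmin - 5.0])
    hi = np.array([1e4 * _rmax_scale(d), 4.0, 20.0, d.tmax + 15.0])
    return lo, hi


def _ratkowsky_start(d: DatasetSummary) -> np.ndarray:
    tmin0 = d.tmin - 5.0
    a0 = np.sqrt(_rmax_scale(d)) / max(d.t_at_rate_max - tmin0, 1.0)
    return np.array([a0, 0.2, tmin0, d.tmax + 5.0])


def _ratkowsky_bounds(d: DatasetSummary):
    lo = np.array([1e-8, 1e-3, d.tmin - 30.0, d.tmin])
    hi = np.array([1e3, 5.0, d.tmin - 1e-6, d.tmax + 15.0])
    return lo, hi


def _briere2_start(d: DatasetSummary) -> np.ndarray:
    tmin0 = d.tmin - 5.0
    tmax0 = d.tmax + 5.0
    b0 = 3.0
    topt0 = max(d.t_at_rate_max, tmin0 + 1.0)
    denom = abs(topt0) * (topt0 - tmin0) * (tmax0 - topt0) ** (1.0 / b0)
    a0 = _rmax_scale(d) / max(denom, 1e-9)
    return np.array([a0, tmin0, tmax0, b0])


def _briere2_bounds(d: DatasetSummary):
    lo = np.array([1e-12, d.tmin - 50.0, d.tmin, 0.2])
    hi = np.array([1e3, d.tmin - 1e-6, d.tmax + 15.0, 20.0])
    return lo, hi


def _thomas_start(d: DatasetSummary) -> np.ndarray:
    b0 = 0.05
    a0 = _rmax_scale(d) / np.exp(b0 * d.t_at_rate_max)
    return np.array([a0, b0, 1.5 * (d.tmax - d.tmin), d.t_at_rate_max])


def _thomas_bounds(d: DatasetSummary):
    lo = np.array([1e-10, -1.0, 1.0, d.tmin - 10.0])
    hi = np.array([1e4 * _rmax_scale(d), 1.0, 200.0, d.tmax + 10.0])
    return lo, hi


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

REGISTRY: dict[str, TpcModelSpec] = {}


def register(spec: TpcModelSpec) -> None:
    """Add a model to the registry (replacing any model of the same name)."""
    REGISTRY[spec.name] = spec


def get_model(name: str) -> TpcModelSpec:
    try:
        return REGISTRY[name]
    except KeyError:
        raise RegistryError(
            f"unknown TPC model {name!r}; registered: {sorted(REGISTRY)}"
        ) from None


def list_models() -> list[TpcModelSpec]:
    """Registered models in registration order (the selection tie-break order)."""
    return list(REGISTRY.values())


for _spec in [
    TpcModelSpec(
        "oneill_1972", ("rmax", "topt", "ctmax", "q10"), oneill_rate,
        explicit={"topt": "topt", "rmax": "rmax", "ctmax": "ctmax"},
        start=_oneill_start, bounds=_oneill_bounds,
    ),
    TpcModelSpec(
        "yanhunt_1999", ("rmax", "topt", "tmax"), yanhunt_rate,
        explicit={"topt": "topt", "rmax": "rmax", "ctmax": "tmax"},
        start=_yanhunt_start, bounds=_yanhunt_bounds,
        accepts_truncate=True,
    ),
    TpcModelSpec(
        "quadratic", ("a", "b", "c"), quadratic_rate,
        start=_quadratic_start, bounds=_quadratic_bounds,
    ),
    TpcModelSpec(
        "gaussian_1987", ("rmax", "topt", "a"), gaussian_rate,
        explicit={"topt": "topt", "rmax": "rmax"},
        start=_gaussian_start, bounds=_gaussian_bounds,
    ),
    TpcModelSpec(
        "modifiedgaussian_2006", ("rmax", "topt", "a", "b"), modified_gaussian_rate,
        explicit={"topt": "topt", "rmax": "rmax"},
        start=_modgauss_start, bounds=_modgauss_bounds,
    ),
    TpcModelSpec(
        "sharpeschoolhigh_1981", ("r_tref", "e", "eh", "th"), sharpeschoolhigh_rate,
        start=_sharpe_start, bounds=_sharpe_bounds,
    ),
    TpcModelSpec(
        "ratkowsky_1983", ("a", "b", "tmin", "tmax"), ratkowsky_rate,
        explicit={"ctmax": "tmax"},
        start=_ratkowsky_start, bounds=_ratkowsky_bounds,
    ),
    TpcModelSpec(
        "briere2_1999", ("a", "tmin", "tmax", "b"), briere2_rate,
        explicit={"ctmax": "tmax"},
        start=_briere2_start, bounds=_briere2_bounds,
    ),
    TpcModelSpec(
        "thomas_2012", ("a", "b", "c", "tm"), thomas_rate,
        start=_thomas_start, bounds=_thomas_bounds,
    ),
]:
    register(_spec)


# ---------------------------------------------------------------------------
# evaluation and derived parameters
# ---------------------------------------------------------------------------

def evaluate(model_name: str, params, temps, truncate: bool = True) -> np.ndarray:
    """Vectorised evaluation of a registered model.

    ``params`` may be a mapping (by parameter name) or a sequence in
    registry parameter order.  ``truncate=False`` keeps the negative branch
    beyond the critical limits for models that have one (Yan-Hunt), for
    responses where negative values are physical; models whose formula is
    undefined there (O'Neill) always return 0 beyond the limit.
    """
    spec = get_model(model_name)
    if isinstance(params, dict):
        vec = [params[name] for name in spec.param_names]
    else:
        vec = list(params)
        if len(vec) != spec.n_params:
            raise ValueError(
                f"{model_name} expects {spec.n_params} params, got {len(vec)}"
            )
    return spec.rate(vec, np.asarray(temps, dtype=float), truncate)


def start_values(model_name: str, temps, rates) -> dict[str, float]:
    """Heuristic NLS start values from the data.

    topt0 = temperature of the maximum observed rate, rmax0 = that rate,
    ctmax0/tmax0 = hottest observed temperature + 5 C, q10_0 = 2; shape
    parameters get model-specific defaults.  Raises DegenerateDataError
    when no positive rate exists.
    """
    spec = get_model(model_name)
    d = DatasetSummary.from_points(temps, rates)
    return spec.params_dict(spec.start(d))


def derived_params(
    model_name: str,
    params,
    temp_window: tuple[float, float],
    grid_points: int = 2001,
) -> dict[str, float]:
    """Extract the biological parameters (topt, rmax, and ctmax when the
    curve reaches zero) from a fitted model.

    Models with explicit parameters return them directly (bit-identical);
    otherwise topt is the argmax of the curve on ``temp_window``, found on a
    fine grid and refined by bounded scalar minimisation, rmax is the rate
    there, and ctmax is the smallest temperature above topt at which the
    rate falls to <= 0 (searched up to 40 C past the window; absent if the
    curve never reaches zero, as for Sharpe-Schoolfield).
    """
    spec = get_model(model_name)
    pdict = params if isinstance(params, dict) else spec.params_dict(params)
    out: dict[str, float] = {}
    for key in ("topt", "rmax", "ctmax"):
        if key in spec.explicit:
            out[key] = float(pdict[spec.explicit[key]])
    if "topt" not in out:
        lo, hi = float(temp_window[0]), float(temp_window[1])
        grid = np.linspace(lo, hi, grid_points)
        vals = evaluate(model_name, pdict, grid)
        i = int(np.nanargmax(vals))
        a = grid[max(i - 1, 0)]
        b = grid[min(i + 1, grid_points - 1)]
        res = minimize_scalar(
            lambda t: -float(evaluate(model_name, pdict, [t])[0]),
            bounds=(a, b), method="bounded",
            options={"xatol": 1e-8},
        )
        out["topt"] = float(res.x)
    if "rmax" not in out:
        out["rmax"] = float(evaluate(model_name, pdict, [out["topt"]])[0])
    if "ctmax" not in out:
        topt = out["topt"]
        hi = float(temp_window[1]) + 40.0
        grid = np.linspace(topt, hi, 4001)
        vals = evaluate(model_name, pdict, grid)
        below = np.nonzero(vals <= 0)[0]
        below = below[grid[below] > topt]
        if below.size:
            j = int(below[0])
            if j > 0 and vals[j - 1] > 0:
                out["ctmax"] = float(
                    brentq(
                        lambda t: float(evaluate(model_name, pdict, [t])[0]),
                        grid[j - 1], grid[j], xtol=1e-10,
                    )
                )
            else:
                out["ctmax"] = float(grid[j])
    return out
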