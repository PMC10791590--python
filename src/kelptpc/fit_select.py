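"""Nonlinear least-squares TPC fitting and rule-based model selection.

Every registered model is fitted to each response dataset by bounded,
multi-start nonlinear least squares.  Selection then proceeds in three
deterministic steps: (1) discard converged fits whose RMSE exceeds 1.02x
the best RMSE; (2) discard fits that are biologically non-sensical
(negative predictions for a non-negative response, or no interior optimum
near the observed temperature range); (3) among the survivors, prefer
models with explicit thermal-optimum and maximum-rate parameters, then
models with an explicit critical thermal maximum, then the lowest RMSE.
A quadratic closed-form least-squares fit is provided for the carbon
stable-isotope (d13C) vs temperature relationship.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from . import tpc_models
from .errors import DegenerateDataError, SelectionError
from .ingest import NEGATIVE_ALLOWED_RESPONSES, NON_NEGATIVE_RESPONSES, ResponseDataset


@dataclass(frozen=True)
class FitConfig:
    n_starts: int = 10            # random multiplicative perturbations of the heuristic start
    perturb_frac: float = 0.2     # +-20% perturbation scale
    seed: int = 0
    tol: float = 1e-8             # ftol/xtol/gtol for the least-squares solver
    max_nfev: int = 2000


@dataclass
class FitResult:
    model_name: str
    params: dict[str, float]
    rmse: float
    converged: bool
    n_points: int
    predictions: np.ndarray
    sensible: bool = True
    reasons: list[str] = field(default_factory=list)
    derived: dict[str, float] = field(default_factory=dict)
    truncate: bool = True  # False when negative values are physical for the response

    def to_dict(self) -> dict:
        return {
            "model_name": self.model_name,
            "params": self.params,
            "rmse": None if not np.isfinite(self.rmse) else float(self.rmse),
            "converged": self.converged,
            "n_points": self.n_points,
            "predictions": [float(v) for v in np.atleast_1d(self.predictions)],
            "sensible": self.sensible,
            "reasons": list(self.reasons),
            "derived": {k: float(v) for k, v in self.derived.items()},
        }


@dataclass
class SelectionReport:
    all_fits: list[FitResult]
    admissible: list[FitResult]
    chosen: FitResult
    rule_trace: list[tuple[str, list[str]]]

    def to_dict(self) -> dict:
        return {
            "all_fits": [f.to_dict() for f in self.all_fits],
            "admissible": [f.model_name for f in self.admissible],
            "chosen": self.chosen.to_dict(),
            "rule_trace": [{"rule": r, "removed": m} for r, m in self.rule_trace],
        }


def rmse(observed, predicted) -> float:
    """Root mean square error sqrt(mean((obs - pred)**2))."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size == 0:
        raise ValueError("observed and predicted must be equal-length, non-empty")
    return float(np.sqrt(np.mean((obs - pred) ** 2)))


def _residual_fn(
    spec: tpc_models.TpcModelSpec, temps: np.ndarray, values: np.ndarray, truncate: bool
):
    big = 1e6 * max(1.0, float(np.max(np.abs(values))))

    def residuals(p: np.ndarray) -> np.ndarray:
        pred = spec.rate(p, temps, truncate)
        r = pred - values
        bad = ~np.isfinite(r)
        if np.any(bad):
            r = np.where(bad, big, r)
        return r

    return residuals


def fit_model(
    dataset: ResponseDataset,
    model_name: str,
    fit_config: FitConfig | None = None,
    x0: np.ndarray | None = None,
) -> FitResult:
    """Fit one model by bounded multi-start nonlinear least squares.

    Starts from the data-driven heuristic start values plus ``n_starts``
    seeded multiplicative perturbations (all clipped into the parameter
    bounds); the best converged solution is kept.  Total failure returns a
    ``converged=False`` result rather than raising.  Passing ``x0`` skips
    the multi-start and refits from that single start (used by the
    bootstrap, which restarts each replicate from the point estimate).
    """
    cfg = fit_config or FitConfig()
    spec = tpc_models.get_model(model_name)
    temps, values = dataset.temps_c, dataset.values
    n = temps.size
    truncate = dataset.response not in NEGATIVE_ALLOWED_RESPONSES

    failed = FitResult(
        model_name=model_name, params={}, rmse=float("inf"), converged=False,
        n_points=n, predictions=np.full(n, np.nan),
    )

    try:
        d = tpc_models.DatasetSummary.from_points(temps, values)
    except DegenerateDataError:
        return failed

    lo, hi = spec.bounds(d)
    if x0 is not None:
        starts = [np.clip(np.asarray(x0, dtype=float), lo, hi)]
    else:
        base = np.clip(spec.start(d), lo, hi)
        rng = np.random.default_rng(cfg.seed)
        starts = [base]
        for _ in range(cfg.n_starts):
            fac = 1.0 + cfg.perturb_frac * rng.uniform(-1.0, 1.0, size=base.size)
            starts.append(np.clip(base * fac, lo, hi))

    residuals = _residual_fn(spec, temps, values, truncate)
    best = None
    for s in starts:
        try:
            sol = least_squares(
                residuals, s, bounds=(lo, hi), method="trf",
                ftol=cfg.tol, xtol=cfg.tol, gtol=cfg.tol, max_nfev=cfg.max_nfev,
            )
        except Exception:
            continue
        if sol.status <= 0 or not np.all(np.isfinite(sol.x)):
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return failed

    params = spec.params_dict(best.x)
    pred = spec.rate(best.x, temps, truncate)
    if not np.all(np.isfinite(pred)):
        return failed
    window = (float(temps.min()) - 1.0, float(temps.max()) + 1.0)
    derived = tpc_models.derived_params(model_name, params, window)
    return FitResult(
        model_name=model_name, params=params, rmse=rmse(values, pred),
        converged=True, n_points=n, predictions=pred, derived=derived,
        truncate=truncate,
    )


def fit_all_models(
    dataset: ResponseDataset,
    model_names: list[str] | None = None,
    fit_config: FitConfig | None = None,
) -> list[FitResult]:
    names = model_names or [m.name for m in tpc_models.list_models()]
    return [fit_model(dataset, name, fit_config) for name in names]


def filter_by_rmse(fits: list[FitResult], factor: float = 1.02) -> list[FitResult]:
    """Keep converged fits whose RMSE is within ``factor`` of the best
    (RMSE <= factor * min RMSE); always contains the minimum-RMSE fit."""
    converged = [f for f in fits if f.converged]
    if not converged:
        raise SelectionError("no converged fits to filter")
    best = min(f.rmse for f in converged)
    return [f for f in converged if f.rmse <= factor * best]


def sensibility_check(
    fit: FitResult,
    dataset: ResponseDataset,
    non_negative: bool | None = None,
    window_pad_c: float = 1.0,
    grid_points: int = 500,
) -> FitResult:
    """Screen a fit for biological plausibility.

    Fails with reason ``negative_prediction`` if the curve goes below zero
    anywhere on the observed temperature range for a response where
    negative values are impossible, and with ``no_interior_optimum`` if the
    curve has no maximum strictly inside the observed range padded by
    ``window_pad_c`` (i.e. it is monotone over the window, not a thermal
    performance pattern).  Returns a copy with ``sensible``/``reasons`` set.
    """
    if not fit.converged:
        raise ValueError("sensibility check requires a converged fit")
    if non_negative is None:
        non_negative = dataset.response in NON_NEGATIVE_RESPONSES
    reasons: list[str] = []
    tmin, tmax = float(dataset.temps_c.min()), float(dataset.temps_c.max())

    if non_negative:
        grid = np.linspace(tmin, tmax, grid_points)
        vals = tpc_models.evaluate(fit.model_name, fit.params, grid, truncate=fit.truncate)
        if np.any(vals < -1e-12):
            reasons.append("negative_prediction")

    lo, hi = tmin - window_pad_c, tmax + window_pad_c
    grid = np.linspace(lo, hi, grid_points)
    vals = tpc_models.evaluate(fit.model_name, fit.params, grid, truncate=fit.truncate)
    i = int(np.nanargmax(vals))
    if i == 0 or i == grid_points - 1:
        reasons.append("no_interior_optimum")

    return replace(fit, sensible=not reasons, reasons=reasons)


def select_model(admissible_fits: list[FitResult]) -> FitResult:
    """Priority ranking of admissible fits: explicit topt AND rmax first,
    then explicit ctmax, then lowest RMSE, then registry order."""
    if not admissible_fits:
        raise SelectionError(
            "empty admissible set: relax the RMSE filter or sensibility rules"
        )
    order = [m.name for m in tpc_models.list_models()]

    def key(fit: FitResult):
        spec = tpc_models.get_model(fit.model_name)
        has_topt_rmax = "topt" in spec.explicit and "rmax" in spec.explicit
        has_ctmax = "ctmax" in spec.explicit
        reg = order.index(fit.model_name) if fit.model_name in order else len(order)
        return (not has_topt_rmax, not has_ctmax, fit.rmse, reg)

    return min(admissible_fits, key=key)


def select_for_dataset(
    dataset: ResponseDataset,
    model_names: list[str] | None = None,
    fit_config: FitConfig | None = None,
    rmse_factor: float = 1.02,
) -> SelectionReport:
    """Full fit-and-select pipeline for one response dataset."""
    all_fits = fit_all_models(dataset, model_names, fit_config)
    trace: list[tuple[str, list[str]]] = []

    kept = filter_by_rmse(all_fits, rmse_factor)
    removed = [f.model_name for f in all_fits if f.converged and f not in kept]
    not_conv = [f.model_name for f in all_fits if not f.converged]
    if not_conv:
        trace.append(("not_converged", not_conv))
    trace.append((f"rmse_within_{rmse_factor:g}x_best", removed))

    checked = [sensibility_check(f, dataset) for f in kept]
    admissible = [f for f in checked if f.sensible]
    trace.append(
        ("sensibility", [f"{f.model_name}:{'|'.join(f.reasons)}" for f in checked if not f.sensible])
    )
    chosen = select_model(admissible)
    trace.append(("parameter_priority", [f.model_name for f in admissible if f is not chosen]))
    return SelectionReport(all_fits=all_fits, admissible=admissible, chosen=chosen, rule_trace=trace)


def fit_quadratic(temps, values) -> tuple[float, float, float]:
    """Exact closed-form least squares for value = a + b*T + c*T**2.

    Used for the d13C vs temperature relationship; the vertex -b/(2c) is
    the temperature of the extreme value.  Requires >= 3 distinct
    temperatures.
    """
    t = np.asarray(temps, dtype=float)
    v = np.asarray(values, dtype=float)
    if np.unique(t).size < 3:
        raise DegenerateDataError("quadratic fit needs >= 3 distinct temperatures")
    c, b, a = np.polyfit(t, v, 2)
    return float(a), float(b), float(c)
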