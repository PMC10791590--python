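"""Case-resampling bootstrap for TPC fits.

Individuals (cases) are resampled with replacement, the model is refitted
to each replicate starting from the point estimate, and parameter and
derived-parameter (topt/rmax/ctmax) draws are collected.  Confidence
intervals are percentile by default (empirical quantiles with linear
interpolation), with bias-corrected accelerated (BCa) intervals available;
prediction bands are pointwise quantiles of the replicate curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from . import tpc_models
from .errors import DegenerateDataError
from .fit_select import FitConfig, FitResult, fit_model
from .ingest import ResponseDataset

DEFAULT_B = 1999


@dataclass
class BootstrapDistribution:
    model_name: str
    B: int
    seed: int
    param_names: tuple[str, ...]
    param_draws: np.ndarray               # rows = converged replicates
    derived_draws: dict[str, np.ndarray]  # topt / rmax (/ ctmax) per replicate
    point: FitResult | None = None
    n_dropped: int = 0
    warn_high_failure: bool = False

    @property
    def n_kept(self) -> int:
        return int(self.param_draws.shape[0])


@dataclass(frozen=True)
class IntervalEstimate:
    point: float
    lower: float
    upper: float
    level: float
    method: str

    def __post_init__(self):
        if self.lower > self.upper:
            raise ValueError("interval lower bound exceeds upper bound")


def bootstrap_fit(
    dataset: ResponseDataset,
    model_name: str,
    B: int = DEFAULT_B,
    seed: int = 0,
    fit_config: FitConfig | None = None,
    point: FitResult | None = None,
) -> BootstrapDistribution:
    """Case-resampling bootstrap of one model fit.

    Each of the B replicates resamples the n individuals with replacement
    and refits from the point estimate (single start).  Replicates that
    fail to converge are dropped and counted; if more than half fail the
    distribution carries a warning flag.  Fully reproducible from ``seed``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    cfg = fit_config or FitConfig()
    spec = tpc_models.get_model(model_name)
    if point is None:
        point = fit_model(dataset, model_name, cfg)
    if not point.converged:
        raise DegenerateDataError("point fit did not converge; cannot bootstrap")
    x0 = np.array([point.params[p] for p in spec.param_names])

    rng = np.random.default_rng(seed)
    n = dataset.n
    draws: list[np.ndarray] = []
    derived: dict[str, list[float]] = {}
    dropped = 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        boot = ResponseDataset(
            response=dataset.response, co2_level=dataset.co2_level,
            temps_c=dataset.temps_c[idx], values=dataset.values[idx],
            individual_ids=[dataset.individual_ids[i] for i in idx],
            units=dataset.units,
        )
        fit = fit_model(boot, model_name, cfg, x0=x0)
        if not fit.converged:
            dropped += 1
            continue
        draws.append(np.array([fit.params[p] for p in spec.param_names]))
        for key, val in fit.derived.items():
            derived.setdefault(key, []).append(val)

    param_draws = np.array(draws) if draws else np.empty((0, spec.n_params))
    return BootstrapDistribution(
        model_name=model_name, B=B, seed=seed, param_names=spec.param_names,
        param_draws=param_draws,
        derived_draws={k: np.array(v) for k, v in derived.items()},
        point=point, n_dropped=dropped,
        warn_high_failure=dropped > B / 2,
    )


def interval(
    draws,
    level: float = 0.95,
    method: str = "percentile",
    point: float | None = None,
    jackknife_values=None,
) -> IntervalEstimate:
    """Confidence interval from bootstrap draws.

    percentile: empirical (1 +- level)/2 quantiles, linear-interpolation
    quantile rule (numpy default), requiring >= 20 draws.
    bca: bias-corrected accelerated; needs ``point`` (the original
    estimate) and ``jackknife_values`` (leave-one-out estimates) for the
    acceleration term.
    """
    x = np.sort(np.asarray(draws, dtype=float))
    if x.size < 20:
        raise ValueError(f"need >= 20 draws for a {method} interval, got {x.size}")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    alpha = (1.0 - level) / 2.0
    pt = float(np.median(x)) if point is None else float(point)

    if method == "percentile":
        lo, hi = np.quantile(x, [alpha, 1.0 - alpha])
        return IntervalEstimate(pt, float(lo), float(hi), level, "percentile")

    if method == "bca":
        if point is None or jackknife_values is None:
            raise ValueError("bca needs the point estimate and jackknife values")
        jk = np.asarray(jackknife_values, dtype=float)
        # bias correction from the fraction of draws below the point estimate
        prop = np.clip(np.mean(x < pt), 1.0 / (x.size + 1), x.size / (x.size + 1.0))
        z0 = norm.ppf(prop)
        d = jk.mean() - jk
        denom = 6.0 * (np.sum(d**2)) ** 1.5
        a = float(np.sum(d**3) / denom) if denom > 0 else 0.0
        za, zb = norm.ppf(alpha), norm.ppf(1.0 - alpha)
        p_lo = norm.cdf(z0 + (z0 + za) / (1.0 - a * (z0 + za)))
        p_hi = norm.cdf(z0 + (z0 + zb) / (1.0 - a * (z0 + zb)))
        lo, hi = np.quantile(x, [p_lo, p_hi])
        return IntervalEstimate(pt, float(lo), float(hi), level, "bca")

    raise ValueError(f"unknown interval method {method!r}")


def param_interval(
    dist: BootstrapDistribution, name: str, level: float = 0.95,
    method: str = "percentile",
) -> IntervalEstimate:
    """Interval for a model parameter or derived parameter by name."""
    if name in dist.param_names:
        draws = dist.param_draws[:, dist.param_names.index(name)]
    elif name in dist.derived_draws:
        draws = dist.derived_draws[name]
    else:
        raise KeyError(f"{name!r} not a parameter of {dist.model_name}")
    pt = None
    if dist.point is not None:
        pt = dist.point.params.get(name, dist.point.derived.get(name))
    return interval(draws, level, method, point=pt)


def prediction_band(
    dist: BootstrapDistribution, temps, level: float = 0.95
) -> dict[str, np.ndarray]:
    """Pointwise bootstrap band around the fitted curve.

    Every replicate's curve is evaluated at ``temps``; the band endpoints
    are the pointwise (1 +- level)/2 quantiles across replicates.
    """
    if dist.n_kept == 0:
        raise DegenerateDataError("no converged bootstrap replicates")
    t = np.asarray(temps, dtype=float)
    truncate = dist.point.truncate if dist.point is not None else True
    curves = np.array([
        tpc_models.evaluate(dist.model_name, row, t, truncate=truncate)
        for row in dist.param_draws
    ])
    alpha = (1.0 - level) / 2.0
    lower = np.quantile(curves, alpha, axis=0)
    upper = np.quantile(curves, 1.0 - alpha, axis=0)
    out = {"temps": t, "lower": lower, "upper": upper}
    if dist.point is not None:
        out["point"] = tpc_models.evaluate(
            dist.model_name, dist.point.params, t, truncate=truncate
        )
    return out
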