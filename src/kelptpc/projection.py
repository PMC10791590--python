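"""Annual performance projection under ocean-warming scenarios.

A day-of-year sea-surface-temperature (SST) climatology is built from a
multi-year daily record, uniform warming offsets are applied (+3 C and
+4.5 C represent upper-end RCP 4.5 / RCP 8.5 projections for 2090), and
the fitted thermal performance curves are evaluated along the warmed
series.  Scenario output is the percentage change in performance relative
to the current scenario (ambient-CO2 fit at unshifted temperatures);
future scenarios use the elevated-CO2 fit, since a high-emissions future
is both warmer and CO2-enriched.  These are relative performance
projections only — seasonal light, daylength and nutrient drivers are
outside the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import tpc_models
from .fit_select import FitResult
from .uncertainty import BootstrapDistribution

#: scenario name by warming offset (C); Southern Hemisphere site
SCENARIO_NAMES = {0.0: "current", 3.0: "future", 4.5: "future_extreme"}

_MONTH_DAYS = [31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31]
_MONTH_NAMES = ["January", "February", "March", "April", "May", "June", "July",
                "August", "September", "October", "November", "December"]
_MONTH_EDGES = np.cumsum([0] + _MONTH_DAYS)


def month_of_day(day_of_year: int) -> str:
    """Calendar month of a day-of-year on the 365-day (no-leap) calendar."""
    if not 1 <= day_of_year <= 365:
        raise ValueError(f"day_of_year must be in 1..365, got {day_of_year}")
    return _MONTH_NAMES[int(np.searchsorted(_MONTH_EDGES, day_of_year, side="left")) - 1]


@dataclass
class SstClimatology:
    """Mean SST per day-of-year (1..365) over a span of years."""

    day_of_year: np.ndarray
    mean_sst_c: np.ndarray
    source_years: tuple[int, int]

    def __post_init__(self):
        self.day_of_year = np.asarray(self.day_of_year, dtype=int)
        self.mean_sst_c = np.asarray(self.mean_sst_c, dtype=float)
        if self.day_of_year.size != 365 or not np.array_equal(self.day_of_year, np.arange(1, 366)):
            raise ValueError("climatology must cover days 1..365 exactly")
        if not np.all(np.isfinite(self.mean_sst_c)):
            raise ValueError("climatology contains non-finite SST values")


@dataclass
class ScenarioProjection:
    scenario: str
    offset_c: float
    day_of_year: np.ndarray
    performance: np.ndarray
    pct_change: np.ndarray          # NaN on masked days
    masked: np.ndarray              # boolean; baseline within eps of zero
    ci_lower: np.ndarray | None = None
    ci_upper: np.ndarray | None = None


def _noleap_day_of_year(dates: pd.DatetimeIndex) -> np.ndarray:
    """Day-of-year on a 365-day calendar: Feb 29 folds onto day 59 (Feb 28),
    and later days of a leap year shift back by one."""
    doy = np.asarray(dates.dayofyear, dtype=int)
    leap = np.asarray(dates.is_leap_year)
    doy = np.where(leap & (doy >= 60), doy - 1, doy)
    return doy


def build_climatology(daily_records: pd.DataFrame) -> SstClimatology:
    """Per-day-of-year mean SST from a daily record with columns
    ``date`` (ISO-8601) and ``sst_c``.

    Raises if any day of year has no observations (gaps listed).
    """
    if not {"date", "sst_c"}.issubset(daily_records.columns):
        raise ValueError("daily records need columns 'date' and 'sst_c'")
    dates = pd.DatetimeIndex(pd.to_datetime(daily_records["date"]))
    sst = daily_records["sst_c"].to_numpy(dtype=float)
    doy = _noleap_day_of_year(dates)
    sums = np.zeros(365)
    counts = np.zeros(365, dtype=int)
    np.add.at(sums, doy - 1, sst)
    np.add.at(counts, doy - 1, 1)
    gaps = np.nonzero(counts == 0)[0] + 1
    if gaps.size:
        raise ValueError(f"no SST records for days of year: {gaps.tolist()}")
    years = (int(dates.year.min()), int(dates.year.max()))
    return SstClimatology(np.arange(1, 366), sums / counts, years)


def _curve(fit: FitResult, temps: np.ndarray) -> np.ndarray:
    return tpc_models.evaluate(
        fit.model_name, fit.params, temps, truncate=getattr(fit, "truncate", True)
    )


def project_scenarios(
    fit_current_co2: FitResult,
    fit_future_co2: FitResult,
    climatology: SstClimatology,
    offsets: tuple[float, ...] = (0.0, 3.0, 4.5),
    boot_current: BootstrapDistribution | None = None,
    boot_future: BootstrapDistribution | None = None,
    level: float = 0.95,
    eps: float = 1e-3,
) -> list[ScenarioProjection]:
    """Daily percentage performance change for each warming scenario.

    The baseline is the ambient-CO2 fit evaluated on the unshifted
    climatology; the offset-0 scenario uses that fit (0% change by
    construction) and warmed scenarios use the elevated-CO2 fit.  Days
    where the baseline performance is within ``eps`` of zero (relative to
    the annual maximum magnitude) are masked rather than divided by.
    Bootstrap bands propagate paired replicate curves through the same
    percentage formula, pointwise.
    """
    clim = climatology.mean_sst_c
    days = climatology.day_of_year
    baseline = _curve(fit_current_co2, clim)
    scale = float(np.max(np.abs(baseline)))
    if scale == 0:
        raise ValueError("baseline performance is identically zero")
    masked = np.abs(baseline) < eps * scale

    have_boot = boot_current is not None and boot_future is not None
    if have_boot:
        nrep = min(boot_current.n_kept, boot_future.n_kept)
        trunc_cur = getattr(fit_current_co2, "truncate", True)
        cur_reps = np.array([
            tpc_models.evaluate(boot_current.model_name, row, clim, truncate=trunc_cur)
            for row in boot_current.param_draws[:nrep]
        ])

    out = []
    for offset in offsets:
        name = SCENARIO_NAMES.get(float(offset), f"offset_{offset:g}")
        fit = fit_current_co2 if offset == 0 else fit_future_co2
        perf = _curve(fit, clim + offset)
        pct = np.where(masked, np.nan, 100.0 * (perf - baseline) / np.where(masked, 1.0, baseline))
        lo = hi = None
        if have_boot:
            boot = boot_current if offset == 0 else boot_future
            sc_reps = np.array([
                tpc_models.evaluate(
                    boot.model_name, row, clim + offset,
                    truncate=getattr(fit, "truncate", True),
                )
                for row in boot.param_draws[:nrep]
            ])
            with np.errstate(divide="ignore", invalid="ignore"):
                pct_reps = 100.0 * (sc_reps - cur_reps) / cur_reps
            alpha = (1.0 - level) / 2.0
            lo = np.where(masked, np.nan, np.nanquantile(pct_reps, alpha, axis=0))
            hi = np.where(masked, np.nan, np.nanquantile(pct_reps, 1 - alpha, axis=0))
        out.append(ScenarioProjection(
            scenario=name, offset_c=float(offset), day_of_year=days,
            performance=perf, pct_change=pct, masked=masked,
            ci_lower=lo, ci_upper=hi,
        ))
    return out


def summarize_projection(projection: ScenarioProjection) -> dict:
    """Peak percentage increase/decrease over the year and their months."""
    pct = projection.pct_change
    ok = ~projection.masked & np.isfinite(pct)
    if not np.any(ok):
        raise ValueError("all days are masked; no summary possible")
    days = projection.day_of_year[ok]
    vals = pct[ok]
    imax, imin = int(np.argmax(vals)), int(np.argmin(vals))
    return {
        "peak_increase_pct": float(vals[imax]),
        "peak_increase_day": int(days[imax]),
        "peak_increase_month": month_of_day(int(days[imax])),
        "peak_decrease_pct": float(vals[imin]),
        "peak_decrease_day": int(days[imin]),
        "peak_decrease_month": month_of_day(int(days[imin])),
    }


def projection_frame(projections: list[ScenarioProjection]) -> pd.DataFrame:
    """Long-format table (scenario, day, performance, pct_change, ci, masked)."""
    frames = []
    for p in projections:
        frames.append(pd.DataFrame({
            "scenario": p.scenario,
            "day_of_year": p.day_of_year,
            "performance": p.performance,
            "pct_change": p.pct_change,
            "ci_lower": p.ci_lower if p.ci_lower is not None else np.nan,
            "ci_upper": p.ci_upper if p.ci_upper is not None else np.nan,
            "masked": p.masked,
        }))
    return pd.concat(frames, ignore_index=True)
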