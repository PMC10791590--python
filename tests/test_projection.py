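"""SST climatology and warming-scenario performance projection."""

import numpy as np
import pandas as pd
import pytest

from kelptpc import fit_select, projection, tpc_models, uncertainty
from kelptpc.fit_select import FitResult

from conftest import oneill_dataset


def _fit(model_name, params):
    return FitResult(
        model_name=model_name, params=params, rmse=0.0, converged=True,
        n_points=0, predictions=np.empty(0),
        derived=tpc_models.derived_params(model_name, params, (0.0, 30.0)),
    )


ONEILL = {"rmax": 1.0, "topt": 16.0, "ctmax": 30.0, "q10": 2.0}


def _sinusoidal_clim(mean=14.5, amp=3.0, peak_day=32):
    d = np.arange(1, 366)
    return projection.SstClimatology(
        d, mean + amp * np.cos(2 * np.pi * (d - peak_day) / 365.0), (2002, 2020)
    )


class TestClimatology:
    def test_single_year_reproduces_input(self):
        dates = pd.date_range("2003-01-01", "2003-12-31", freq="D")
        sst = np.linspace(10, 20, 365)
        clim = projection.build_climatology(pd.DataFrame({"date": dates, "sst_c": sst}))
        np.testing.assert_allclose(clim.mean_sst_c, sst)

    def test_two_constant_years_average(self):
        frames = []
        for year, val in [(2003, 10.0), (2005, 12.0)]:
            dates = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
            frames.append(pd.DataFrame({"date": dates, "sst_c": val}))
        clim = projection.build_climatology(pd.concat(frames))
        np.testing.assert_allclose(clim.mean_sst_c, 11.0)

    def test_leap_year_folds_feb29(self):
        dates = pd.date_range("2004-01-01", "2004-12-31", freq="D")  # 366 days
        sst = np.full(366, 10.0)
        sst[59] = 20.0  # Feb 29
        clim = projection.build_climatology(pd.DataFrame({"date": dates, "sst_c": sst}))
        assert clim.mean_sst_c.size == 365
        assert clim.mean_sst_c[58] == pytest.approx(15.0)  # Feb 28+29 averaged
        assert np.all(clim.mean_sst_c[59:] == 10.0)

    def test_gaps_reported(self):
        dates = pd.date_range("2003-01-01", "2003-06-30", freq="D")
        with pytest.raises(ValueError, match="days of year"):
            projection.build_climatology(pd.DataFrame({"date": dates, "sst_c": 10.0}))


class TestProjectScenarios:
    def test_offset_zero_identity(self):
        fit = _fit("oneill_1972", ONEILL)
        clim = _sinusoidal_clim()
        (proj,) = projection.project_scenarios(fit, fit, clim, offsets=(0.0,))
        ok = ~proj.masked
        assert np.all(proj.pct_change[ok] == 0.0)
        np.testing.assert_allclose(proj.performance, tpc_models.evaluate("oneill_1972", ONEILL, clim.mean_sst_c))

    def test_constant_model_zero_change_any_offset(self):
        flat = _fit("quadratic", {"a": 2.0, "b": 0.0, "c": 0.0})
        clim = _sinusoidal_clim()
        projs = projection.project_scenarios(flat, flat, clim, offsets=(0.0, 3.0, 4.5))
        for p in projs:
            assert np.nanmax(np.abs(p.pct_change)) == 0.0

    def test_sign_pattern_under_warming(self):
        """With a summer peak above Topt, +3 C hurts the warmest months and
        helps the coolest ones."""
        fit = _fit("oneill_1972", ONEILL)
        clim = _sinusoidal_clim(mean=14.5, amp=3.5, peak_day=32)  # summer max 18 > topt 16
        projs = projection.project_scenarios(fit, fit, clim, offsets=(0.0, 3.0))
        p3 = projs[1]
        feb = slice(31, 59)
        jul = slice(181, 212)
        assert np.all(p3.pct_change[feb] < 0)
        assert np.all(p3.pct_change[jul] > 0)

    def test_warming_beyond_optimum_never_helps(self):
        fit = _fit("oneill_1972", ONEILL)
        d = np.arange(1, 366)
        clim = projection.SstClimatology(
            d, 17.0 + 2.0 * np.cos(2 * np.pi * d / 365.0), (2002, 2020)
        )  # entire year already at/above topt=16 after any positive offset
        projs = projection.project_scenarios(fit, fit, clim, offsets=(0.0, 3.0))
        assert np.all(projs[1].pct_change[~projs[1].masked] <= 1e-9)

    def test_invariant_to_common_rmax_rescaling(self):
        cur = _fit("oneill_1972", ONEILL)
        fut = _fit("oneill_1972", {**ONEILL, "rmax": 1.2, "topt": 17.0})
        cur2 = _fit("oneill_1972", {**ONEILL, "rmax": 5.0})
        fut2 = _fit("oneill_1972", {**ONEILL, "rmax": 6.0, "topt": 17.0})
        clim = _sinusoidal_clim()
        a = projection.project_scenarios(cur, fut, clim, offsets=(3.0,))[0]
        b = projection.project_scenarios(cur2, fut2, clim, offsets=(3.0,))[0]
        np.testing.assert_allclose(a.pct_change, b.pct_change, rtol=1e-9)

    def test_ci_band_brackets_point_series(self):
        ds_cur = oneill_dataset(noise_sd=0.08, seed=21)
        ds_fut = oneill_dataset(rmax=1.1, topt=17.0, noise_sd=0.08, seed=22)
        fit_cur = fit_select.fit_model(ds_cur, "oneill_1972")
        fit_fut = fit_select.fit_model(ds_fut, "oneill_1972")
        boot_cur = uncertainty.bootstrap_fit(ds_cur, "oneill_1972", B=100, seed=5, point=fit_cur)
        boot_fut = uncertainty.bootstrap_fit(ds_fut, "oneill_1972", B=100, seed=6, point=fit_fut)
        clim = _sinusoidal_clim()
        p = projection.project_scenarios(
            fit_cur, fit_fut, clim, offsets=(3.0,),
            boot_current=boot_cur, boot_future=boot_fut,
        )[0]
        ok = ~p.masked
        frac = np.mean((p.ci_lower[ok] <= p.pct_change[ok]) & (p.pct_change[ok] <= p.ci_upper[ok]))
        assert frac > 0.9


class TestSummarize:
    def test_extrema_bookkeeping(self):
        d = np.arange(1, 366)
        pct = np.zeros(365)
        pct[259] = 26.0   # day 260, September
        pct[30] = -10.0
        p = projection.ScenarioProjection(
            scenario="future", offset_c=3.0, day_of_year=d,
            performance=np.ones(365), pct_change=pct, masked=np.zeros(365, bool),
        )
        s = projection.summarize_projection(p)
        assert s["peak_increase_pct"] == 26.0
        assert s["peak_increase_month"] == "September"
        assert s["peak_decrease_pct"] == -10.0
        assert s["peak_decrease_month"] == "January"

    def test_matches_brute_force_extrema(self):
        rng = np.random.default_rng(3)
        pct = rng.normal(0, 10, 365)
        p = projection.ScenarioProjection(
            scenario="future", offset_c=3.0, day_of_year=np.arange(1, 366),
            performance=np.ones(365), pct_change=pct, masked=np.zeros(365, bool),
        )
        s = projection.summarize_projection(p)
        assert s["peak_increase_pct"] == pct.max()
        assert s["peak_decrease_pct"] == pct.min()

    def test_all_masked_errors(self):
        p = projection.ScenarioProjection(
            scenario="future", offset_c=3.0, day_of_year=np.arange(1, 366),
            performance=np.ones(365), pct_change=np.full(365, np.nan),
            masked=np.ones(365, bool),
        )
        with pytest.raises(ValueError):
            projection.summarize_projection(p)
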