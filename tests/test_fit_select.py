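"""NLS fitting, RMSE filtering, sensibility screening, and model selection."""

import numpy as np
import pytest

from kelptpc import fit_select, ingest, tpc_models
from kelptpc.errors import DegenerateDataError, SelectionError

from conftest import oneill_dataset


class TestRmse:
    def test_identical_vectors(self):
        assert fit_select.rmse([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_two_residuals(self):
        assert fit_select.rmse([3.0, 4.0], [0.0, 0.0]) == pytest.approx(np.sqrt(12.5))

    def test_single_residual(self):
        assert fit_select.rmse([2.0], [0.0]) == 2.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            fit_select.rmse([1.0], [1.0, 2.0])


class TestFitModel:
    def test_noise_free_recovery(self):
        ds = oneill_dataset(rmax=1.0, topt=16.0, ctmax=30.0, q10=2.0, noise_sd=0.0)
        fit = fit_select.fit_model(ds, "oneill_1972")
        assert fit.converged
        assert fit.rmse < 1e-6
        for name, truth in [("rmax", 1.0), ("topt", 16.0), ("ctmax", 30.0), ("q10", 2.0)]:
            assert fit.params[name] == pytest.approx(truth, rel=1e-3)

    def test_all_zero_dataset_returns_nonconverged(self):
        ds = ingest.ResponseDataset(
            response="growth", co2_level="current",
            temps_c=[5.0, 10.0, 15.0], values=[0.0, 0.0, 0.0],
            individual_ids=["a", "b", "c"],
        )
        fit = fit_select.fit_model(ds, "oneill_1972")
        assert not fit.converged

    def test_objective_beats_coarse_grid_oracle(self):
        """NLS objective must be at least as good as exhaustive grid search
        over a bounded box for a 3-parameter model (Yan-Hunt)."""
        rng = np.random.default_rng(42)
        for k in range(10):
            temps = np.array([5.57, 8.58, 12.82, 16.69, 20.04, 22.59, 25.63, 28.84])
            truth = tpc_models.evaluate(
                "yanhunt_1999", {"rmax": 1.0 + 0.2 * k, "topt": 14.0 + 0.5 * k, "tmax": 30.0}, temps
            )
            vals = truth + rng.normal(0, 0.1, temps.size)
            ds = ingest.ResponseDataset(
                response="growth", co2_level="current", temps_c=temps, values=vals,
                individual_ids=[str(i) for i in range(temps.size)],
            )
            fit = fit_select.fit_model(ds, "yanhunt_1999")
            assert fit.converged
            best_grid = np.inf
            for rmax in np.linspace(0.2, 3.5, 20):
                for topt in np.linspace(6.0, 24.0, 20):
                    for tmax in np.linspace(24.5, 40.0, 20):
                        pred = tpc_models.evaluate(
                            "yanhunt_1999", {"rmax": rmax, "topt": topt, "tmax": tmax}, temps
                        )
                        best_grid = min(best_grid, float(np.sum((pred - vals) ** 2)))
            assert np.sum((fit.predictions - vals) ** 2) <= best_grid + 1e-9

    def test_deterministic_given_seed(self):
        ds = oneill_dataset(noise_sd=0.1, seed=3)
        f1 = fit_select.fit_model(ds, "oneill_1972", fit_select.FitConfig(seed=7))
        f2 = fit_select.fit_model(ds, "oneill_1972", fit_select.FitConfig(seed=7))
        assert f1.params == f2.params


class TestRmseFilter:
    def _fake(self, name, rmse_val):
        return fit_select.FitResult(
            model_name=name, params={}, rmse=rmse_val, converged=True,
            n_points=5, predictions=np.zeros(5),
        )

    def test_two_percent_band(self):
        fits = [self._fake("a", 1.00), self._fake("b", 1.015), self._fake("c", 1.03)]
        kept = fit_select.filter_by_rmse(fits)
        assert [f.model_name for f in kept] == ["a", "b"]

    def test_single_fit_kept(self):
        fits = [self._fake("a", 2.0)]
        assert fit_select.filter_by_rmse(fits) == fits

    def test_ties_all_retained(self):
        fits = [self._fake("a", 1.0), self._fake("b", 1.0)]
        assert len(fit_select.filter_by_rmse(fits)) == 2

    def test_minimum_always_kept(self):
        rng = np.random.default_rng(0)
        fits = [self._fake(str(i), r) for i, r in enumerate(rng.uniform(0.5, 2.0, 20))]
        kept = fit_select.filter_by_rmse(fits)
        assert min(fits, key=lambda f: f.rmse) in kept

    def test_no_converged_fits_error(self):
        bad = fit_select.FitResult(
            model_name="x", params={}, rmse=float("inf"), converged=False,
            n_points=5, predictions=np.zeros(5),
        )
        with pytest.raises(SelectionError):
            fit_select.filter_by_rmse([bad])


class TestSensibility:
    def test_negative_prediction_fails_growth(self):
        ds = oneill_dataset(noise_sd=0.0)
        # concave quadratic that dips negative at the cold end of the range
        params = {"a": -4.0, "b": 0.5, "c": -0.01}
        fit = fit_select.FitResult(
            model_name="quadratic", params=params,
            rmse=0.1, converged=True, n_points=ds.n,
            predictions=tpc_models.evaluate("quadratic", params, ds.temps_c),
        )
        checked = fit_select.sensibility_check(fit, ds)
        assert not checked.sensible and "negative_prediction" in checked.reasons

    def test_monotone_curve_fails(self):
        ds = oneill_dataset(noise_sd=0.0)
        fit = fit_select.FitResult(
            model_name="quadratic", params={"a": 0.1, "b": 0.05, "c": 0.0},
            rmse=0.1, converged=True, n_points=ds.n,
            predictions=tpc_models.evaluate("quadratic", {"a": 0.1, "b": 0.05, "c": 0.0}, ds.temps_c),
        )
        checked = fit_select.sensibility_check(fit, ds)
        assert not checked.sensible and "no_interior_optimum" in checked.reasons

    def test_unimodal_nonnegative_passes(self):
        ds = oneill_dataset(noise_sd=0.0)
        fit = fit_select.fit_model(ds, "oneill_1972")
        checked = fit_select.sensibility_check(fit, ds)
        assert checked.sensible and not checked.reasons


class TestSelection:
    def _fit(self, name, rmse_val):
        return fit_select.FitResult(
            model_name=name, params={}, rmse=rmse_val, converged=True,
            n_points=5, predictions=np.zeros(5),
        )

    def test_explicit_biology_beats_quadratic(self):
        chosen = fit_select.select_model([self._fit("quadratic", 0.10), self._fit("oneill_1972", 0.101)])
        assert chosen.model_name == "oneill_1972"

    def test_single_admissible(self):
        only = self._fit("quadratic", 1.0)
        assert fit_select.select_model([only]) is only

    def test_full_explicit_tie_broken_by_rmse(self):
        chosen = fit_select.select_model([self._fit("oneill_1972", 0.2), self._fit("yanhunt_1999", 0.1)])
        assert chosen.model_name == "yanhunt_1999"

    def test_ctmax_breaks_topt_rmax_tie(self):
        # gaussian has explicit topt+rmax but no ctmax; yanhunt has all three
        chosen = fit_select.select_model([self._fit("gaussian_1987", 0.1), self._fit("yanhunt_1999", 0.2)])
        assert chosen.model_name == "yanhunt_1999"

    def test_empty_admissible_raises(self):
        with pytest.raises(SelectionError):
            fit_select.select_model([])

    def test_selection_deterministic(self):
        ds = oneill_dataset(noise_sd=0.1, seed=9)
        r1 = fit_select.select_for_dataset(ds, fit_config=fit_select.FitConfig(seed=1))
        r2 = fit_select.select_for_dataset(ds, fit_config=fit_select.FitConfig(seed=1))
        assert r1.chosen.model_name == r2.chosen.model_name
        assert r1.chosen.params == r2.chosen.params
        assert r1.rule_trace == r2.rule_trace


class TestQuadraticFit:
    def test_exact_interpolation(self):
        t = np.array([5.0, 10.0, 15.0, 20.0, 25.0])
        v = 1.0 + 2.0 * t - 0.1 * t**2
        a, b, c = fit_select.fit_quadratic(t, v)
        assert (a, b, c) == pytest.approx((1.0, 2.0, -0.1), abs=1e-10)

    def test_symmetric_data_vertex(self):
        t = np.array([12.0, 14.0, 16.0, 18.0, 20.0])
        v = -((t - 16.0) ** 2)
        a, b, c = fit_select.fit_quadratic(t, v)
        assert -b / (2 * c) == pytest.approx(16.0, abs=1e-8)

    def test_matches_general_nls(self):
        """Closed-form least squares agrees with the generic NLS path."""
        rng = np.random.default_rng(1)
        t = np.repeat(np.linspace(5, 29, 8), 5)
        v = -24.2 + 0.64 * t - 0.02 * t**2 + rng.normal(0, 0.5, t.size)
        a, b, c = fit_select.fit_quadratic(t, v)
        ds = ingest.ResponseDataset(
            response="d13c", co2_level="current", temps_c=t, values=v,
            individual_ids=[str(i) for i in range(t.size)],
        )
        nls = fit_select.fit_model(ds, "quadratic")
        assert nls.params["a"] == pytest.approx(a, abs=1e-6)
        assert nls.params["b"] == pytest.approx(b, abs=1e-6)
        assert nls.params["c"] == pytest.approx(c, abs=1e-6)

    def test_too_few_temperatures(self):
        with pytest.raises(DegenerateDataError):
            fit_select.fit_quadratic([5.0, 5.0, 10.0], [1.0, 1.1, 2.0])
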