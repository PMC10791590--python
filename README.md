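# kelptpc

Thermal performance curve (TPC) analysis for kelp CO₂ × temperature
experiments: from raw chamber measurements to fitted thermal optima,
bootstrap confidence intervals, seawater carbonate-system verification,
and annual performance projections under ocean-warming scenarios.

## The problem

Kelp forests are declining under ocean warming, and whether elevated CO₂
can offset thermal stress is an open question — kelps run a carbon
concentrating mechanism (CCM), so photosynthesis is near CO₂-saturated
today, but CCM down-regulation under high CO₂ could free energy for
thermal acclimation. The standard way to quantify thermal sensitivity is
the TPC: a unimodal curve of a physiological rate against temperature,
summarised by the thermal optimum *T*ₒₚₜ, the maximum rate *R*ₘₐₓ =
rate(*T*ₒₚₜ), and the critical thermal maximum CT*ₘₐₓ* where the rate
falls to zero.

`kelptpc` implements the complete analysis for a factorial design —
8 temperature treatments (≈6–29 °C) × 2 pCO₂ levels (≈420 / ≈1000 µatm) ×
5 replicate juvenile sporophytes over 21 days:

1. **ingest** — derive blade linear extension (mm d⁻¹), % wet-weight
   change, and blank-corrected net photosynthesis (µmol O₂ g⁻¹ h⁻¹) from
   raw hole-punch distances, weights and O₂ time points; flag dead
   individuals (negative net photosynthesis AND substantial tissue loss)
   and exclude them from photosynthesis datasets only.
2. **tpc_models** — a registry of nine commonly used TPC forms (O'Neill,
   Yan–Hunt, quadratic, Gaussian, modified Gaussian, Sharpe–Schoolfield
   with high-temperature inactivation, Ratkowsky, Brière-2, Thomas), with
   start-value heuristics and numeric extraction of *T*ₒₚₜ/*R*ₘₐₓ/CTₘₐₓ
   for models that do not expose them as parameters.
3. **fit_select** — bounded multi-start nonlinear least squares for every
   model, then rule-based selection: drop fits with RMSE > 1.02× the best,
   drop biologically non-sensical fits (negative growth predictions, no
   interior optimum), and among survivors prefer models with explicit
   *T*ₒₚₜ and *R*ₘₐₓ, then explicit CTₘₐₓ, then lowest RMSE. A closed-form
   quadratic fit handles δ¹³C vs temperature.
4. **uncertainty** — case-resampling bootstrap (resample individuals,
   refit from the point estimate) for percentile or BCa parameter CIs and
   pointwise prediction bands.
5. **carbonate** — solve the seawater CO₂ system from total alkalinity +
   total-scale pH (+T, S) for treatment verification: Lueker K1/K2,
   Dickson KB, Millero KW, Weiss K0, Uppström borate; closed-form DIC and
   pCO₂ plus a bracketed inverse (pH from AT + DIC) for round-trip checks.
6. **projection** — build a day-of-year SST climatology from a multi-year
   daily record, apply +3 °C / +4.5 °C offsets (upper RCP 4.5 / RCP 8.5
   projections), and express daily performance as % change relative to the
   current scenario, with bootstrap bands.
7. **synthetic_data** — generate raw-format experiments from known TPCs
   (defaults are this experiment's fitted point estimates) and synthetic
   SST series, so the whole pipeline is testable without external data.

## Worked example

```python
import numpy as np
from kelptpc import synthetic_data, ingest, fit_select, uncertainty

# simulate the factorial experiment and derive response variables
records, blanks = synthetic_data.simulate_experiment(
    synthetic_data.ExperimentSimConfig(seed=1))
datasets = {(d.response, d.co2_level): d
            for d in ingest.build_response_datasets(records, blanks)}

# fit all nine models to ambient-CO2 growth and select one
report = fit_select.select_for_dataset(datasets[("growth", "current")])
print(report.chosen.model_name,
      {k: round(v, 2) for k, v in report.chosen.derived.items()})

# bootstrap the thermal optimum
dist = uncertainty.bootstrap_fit(datasets[("growth", "current")],
                                 report.chosen.model_name, B=200, seed=2,
                                 point=report.chosen)
ci = uncertainty.param_interval(dist, "topt")
print(f"Topt {ci.point:.2f} C (95% CI {ci.lower:.2f}-{ci.upper:.2f})")
```

prints

```
oneill_1972 {'topt': 15.67, 'rmax': 0.97, 'ctmax': 34.53}
Topt 15.67 C (95% CI 15.10-16.72)
```

The selection chose the O'Neill curve (explicit *T*ₒₚₜ, *R*ₘₐₓ and CTₘₐₓ);
the fitted optimum ≈15.7 °C recovers the generating growth optimum of
16.05 °C within its bootstrap CI — a cool-edge kelp population whose
growth peaks well below summer maxima.

The same steps are available from a shell:

```bash
kelptpc simulate experiment --seed 1 --out-dir data/
kelptpc ingest --experiment data/experiment.csv --blanks data/blanks.csv --out data/responses.csv
kelptpc fit --responses data/responses.csv --out data/fits.json
kelptpc simulate sst --seed 2 --out data/sst.csv
kelptpc project --responses data/responses.csv --response growth --sst data/sst.csv --out data/projection.csv
```

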