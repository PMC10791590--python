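# Methods

This note documents the models, conventions and numerical choices behind
`kelptpc`, and what the synthetic-data generator does and does not
emulate.

## Response-variable derivation

Raw inputs are per-individual records from a 21-day factorial culture
experiment (8 temperature baths × 2 pCO₂ levels × 5 replicates).

- **Linear extension** (mm d⁻¹): displacement of a hole punched above the
  meristem, (d21 − d1)/Δt. Δt defaults to 20 days — photographs on day 1
  and day 21 bracket a 20-day interval — and is configurable, since the
  raw convention (20 vs 21 days) is a judgement call. Negative rates are
  retained; curve-level screening handles plausibility later.
- **Weight change** (%): 100 × (w21 − w1)/w1. Negative values are
  physical (erosion/tissue loss can exceed growth).
- **Net photosynthesis** (µmol O₂ g⁻¹ h⁻¹ wet weight): the O₂ change over
  a 3 h sealed incubation, minus the mean drift of the three alga-free
  blank chambers of the same treatment, scaled by chamber volume
  (0.26 L; algal displacement volume ignored) and normalised by the
  day-21 wet weight (the weighing contemporaneous with the incubation)
  and duration. Subtracting the blank mean makes the rate invariant to
  any drift common to sample and blanks.
- **Mortality rule**: an individual is dead iff net photosynthesis < 0
  AND weight change ≤ −50%. "Substantial tissue loss" is not a measured
  threshold, so −50% is a configurable convention. Dead individuals are
  excluded from net-photosynthesis datasets only (they would otherwise
  dominate the hot tail of the curve); growth, weight-change and tissue
  composition keep every individual.

Tables are validated row-by-row; offending rows are reported by CSV line
number and never silently dropped.

## TPC models

The registry holds nine commonly used closed-form TPC models: O'Neill,
Yan–Hunt, quadratic, Gaussian, modified (Weibull-type) Gaussian,
Sharpe–Schoolfield (high-temperature inactivation form, Tref = 15 °C,
Boltzmann constant in eV), Ratkowsky, Brière-2 and Thomas. This set
covers both families actually selected for these data (O'Neill and
Yan–Hunt) plus standard alternatives; the registry is extensible if a
different nine-model set is preferred.

O'Neill: rate = Rmax·((CTmax−T)/(CTmax−Topt))^x · exp(x·(T−Topt)/(CTmax−Topt)),
with w = (Q10−1)(CTmax−Topt) and x = (w²/400)(1+√(1+40/w))². Yan–Hunt:
rate = Rmax·((Tmax−T)/(Tmax−Topt))·(T/Topt)^(Topt/(Tmax−Topt)). Both have
explicit Topt, Rmax and a critical maximum; Gaussian variants have
explicit Topt/Rmax only; the rest expose none, and their Topt/Rmax/CTmax
are extracted numerically (fine grid + bounded refinement to 10⁻⁸ °C;
CTmax as the first zero above Topt by bracketed root finding, absent for
curves that never reach zero, e.g. Sharpe–Schoolfield).

**Truncation.** Models whose formula is undefined beyond the critical
maximum (negative base to a real power: O'Neill, Yan–Hunt, Ratkowsky,
Brière) return 0 there. For responses where negative values are physical
— weight change, net photosynthesis, δ¹³C — truncation is disabled where
the formula admits it: the Yan–Hunt negative branch beyond Tmax
represents net tissue loss at supra-critical temperatures and is
essential for describing the severe weight loss observed at the hottest
treatment. Temperatures are °C throughout (internal Kelvin conversion
where needed, offset 273.15).

## Fitting and selection

Nonlinear least squares uses scipy's trust-region-reflective solver with
parameter bounds (Rmax > 0; Topt within the observed range ± 5 °C;
CTmax/Tmax in (observed min, observed max + 15 °C]; Q10 ∈ (1, 10];
generous boxes for shape parameters), tolerances 10⁻⁸, and a multi-start
strategy: data-driven heuristic starts (Topt₀ = temperature of the
maximum observed rate, Rmax₀ = that rate, CTmax₀ = hottest temperature +
5 °C, Q10₀ = 2) plus 10 seeded ±20% multiplicative perturbations, best
converged solution kept. Convergence failure yields a flagged result, not
an exception. A unit test verifies the optimiser is never beaten by an
exhaustive 20³ grid over a bounded box.

Selection is a deterministic three-rule procedure:

1. **RMSE filter** — keep converged fits with RMSE ≤ 1.02 × the minimum.
   The rule is read as "within 2% of the best fit"; the alternative
   literal reading (> 0.02 × min excluded) would exclude every fit and
   contradict the rule's purpose.
2. **Sensibility screen** — reject fits predicting negative values on the
   observed range for non-negative responses (linear extension), and fits
   with no interior maximum within the observed range ± 1 °C (monotone
   curves are not thermal-performance patterns). Reason codes are kept.
3. **Parameter priority** — explicit Topt AND Rmax first, then explicit
   CTmax, then lowest RMSE, then registry order. The full rule trace is
   recorded so any selection can be audited.

δ¹³C vs temperature is fitted by exact closed-form quadratic least
squares (vertex −b/2c); it agrees with the generic NLS route to < 10⁻⁶.

## Bootstrap uncertainty

Case resampling: individuals are resampled with replacement (same n) and
the model refitted from the point estimate (single start — the replicate
likelihood is a perturbation of the original). Non-converged replicates
are dropped and counted; > 50% failures sets a warning flag. Intervals
default to percentile (numpy linear-interpolation quantile rule,
documented and fixed; ≥ 20 draws required) with BCa available (jackknife
acceleration); B defaults to 1999 where not specified. Prediction bands
are pointwise quantiles of replicate curves. All outputs are a pure
function of (dataset, model, B, seed). A simulation study (50 datasets of
the experimental design, noise 0.1 × Rmax, B = 200) checks that the 95%
Topt interval covers truth 85–100% of the time — the wide band reflects
small B and n, not a calibration target.

## Carbonate system

Inputs are total alkalinity (µmol kg⁻¹), pH on the total scale
(spectrophotometric pH is measured on that scale), temperature and
salinity. Constants: K1/K2 from Lueker et al. (2000) (Mehrbach refit,
total scale), KB Dickson (1990), KW Millero (1995), K0 Weiss (1974),
total borate linear in salinity (Uppström 1974). The transcriptions
reproduce the published check values at 25 °C, S = 35 (pK1 = 5.8472,
pK2 = 8.9660, ln KB = −19.7964, ln KW = −30.434, ln K0 = −3.5617) to the
printed precision, and the closed-form solve is cross-checked against an
independent numeric rooting of the full equilibrium system (frozen
fixture, agreement ≲ 0.01%). The alkalinity model excludes phosphate,
silicate and ammonia contributions (not measured here) — a documented
limitation of order a few µmol kg⁻¹. Surface pressure; pCO₂ without
fugacity correction, in µatm. The inverse solve (pH from AT + DIC)
brackets pH in [6, 9] and closes round trips to 10⁻⁶.

## Warming projection

The SST climatology is the per-day-of-year mean over the record's years
on a 365-day calendar (Feb 29 folded into Feb 28). Scenarios add uniform
offsets: 0 (current), +3 °C and +4.5 °C (upper-end RCP 4.5 / RCP 8.5 for
2090 in this region). The current scenario uses the ambient-CO₂ fit; both
warmed scenarios use the elevated-CO₂ fit, since the high-emissions
future is simultaneously warm and CO₂-enriched. Daily % change is
100 × (perf_scenario − perf_current)/perf_current; days where the
baseline is within 10⁻³ of its annual maximum magnitude are masked rather
than divided by. CI bands propagate paired bootstrap replicate curves
through the same formula and take pointwise 2.5/97.5% quantiles. Peaks
are per-day extrema (no smoothing), labelled with Southern Hemisphere
calendar months. These are relative-performance projections only: light,
daylength, nutrients and grazing are deliberately outside the model, so a
projected spring gain does not imply realized growth.

## Synthetic data generator

The generator emulates the experimental design: realized treatment means
5.57–28.84 °C, two CO₂ levels, 5 replicates, 3 blanks per cell. True
rates come from generating TPCs — defaults are the fitted point estimates
of this experiment (O'Neill growth 1.01 mm d⁻¹ at 16.05 °C ambient /
1.06 at 15.72 elevated; O'Neill net photosynthesis 4.65 at 16.67 /
7.48 at 18.44; Yan–Hunt ambient weight change 43.04% at 16.60 °C with
Tmax = 24.856 °C placed so the curve passes through the observed mean
−63.06% at 28.84 °C; O'Neill elevated weight change 50.95% at 14.80 °C).
Unreported shape parameters (CTmax = 30 °C, Q10 = 2) are fixed realistic
values for a kelp surviving to ≈29 °C. Additive Gaussian noise defaults
to 0.1 × |Rmax| per curve (0.5‰ for δ¹³C) — replicate scatter is a
convention, as no variance estimates exist to match. Raw fields are
back-calculated so ingest inverts them exactly (hole distance = d1 +
rate × 20; day-21 weight from % change; O₂ endpoint from rate, volume,
weight and the cell's simulated blank drift). Mortality at the hottest
bath is forced with probability 0.8 (ambient) / 0.4 (elevated), matching
the observed 4/5 and 2/5 dead: forced-dead individuals get negative net
photosynthesis and weight change capped at ≤ −55%. Additional "natural"
mortality can emerge when a drawn individual happens to satisfy the
mortality rule — that is by design, since death is diagnosed from the
measurements, not assigned.

What the generator does **not** emulate: within-chamber carbonate drift
(CO₂ enters only as a label and different generating parameters),
non-Gaussian or heteroscedastic replicate scatter, temperature logger
variation within a bath, and any covariance between responses of the same
individual. Passing tests therefore demonstrate correct inference under
idealised scatter of the right magnitude, not robustness to every feature
of real chamber data.

The SST simulator is a sinusoid (default mean 14.5 °C, amplitude 3 °C,
peak day 32 — early February, Southern Hemisphere summer, matching a
Tasmanian collection site) plus daily Gaussian noise (0.5 °C) over
2002–2020.

## Problem sizes

Default test and acceptance runs use the design sizes themselves (n = 40
per dataset), 50 simulated datasets for recovery/coverage studies, and
B = 200 bootstrap replicates in simulation studies (B = 1999 recommended
for final analyses); a 225-case grid exercises the carbonate round trip.

## Known limitations

- The nine-model registry is a standard set; if a different published
  nine-model list is required, register it and the selection logic is
  unchanged.
- O'Neill-type curves cannot represent negative rates beyond CTmax, so a
  response that truly goes negative there (ambient weight change) is
  better served by Yan–Hunt — the selection rules discover this, but only
  because the negative branch is retained for that response.
- BCa intervals need jackknife estimates; for the 40-point datasets here
  percentile intervals are the robust default.
- The % change projection is undefined where baseline performance ≈ 0;
  masked days are reported, not interpolated.
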