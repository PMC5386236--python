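# Methods

`chamberflux` implements the data-processing chain for a multichannel
automated soil-CO2-efflux chamber system deployed in a soil-warming
experiment, together with a synthetic campaign generator that emulates
the measurement system closely enough to exercise every downstream stage
with known ground truth.  This note records the models, the defaults and
their rationale, the numerical choices, and what the synthetic tests do
and do not demonstrate about real data.

## Measurement model

The system is a flow-through, non-steady-state design: each hour, 15
chambers close sequentially for 240 s each while chamber air circulates
through an infrared gas analyser (IRGA); the datalogger stores
10-s-averaged records of CO2 mole fraction, flow, pressure and
temperature.  Each chamber is therefore open 56 min and closed 4 min per
hour (93% open), and one closure yields 24 records.

Efflux follows from the rate of CO2 accumulation in the chamber
headspace.  With the ideal-gas molar density `P/(R·T)` and the effective
volume-to-surface ratio `V/S` (0.5 m for this geometry), the working
equation in kPa units is

    Rs = k · P_air / (T_air + 273.15) · dC/dt ,   k = 1000·(V/S)/R = 60.14

with `Rs` in μmol CO2 m⁻² s⁻¹ and `dC/dt` in ppm s⁻¹.  The package
always computes `k` exactly (60.1395… for V/S = 0.5) rather than using
the rounded constant, so the generator's inverse mapping and the flux
computation agree to floating precision; 60.14 is the 4-s.f. value.

Three slope estimators are provided:

* **linear** (default) — OLS slope of CO2 against closure time on the
  QC-retained records;
* **average** — mean of per-interval concentration changes ΔC/Δt over
  retained record pairs.  The normalisation divides by the number of
  intervals (n−1); a literal divide-by-n variant is kept as an option
  but is not recommended, since it biases the slope low by (n−1)/n.
  Interval slopes use actual record spacing, so gaps left by outlier
  removal do not bias the estimate;
* **full** — the dilution-corrected form in Pa units, adding
  `C/(1000−W)·dW/dt` to the concentration slope when a water-vapour
  series `W` (mmol mol⁻¹) is available.  The deployed IRGA cannot
  measure water vapour, so this path exists for synthetic closures and
  completeness; in the generator's humidity regime (vapour ramps around
  0.002 mmol mol⁻¹ s⁻¹) the correction stays below 1% of the flux, and
  with `dW/dt = 0` the full form reduces exactly to the linear model.

`P_air` must be the chamber-height ambient pressure.  The IRGA cell
pressure runs about 5 kPa above ambient in this class of system; using
it would inflate fluxes by ~5/101 ≈ 4.9%, which the tests assert as a
regression guard.

The air temperature entering the flux equation is the mean chamber air
temperature over retained records (configurable to first-record
temperature); when a chamber's sensor is missing, a site-level fallback
temperature can be supplied and the record is flagged `t_air_site`.

## Quality control

Per closure, in order:

1. **Dead band** — the first `k` records (default 3, i.e. 20–30 s) are
   discarded: lid-switching time and tubing lag make the initial rise
   non-representative.
2. **Iterative outlier rejection** — OLS of CO2 on time is fitted up to
   3 times in total (initial + two repeats, configurable); after each of
   the first two fits, records with |residual| > 3·sd(residuals) are
   removed and the regression repeated, stopping early when nothing is
   removed.  The criterion is applied at each pass.  A residual sd at or
   below 1e-9 ppm is treated as an exact line (floating rounding only):
   nothing is rejected and no division is performed.  If fewer than 10
   records remain (about half a closure — a conservative, configurable
   floor) the closure is unusable.
3. **Usability** — the closure is usable when the final fit's |Pearson
   r| ≥ 0.95 (threshold configurable; interpreted as correlation r, not
   R²) and enough records remain.  Near-zero fluxes are a special case:
   r is meaningless when the true slope is ~0, so a closure whose slope
   95% CI includes zero *and* whose residual sd is within the
   instrument-noise bound (default 1 ppm) is marked `usable_zero` and
   kept at its fitted (near-zero) flux.  Without this rule, cold-season
   fluxes would be discarded wholesale for having weak ramps.

All rejected indices carry a reason (`dead_band`, `outlier_pass1..n`,
`short_segment`), the retained/rejected sets always partition the
closure, and pipeline logs count records in/out per reason so the
filters can be audited.

## Treatment-level analysis

Chambers split into three treatment groups: control (total efflux, Rs),
trenched (roots excluded; heterotrophic respiration, Rh) and
warmed-trenched (Rhw).

* **Calibration (Qc)** — over a pre-treatment window (the experiment
  design provides 18 days before the warming onset),
  `Qc(group) = mean(all trenched) / mean(group)` using paired hours;
  the reference set is the ten trenched chambers (control excluded;
  configurable).  Multiplying each group by its Qc removes initial
  spatial heterogeneity between the two trenched groups.
* **Warming effect (Fe)** —
  `Fe = (Qcw·Rhw − Qch·Rh) / (Qch·Rh·(Tsw − Tsh)) × 100` in % °C⁻¹.
  The default applies the formula to period-mean calibrated fluxes and
  the period-mean temperature difference (the formula is written in
  mean quantities); a per-hour variant that averages hourly Fe values
  is provided since the aggregation order is ambiguous in principle.
* **Q10** — `ln R = a + b·T` by OLS on hourly pairs, `Q10 = exp(10 b)`,
  reference flux at `T_ref = 10 °C`.  Only positive fluxes enter the log
  fit (excluded count reported); the fit refuses temperature spans below
  5 °C or fewer than 30 points as unidentifiable.  Log-linear OLS is the
  default because multiplicative (lognormal) flux noise makes it the
  natural estimator; a nonlinear least-squares option is kept as an
  independent route and cross-checked in the tests.
* **Spatial variation** — per hour, CV = 100·sd/mean across a
  treatment's chambers (sample sd), averaged over hours; chambers can be
  excluded to quantify hot-spot sensitivity.  Hours with fewer than two
  chambers or near-zero mean are skipped and counted.
* **Aggregation** — 1 μmol m⁻² s⁻¹ sustained for 1 h = 12.011·3600·10⁻⁶
  = 0.04324 g C m⁻²; daily sums add exactly to the period total, and
  annualised figures scale the total to 365 days.  Missing hours may be
  filled from the fitted Q10 response driven by measured soil
  temperature (standard practice, clearly labelled, optional); the
  filled fraction is always reported.
* **Coverage** — a day counts as missing when fewer than a configurable
  fraction (default half) of expected closures are usable; percentages
  are reported to one decimal.

## Synthetic campaign generator

The generator's defaults are the study conditions; they are drawn from
the experimental site wherever a number is available.

* **Temperature** — a single seasonal sinusoid solved to pass exactly
  through the site's printed coldest/warmest monthly means (7.0 °C
  mid-January, 27.9 °C mid-August, peak mid-August), plus a diel
  sinusoid (3 °C amplitude in air, damped ×0.5 and lagged 2 h at 5 cm
  soil depth).  Warmed plots carry a +2.5 °C offset at 5 cm, the
  experiment's target level.
* **True flux** — `R = base(treatment) · offset_ch · Q10^((Ts−10)/10)`
  with Q10 = 2.5 and a control baseline of 2.0 μmol m⁻² s⁻¹ at 10 °C
  (back-computed from the experiment's multi-year mean annual efflux of
  ~15.7 t C ha⁻¹ at 17.6 °C mean temperature); the trenched baseline is
  0.75× control (the observed Rh/Rs ratio).  Per-chamber spatial offsets
  are lognormal (sd 0.2), with an optional large-multiplier hot-spot
  chamber.  Warmed-trenched chambers are multiplied by `1 + Fe·ΔT/100`
  (Fe default 9.4% °C⁻¹) after the warming onset, with the Q10 response
  evaluated at the *unwarmed* temperature — this keeps Fe an independent
  dial rather than a consequence of Q10, which is what the recovery
  experiments require.  Soil moisture is generated as forcing (base 0.30
  with exponentially decaying rain pulses) but is *not* wired into the
  flux truth by default, because no functional form is established for
  this site; an optional multiplicative modifier exists, off by default.
* **Records** — concentration ramps invert the working equation
  (slope = R·(T+273.15)/(k·P)), start from a 400 ppm ambient baseline,
  and carry i.i.d. Gaussian noise (sd 0.5 ppm, an upper bound for
  10-s-averaged readings from this class of IRGA).  Dead-band records
  sit near ambient with ~1 ppm jitter, deviating from the back-
  extrapolated ramp.  Rare electrical spikes (rate 10⁻³ per record,
  ±10–20 ppm) are injected and logged.  Site pressure is 99.8 kPa
  (~130 m a.s.l.) with a slow synoptic wobble; the recorded cell
  pressure is ambient + 5 kPa.  Meteorology is held constant within a
  single 240-s closure, which is what makes the zero-noise round-trip
  exact.
* **Faults** — pump stoppage (reading plateaus for about half the
  closure, then decays toward ambient with a ~150 s time constant while
  the flow column collapses to ~0), lid leak (ramp attenuated with a
  concave saturating shape; zero attenuation is the identity) and fan
  failure (record scatter inflated ~8×).  The pump-stop shape parameters
  were set so faulty closures show the fit quality that characterises
  real faults on this kind of system (R² well below 0.9, versus >0.99 in
  normal operation).  Every injected fault and spike is logged in the
  truth bundle with chamber and timestamp.

Everything is driven by one `numpy` generator seeded from the campaign
seed; identical configuration and seed give byte-identical output files.

### What the generator does not emulate

Real campaigns include synoptic weather (fronts, rain-driven flux
pulses), moisture limitation of respiration, drifting IRGA calibration,
autocorrelated sensor noise, thermocouple failures and datalogger gaps.
Passing the synthetic recovery tests therefore demonstrates the
*correctness of the computation chain* — that the implemented equations,
filters and estimators recover known parameters under the stated noise
model — not that the pipeline is robust to every failure mode of field
data.  The QC power results in particular are conditional on the fault
phenomenology described above.

## Numerical choices and problem sizes

* OLS fits use closed-form sums per closure (the per-closure problem is
  24 points); residual sd uses the sample (n−1) normalisation, as does
  the CV.
* Slopes are computed against actual record timestamps, never an assumed
  10-s grid, so short or gappy segments are handled correctly.
* Segmentation splits at every chamber-id change, at time gaps larger
  than 1.5 record intervals (interrupted closures are never merged
  across a gap) and at cycle boundaries; segments shorter than 12
  records are flagged.
* File round-trips are lossless: floats are written at full shortest
  round-trip precision and parsed with round-trip precision.
* The recovery experiments in the test suite run at sizes chosen to make
  sampling error small relative to the tolerances while staying
  desk-scale: a one-year, 15-chamber campaign (~3.2 M records, ~131 k
  closures) for model agreement and warming-effect recovery; 50
  year-long hourly replicates for the Q10 bias study; a one-week
  campaign with 100 injected faults for QC power.

## Known limitations

* The raw-file dialect is a documented stand-in; the original deposited
  files' column layout and missing-value sentinel are not public in a
  machine-readable form.  Real files are supported by supplying a column
  map in the `Dialect`, not by auto-detection.
* Only linear (and interval-mean) flux models are implemented; curvature
  corrections for long closures are out of scope because 240-s closures
  on this system show no concave-downward saturation.
* The warming multiplier is linear in ΔT; treating Fe as
  temperature-independent is a modelling convenience mirrored by the
  estimator, not a mechanistic claim.
* `usable_zero` closures report their fitted near-zero slope as the
  flux; with a very noisy instrument this admits small spurious fluxes,
  bounded by the configured noise bound.
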