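# Methods

## Scope and model chain

`pkusim` predicts the plasma-Phe-lowering effect of an orally administered
PAL-expressing bacterium in PKU patients. Three deterministic ODE models are
chained: whole-cell PAL kinetics → upper-GI transit → blood Phe metabolism.
Only the PAL pathway of the strain is modelled; the strain's second
Phe-consuming enzyme (LAAD) has no validated in vivo biomarker and is out of
scope, so lowering predictions are conservative. Enterorecirculation of
systemic Phe into the lumen, gastric killing of cells, in vivo replication,
and labelled-tracer bookkeeping are likewise not modelled.

## Whole-cell PAL kinetics

Each cell is treated as one enzyme equivalent; the rate law is
Michaelis–Menten in Phe with two multiplicative inhibition factors:

    v = Vmax/(1 + Km/Phe) * Cells * Ki_pH * Ki_TCA        [umol/(mL min)]

* `Km = 0.0184 umol/mL` (95 % CI 0.005–0.0442), `Vmax = 0.0162
  umol/(min·1e9 CFU)` (95 % CI 0.0154–0.0171), estimated from whole-cell
  rate assays; cells enter in units of 1e9 CFU/mL, scaled explicitly to avoid
  silent unit errors.
* `Ki_pH = clamp(0.25*pH − 0.7, 0, 1)`. The raw line is negative below pH 2.8
  and exceeds 1 above pH 6.8; both are unphysical for a multiplier with a
  stated (0–1) range, so it is clamped. This makes stomach PAL activity shut
  off entirely once postprandial gastric pH falls below 2.8.
* `Ki_TCA = 0.67*exp(−0.53*TCA_mM) + 0.33`: product inhibition saturating at
  a 67 % loss of activity. TCA enters in mM (= umol/mL), matching the 0–8 mM
  calibration range; compartment amounts are converted upstream.
* During batch and GI simulations `Ki_TCA` is evaluated at the instantaneous
  TCA concentration — de novo product is assumed to inhibit identically to
  the exogenous TCA used in calibration.

The batch simulator integrates the closed system (dPhe/dt = −v,
dTCA/dt = +v) with LSODA at rtol 1e−9/atol 1e−12; Phe + TCA is conserved to
integrator tolerance and an independent fixed-step Euler oracle (dt = 0.001
min) agrees within 0.5 % over 2 h in the test suite.

### Fitting

Three fitters recover the coefficients from rate datasets: trust-region
nonlinear least squares (multi-start, 3 starts spread around
method-of-moments initial guesses, ftol/xtol/gtol 1e−14) for the
Michaelis–Menten and exponential-decay forms, and OLS for the pH line.
R² = 1 − SS_res/SS_tot; 95 % CIs are asymptotic Wald intervals from the
Jacobian with a t-quantile on n − p degrees of freedom. Degenerate inputs
(constant response, flat decay, too few distinct levels) are rejected or
flagged rather than silently fitted.

In vitro rates in the calibration assays are endpoint-derived
(product at 60 min ÷ 60 min); at the assay cell density (2.5e7 CFU/mL)
substrate depletion within the hour is ≤ 7 % even at the lowest
concentration, so the endpoint rate is a close but not exact proxy for the
initial rate. The fixtures generator therefore evaluates the instantaneous
rate law by default (giving exact fit round-trips) and offers the endpoint
convention (`endpoint_min=60`) where the assay's small depletion bias is the
object of study.

## Upper-GI transit

Two well-mixed compartments, stomach and small intestine (SI); state is
amounts (umol, CFU), horizon 360 min (the urine-collection window used for
validation against urinary hippurate).

* **Gastric emptying**: fraction remaining `f(t) = 2^(−(t/t_half)^beta)`
  (liquid meal: beta = 1.12, t_half = 43 min human; 24.5 min NHP). The ODEs
  drain each stomach species at the hazard `k(t) = −f'(t)/f(t)`, so a pure
  tracer decays exactly along f(t). The printed transfer term −(df/dt·X) is
  dimensionally a rate only under this hazard reading (with df/dt < 0 it
  would otherwise grow the stomach); the hazard form is the implementation.
  Cells, Phe and TCA co-empty with the liquid phase.
* **Gastric pH**: `(pH0 − pH_min)·exp(−k_pH·t) + pH_min` (human: 6.0 → 1.71,
  k = 0.02653 /min). Stomach PAL flux uses this pH; SI pH is fixed (6.5
  human, 5.8 NHP).
* **Absorption**: first-order loss of SI Phe and TCA at λ = 0.1019 /min into
  cumulative absorbed accumulators; TCA absorption is assumed identical to
  Phe (no TCA-specific data). SI emptying is not modelled over 6 h.
* **Concentration basis**: Km/Ki terms need concentrations. Stomach liquid
  volume is the fasted 35 mL plus the 100 mL dose vehicle scaled by f(t)
  (the vehicle empties with the contents); SI volume is fixed at 54 mL. The
  source physiology leaves this basis unspecified; this is a declared package
  choice. NHP runs use the fasted stomach volume only (vehicle volume
  unstated for NHP studies).
* **Dosing**: a dose of CFU and a meal of Phe (g ÷ 165.19 g/mol → umol)
  initialise the stomach. Predicted urinary HA (umol) equals total TCA
  produced, assuming 1:1 TCA→HA stoichiometry and complete urinary recovery;
  the optional mg display conversion uses the HA molar mass 179.17 g/mol.
* **Integrator**: LSODA, rtol 1e−8/atol 1e−10, 1-min output grid. Mass
  balance (Phe + TCA pools + absorbed) and cell conservation hold to 1e−6
  relative; a dt = 0.01 min Euler oracle agrees within 0.5 % at 360 min.
* **Uncertainty**: HA and downstream lowering bands re-run the pipeline at
  the CI corner kinetics (low Km, high Vmax) = upper activity bound and
  (high Km, low Vmax) = lower bound, treating the marginal CIs as
  independent.

## Blood Phe metabolism

State: plasma Phe (mmol/L) and a gut depot (mg). Time in hours.

    dGut/dt = −Ka_gut·Gut                       (+ meal boluses)
    dPhe/dt = Ka_gut·Gut/(MW·Vd·W) + V_npd − V_PAH − V_trans − V_renal

    V_PAH   = Vmax_PAH·F_PAH / (1 + Km_PAH/Phe + Km_PAH·Ka_PAH/Phe²)
    V_trans = Vmax_trans / (1 + Km_trans/Phe)
    V_renal = Phe·CL_renal·Vd

Defaults: Ka_gut 0.25 /h, V_npd 0.012 (mmol/L)/h, Vmax_PAH 0.9 (mmol/L)/h,
Km_PAH 0.51 mmol/L, Ka_PAH 0.54 mmol/L (substrate activation), Vmax_trans
0.063 (mmol/L)/h, Km_trans 1.37 mmol/L, CL_renal 5.696e−4 (L/kg)/h, Vd 0.5
L/kg, W 70 kg, MW 165.19 g/mol. The renal term is implemented literally as
printed in its source even though its unit composition does not reduce
cleanly; the resulting ≈1 % renal share of elimination at PKU steady state
matches the source's own attribution, confirming the literal reading.

* **Meals**: 2.5 g Phe/day split equally across meals at 0, 4 and 10 h
  (relative to 8:00 AM) is the standard scenario; boluses are instantaneous
  additions to the gut depot and the solver restarts at each discontinuity
  (LSODA, rtol 1e−8/atol 1e−10, 0.1 h output grid).
* **Luminal removal**: a Phe-consuming agent is represented by removing
  mg (or a fraction) from each bolus before it enters the depot, clipped at
  the meal content.
* **Readout**: fasting plasma Phe 14 h after the last (10 h) meal — 8:00 AM
  the next morning — converted to µmol/L. Steady-state scans run 180 days;
  the trajectory is periodic (day-to-day drift < 0.1 %) long before that, so
  results are initial-condition independent. PKU scans start at 1.18 mmol/L,
  healthy-subject runs at 0.06 mmol/L.
* **Heterozygote**: residual PAH activity is not specified for carriers;
  F_PAH = 0.5 is the conventional assumption used here.
* **Inversion**: the removal (mg/day) achieving a target % lowering is found
  by bracketed root-finding (Brent, 1 mg tolerance) over 180-day simulations;
  targets beyond the lowering achievable at 100 % removal raise a domain
  error.
* **Attribution**: elimination shares integrate each flux over the final
  simulated day by the trapezoidal rule on the output grid.

## Combined dose–response

Dosing is three-times daily with meals for 28 days (long enough for
pseudo-steady state — intra-day meal variation, no day-to-day drift). Each
administration is simulated independently with the GI model over its full 6 h
horizon using the meal's own Phe content (2.5/3 ≈ 0.833 g) as substrate;
identical meals mean one GI run scaled by three. Consumed µmol → mg
(× 165.19/1000), capped at the daily diet, and removed per meal from the
blood-model boluses. Percent lowering compares day-28 fasting Phe with and
without removal; the CI band repeats the whole pipeline at the kinetic corner
sets. The per-meal GI substrate for combined runs is not pinned down by the
source physiology; using the meal's own Phe content is the package's choice,
and the coupling itself adds no dynamics (lowering at a fixed removal equals
the direct diet-reduction scan within 0.1 percentage points, verified in the
tests).

## Synthetic data generator

`fixtures` emulates the three calibration assays (rate vs Phe at the 8-level
two-fold dilution 0.312–40 mM; relative activity vs pH at 4–7; relative
activity vs TCA at 0–8 mM) and the 2 h gastric-simulation time course at
2.5e9 cells/mL, each with multiplicative lognormal noise
(σ = √log(1+CV²), median on the model curve) at a default assay-like CV of
15 % and 3 replicates. The pH flavor emits the unclamped line — the clamp
belongs to the inhibition term, not to relative-activity measurements.
What the generator does *not* emulate: LC-MS/MS error structure,
between-batch cell-density variation, or real-assay substrate depletion
(unless `endpoint_min` is set). Passing recovery tests therefore show the
fitters are correct and calibrated under idealised noise, not that real-assay
estimates carry these error bars. One consequence measured during test
calibration: because the rate design sits entirely above the true Km,
individual Km estimates under 15 % noise are weakly identified (CIs are wide
and honest — 94.5 % coverage over 200 seeds — but point estimates scatter
several-fold), so the recovery suite asserts CI coverage, Vmax accuracy, and
median-Km accuracy rather than per-seed Km precision.

## Numerical choices and limitations

* All simulations are deterministic; seeds affect only synthetic-data noise.
* LSODA throughout (the GI system stiffens as gastric pH crosses the Ki_pH
  clamp); tolerances as above; clamped non-negative state inside RHS
  evaluations guards against tiny negative excursions.
* Problem sizes: steady-state scans use 180-day horizons and dosing runs 28
  days, matching the scenarios the scans represent; a 180-day run integrates
  540 meal-to-meal segments in well under a second.
* The models carry population-average physiology — no inter-individual
  variability, no adherence effects, constant viable dose (no gastric
  killing or replication). Predictions are point estimates with
  kinetic-parameter bands, not population intervals.
* Healthy-subject postprandial kinetics are reproduced qualitatively;
  elimination returns to baseline somewhat slower in the model than in
  observed healthy-subject data, a known limitation of the elimination
  parameterisation at low Phe.
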