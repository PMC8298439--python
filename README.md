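# pkusim

Mechanistic simulation of an orally dosed, phenylalanine-consuming engineered
bacterium (a "synthetic biotic") and of blood phenylalanine (Phe) dynamics in
phenylketonuria (PKU).

PKU patients lack functional phenylalanine hydroxylase (PAH) and accumulate
toxic plasma Phe from dietary protein. An engineered *E. coli* strain
expressing phenylalanine ammonia lyase (PAL) consumes Phe in the gut lumen,
converting it to trans-cinnamic acid (TCA), which the host excretes in urine
as hippuric acid (HA). `pkusim` answers the development question behind such a
therapeutic: **given a dose in CFU, how much does plasma Phe fall?** It does
so with three chained mechanistic models:

1. **Whole-cell PAL kinetics** (`pal_kinetics`) — Michaelis–Menten conversion
   of Phe to TCA with pH and product inhibition:

   $v = \dfrac{V_{\max}}{1 + K_m/\mathrm{Phe}}\cdot \mathrm{Cells}\cdot
   K_{i,\mathrm{pH}}\cdot K_{i,\mathrm{TCA}}$,
   with $K_{i,\mathrm{pH}} = \mathrm{clamp}(0.25\,\mathrm{pH} - 0.7,\,0,\,1)$ and
   $K_{i,\mathrm{TCA}} = 0.67\,e^{-0.53\,\mathrm{TCA}} + 0.33$.

   Includes closed-batch (simulated gastric fluid) simulation and nonlinear
   fitters for all coefficients from rate data.

2. **Upper-GI transit** (`gut_transit`) — a two-compartment stomach/small-
   intestine ODE system: power-exponential gastric emptying
   $f(t) = 2^{-(t/t_{1/2})^\beta}$, postprandial gastric pH decay, PAL activity
   in both compartments, and first-order intestinal absorption of Phe and TCA.
   Output: predicted urinary HA (1:1 with TCA produced) over a 6 h window, for
   human or non-human-primate physiology.

3. **Blood Phe metabolism** (`blood_phe`) — plasma Phe driven by meal
   absorption from a gut depot, net protein breakdown, PAH (with substrate
   activation, scaled by residual activity $F_\mathrm{PAH}$), transaminase,
   and renal elimination. The clinical readout is fasting plasma Phe 14 h
   after the last meal.

`dose_response` couples (2) and (3): per-meal luminal Phe consumption from the
GI model is removed from each meal bolus in the blood model, yielding percent
plasma-Phe lowering versus dose with 95 % CI bands propagated from the PAL
Km/Vmax confidence intervals. `fixtures` generates synthetic calibration
datasets with known ground truth for parameter-recovery testing.

## Worked example

```python
from pkusim import (MealSchedule, simulate_blood, fasting_phe,
                    DoseRegimen, predict_lowering)

# untreated classical PKU (0% PAH) on 2.5 g Phe/day in three meals
res = simulate_blood(days=180, schedule=MealSchedule(daily_phe_g=2.5), f_pah=0.0)
print(f"fasting plasma Phe: {fasting_phe(res):.0f} umol/L")

# three-times-daily dosing with meals for 28 days
for dose in (1e11, 2e12):
    p = predict_lowering(DoseRegimen(dose_cfu=dose))
    print(f"dose {dose:.0e} CFU TID: consumes {p.consumed_mg_day:.0f} mg Phe/day, "
          f"lowers fasting Phe {p.pct_lowering:.1f}% "
          f"[{p.lowering_lo:.1f}, {p.lowering_hi:.1f}]")
```

prints

```
fasting plasma Phe: 1154 umol/L
dose 1e+11 CFU TID: consumes 149 mg Phe/day, lowers fasting Phe 6.5% [6.0, 7.0]
dose 2e+12 CFU TID: consumes 953 mg Phe/day, lowers fasting Phe 35.6% [34.7, 36.5]
```

The untreated patient sits near 1150 µmol/L — far above the recommended
range — and a 2 × 10¹² CFU dose three times daily is predicted to consume
most of each meal's Phe before absorption, lowering fasting Phe by about a
third. The bracketed band reflects the 95 % CIs on the whole-cell PAL Km and
Vmax.

The same pipelines are scriptable from the shell:

```sh
pkusim blood scan --reductions 0.2,0.3,0.5 --out scan.csv
pkusim gi simulate --dose 1e11 --meal-phe-g 2.0 --out traj.csv
pkusim combined dose-response --doses 1e11,5e11,2e12 --out curve.csv
```

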