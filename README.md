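# adwarn — early-warning analysis for corn-stalk anaerobic digestion

`adwarn` is an analysis package for studying **early-warning indicators of
process failure in anaerobic digestion (AD)** of lignocellulosic feedstock
(corn stalk) in continuously stirred tank reactors (CSTRs). It couples two
things a process engineer needs when deciding which indicator to monitor
and what relative change should trigger an alarm:

1. a **kinetic bioconversion model** of the digester — first-order
   hydrolysis of degradable particulate organics, five Monod microbial
   groups (acidogens, propionate and butyrate degraders, acetoclastic and
   hydrogenotrophic methanogens), noncompetitive inhibition of acetoclastic
   methanogens by the *total* volatile fatty acid (VFA) pool
   (Ki ≈ 315–365 mg/L) and by free ammonia, charge-balance pH, and
   gas–liquid transfer to a vented headspace; and
2. an **indicator-screening pipeline** that turns daily series (CH₄ yield,
   CH₄/CO₂, individual and total VFA, pH, and the titration alkalinities
   TA/IA/BA with their coupled ratios IA/BA, BA/TA, VFA/BA) into
   abrupt-change days, failure days, warning times and amplitude
   thresholds.

## The statistics at the core

Fluctuation between consecutive days is measured by the pairwise relative
standard deviation

    RSD = S / x̄ × 100 %,   S = √((x_t − x̄)² + (x_{t−1} − x̄)²),

with x̄ the two-day mean (equivalently RSD = |x_t − x_{t−1}|/(√2·x̄)·100).
RSD > 10 % marks a slightly unstable process and RSD > 20 % (in the
indicator's acidification direction) an **abrupt change**. **Failure** is
the first day with pH < 6.4 or a >20 %-RSD drop in CH₄ yield. **Steady
state** is ≥ 6 consecutive days of biogas production within ±10 % of the
period mean. The **warning time** of an indicator is the number of days
its abrupt change precedes failure, and its **amplitude** relative to a
steady-state extreme x* is (x_ref − x*)/x* × 100 %. Simulation accuracy is
scored with rRMSE and MAPE over configurable day windows.

Because no machine-readable daily measurements exist for this system, the
`adwarn.synthetic` module is a first-class component: it generates the
reactor operating schedules, noisy simulated measurements (multiplicative
lognormal noise, additive for pH), engineered overload fixtures with known
event days, and parameter-recovery datasets with a hidden Ki.

## Worked example

Simulate reactor R1 (25-day HRT, organic loading stepped 1.50 → 2.24 →
2.99 g VS/(L·day), recovery week, then a sudden overload ramp to
3.37 g VS/(L·day)) and screen an engineered gradual-overload dataset:

```bash
python analysis/01_simulate_reactors.py
python analysis/02_screen_indicators.py
```

which prints, for the full-load plateau,

```
R1 (Ki=315 mg/L): full-load days 26-100: CH4 yield 0.200 L/g VS, CH4 content 60.4 %,
total VFA 0.093 g/L, pH 6.96
```

— a healthy digester: about 0.20 L CH₄ per g volatile solids fed, ~60 %
CH₄ in the biogas, residual VFA below 0.1 g/L — and, from the screening of
the R1 gradual-overload fixture,

```
screening mode: experimental
process failure day: 112
  [101-113] ia_ba      abrupt=105 warn=7  amplitude=+60% to +60% risk=YES
  [101-113] vfa_total  abrupt=109 warn=3  amplitude=+60% to +60% risk=YES
  [101-113] BA         abrupt=107 warn=5  amplitude=-35% to -35% risk=YES
```

— the alkalinity ratio IA/BA moves 7 days before failure under gradual
overload, total VFA 3 days; under the sudden-overload fixture
(`screening_r1_sudden.csv`) the ranking flips: VFA leads by 12 days while
the alkalinity indicators respond only 1–2 days ahead. The `risk=YES`
flags fire when an indicator's amplitude versus steady state crosses its
configured threshold (defaults: IA/BA +10 %, total VFA +51 %, IA +20 %,
BA −11 %, VFA/BA +30 % for experimental data).

The remaining drivers evaluate simulation accuracy (rRMSE/MAPE tables,
`analysis/03_goodness_of_fit.py`) and the identifiability of the VFA
inhibition constant from noisy data (`analysis/04_parameter_recovery.py`,
recovering Ki = 315 mg/L to −0.0 % noiseless and +6 % at 5 % measurement
noise).

A thin CLI wraps the same functions:

```bash
adwarn simulate --schedule r1 --ki 315 --out sim.csv
adwarn synth fixture --preset r1_gradual --out fixture.csv
adwarn screen --input fixture.csv --schedule R1 --mode experimental --out report/
adwarn gof --exp exp.csv --sim sim.csv --windows 0:165,30:165 --out gof.csv
```

## Layout

```
src/adwarn/        biomodel, chemistry, indicators, gof, synthetic, io, cli
analysis/          numbered narrative drivers writing to results/
tests/             pytest suite (unit, property and end-to-end checks)
docs/methods.md    model equations, parameter choices, limitations
```
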