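# Methods

This note documents the models, rules and numerical choices implemented in
`adwarn`, the defaults shipped with it, and what the synthetic data do and
do not establish.

## 1. Kinetic bioconversion model (`adwarn.biomodel`)

### Structure

The digester is a completely stirred tank reactor (CSTR): every dissolved
and suspended pool obeys dC/dt = D·(C_in − C) + r(C), with dilution rate
D = 1/HRT and reaction terms r. The biological network is the classical
staged description of anaerobic digestion:

1. **Hydrolysis** — degradable particulate organics X_carb break down to
   soluble monomers at a first-order rate k_hyd·X_carb.
2. **Acidogenesis** — acidogens ferment monomers to acetate, propionate,
   butyrate and H₂ (catabolic COD fractions 0.50/0.15/0.25/0.10).
3. **Acetogenesis** — propionate degraders (products 0.57 acetate /
   0.43 H₂ on a COD basis) and butyrate degraders (0.80/0.20).
4. **Methanogenesis** — acetoclastic methanogens (acetate → CH₄) and
   hydrogenotrophic methanogens (H₂ + CO₂ → CH₄).

Each group g grows at μ = μ_max·S/(K_S+S)·F_pH·(inhibition factors) and
decays at first order; decay products return to the soluble monomer pool
with their nitrogen mineralizing to ammonia. Two structural choices
define this variant of the model family:

* **ammonia is never a growth substrate** — corn stalk carries almost no
  nitrogen, so ammonia enters only the charge balance and the free-NH₃
  inhibition term; and
* **acetoclastic methanogens are inhibited by the total VFA pool**
  (acetate + propionate + butyrate in mg/L), noncompetitively:
  F = 1/(1 + VFA/Ki), with Ki = 315 mg/L (R1 configuration) or 365 mg/L
  (R2). A config switch (`vfa_inhibitor_free_acid_only`) restricts the
  inhibitor to the undissociated acids instead; the default is the total
  (dissociated + undissociated) sum, the simplest reading of "total VFA".

pH inhibition uses the two-sided form customary in this model family,
F(pH) = (1 + 2·10^{0.5(pKl−pKh)}) / (1 + 10^{pH−pKh} + 10^{pKl−pH}),
which equals 1 exactly at the midpoint of (pKl, pKh) and is symmetric
about it.

### COD-consistent stoichiometry

All reaction stoichiometry is expressed in chemical oxygen demand: each
uptake of 1 g COD substrate yields Y g COD biomass and (1−Y) g COD
catabolic products whose fractions sum to one, so **COD is conserved
exactly by construction** (the test suite verifies drift < 0.1 % over
sealed-batch integrations, and < 1e-8 relative in the instantaneous rate
balance). Carbon is balanced reaction-by-reaction: the carbon content of
substrate, products and biomass (C₅H₇NO₂) is computed per g COD, and the
residual is routed to (or drawn from) the total-inorganic-carbon pool as
CO₂. The elemental composition of the degradable organics comes from the
substrate characterization (C, H, N, S mass fractions of TS; oxygen by
difference within the VS), which makes the bulk CH₄/CO₂ ratio of the gas a
property of the feedstock's degree of reduction rather than a free
parameter.

### Acid–base chemistry and gas phase

pH solves electroneutrality — Z + [NH₄⁺] + [H⁺] = [HCO₃⁻] + 2[CO₃²⁻] +
[Ac⁻] + [Pro⁻] + [Bu⁻] + [OH⁻] — by Brent root-finding on pH ∈ [1, 13]
with the charge residual polished below 1e-10 eq/L. Z is the net
strong-ion charge (strong cations minus strong anions), fed at
0.036 eq/L, which reproduces the observed working alkalinity of
~1800 mg CaCO₃/L; the inoculum starts at 0.12 eq/L (~6000 mg CaCO₃/L),
reflecting seed sludge from a full-scale plant. pKa values (acetic
4.76, propionic 4.87, butyric 4.82, carbonate 6.35/10.33, ammonium 9.25,
water 14.00 at 25 °C) are van 't Hoff-corrected to the operating
temperature (35 °C default) with shipped reaction enthalpies.

CO₂ and H₂ transfer to the headspace through kLa·(C − K_H·p); produced
CH₄ is routed directly to the headspace (its solubility is low and a
dissolved-CH₄ state would add stiffness without affecting any reported
quantity). The headspace is a well-mixed 3 L compartment vented so total
pressure stays at 1 atm; daily gas volumes are differences of the
cumulative vented moles, reported at 1 atm and 35 °C (configurable to
STP), on a dry basis (water vapor ignored).

### Simulated alkalinity proxies (`adwarn.chemistry`)

A model cannot titrate, so the experimental alkalinities are mirrored by
proxies: **BA_sim** = ([HCO₃⁻] + 2[CO₃²⁻]) in mEq/L × 50.05 mg CaCO₃/mEq,
and **IA_sim** = the VFA molar sum expressed either in acetic-acid
equivalents (g/L) or CaCO₃ units. Experimental-side conversion follows
the three-point titration method: alkalinity (mg CaCO₃/L) =
HCl_conc × HCl_volume × 50.05 / sample_volume × 1000, PA to pH 5.75, TA
to pH 4.3, IA = TA − PA, BA = 1.25·PA. The pH-3.8 reading is stored but
by default does not enter TA (the published correction term for it is not
specified; a switch enables using it).

### Default parameters and calibration

Kinetic constants (`src/adwarn/data/default_params.txt`) are
order-of-magnitude values customary for mesophilic digestion models:
μ_max 5.0/0.54/0.68/0.40/1.2 d⁻¹ and K_S 0.5/0.25/0.15/0.15/1e-5 g/L for
acidogens / propionate degraders / butyrate degraders / acetoclastic /
hydrogenotrophic methanogens, COD yields 0.10/0.05/0.06/0.05/0.06, decay
0.02 d⁻¹, k_hyd 0.20 d⁻¹, kLa 200 d⁻¹. Two quantities were calibrated to
the reported steady-state performance of the R1 reactor (0.20 L CH₄/g VS
at 62 % CH₄ over the full-load phase): the **effective anaerobic
degradability of the corn-stalk VS** (0.51 — about half the
lignocellulose, a typical value for untreated straw) and the feed
strong-ion charge above. Everything else was fixed a priori. With these
defaults the simulated R1 full-load plateau gives 0.200 L CH₄/g VS and
60.4 % CH₄ (the residual ~2-point CH₄ gap traces to bicarbonate washout
in the effluent, which the vent/effluent split fixes once the feed
alkalinity is set).

### Feeding, recovery and schedules (`adwarn.schedules`)

Phases store days inclusive (0–25, 26–50, …) exactly as operating tables
print them; a phase covers [start, end+1) in continuous time. The
simulator **feeds by the stated OLR on a VS basis** — OLR is the
controlled variable — rather than recomputing the load from feed TS and
HRT, whose printed arithmetic is not always self-consistent. Recovery
phases switch off feed *and* dilution (effluent is recycled) and add a
configurable biomass bolus (0.05 g/L per group) at phase start,
representing re-inoculation.

### Numerics

`scipy.integrate.solve_ivp` (BDF) integrates each phase with rtol 1e-8 /
atol 1e-10, chaining states across phase boundaries (feed steps are
discontinuous). Integrator excursions below zero are clipped at zero on
output with a counted, logged event (typical runs clip a few dozen
samples at magnitudes near atol). Two runs with identical inputs are
bitwise identical. Halving the output step changes daily outputs by
< 0.1 %.

**Known limitations**: no solids accumulation or floating-layer mass
transfer delay (reported in the physical reactors), no trace-element or
ionic-strength effects, no microbial community structure, single
homogeneous substrate. Under the overload ramps the simulated reactor
accumulates VFA only mildly and does not reach pH < 6.4 — consistent with
the original observation that simulated acidification is slower and
weaker than in the physical reactors — so simulated failure timing is not
a validated output; the screening thresholds for simulated data are
correspondingly looser.

## 2. Screening rules (`adwarn.indicators`)

* **Pairwise RSD** exactly as defined for two consecutive days (no n−1
  divisor); a zero two-day mean yields a missing value.
* **Steady state**: maximal runs (greedy extension, non-overlapping) of
  ≥ 6 consecutive days with every daily biogas value within ±10 % of the
  run mean. "Within 10 % variation" is not an arithmetic definition; the
  mean-band reading is the default and a day-to-day-RSD alternative is
  exposed (`rule="day_to_day"`).
* **Failure**: first day with pH < 6.4, or a day-on-day CH₄-yield *drop*
  with RSD > 20 %.
* **Abrupt change**: first day in the overload window with RSD > 20 %
  *in the indicator's acidification direction* (VFAs, IA, IA/BA, VFA/BA
  rise; BA, BA/TA, CH₄/CO₂, pH, CH₄ yield fall). Direction-awareness
  avoids flagging recovery rebounds. 10–20 % days are reported as
  "slight". pH is exempt from RSD screening (it acts only through the
  6.4 failure rule). Ties are impossible on integer days; the first
  qualifying day is reported.
* **Amplitude**: (reference − extreme)/extreme × 100 per steady period,
  extreme = period maximum for rising indicators, minimum for falling;
  the reference is the indicator value on its abrupt-change day. The
  bounds are the lowest and highest period changes; when all periods give
  the same change the comparison is redone against period means and that
  single value is reported for both bounds. Reference periods are all
  steady periods before the overload window (a period running into the
  window is clipped at its start).
* **Risk flags** fire when the amplitude crosses the configured
  threshold; defaults for experimental data: IA/BA +10 %, total VFA
  +51 %, IA +20 %, BA −11 %, VFA/BA +30 %; for simulated data IA/BA
  +20 % and total VFA +19 % (the auxiliary thresholds unchanged).

## 3. Goodness of fit (`adwarn.gof`)

rRMSE and MAPE per variable over inclusive day windows (defaults 0–165
and 30–165; the second drops the stochastic start-up). The dense
simulated series is linearly interpolated at the measured days —
measurements are the reference and are never interpolated. Zero-valued
measurements make their MAPE term undefined and are dropped with a count
reported in the result; rRMSE keeps them.

## 4. Synthetic data (`adwarn.synthetic`)

* **Noise**: multiplicative lognormal with mean 1 (concentrations are
  positive and errors roughly proportional; default CV 5 %, a typical
  day-to-day analytic repeatability for titration/GC measurements), pH
  additive Gaussian with sd CV/2. No error model was reported for the
  physical measurements; this is the package's own choice. All
  generators are deterministic per seed.
* **Overload fixtures** emulate the event timing observed in the two
  reactors: each indicator is flat (±1 % uniform jitter; ±0.6 % for the
  coupled ratios, which are observably steadier in real digesters) until
  its engineered abrupt day, jumps by +60 % (rising) or −35 % (falling)
  onto its published abrupt value, then drifts 5 %/day in the
  acidification direction; pH dips gently from day failure−3 but first
  crosses 6.4 exactly on the engineered failure day. Jump sizes are
  validated at build time to exceed the 20 % RSD trigger with margin;
  undersized jumps raise immediately. Indicator columns are engineered
  independently, so ratio columns are not arithmetically consistent with
  their base columns — the fixtures test event *timing*, not mass
  balance. Baseline levels default to published steady-state values
  (e.g. CH₄ yield 0.20 L/g VS, abrupt values from the event tables).
* **Parameter recovery** simulates the R1 schedule (50–60 days is enough:
  the steady VFA residual is strictly monotone in Ki), adds noise, and
  re-fits Ki by bounded scalar minimization of the squared total-VFA
  mismatch. Noiseless recovery is exact to < 1 %; at 5 % noise the
  packaged experiment recovers Ki within ~6 %.

What passing fixture tests shows: the screening rules recover engineered
event days exactly under realistic jitter. What it does not show:
performance on real reactor data with drifting baselines, missing days,
or correlated sensor error — none of which the generator emulates.

## 5. Problem sizes used in the shipped analyses

The packaged drivers and checks run the R1 schedule in full (166 days) or
truncated at day 101 (full-load calibration) / day 50 (parameter
recovery), R2 in full (171 days), 100-state randomized pH-solver
comparisons, and 20-day sealed-batch conservation runs — sizes chosen so
the whole analysis reruns from scratch in a couple of minutes on one
core.
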