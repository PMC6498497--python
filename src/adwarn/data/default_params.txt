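# Default kinetic and physico-chemical constants for the corn-stalk CSTR
# bioconversion model.  Flat key = value; '#' starts a comment.
#
# Per-group kinetics: mu_max (1/day), ks (g/L of the consumed substrate),
# yield_cod (g COD biomass per g COD substrate), decay (1/day), and the
# two-sided pH-inhibition pair (pk_low, pk_high).

acidogens.mu_max = 5.0
acidogens.ks = 0.5
acidogens.yield_cod = 0.10
acidogens.decay = 0.02
acidogens.pk_low = 4.5
acidogens.pk_high = 8.5

propionate_degraders.mu_max = 0.54
propionate_degraders.ks = 0.25
propionate_degraders.yield_cod = 0.05
propionate_degraders.decay = 0.02
propionate_degraders.pk_low = 5.5
propionate_degraders.pk_high = 8.5

butyrate_degraders.mu_max = 0.68
butyrate_degraders.ks = 0.15
butyrate_degraders.yield_cod = 0.06
butyrate_degraders.decay = 0.02
butyrate_degraders.pk_low = 5.5
butyrate_degraders.pk_high = 8.5

acetoclastic_methanogens.mu_max = 0.40
acetoclastic_methanogens.ks = 0.15
acetoclastic_methanogens.yield_cod = 0.05
acetoclastic_methanogens.decay = 0.02
acetoclastic_methanogens.pk_low = 6.0
acetoclastic_methanogens.pk_high = 8.5

hydrogenotrophic_methanogens.mu_max = 1.2
hydrogenotrophic_methanogens.ks = 1.0e-5
hydrogenotrophic_methanogens.yield_cod = 0.06
hydrogenotrophic_methanogens.decay = 0.02
hydrogenotrophic_methanogens.pk_low = 5.5
hydrogenotrophic_methanogens.pk_high = 8.5

# hydrolysis and inhibition
k_hyd = 0.20            # 1/day, first-order on degradable particulate
ki_vfa = 315.0          # mg total VFA/L on acetoclastic methanogens (R1); 365 for R2
ki_nh3 = 250.0          # mg free NH3-N/L on acetoclastic methanogens

# catabolic COD fractions
f_mono_ac = 0.50
f_mono_pro = 0.15
f_mono_bu = 0.25
f_mono_h2 = 0.10
f_pro_ac = 0.57
f_pro_h2 = 0.43
f_bu_ac = 0.80
f_bu_h2 = 0.20

# gas transfer / equilibria at 35 degC
kla = 200.0             # 1/day
kh_co2 = 0.0246         # mol/(L atm)
kh_h2 = 7.2e-4          # mol/(L atm)
temp_c = 35.0

# reactor and feed medium
v_liq = 17.0            # L working volume
v_gas = 3.0             # L headspace
feed_z = 0.036          # eq/L net strong cations carried by the feed slurry
feed_tic = 0.0          # mol/L
reinoculation_biomass = 0.05   # g/L per group, added at recovery-phase start
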