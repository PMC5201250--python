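# Baseline kinetic parameter set for the two-strain cross-feeding chemostat
# model.
#
# Provenance: "fallback" — a documented default set calibrated by
# scripts/calibrate_fallback.py (see docs/methods.md) to reproduce the
# qualitative multistability structure of the system: washout-only ->
# glucose-specialist-only -> bistable -> tristable as the inflow glucose
# concentration S0 rises, with tristability at S0 = 350 umol/L and a sharp
# acetate-specialist invasion threshold near 0.0033 at 0.025 % w/v glucose.
#
# Units: Vmax_* and Vhat are per-cell rates [umol cell^-1 h^-1]; Km_*, Krt,
# Khat, Kc are concentrations [umol/L]; G is cells per umol ATP; n_g and
# n_tca are ATP yields per lumped reaction; D is 1/h; S0 and A_in are umol/L.
provenance: fallback
strain1:                 # glucose specialist (fermenter-like, CV103 analogue)
  Vmax_g: 3.0e-9         # fast glucose scavenging (rate side of the trade-off)
  Km_g: 10.0             # high affinity for the limiting sugar
  Vmax_tca: 8.5e-10      # modest respiratory capacity -> overflow at high flux
  Km_tca: 60.0
  Vrt: 1.5e-9            # freely excretes the intermediate
  Krt: 100.0
  Kc: 250.0              # more sensitive to intermediate toxicity
strain2:                 # acetate specialist (respirer-like, CV101 analogue)
  Vmax_g: 2.7e-9         # slightly lower maximum glucose uptake (small cost)
  Km_g: 60.0             # poorer glucose scavenger
  Vmax_tca: 3.0e-9       # strong respiratory capacity (yield side)
  Km_tca: 300.0
  Vrt: 1.0e-9
  Krt: 100.0
  Kc: 400.0
  Vhat: 1.16e-9          # high-affinity acetate uptake (acs-like); strain 1: 0
  Khat: 20.0
shared:
  n_g: 2.0               # ATP per lumped glycolysis reaction
  n_tca: 12.0            # ATP per lumped TCA reaction (per triose unit)
  G: 1.0e+8              # cells produced per umol ATP
forms:
  uptake: michaelis_menten
  transport: odd_saturating
  cost: hyperbolic
environment:
  D: 0.2                 # dilution rate [1/h]
  S0: 350.0              # inflow glucose [umol/L] (the outcome-map condition)
  A_in: 0.0
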