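# Methods

## The model

Two strains compete for a single limiting sugar (glucose) in a chemostat with
dilution rate `D` and inflow concentration `S0`.  Catabolism is lumped into
two reactions per strain: glycolysis (glucose → intracellular intermediate,
ATP yield `n_g` per reaction) and the TCA cycle (intermediate → CO₂, yield
`n_tca` per triose unit).  One hexose yields two trioses, hence the
stoichiometric factor 2 on glucose uptake in the intermediate balance.  The
intermediate — acetate in the motivating *E. coli* system — crosses the
membrane through a reversible saturating transporter driven by the gradient
`Xin − Xex`, and the acetate specialist additionally carries a high-affinity
irreversible uptake enzyme (`v̂`, acetyl-CoA synthetase-like, no ATP
cofactor).  Per-capita growth is proportional (constant `G`) to the total
ATP production rate, multiplied by an inhibition factor `c(Xin) ∈ (0, 1]`
that encodes the toxicity of the accumulated intermediate.

The state is six-dimensional: `(S, Xex, N1, N2, Xin1, Xin2)`, with
concentrations in µmol/L, densities in cells/L, time in hours.  The
intracellular pools are *culture-level* quantities: they are filled by
per-cell rates times density and diluted at `D`.  This is implemented
literally as written; the per-cell alternative (dividing by `N_i`) is a
noted open modelling question, not silently adopted.  The culture-level
reading has a consequence that the entire analysis relies on: a rare strain
has an almost empty pool (its pool fills at a rate proportional to its own
density), so rare-type physiology is glycolysis-only and invasion fitness is
density- and frequency-dependent.  That is the mechanism behind the sharp
invasion thresholds and the multistability.

All saturating kinetics default to Michaelis–Menten; the reversible
transporter uses the odd saturating form `V δ/(K + |δ|)`; the cost defaults
to the hyperbolic `1/(1 + Xin/Kc)`.  Functional forms are selected by name
in the config, so alternatives (including `cost: none`, the no-toxicity
variant) can be swapped without code changes.

Acetate supplementation is modelled as a continuous inflow term `+D·A_in` in
the `Xex` equation, the chemostat-consistent reading of adding acetate to
the medium of a continuous culture; a one-time bolus is available as an
initial-condition option (`Xex0`).

## Parameters

The shipped baseline (`src/crossfeed/data/baseline.yaml`, provenance flag
`fallback`) encodes a rate–yield trade-off plus a resource-specialization
trade-off:

| parameter | strain 1 (glucose specialist) | strain 2 (acetate specialist) | unit |
|---|---|---|---|
| `Vmax_g` | 3.0e-9 | 2.7e-9 | µmol cell⁻¹ h⁻¹ |
| `Km_g` | 10 | 60 | µmol/L |
| `Vmax_tca` | 8.5e-10 | 3.0e-9 | µmol cell⁻¹ h⁻¹ |
| `Km_tca` | 60 | 300 | µmol/L |
| `Vrt`, `Krt` | 1.5e-9, 100 | 1.0e-9, 100 | —, µmol/L |
| `Vhat`, `Khat` | 0 (negligible) | 1.16e-9, 20 | —, µmol/L |
| `Kc` | 250 | 400 | µmol/L |

Shared: `n_g = 2`, `n_tca = 12`, `G = 1e8` cells/µmol ATP; environment
`D = 0.2 h⁻¹`.  Magnitudes follow from per-cell uptake capacities of order
10 mmol gDW⁻¹ h⁻¹ (≈3e-9 µmol cell⁻¹ h⁻¹) and glucose-limited chemostat
densities of order 10¹¹–10¹² cells/L; `Khat = 20 µmol/L` is within the
published affinity range of acetyl-CoA synthetase.

Three structural choices carry the phenomenology, and were made
deliberately (`scripts/calibrate_fallback.py` re-derives the final scan):

1. **Strain 1's TCA branch is low-capacity but saturating** (`Vmax_tca` ≈
   the steady-state glycolytic flux, `Km_tca` well below the operating pool
   level).  An established strain-1 population therefore respires most of
   its intermediate and is the superior steady-state glucose competitor,
   while the *marginal* benefit of further pool accumulation is nearly zero,
   so the toxicity cost dominates at the margin.  This is what makes higher
   `S0` (hence higher density and higher pools) shift the coexistence
   balance toward the acetate specialist rather than away from it.
2. **Strain 2 is a poor glucose scavenger** (`Km_g` 60 vs 10) with a small
   `Vmax_g` deficit — the concave specialization trade-off: a large gain in
   acetate affinity for a small cost in maximum glucose uptake.  At the
   coexistence point strain 2 is acetate-limited, not glucose-limited.
3. **The acetate enzyme's capacity `Vhat` sets the invasion threshold.**  A
   rare acetate specialist needs its culture-level pool to reach the level
   where respiration pays for dilution; the critical absolute density is
   roughly `Xin_crit·D/(Vhat + 2·v_g,2)`, nearly independent of the
   resident's density.  Dividing by the resident monoculture density gives
   the threshold *frequency*, which therefore falls with density and with
   `S0` — the observed direction.  `Vhat = 1.16e-9` places the threshold at
   0.0033 at 0.025 % w/v glucose with the population at the strain-1
   monoculture maximum.

Under this set the model reproduces, at desk scale: the regime sequence
washout-only (S0 < 5 µmol/L) → strain-1-only (≈5–20) → bistable exclusion
(≈20–80) → tristable (≈80 through ≥1400 µmol/L); tri-stability at
`S0 = 350 µmol/L`; a sharp invasion threshold of ≈0.0033 at 0.025 % w/v;
and all four directional effects (acetate supplementation and higher `S0`
suppress the glucose specialist; the threshold falls with density and with
`S0`).  A *narrow* additional tristable window at low `S0`, between the
strain-1-only and bistable regimes, is not produced by this parameter set;
`classify_regimes` reports such a window whenever one exists, but the tests
assert only the four-regime backbone.  In other corners of parameter space
(weak strain-1 TCA with a strong cost) the low-`S0` window appears but
high-`S0` tristability is lost, so the backbone was preferred.

## Numerical choices

* **Integration**: LSODA (stiff-capable) with `rtol = 1e-8` and
  componentwise absolute tolerances scaled to the problem (concentrations by
  `S0·1e-9`, densities by the initial total density `·1e-9`).  Negative
  states are handled by *rejection*: a trajectory that dips below 100× the
  absolute tolerance raises, rather than being clamped; mild integrator
  probing below zero is well defined because every rate function is.
* **Generations**: one generation is `ln 2 / D` hours (steady-state
  chemostat doubling).  "Long-term" outcomes use a 500-generation horizon
  with a trailing-window settling check (window 20 %, relative variation
  < 1e-3); classification with an undecided trailing window returns
  `undecided`, never a coerced label.  Extinction is a density below 1e-6 of
  the initial total throughout the trailing window — far below one cell per
  realistic culture volume, and far above the integrator's density floor.
* **Equilibria**: multistart damped `hybr` root-finding on the scaled
  residual, in plain coordinates so boundary equilibria are reachable.
  Seeds: the analytic washout state; reduced monoculture solves over a
  logarithmic grid of residual-sugar values (the monoculture subsystem can
  carry coexisting efficient and self-poisoned branches); mixtures of
  monoculture solutions, including near-boundary weights that target the
  rare-invader saddles; and a Latin-hypercube cloud with log-uniform
  sampling of the concentration axes.  Roots are merged at 1e-6 relative
  distance in the scaled norm, verified to residual < 1e-9, and classified
  by the eigenvalues of the Jacobian (analytic for the default forms,
  central finite differences otherwise; the two agree to 1e-6 and are
  cross-checked in the tests).  Stability uses an eigenvalue margin of
  1e-8 on real parts; branch labels use a zero-density tolerance of 1e-9
  relative to a reference density.  Complex pairs crossing the axis would
  be classified as stability changes; none occur for the baseline set.
* **Continuation**: natural-parameter over an S0 grid with warm starts and
  periodic multistart re-seeding (every 4th point), which is what finds
  disconnected branches; folds and stability flips are recorded as brackets
  between adjacent grid points.  Checkpoint equality between continuation
  and fresh multistart is a standing test.
* **Thresholds**: invasion thresholds by bisection on the initial
  acetate-specialist frequency (establishment = `N2_only` or `coexistence`
  at the decision horizon), default resolution 1e-4; the washout survival
  threshold by bisection on washout invadability `max_i µ_i(S0) = D`, which
  has the closed form `Km·D/(G·n_g·Vmax − D)` for a single strain — the
  bisection is tested against it.
* **Carbon bookkeeping**: the weighted sum `2S + Xex + Xin1 + Xin2` obeys a
  one-dimensional balance in which all transport terms cancel; the residual
  of that identity along every trajectory is recorded and must stay below
  10× the integration tolerance.

## Problem sizes

The shipped analyses run at desk scale: 20×20 outcome-map grids (the CLI
default is 40×40), 16–24-point S0 continuations, 5-point directional
sweeps, and 500-generation decision horizons.  A single 500-generation
integration costs ~10 ms, so the full test suite and the acceptance script
each complete in well under a minute.

## What the scenarios do and do not emulate

The canned scenarios reproduce the *structure* of the motivating chemostat
experiments: mixed-culture competition over 30 generations, acetate
supplementation of the inflow, input-concentration sweeps, paired runs
flanking the invasion threshold, and threshold-versus-density and
-versus-`S0` sweeps with densities normalized to the monoculture maximum.
They are deterministic ODE runs: no demographic noise, no mutation, no
lag-phase or batch-transfer physiology, and the fallback kinetic constants
are calibrated to reproduce qualitative structure rather than fitted to
time-course data.  Passing tests therefore demonstrate that the mechanism
— overflow metabolism plus a rate–yield and a specialization trade-off
generating density-dependent multistability — is faithfully implemented and
robust at these scales, not that the specific numbers would be observed in
any particular culture.

## Known limitations

* The fresh-inoculum start at very high `S0` (≳0.05 % w/v) can relax onto a
  self-poisoned, low-density strain-1 monoculture state: the transient pool
  spike at full glucose crosses into the poisoned basin of the bistable
  monoculture subsystem.  The healthy branch still exists there (the
  continuation tracks it); density sweeps that rely on fresh-start
  monoculture maxima are therefore confined to ≤0.025–0.1 % w/v.
* `classify_regimes` names only the label combinations that occur in the
  analysis (washout-only, N1-only, N2-only, bistable, tristable); any other
  stable-set composition is reported with an explicit `+`-joined label
  rather than forced into a named regime.
* No limit-cycle continuation: oscillatory attractors would surface as
  `undecided` classifications and axis-crossing complex pairs, and none are
  observed at the baseline set.
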