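# crossfeed

Multistability analysis of a two-strain cross-feeding chemostat model.

Glucose-limited continuous cultures of *E. coli* can spontaneously become
polymorphic: a fast but wasteful glucose specialist excretes acetate, and an
acetate specialist evolves to scavenge it.  Yet the interaction does not
always establish.  This package implements a mechanistic model of that
system and the analyses that explain the inconsistency: whether
cross-feeding forms depends jointly on the inflowing resource concentration
and on the initial density and frequency of the competitors, because the
system is multistable.

It is aimed at microbial ecologists and modellers who want to simulate the
system, locate and classify its steady states, continue them in the inflow
concentration, map basins of attraction, and compute invasion and survival
thresholds — from Python or from a small CLI.

## Model

For strains *i* = 1 (glucose specialist) and 2 (acetate specialist), with
glucose *S*, extracellular intermediate *X*<sub>ex</sub>, densities
*N*<sub>i</sub> and culture-level intracellular pools *X*<sub>in,i</sub>:

```
dS/dt      = D (S0 − S) − v_g,1(S) N1 − v_g,2(S) N2
dXex/dt    = v_rt,1(Xin,1 − Xex) N1 + (v_rt,2(Xin,2 − Xex) − v̂(Xex)) N2 − D Xex
dN_i/dt    = [ G (n_g v_g,i(S) + n_tca v_tca,i(Xin,i)) c_i(Xin,i) − D ] N_i
dXin,i/dt  = (2 v_g,i(S) − v_tca,i(Xin,i) − v_rt,i(Xin,i − Xex) [+ v̂(Xex)]) N_i − D Xin,i
```

All kinetics are saturating (Michaelis–Menten; the reversible transporter is
odd and saturating); growth is proportional to ATP production and inhibited
by the accumulated intermediate through c_i; the high-affinity acetate
enzyme v̂ belongs to strain 2 only.  Because the intracellular pools are
culture-level quantities, a rare strain runs on glycolysis alone — invasion
fitness is density- and frequency-dependent, which is what produces sharp
invasion thresholds, bistable exclusion, and a tristable regime in which
either monoculture or stable cross-feeding coexistence can be reached.

Parameters ship as a documented fallback calibration
(`src/crossfeed/data/baseline.yaml`; see `docs/methods.md` and
`scripts/calibrate_fallback.py`).

## Worked example

```python
import numpy as np
import crossfeed as cf

params, env = cf.baseline_parameters()        # D = 0.2/h, S0 = 350 umol/L

# all steady states at S0 = 350, with stability
for q in cf.find_equilibria(params, env, n_starts=48, seed=1):
    print(f"{q.label:16s} {q.stability:9s} N1={q.state[2]:.3g} N2={q.state[3]:.3g}")

# bistable invasion at 0.025 % w/v glucose, density at the monoculture maximum
env4 = env.replace(S0=cf.percent_wv_to_umolL(0.025))
nmax = cf.monoculture_max_density(params, env4)
thr, (lo, hi) = cf.invasion_threshold(params, env4, nmax, resolution=1e-4)
print(f"invasion threshold f2 = {thr:.5f} in [{lo:.5f}, {hi:.5f}]")
```

prints

```
washout          unstable  N1=0 N2=0
N1_monoculture   stable    N1=8.29e+11 N2=0
N2_monoculture   stable    N1=0 N2=8.46e+11
coexistence      unstable  N1=1.85e+09 N2=8.36e+11
coexistence      stable    N1=4.71e+11 N2=3.53e+11
coexistence      unstable  N1=7.96e+11 N2=1.34e+10
invasion threshold f2 = 0.00327 in [0.00322, 0.00332]
```

Read: at 350 µmol/L inflowing glucose the system is tristable — three
stable states (either monoculture, or coexistence at ≈43 % acetate
specialist) separated by two saddle points, so the outcome depends on where
the population starts.  At 0.025 % w/v glucose an acetate specialist
arising at the monoculture maximum density must exceed a frequency of about
0.0033 to establish cross-feeding; at 0.0032 it is lost.

The same analyses are available from the shell:

```
crossfeed continue --S0-min 2 --S0-max 1500 --out-dir out   # bifurcation sweep
crossfeed map --S0 350 --grid 40 --out-dir out              # basin map
crossfeed threshold --S0 0.025% --out-dir out               # invasion threshold
crossfeed scenarios --scenario fig4_bistable_invasion --out-dir out
```

Each command writes tidy CSV/JSON outputs with unit-suffixed headers plus an
append-only `manifest.json` recording version, config hash, provenance and
tolerances.

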