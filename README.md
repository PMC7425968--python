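# metapva

Stochastic, spatially structured metapopulation viability analysis (PVA)
for species living in small, patchy, water-limited habitat — the kind of
system where a few dozen marsh fragments hold a few hundred animals and
managers must decide where scarce restoration money does the most good.

Each habitat patch *i* carries a subpopulation governed by a Ricker
recursion with environmental stochasticity,

    N_{i,t+1} = N_{i,t} · exp( r_d (1 − N_{i,t}/K_i) + ε ),   ε ~ N(0, v_r)

with carrying capacity `K_i = depth_i × area_i × K_volume` (water depth in
cm, area in ha, `K_volume` in voles per cm·ha), a post-growth ceiling at
`K_i`, and local extinction whenever `N_i < 1`. Patches are coupled by an
incidence-function-style migration pressure: patch *i* receives immigrants
as a Poisson draw with yearly rate

    λ_i = β · Σ_{j≠i} N_j · exp(−α d_ij)

where `α` is the exponential dispersal-kernel rate (1/mean dispersal
distance) and `β` a dimensionless migration calibrator. Monte-Carlo trials
(default 500 × 101 years) yield the expected time to metapopulation
extinction `T_e` (censored at the run length) and the year-25 response
variables `mvp25` (occupied-patch fraction), `mN25` (total population) and
`mcol25` (migrants). On top of the engine sit:

- **source/sink classification** — each patch is simulated in isolation
  (all other patches stripped of habitat) and in context, yielding
  Context-independent Source / Rescued Sink / Context-independent Sink /
  Converted Sink, plus sink classes I (>25 yr), II (10–25 yr), III (<10 yr);
- **scenario analysis** — drought (habitat scaling), wildland fire and
  hydrologic water loss (zeroing patch groups), megamarsh creation
  (merging a regional cluster into one large patch), and additive
  combinations, compared through common-random-number simulation;
- **OFAT sensitivity analysis** — one-factor-at-a-time sweeps of `r_d`,
  `K_volume`, `v_r`, `β`, `α` against `T_e`;
- **calibration utilities** — `α` as the reciprocal mean movement
  distance (exponential-kernel MLE), `r_d = ln λ` from a finite rate of
  increase, and `K_volume` by through-origin regression of patch counts
  on habitat volume.

A seeded synthetic-landscape generator ships a 36-patch preset in three
regional clusters (north/central/south) with right-skewed patch sizes, so
the full pipeline runs out of the box without any field data.

## Worked example

```python
from metapva import generate_synthetic_landscape, load_config, response_variables, run_simulation
from metapva.simulator import SimConfig

landscape = generate_synthetic_landscape(seed=0)      # 36 patches, 3 clusters
params, _ = load_config()                             # documented defaults
summary = run_simulation(landscape, params, SimConfig(tmax=101, trials=200, seed=42))
print(response_variables(summary, t=25))
```

prints (see `examples/01_baseline_viability.py`):

```
landscape: 36 patches, total K = 537 voles (median patch K = 4.7)
mean time to extinction T_e = 68.5 yr (censored at 101)
occupied patch fraction at 25 yr (mvp25) = 0.179
mean metapopulation size at 25 yr (mN25) = 98.0 voles
mean migrants at 25 yr (mcol25) = 1.21 voles/yr
```

The metapopulation is expected to persist about 69 years; at the 25-year
planning horizon roughly 18% of patches are occupied at any moment and
about one migrant moves between marshes per year. The other scripts in
`examples/` walk through classification, scenario comparison, sensitivity
sweeps and calibration, each printing what its numbers mean.

The same capabilities are available from the shell:

```bash
metapva make-landscape --out land.csv --seed 0
metapva simulate --landscape land.csv --out run/ --seed 42
metapva classify --landscape land.csv --out classes.csv
metapva sensitivity --param v_r --landscape land.csv --out sweep.csv
metapva calibrate alpha --movements movements.csv
```

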