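# Methods

## Model

The simulator couples within-patch density-dependent growth to
between-patch colonization over an explicit landscape, with one-year time
steps.

**Within-patch dynamics.** Each patch *i* has carrying capacity
`K_i = depth_i × area_i × K_volume`. Subpopulations follow a Ricker
recursion with environmental stochasticity on the exponent:

    N' = N · exp( r_d (1 − N/K_i) + ε ),    ε ~ Normal(0, v_r)

After growth, `N` is capped at `ceiling × K_i` (default `ceiling = 1`),
and any subpopulation below one individual is set to exactly zero (local
extinction). A patch with `K_i = 0` (no area or no water) maps to zero
regardless of `N`.

*Why the ceiling.* With lognormal multiplicative noise the raw recursion
has `E[e^ε] = e^{v_r/2}` — at the default `v_r = 1` the *expected*
multiplicative growth is ≈1.65/yr even at `N = K`, so uncapped
subpopulations episodically "boom" to tens or hundreds of times `K` and a
multi-patch system almost never goes extinct within the run length. That
contradicts the empirical picture these models are built on: subpopulations
of habitat-limited rodents sit at or near carrying capacity, and even the
largest patches are not expected to persist beyond a few decades alone.
With the ceiling, isolated persistence scales with patch size the way
observed systems do (K ≤ 7 → under a decade; K ≈ 10–40 → one to two
decades; K ≳ 45 → beyond the 25-yr planning horizon). Setting
`ceiling=None` recovers the unbounded recursion for comparison.

**Spatially correlated noise.** `spacecor ∈ [0, 1]` sets the cross-patch
correlation of ε to `spacecor · exp(−d_ij / L)` where `L` is the mean
inter-patch distance, so `spacecor = 0` (the default) gives independent
patches and `spacecor = 1` strong local synchrony. The correlation matrix
is factorized once per run by symmetric eigendecomposition; if a
user-supplied (non-metric) distance matrix makes it indefinite, negative
eigenvalues are clipped to zero (nearest-PSD repair) and a warning is
logged. For planar Euclidean landscapes the exponential kernel is always
positive-definite, so the repair never triggers on real geometries.

**Migration.** Patch *i* receives immigrants as a Poisson draw with rate
`λ_i = β Σ_{j≠i} N_j e^{−α d_ij}`, independent across patches within a
year. Distances are center-to-center Euclidean meters (patches are treated
as points; `α` is per meter, so coordinates must be projected, not
lat/lon). Migrants are added to the receiving patch; source patches are
not decremented — emigration of a handful of animals from a
high-density patch does not measurably change its dynamics, and
high density is itself the trigger for emigration. Migration is not
colonization: immigrants landing in an occupied patch simply join it, and
immigrants landing in a zero-habitat patch die within the year (they are
counted in the migrant accounting as immigration events, but never appear
as residents — such patches act as dead ends, which is exactly how
stepping-stone loss harms a network).

**Yearly event order.** (1) draw the noise vector, (2) Ricker step all
patches simultaneously, (3) ceiling, (4) extinction rule, (5) migration
pressures from the post-step sizes, (6) Poisson immigrant draws added,
(7) record. The metapopulation extinction year is the first year total
N = 0; extinction is absorbing (no migration source remains).

## Parameters

| name | default | units | meaning |
|---|---|---|---|
| `r_d` | 0.01 | per vole·yr | low-density per-capita growth rate |
| `v_r` | 1.0 | (vole·yr)² | variance of environmental noise ε |
| `spacecor` | 0 | — | distance-decaying noise correlation scale |
| `ceiling` | 1.0 | ×K | post-growth cap on N (None disables) |
| `K_volume` | 17 | voles/(cm·ha) | habitat-quality (density) proxy |
| `α` | 0.01 | 1/m | exponential dispersal-kernel rate |
| `β` | 0.01 | — | migration calibrator (low for a sparse, poorly dispersing species; ~1 for vagile, locally common ones) |
| `tmax` | 101 | yr | years per trial (T_e censor) |
| `trials` | 500 | — | Monte-Carlo trials per run |
| `n0_rule` | carrying_capacity | — | N₀ = K_i; `k_volume_area` gives N₀ = K_volume × area_i instead |

Initialization at `K_i` reflects the assumption that extant subpopulations
sit near carrying capacity; the alternative rule (area-only) is exposed
because either convention appears in field practice.

**Reproducibility.** A run's base seed is split into per-trial streams with
`numpy.random.SeedSequence(seed).spawn(trials)`; trial *k* of a run is
identical no matter how many trials follow it, and identical seeds give
bit-identical output. OFAT sweep rows derive their seeds from the
parameter name and value (CRC32-tagged), never the row position, so sweep
results are invariant to grid ordering.

## Derived analyses

**T_e and response variables.** `T_e` is the mean extinction year across
trials, with trials surviving to `tmax` contributing `tmax` (censoring is
never extrapolated; saturation of T_e near `tmax` in sweeps is a censor
artifact and is documented as such). `mvp_t` is the mean occupied-patch
fraction at year *t* (occupancy ≡ N ≥ 1, the complement of the extinction
rule), `mN_t` the mean total population, `mcol_t` the mean immigrants
summed over patches, all at *t* = 25 by default.

**Classification.** Each patch is simulated (a) isolated — every other
patch's depth set to 0, same trials/tmax for comparability — giving
`T_e_iso`, and (b) in context, giving its year-25 occupancy. Source in
isolation ≡ `T_e_iso > 25`; persistent in context ≡ occupancy ≥ 0.5 (the
cut is a config knob: "frequently maintains a resident subpopulation" must
be made quantitative somewhere, and half the time is the natural reading).
Crossing the two booleans yields the four classes; `T_e_iso` also grades
sink classes I (>25), II (10–25, boundaries inclusive), III (<10).

**Scenarios.** Pure landscape transformations: drought scales every
patch's habitat (area × depth) by `1 − p` via the depth term (p = 0.35 is
the printed moderate level; 0.15/0.55 are package defaults for minor and
severe, overridable); fire and water loss zero the depth of a selected
patch group; megamarsh replaces a regional cluster with a single patch
holding the cluster's summed area (conserved exactly), maximum depth and
area-weighted centroid. Scenario runs share the baseline's seed (common
random numbers), so differences between rows reflect the landscape change
alone. Per-trial extinction years are retained for downstream ANOVA/Tukey
with standard statistics packages.

**Sensitivity.** One factor at a time over the documented grids: r_d
−0.5..0.5 step 0.1; K_volume 1..100 step 5 (i.e. 1, 6, …, 96 — whether
the endpoint 100 belongs to the grid is ambiguous, so an
`include_endpoint` flag adds it, default off); v_r 0..10 step 1; β and α
0..0.1 step 0.01. Reported per grid value: mean and SD across trials of
the censored-substituted extinction year.

**Calibration.** `alpha_mle` is the exponential-kernel MLE, the
reciprocal mean movement distance, returned unrounded (rounding for
modeling is the config author's choice; outlier exclusion is the
caller's). `rd_from_lambda` is `ln λ`. `fit_k_volume` regresses counts on
volume through the origin (slope = ΣNV/ΣV², computed via OLS without a
constant; R² is the uncentered no-intercept version), and
`compare_k_models` ranks candidate predictor sets by AIC the way habitat
quality proxies are chosen in practice.

## Synthetic landscape

`generate_synthetic_landscape` emulates a small desert-marsh complex: 36
patches in three regional clusters (north/central/south) whose centers
are ~1.6 km apart (full extent ~3.5 km), with within-cluster centroid
scatter of SD 180 m — so neighbor distances are tens to a few hundred
meters and cross-cluster distances are effectively beyond the default
dispersal kernel. Areas (0.02–2 ha) and depths (0.1–4 cm) are drawn
log-uniformly: fragmented-habitat patch sizes are strongly right-skewed
(many patches supporting a handful of animals, a few supporting >80), and
at `K_volume = 17` the resulting K_i span [0.03, 136] voles with median
≈3. All draws are seeded and reproducible.

What the preset does *not* emulate: real marsh geometry or hydrological
grouping, temporal trends in water levels, correlated drought forcing, or
any particular site's patch identities. Tests passing on the preset show
that the machinery behaves correctly and that the qualitative response
surfaces (linear T_e in r_d and β, exponential decay in v_r and α,
censor-driven saturation in K_volume, monotone drought damage, additive
stressor severity) emerge under realistic conditions — not that any
specific real landscape has a particular T_e.

## Numerical choices and limitations

- N is continuous; only the N < 1 rule and the integer migrant counts
  discretize anything.
- Problem sizes: the default run (36 patches × 101 yr × 500 trials)
  completes in seconds; the shipped sensitivity and scenario analyses use
  100-trial runs where only qualitative shapes are at stake and 500 where
  a number is reported.
- Extreme ε draws are not truncated; the ceiling bounds their effect on N.
- No demographic (individual-level) stochasticity, age structure,
  within-year time steps, density-dependent dispersal, or synchronized
  pulse events. `spacecor` provides spatial noise correlation but no
  temporal autocorrelation — real droughts are both, so drought impacts
  here are conservative.
- Classification boundary cases: T_e_iso exactly 25 is "not a source"
  (class II); the occupancy cut is a knob because the persistence
  criterion ("high probability of persisting") admits either an
  occupancy- or a T_e-based reading. We chose occupancy.
- λ is linear in neighbor abundance and never saturates; at very large β
  this can overstate rescue.
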