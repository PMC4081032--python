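# Methods

This note documents the model equations, parameter defaults, the synthetic
data the package runs on, and the numerical and design choices a maintainer
would want to know. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Model structure

The simulator is a spatially explicit, stochastic landscape model on a
rectangular lattice (nominally 1 km² pixels) with an annual time step and
five vegetation classes: rock/ice, tundra, black spruce, white spruce,
deciduous. State per pixel is (class, stand age), where stand age is years
since last fire; rock/ice carries the sentinel age −1, holds no fuel, never
burns and never changes class.

### Flammability

Per-cell, per-year:

    f = clamp01( logistic(b0 + bT*T + bP*P) * s_veg * fuel(age) )
    fuel(age) = min(1, age / A_fuel)

with T, P the growing-season temperature (°C) and precipitation (mm). The
regression behind the climate–fire link in operational frame-based fire
models is not published with coefficients; this logistic parameterisation
is this package's own stand-in, preserving the stated dependencies (climate,
vegetation state, time since fire) with bounded output, and must not be
read as a calibrated operational model.

Defaults (all configurable on `FlammabilityParams`):

| parameter | default | units | rationale |
|---|---|---|---|
| `b0` | −7.3 | logit | mature black spruce ignites at ~1e-3 /pixel/yr at the baseline climate (11 °C, 300 mm) |
| `bT` | +0.09 | /°C | the hot trajectory's +5.4 °C end-of-century warming raises flammability ~1.6×, giving a clear but non-degenerate contrast |
| `bP` | −0.002 | /mm | wetter growing seasons damp fire, weakly |
| `s_veg` | rock/ice 0, tundra 0.25, deciduous 0.6, white spruce 0.9, black spruce 1.0 | — | tundra burns rarely relative to boreal conifer; the constraint s_tundra ≤ s_black_spruce is enforced |
| `A_fuel` | 30 | yr | simplest ramp realising fuel build-up through succession |
| `spread_factor` | 220 | — | neighbour spread probability ~0.2 at baseline, below the 8-neighbour site-percolation threshold, so fires stay finite while responding super-linearly to warming |

With these defaults the baseline regime burns roughly 0.5–1% of the fuel
area per year (fire rotation on the order of a century), which keeps a
substantial >60-year habitat fraction while leaving room for decline under
warming.

### Ignition and spread mechanics

Each cell ignites independently iff a uniform draw < f (optional annual cap
by random subsampling; default uncapped). Fires spread as a breadth-first
front on the 8-neighbourhood, one attempt per directed edge, success
probability `clamp01(spread_factor * f(neighbour))`; the front terminates
when no attempt succeeds, which bounds work at O(8 · cells). Several fires
in one year ignite simultaneously but spread sequentially in RNG-shuffled
order; cells burned by an earlier fire are excluded, so per-year burn masks
are well-defined disjoint unions. A full-height rock/ice column is
impassable even on the 8-neighbourhood (a diagonal step changes the column
index by exactly one); only gaps in a barrier can be crossed diagonally.

### Succession

Closed transition graph: spruce → deciduous (burn); deciduous → deciduous
(burn, rescheduled); tundra → tundra (burn); deciduous → spruce
(maturation). No treeline movement, shrubification or region-specific
tundra modifiers. Transition times are uniform on (25, 75) years by
default — a window bracketing the 60-year lichen-recovery horizon so
habitat dynamics are exercised rather than assumed — scaled by the
fire-size severity multiplier `1 + k*log10(size_km2 + 1)` (default
k = 0.5, keeping the multiplier below ~2 for the fire sizes a desk-scale
domain produces; topography, though also a severity driver in the field,
is out of scope). A burned spruce stand's scheduled climax is its own
species with probability 0.9, else the other spruce class. Maturation
preserves stand age (habitat classification is by time since fire, not
time in class); a deciduous stand that has never been scheduled (initial
landscapes) receives a schedule on its first annual update with severity
multiplier 1 — without this, a no-fire deciduous landscape would never
reach climax.

### Spin-up and ensembles

Projections start from landscapes driven to quasi-stationarity by a
spin-up under a stationary baseline climate sampler (fixed means + white
noise). Ensembles run n independent replicates from child streams of one
master `SeedSequence`; each replicate spins up its own initial state. All
stochastic operations take explicit generators, so identical seeds give
bit-identical outputs.

Simulation years are indexed 1..n and mapped to calendar labels 2011..2100;
decade d covers years 10(d−1)+1..10d and is labelled "2010s".."2090s". This
resolves the ambiguity between a "2010–2100" horizon and a 90-year run.

## Synthetic data: what it emulates, what it does not

- **Landscapes** emulate a reclassified land-cover raster: a per-pixel
  multinomial draw on the target class proportions, smoothed into patches
  by three 8-neighbour majority-filter passes, then repaired to the exact
  target counts by flipping surplus-class pixels adjacent to deficit-class
  patches (majority filtering alone erodes minority classes such as 5%
  rock/ice well beyond tolerance; the repair preserves patchiness while
  restoring composition). Initial stand ages are geometric with mean 80
  years — the stationary time-since-fire distribution under a ~1%/yr
  constant hazard, which spin-up then refines.
- **Climate** is trend + optional row gradient + white noise:
  `t0 + t_trend*year/10 + gradient*row + N(0, sd)`, precipitation
  analogous and floored at 0. The default warm/hot pair differs only in
  trend (0.3 vs 0.6 °C/decade, i.e. +2.7 vs +5.4 °C over nine decades,
  bracketing mid-range high-latitude projections under a moderate
  emissions pathway). No AR(1) memory, seasonal detail, or
  downscaling artefacts.
- **Range masks** are connected blobs grown by repeated dilation from an
  anchor, subsampling the final ring to hit the target pixel count
  exactly; masks built later may overlap earlier ones (construction is in
  list order).
- **Fire records** seed fires at rate `burn_rate / mean_fire_size` per
  fuel pixel and grow random 8-connected regions to geometric target
  sizes, so the expected annual burned fraction equals `burn_rate`;
  forced fires of exact sizes support known-answer fixtures.

Because these generators omit real geography, orography, fire weather and
suppression, passing tests demonstrate the *mechanics and internal
consistency* of the model and analytics — not predictive skill on the real
Alaska–Yukon domain. The paired warm/hot contrasts are directional claims
under the synthetic conditions, evaluated as Monte-Carlo majorities over
many seeds, never per seed.

## Analytics conventions

- **Winter habitat**: class ∈ {tundra, black spruce, white spruce} and age
  strictly > 60. The boundary case (exactly 60) is excluded by convention
  and the threshold is configurable.
- **Representative run**: arg-max over replicates of the Pearson r between
  the replicate's annual area-burned series and the per-year across-run
  median series; constant series are excluded (all-constant input is an
  error), ties break to the lowest run index.
- **Percentiles** (habitat envelopes) and the **top-20% flammability
  threshold** use the nearest-rank rule; threshold ties are all included,
  so the top-quantile mask can exceed its nominal fraction (an all-equal
  map selects the whole fuel domain).
- **Regime statistics**: a fire counts toward a region/class filter if ≥ 1
  pixel intersects it, contributing its intersected area (keeps areas
  additive across disjoint class filters, at the cost of counts not being
  additive). Decadal summaries are means and sample SDs (ddof = 1) across
  the years within a decade of a single record or run.
- **Calibration** is a diagnostic grid search: the distance between
  regimes is the sum of squared relative errors over (mean annual count,
  overall mean fire size = total area / total fires, mean annual area),
  with absolute differences substituted where the reference value is 0.
- **Difference maps** are reported as hot − warm (positive = the hotter
  trajectory burns more); the subtraction order is explicit in the API.
- **Percent changes** are reported rounded to integer percent when
  |x| ≥ 1 and to one decimal below 1.

## Problem sizes

The test suite and acceptance script run at desk scale, chosen so the full
pipeline (including per-replicate spin-up) completes in seconds while the
statistics remain informative: toy oracle checks on ≤ 10×10 grids;
invariant audits on a 50×50, 10-run, 90-year ensemble with 250-year
spin-ups; stationarity on a 30×30 constant-hazard lattice over 1200 years;
calibration on 30×30 with 60-year records; directional contrasts as 20
paired 40×40 single-replicate experiments. Larger domains and replicate
counts are a matter of the same API with bigger numbers.

## Known limitations

- No sub-annual fire weather, suppression, topographic effects on spread
  or severity, spotting, or fire-size caps.
- One tundra class with a single flammability scalar; no shrub expansion
  or treeline advance, so long-horizon tundra dynamics are conservative.
- The flammability regression is a parameterised stand-in, not a
  calibrated reconstruction of any operational model's coefficients.
- Climate noise is white; interannual persistence (e.g. multi-year
  droughts) is not represented unless supplied via a custom cube.
- `RunEnsemble` stores dense per-run-year snapshots, which is simple and
  fast at desk scale but memory-hungry for very large domains.
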