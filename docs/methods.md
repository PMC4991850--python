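# Methods

## Model overview

`beeforage` simulates one day of colony-level nectar foraging from a
fixed hive in a landscape of discrete, internally homogeneous resource
patches, and converts the day's deliveries into a pesticide-exposure
estimate at the hive entrance. The day is discretized into hourly steps
(default 10 h). The model deliberately excludes in-hive colony dynamics,
pollen foraging, individual flight paths and basal metabolism: it is a
foraging-and-exposure layer, not a full colony model.

### Per-trip energetics

Within a patch, flowers are found according to a Holling type-II
functional response, `f = aF/(1 + ahF)` visits per second at open-flower
density `F`. A forager always fills its crop (`γ` = 32.5 mg), taking
`t_L = γ/(fg)` seconds, where `g` is the nectar yield per flower. Trip
duration adds the out-and-back flight `2D/v`. The energy budget is

* intake `EI = γ e_R`, with `e_R = (sugar share) × e_SUGAR` the energy
  density of the nectar;
* expenditure `EE = γ e_F/(gaF) + 2(D/v) e_F`.

Handling time cancels out of the budget because the cost of sitting on a
flower is roughly an order of magnitude below flight cost and is
ignored; `h` still matters for trip *duration* and hence for how many
trips fit in an hour. Patch attractiveness is the net energetic
efficiency `NEE = (EI − EE)/EE`, the currency best supported for
honeybee foraging decisions. A patch is feasible when its flowers are
open, it lies within the foraging range `D_max`, and `NEE > 0`. Setting
`NEE = 0` gives the threshold distance

```
D_T = (vγ/2) [ e_R/e_F − 1/(gaF) ]
```

which simplifies to `[γv/(2 e_F)] e_R` for mass-flowering crops (dense
flowers, field costs negligible).

### Parameter tables and the flight-cost presets

Honeybee constants: `γ = 32.5 mg`, `v = 4.17 m/s`, unloaded/loaded
flight costs `0.037 / 0.075 J/s`, `e_SUGAR = 17.2 J/mg`, unload-and-dance
time `t_UD = 300 s`, `D_max = 2000 m`, 100 active foragers. Resources:
oilseed rape (`g = 1.071 mg`, `F0 = 264 /m²`, sugar share 0.47,
`a = 1.47e-3 m²/s`, `h = 4.1 s`) and white clover (`g = 0.373 mg`,
`F0 = 2808 /m²`, sugar share 0.74, `a = 2.0e-4 m²/s`, `h = 1.22 s`).

Two presets for the mean flight cost `e_F` are exposed because the
literature values are not mutually consistent: the arithmetic mean of
the measured unloaded/loaded costs gives `0.056 J/s` (threshold
distances 9.6 / 15.1 km for rape/clover), while the published threshold
distances of 8.1 / 12.7 km require `e_F = 0.066 J/s`. The package
defaults to the literal table mean; `BeeParameters.calibrated()` selects
0.066. Both run through identical code — only the constant differs.

### Hourly dynamics

Trips per forager per hour are `b = Δt/(t_trip + t_UD)`, kept
fractional: the delivery equation is a rate equation and integer
truncation would introduce spurious discontinuities. Per patch and hour,
`n (γ − E_c/e_R) b` mg of nectar arrive, where `E_c = e_L D/v` is the
energy burned on the loaded return flight. Open-flower density updates
synchronously:

```
F(t+1) = F(t) − (nγ/(gA)) b − f(F) Z + r (F0 − F),   clamped to [0, F0]
```

(colony depletion, background competitors `Z`, nectar renewal `r`;
defaults `Z = 0`, `r = 0`). Anthesis is binary per hour.

### Colony models

**SO** assigns all foragers to the feasible patch with maximum NEE each
hour. Exact ties are broken by smaller distance, then lexicographic
patch id. A consequence worth knowing: two *exactly* identical
equidistant patches alternate hour by hour, because exploiting one
lowers its density infinitesimally below the other's — deterministic,
and the natural limit of the model rather than a defect.

**RL** models the dance-floor bottleneck. Its mechanism — NEE governs
the probability of abandoning a patch and of recruiting unemployed
followers — is implemented with explicit, replaceable functional forms:
abandonment probability `clamp(κ_a (1 − NEE_i/NEE*), 0, 1)` against the
current best patch (probability 1 on infeasible patches), a fraction `ρ`
of the unemployed pool recruited per hour, split proportionally to dance
strength `n_i · NEE_i⁺` with a floor weight `ε · NEE_i⁺` for unoccupied
patches. Defaults `κ_a = 0.3`, `ρ = 0.3`, `ε = 0.01`; all three surface
in `SimulationConfig`. These forms are a parameterized stand-in honouring
the stated mechanism, not a fit to recruitment data — they should be
treated as the package's own design choice and replaced if calibrated
dynamics become available. Updates are deterministic expected-value
fractions by default (an optional binomial mode samples transitions);
all foragers start the day unemployed; the forager budget is conserved
exactly every hour.

Scout detection `P = 1 − (1−σ)^s` is implemented but the default is
perfect knowledge (`P = 1` for every patch), appropriate for landscapes
with abundant nearby resources.

### Exposure and dilution

Patch contamination is a fixed nectar concentration `C_i` (μg/mg) for
the day — no fate kinetics. Total chemical influx is `Σ n_i γ b_i C_i`
if the chemical is not metabolised (enrichment: the full amount arrives
in a partly consumed load) or `Σ n_i (γ − E_c,i/e_R,i) b_i C_i` if it is
metabolised with the sugar. Dividing by the sugar influx
`Σ n_i (γ e_R,i − E_c,i)/e_SUGAR · b_i` gives the sugar-based hive
concentration `X_e` or `X_m`; dividing that by the reference
`X_P = C_P e_SUGAR/e_R` gives the dilution factors `φ_e ≥ φ_m`. On
single-resource days `φ` is independent of `C_P` and reduces to the
treated-trip weighted fraction, so `φ_m = 1` exactly when every
exploited patch is treated. A day with no sugar delivered has no defined
concentration and is reported as an explicit no-exposure marker, never
NaN or 0.

### Landscape, hive sites, scenarios

Patches carry planar shapely geometry (GeoJSON or CSV-with-WKT I/O; no
CRS handling). Candidate hive sites are the 25 m grid cells 8-adjacent
to a target-crop field; assessments run on a seeded sample (default 10%)
that depends only on the landscape and seed, hence identical across
scenarios. Hive–patch distance is the Euclidean distance from the cell
centre to the patch geometry, floored at half a grid cell (12.5 m) so
the adjacent field is near-optimal without a `D = 0` singularity. The
field a hive borders is always treated — the worst-case anchor of the
assessment.

Scenarios: (i) *alternative fields* — target fields treated i.i.d.
Bernoulli(p), alternative-crop fields untreated with nectar sugar share
scaled by 0.8–1.2; (ii) *flower strips* — up to four clover strips per
target field, each present with probability p, one per quarter-perimeter
boundary segment, area `w × perimeter/4` subtracted from the host field
(widths 1–10 m); strip geometry is the boundary segment itself, since
only area and distance enter the model; (iii) *off-field habitats* —
each off-field element becomes clover with probability p at 0.5/1/1.5 ×
field density. In (ii) and (iii) all target fields are treated (p refers
to habitat presence, and the worst case for exposure is full treatment).
Presence/treatment draws use `u_i < p` with one uniform per patch and
seed, so realizations are nested across p for a fixed seed — paired-seed
comparisons along the p-grid are exact couplings, not Monte-Carlo races.

Percentiles of the dilution distribution are empirical quantiles with
linear interpolation over the per-site means across realizations (the
estimator is configurable in spirit; sites with no defined exposure in
any realization are excluded and counted). Per-realization seeds derive
from the master seed via `numpy.random.SeedSequence` spawn keys.

### Synthetic landscapes

The generator emulates an intensive arable region: non-overlapping
axis-aligned rectangular fields (2–10 ha) for the target and alternative
crops and hundreds of narrow rectangles (50–300 m × 2–6 m) for off-field
elements, on a 5 × 5 km extent by default. It reproduces the *structure*
that drives the model — patch areas, distances, abundances — but not the
shapes, spatial autocorrelation or road-network alignment of real
parcels, nor mixed-species off-field vegetation. Conclusions from
synthetic runs are therefore structural (which scenario is more
area-efficient, how patch abundance changes exploited-patch counts), not
absolute predictions for any real region.

## Test and example problem sizes

The shipped tests and examples use reduced problem sizes chosen so the
full suite documents the model's behaviour at interactive timescales: a
3 km extent with ~15 target fields and ~120 off-field elements, 4–5
realizations and a few percent of candidate sites for scenario sweeps;
20-patch fuzzed landscapes for the oracle-equivalence and conservation
checks; 1000 treatment realizations for the mean-dilution convergence
check (treatment is independent of patch choice, so the day is simulated
once and only the exposure bookkeeping is re-evaluated per draw). The
library itself has no such limits; the CLI defaults (100 realizations,
11-point p-grid, 10% of sites) match a full assessment.

## Known limitations

* The RL recruitment constants are uncalibrated stand-ins (above).
* Nectar standing crop `g` is a per-visit average; within-day nectar
  secretion dynamics beyond the linear renewal term are not modelled.
* Off-field and strip patches default to zero contamination; spray-drift
  exposure of strips would need per-patch `C` values, which the data
  model supports but no scenario sets.
* Detection (`σ_i`) must be supplied per patch if perfect knowledge is
  switched off; the package provides no movement model to derive it.
* One day, one colony: no carry-over between days, no competition among
  managed hives beyond the constant background density `Z`.
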