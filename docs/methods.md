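# Methods

`medaccess` evaluates how conveniently residents of a gridded study
region reach medical services of three tiers, and how equitably that
convenience is distributed across places and population groups.  This
note documents the models, their assumptions, the parameters that
matter, and the design choices made where the methods literature leaves
the design open.

## Travel costs on the transport network

The transport network is an undirected graph built from typed polyline
segments.  Each road class carries an average speed: national 80,
provincial 70, county 50, township 25, special-purpose 20, village
15 km/h; high-speed and ordinary rail run at 200 and 120 km/h.  Nodes
are created at segment endpoints and at road-road crossings; rail is
deliberately *not* noded where it crosses a road at grade — trains are
boarded only at stations, which are the shared endpoints of rail and
road segments.

Demand points (cell centroids) and facilities rarely sit on the
network, so an origin-destination cost has three parts: an access leg
from the origin to its nearest road point, the shortest network path,
and an access leg to the destination.  Access legs use a two-speed
rule: gaps up to `d_threshold` (1250 m, the distance walked in 15 min
at 5 km/h) are walked at 5 km/h; longer gaps are covered at a feeder
speed of 25 km/h, standing in for informal transport on roads lost in
digitisation.  Because dropped minor roads can make two nearby points
look far apart on the network, the returned cost is

    cost(o, d) = min(network route, direct route),

where the direct route costs the straight-line distance by the same
two-speed rule (time metric) or uses raw metres (space metric).  The
min rule subsumes the weaker conditional "use the direct route when it
beats the two access legs"; that literal conditional is available as
`AccessParams(direct_rule="literal")`, and `direct_rule="network"`
gives the plain node-cost result for comparison.  Disconnected pairs
fall back to the direct route rather than infinity.

Snapping may land mid-edge; the cost engine inserts virtual nodes at
facility snap points and resolves mid-edge origins through the two
bracketing nodes plus a same-edge shortcut, so path costs are exact
rather than rounded to the nearest endpoint.  Equidistant snap
candidates are tie-broken by edge index for determinism.

Two metrics are carried through the whole analysis: `time_min`
(relative accessibility — sensitive to transport quality) and `space_m`
(absolute accessibility — what remains when transport is absent).
Space costs never touch speeds; doubling every speed changes no space
matrix entry.

## Accessibility surfaces

Residents behave differently by disease severity, so three engines
produce six surfaces (each engine × both metrics):

* **Primary (`Pri_T`, `Pri_S`)** — nearest-cost: the minimum travel
  cost from a cell to *any* facility. Lower is better; units are
  minutes or metres.
* **Secondary (`Sec_T`, `Sec_S`)** — two-step floating catchment area
  over secondary + tertiary facilities.  Step one gives each facility
  `j` a supply-demand ratio `R_j = S_j P_j / Σ_k D_k d_kj^-β` over
  demand within the catchment `d_kj < d0`; step two sums
  `Σ_j R_j d_ij^-β` over facilities within `d0` of the cell.  `S_j` is
  staff count, `P_j` the capacity weight (2 for tertiary hospitals, 1
  otherwise), `β = 1` (attractiveness dominates distance for difficult
  cases), and `d0` is 120 min or 10 km — both two hours of travel, the
  latter at walking speed.  The threshold is strict (`d < d0`), so
  boundary ties are excluded.  Higher is better; units are staff per
  person.
* **Tertiary (`Ter_T`, `Ter_S`)** — serious cases are treated in the
  resident's own city or the provincial capital, with no catchment
  limit and rail enabled for the time metric.  The surface is the sum
  of an own-city gravity term (capacity weight 1, friction β₁ = 1.5,
  competition pool = the city's cells) and a capital term (capacity
  weight 2, friction β₂ = 1.0, pool = every cell).  A city without a
  tertiary hospital simply contributes a zero own-city term.

Numerical choices: the decay kernel `d^-β` diverges as `d → 0`, so
distances are floored at `eps` (1 min or 1000 m) before decay; this
keeps self-cell facilities finite without reordering distant
contributions.  Zero-population cells remain demand points (they
receive values but add nothing to denominators).  A facility with no
demand in its catchment gets `R_j = 0` with a logged warning.  As the
capital-term equations are written, capital residents receive their
hospitals under both the own-city and the capital weighting; this
double contribution is implemented as written, with
`FCAParams(suppress_capital_own_term=True)` to drop it.  The capital
term uses β₂ in both its numerator and denominator (single-exponent
reading).

When every facility's catchment holds populated demand, 2SFCA
conserves supply exactly: `Σ_i D_i A_i = Σ_j S_j P_j`.  This identity
is the main correctness check on the implementation.

## Spatial autocorrelation

Global Moran's I is `I = n/S0 · Σ_ij w_ij z_i z_j / Σ_i z_i²` with
`z` the mean-centred surface.  Local Moran's
`I_i = z_i Σ_j w_ij z_j` uses values standardised by the population
(n-divisor) standard deviation, so `Σ_i I_i / S0` reproduces the
global index.  Default weights are queen contiguity on the demand
grid, row-standardised; rook and distance-band schemes are available,
and per-subdivision analyses rebuild weights inside the subdivision
rather than masking the full matrix.  Inference is by permutation —
full permutation for the global index, conditional permutation
(999 draws, α = 0.05, seeded) for the local indices; significant units
are classed HH/LL/LH/HL from the signs of `(z_i, lag_i)`.  For cost
surfaces the labels are reported on the raw costs, so LL marks
good-access clusters.  Constant surfaces are rejected (zero variance),
and isolated units keep zero-weight rows with a warning.

## Equity statistics

Nearest-cost surfaces are first made "higher = better" by taking
reciprocals and min-max normalising; catchment surfaces pass through
unchanged.  The Lorenz curve accumulates population share against
population-weighted accessibility share with units sorted ascending by
value (ties broken by position); Gini = 1 − 2 × trapezoidal area under
the curve, which matches the population-weighted mean-absolute-
difference formula to 1e-10.  Zero-population cells carry no Lorenz
mass.

County accessibility is the population-weighted mean of the county's
cells.  Group equity is assessed by Pearson correlation between county
accessibility and the county share of a group (aging, agricultural),
with two-tailed p-values starred at 0.05/0.01, and by composition
tables across percentile bins of the surface — deciles plus a top-10%
readout, population-weighted binning by default with a cell-count
option.  Composition tables report both the within-bin group share
(group + complement sum to 1) and each group's distribution across
bins.  Correlation and composition use raw (signed) surfaces, so
nearest-cost surfaces correlate positively with disadvantage.

## Sensitivity analysis

The sweep recomputes the catchment surface varying one parameter at a
time from the defaults (`d0` = 120 min, tertiary weight 2): thresholds
90/120/150 min and weights 1.5/2.0/2.5.  Each variant is summarised by
nearest-rank decile values plus max/min/median/mean/std on unweighted
cell values (a population-weighted variant sits behind a flag), and
paired (default, variant) values are emitted for 45-degree scatter
comparison.  Two exact monotonicities hold: per-cell values are
non-decreasing in the tertiary weight, and by the conservation
identity the population-weighted mean is non-decreasing in `d0`.

## The synthetic-data generator

No real region ships with the package; `generate_region` draws study
regions with the structure the analysis assumes.  On a square grid
(default 20 × 20 cells of 5 km) it places `n_cities` urban cores at
least two cells apart, assigns every cell to its nearest core, and
splits the population (default one million): 60% goes to core
neighbourhoods (a decaying kernel around each core), 40% to a uniform
rural field, allocated by largest-remainder rounding so totals are
exact.  Aging shares are higher in core cells (0.15 vs 0.09) and
agricultural shares far higher in rural cells (0.75 vs 0.15), drawn
binomially.  Facilities follow the three-tier structure: primary
facilities sampled proportional to population, secondary proportional
to its square (urban-biased), and tertiary hospitals only in core
cells — about half in the capital, the remainder assigned to other
cities by population rank, so small cities may have none.  Staff
counts are log-normal with level-dependent medians (20/150/800,
σ = 0.5).

The road network is a lattice whose nodes are jittered off the cell
centroids (uniform ±0.2 cell): demand points must not coincide with
the network, because the access-leg model exists precisely for
off-network demand.  A national-class backbone follows core-to-core
routes, county-class edges are random infill (`road_density`), a
township/village spanning tree covers the rest, and leaf edges are
pruned to a target coverage of ~92% of cells (never below 90%, cores
always connected).  One ordinary-rail line threads the cores through
the capital, sharing nodes with roads only at the core stations.
Counties are coarse grid blocks; cities are banded into three
subdivisions by latitude.  Everything derives from a single seeded
generator, so a (config, seed) pair is bit-reproducible.

What the generator does **not** emulate: real road geometry (curvature,
one-way streets, congestion), terrain barriers, facility quality
differences beyond staff counts, within-cell population placement, and
migration/referral behaviour.  Tests passing on these regions
demonstrate that the pipeline recovers the *directional* structure —
concentrated tertiary access, space costs less equitable than time
costs, agricultural deprivation — not that it reproduces any real
province's numbers.

`fixture_minimal` is a 3 × 3-cell region with two crossing roads, one
rail diagonal and four on-road facilities whose every travel cost can
be traced by hand; it anchors the exhaustive path-enumeration oracle
tests.

## Problem sizes and runtimes

The test suite and the acceptance script run the full pipeline on the
default 400-cell region (about ten seconds per region on one CPU) and
use 50 seeded replicates for the directional findings; permutation
inference uses 999 draws in the pipeline, 9999 where the permutation
mean itself is under test.  All randomness flows from one recorded
seed through named substreams.

## Known limitations

* Travel times ignore congestion, schedules, turn restrictions and
  boarding penalties; rail transfer is free at stations.
* The two-speed access rule is discontinuous at `d_threshold`
  (a 1300 m gap is "cheaper" than a 1200 m one), inherited from the
  method; the min rule bounds, but does not remove, its effects.
* Min-max normalisation of reciprocal costs is sensitive to the
  single cheapest cell on small grids.
* The power decay `d^-β` with a floor is one of several defensible
  kernels; Gaussian or kernel-density 2SFCA variants are out of scope.
* LISA p-values are not corrected for multiple testing.
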