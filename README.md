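# medaccess

Spatial accessibility and equity analysis for three-tier medical
services on transport networks.

Health planners and spatial epidemiologists need to know not just where
hospitals are, but how cheaply every resident can reach them — and
whether that cost is shared fairly across places and social groups.
`medaccess` implements a complete, tested pipeline for that question on
gridded population data: travel-cost matrices on typed road/rail
networks, accessibility surfaces matched to how people actually seek
care at three service tiers, spatial-autocorrelation structure, and
population-weighted equity statistics.  Because the underlying
census/road/facility data of such studies are rarely deposited, the
package includes a first-class synthetic-region generator that
reproduces their structure (urban cores, rural periphery, tiered
facilities, typed roads, a rail line) from a single seed.

## The models

**Travel cost.**  An origin-destination cost combines an access leg
from the origin to the nearest road (walked at 5 km/h up to 1250 m —
a 15-minute walk — then at a 25 km/h feeder speed), the shortest
network path at class speeds (national 80 … village 15, rail 120/200
km/h), and an access leg at the destination.  To suppress artefacts of
missing minor roads, the result is `min(network route, direct route)`,
the direct route costed by the same two-speed rule.  Costs come in two
metrics: minutes (`_T`, relative accessibility) and metres (`_S`,
absolute accessibility without transport).

**Three service tiers.**  For common ailments (primary care,
`Pri = min_k Cost_ik`) only proximity matters and every facility
counts.  For difficult cases (secondary, `Sec`) supply, competition
and distance decay all matter — the two-step floating catchment area
method with decay `d^-β`, `β = 1`, within a two-hour catchment
(120 min or 10 km):

    R_j = S_j P_j / Σ_{k: d_kj < d0} D_k d_kj^-β        (supply/demand per facility)
    A_i = Σ_{j: d_ij < d0} R_j d_ij^-β                  (accessibility per cell)

with staff counts `S_j`, capacity weights `P_j` (2 for tertiary, 1
otherwise) and populations `D_k`.  For serious disease (tertiary,
`Ter`) residents use tertiary hospitals in their own city or the
provincial capital, rail included, with no catchment limit: an
own-city gravity term (weight 1, friction 1.5) plus a capital term
(weight 2, friction 1.0) over a province-wide pool.

**Structure and equity.**  Global and local Moran's I with permutation
inference classify HH/LL/LH/HL clusters of each surface; Lorenz curves
and population-weighted Gini coefficients (cost surfaces inverted and
min-max normalised first) quantify inequality; county-level Pearson
correlations and percentile-bin composition tables expose group
deprivation (aging vs agricultural populations); and a sensitivity
sweep varies the catchment threshold (±30 min) and tertiary capacity
weight (±0.5).

See `docs/methods.md` for assumptions, parameter defaults and design
choices.

## Worked example

```python
import numpy as np
import medaccess as m

region = m.generate_region(m.RegionConfig(seed=1))   # 20x20 grid, 4 cities
cells = region.cells
pops = np.array([c.population for c in cells], float)

time_costs = m.cost_matrix(cells, region.facilities, region.network)
pri_t = m.nearest_cost(time_costs, region.facilities)
print(f"Pri_T: mean {pri_t.values.mean():.1f} min, "
      f"range {pri_t.values.min():.1f}-{pri_t.values.max():.1f} min")

sec_f = region.facilities_by_level("secondary", "tertiary")
sec_t = m.two_step_fca(time_costs, cells, sec_f, m.FCAParams.time_defaults())

w = m.build_weights(cells, "queen")
res = m.global_moran(sec_t, w, n_permutations=999, seed=1)
print(f"Moran's I (Sec_T) = {res.global_I:.3f}, p = {res.p_value:.3f}")

print(f"Gini (Sec_T) = {m.lorenz_gini(sec_t.values, pops).gini:.3f}")

r, p, stars = m.group_correlation(
    m.aggregate_to_county(sec_t, cells),
    m.county_group_ratios(cells, "agricultural"))
print(f"agricultural share vs Sec_T: r = {r:.3f}{stars}")
```

prints

```
Pri_T: mean 21.6 min, range 3.0-51.9 min
Moran's I (Sec_T) = 0.899, p = 0.001
Gini (Sec_T) = 0.425
agricultural share vs Sec_T: r = -0.867**
```

Read: the average cell is 21.6 minutes from its nearest facility;
secondary-care accessibility is strongly spatially clustered
(I = 0.899 against an expectation near zero); its population-weighted
Gini of 0.425 signals substantial inequality; and counties with larger
agricultural population shares have significantly worse secondary-care
access (r = −0.867, p < 0.01) — the deprivation pattern the equity
module is designed to surface.

The same analysis runs end to end from the command line:

```sh
medaccess run-all --seed 1 --out output/
medaccess generate --seed 1 --out work/        # or stage by stage
medaccess costs  --region work/region --out work/
medaccess access --region work/region --costs-dir work/ --out work/
```

`run-all` writes every artifact (region GeoJSON/CSV, cost matrices,
six surfaces, Moran/LISA tables, Gini/correlation/composition tables,
sensitivity tables) plus a manifest with parameters, warnings and
checksums; repeated runs with one seed are bit-identical.

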