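# Methods

## Model structure

The simulator couples two layers over a grid of 1-ha cells on an annual
time-step:

1. **State-and-transition layer** — each cell's vegetation class and age
   change through probabilistic succession pathways and area-targeted
   disturbance/management events.
2. **Stock-flow layer** — eight carbon pools per cell evolve by the gain–loss
   method: every flow is either a proportional multiplier of its
   start-of-year "from" stock or an absolute species rate.

Within a year the operation order is: targeted events (in random group
order), probabilistic transitions, carbon flows, age increment. Flows run
after transitions so that fire consumption acts on current-year stocks. Cells
whose age was reset during the year report age 0 at year end. All randomness
flows from a single seeded generator; identical seeds give bit-identical
ledgers and final landscapes.

## Carbon flows and their parameters

Per forested species (Atlantic white cedar AWC, cypress-gum CG, maple-gum MG,
pond pine PP) the packaged tables provide: total NPP (11.35 / 10.78 / 9.29 /
10.47 t C/ha/yr), its leaf/wood/root partition (sums to 1 within 1e-9 for
every species), turnover multipliers from live pools to detritus, and
humification/emission multipliers from each detritus pool. Pond pine stocks
are the mean of the other three species, a constraint re-verified at load
time. A second load-time check confirms that multiplier × mature stock
reproduces the calibrated literature flow density (printed value plus its
calibration delta) within 0.01 t C/ha for all 48 biomass flows.

The update is a simultaneous explicit step on start-of-year stocks. If a
pool's total outflow would exceed its stock, all its outflows are scaled
proportionally; pools are clamped non-negative. Non-forested classes receive
no flows: marsh and open water carry only their passive peat column, and
upland pine is carried but inert (no transitions, no flows).

**Peat.** Carbon density per cm of peat is bulk density × organic fraction ×
carbon fraction × 100 = 0.16 × 0.95 × 0.59 × 100 = 8.968 t C/ha/cm; a 40-cm
upper layer holds 358.7 t C/ha and the 60-cm deep layer 538.1, matching the
published column densities to 0.1% (they round the same product). The upper
peat (acrotelm) is modelled at steady state: its atmospheric emission each
year equals the humification inflow minus the species accumulation rate into
the deep peat (0.36 / 0.14 / 0.12 / 0.17 t C/ha/yr), floored at zero. An
alternative "multiplier" mode applies the published upper-peat multipliers
instead; it exists for sensitivity analysis because the two published
parameterizations of the peat layer are mutually inconsistent (the multiplier
form does not reproduce the tabulated flow densities), and the steady-state
form is the one the source describes in words. The accumulation rates follow
the species-specific "this study" values; where the two published tables
disagree on CG vs MG (0.14/0.12 vs 0.12/0.14) we follow the species-rate
table.

**Disturbance flows.** Hurricane windthrow moves live pools into the
corresponding dead pools (carbon-conserving) and resets age. Deadwood salvage
moves the entire deadwood stock to a harvested-wood-products pool (leaves the
ecosystem ledger) and replants cedar at age 0. Fire consumption removes
fractions of the four above-ground fuels (live leaf, live wood, leaf litter,
deadwood) to the atmosphere as above-ground emissions, and centimetres of
peat (upper layer first, then deep, tracked as depth) plus — for repeat
catastrophic fires — all live and dead roots, as below-ground emissions.
Ordinary (non-catastrophic) fires use severity-based default consumption:
low = 50% of leaf litter; medium = all litter + 50% of deadwood; high = 80%
of all above-ground fuels, no peat. These defaults are this package's own
choices (only the two catastrophic events have documented consumption) and
are fully configurable.

## Spin-up calibration

Growth curves come from a 300-year cold start: all biomass pools at zero,
constant NPP and multipliers. Live wood then follows the exact discrete
recursion W(t+1) = W(t) + I − mW(t), so the iterated curve must match
(I/m)(1−(1−m)^t) to floating point; the tests enforce 1e-9. Live-tree biomass
is defined as live leaf + live wood (roots excluded, configurable). The
curves are strictly concave — constant NPP cannot produce the sigmoid shape
of inventory chronosequences — and should be read as equilibria-consistent
interpolators. Equilibrium is declared at the first age where the annual
relative live-tree increase falls below 1e-3 (no published tolerance exists);
this lands at age ~143 for cedar and ~175 for cypress-gum, with biomass
within a few percent of the analytic fixed points. The monotone segment of
each curve is inverted (binary search, "smallest age whose biomass reaches
the input") into the biomass→age lookup; inputs above the curve maximum
saturate at the equilibrium age.

Initial stocks for a landscape are taken from the mature-stand densities by
default, or re-derived from the growth curves at each cell's age whenever
ages are edited (historic rollback), since the literature densities describe
mature stands only. Rolled-back cells keep the standard peat column; the
biomass pools come from the curve.

## Synthetic landscape and reconstruction

The refuge's vegetation map, age map, strata delineation and fire perimeters
are unpublished, so the generator emulates them:

* **Composition**: 54,000 cells on a 225×240 grid; class quotas by
  largest-remainder apportionment (61% MG, 15% PP, 12% CG, 3% AWC, 6% marsh,
  3% open water), realized exactly by competitive seeded region growing
  (random nuclei, one-cell frontier expansion weighted by remaining quota).
* **Strata**: one contiguous Dry region covering 20% of the landscape (the
  true delineation came from unreproducible interactive mapping); all
  disturbance perimeters are grown inside it.
* **Ages**: forested cells uniform on [20, 80] years as the 1985 initial
  structure — a documented stand-in for the unavailable age map — except the
  disturbance-scar region, overridden to Atlantic white cedar at age 100 (the
  average mature cedar age), per the reconstruction rule for the area later
  hit by the hurricane and both catastrophic fires.
* **Perimeters**: 8-connected masks with exact cell counts; the 2011
  perimeter is grown to exactly 2,125 cells (85%) inside the 2008 perimeter
  and 375 outside. The 0.85 overlap fraction is a reconstruction chosen so
  that 0.85 × 2500 ha × 50 cm × 8.968 t/ha/cm ≈ 0.95 Tg matches the
  documented below-ground loss of the second fire; it is configuration, not
  ground truth.

The reconstructed schedule: hurricane 2003 (625 ha of cedar, live→dead);
salvage+replant 316 ha split evenly over 2004–2007; South One fire 2008
(2,400 ha, 80% of above-ground fuels + 20 cm peat on every burned cell);
Lateral West fire 2011 (2,500 ha; the overlap cells are repeat-catastrophic
and lose all remaining above-ground fuel + 50 cm peat + roots, then convert
to marsh; the non-overlap cells burn at drawn severity). Four smaller fires
(1987/1995/2001/2014, 150–400 ha, severity-based consumption) stand in for
the remainder of the regional fire record; their years and areas are
reconstructions. Simulated salvage removes ~0.03 Tg — an order more than the
published 0.01 Tg, which is arithmetically unreachable for 316 ha of
hurricane-felled cedar deadwood at its simulated density; the published
basis is unknowable and the quantity plays no role in the fire totals.

What passing tests on this synthetic landscape do **not** show: agreement of
full-landscape NEP/NECB with the published totals (those depend on the true
1985 age structure), realistic patch shapes or hydrology, or Wet↔Dry strata
dynamics (pathways exist in concept but no rates are published; the hook
defaults to off). The fire-emission totals are robust to the landscape seed
because the scar region's state is pinned by the reconstruction rule.

## Numerical choices and edge cases

* Float64 throughout; ledger closure (ΔC = Growth − R_h − Fire − Management)
  holds to ~1e-14 Tg per year on the full landscape.
* Severity draws are i.i.d. per burned cell with proportions
  0.163/0.409/0.428; only high severity (and repeat fires) reset age; no
  class change below repeat-catastrophic.
* Adjacency multipliers: 8-neighbor fraction, denominator = in-grid non-void
  neighbors (avoids edge bias); refreshed every 5 simulated years.
* Area targets select uniformly without replacement among eligible cells;
  shortfalls are fulfilled at the eligible area and logged.
* Fires are eligible on forested cells only; a peat-depth request beyond the
  remaining column is clamped.
* Conversion to marsh transfers residual live pools to dead pools so the
  landscape ledger stays closed; marsh detritus is then inert.
* Re-accumulation horizons round to the nearest decade (half-up).
* Raster I/O supports ESRI ASCII grids and CSV cell tables; the geospatial
  layer is deliberately thin (no CRS handling).

## Known limitations

Constant NPP (no age, climate or moisture response); no CH₄/N₂O; no
hydrologic water-table model; strata fixed over a run; detritus
decomposition has no temperature/moisture modifiers; the synthetic landscape
approximates composition and areas, not geography.
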