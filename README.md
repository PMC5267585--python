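# peatlucas

A coupled **state-and-transition / carbon stock-flow simulator** for forested
peatlands, configured for the Great Dismal Swamp (Virginia/North Carolina,
USA). It is aimed at carbon-cycle modellers and land managers who need annual
ecosystem carbon budgets for a disturbance-prone peat swamp: forest
succession, hurricane windthrow, salvage management, and — critically —
catastrophic peat-burning wildfires.

## The model

The landscape is a grid of 1-ha cells. Each cell carries a vegetation state
class (Atlantic white cedar, cypress-gum, maple-gum, pond pine, marsh, open
water, upland pine), a moisture stratum (Wet/Dry), a stand age, and eight
carbon pools (t C/ha): live leaf, live wood, live root, leaf litter,
deadwood, dead root, upper peat (acrotelm, 0–40 cm) and deep peat (catotelm,
41–100 cm).

**Transitions.** Land-cover change is a non-stationary Markov process.
Alternative succession (young cedar/pond-pine stands converting to maple-gum)
is probabilistic, gated by stand age (≤ 5 yr) and by an adjacency multiplier
— the fraction of the eight neighbors already in maple-gum. Known events
(fires, hurricane, salvage) are *area targets*: an exact number of hectares
realized inside a mapped perimeter. A second fire within five years on the
same Dry-stratum cells is a *repeat catastrophic fire*: age resets and the
cell converts to marsh.

**Carbon flows.** Stocks evolve by the IPCC gain–loss method,
`ΔC = Σ [A·(C_g − C_l)]`: per year, NPP is partitioned into the live pools;
fixed fractions of live pools move to detritus (litterfall, mortality);
detritus is split between humification into the upper peat and emission to
the atmosphere; the upper peat is held at steady state (its emission balances
humification inflow net of a slow species-specific accumulation into the deep
peat). Fires combust fractions of the above-ground fuels and centimetres of
the peat column (8.968 t C/ha per cm at bulk density 0.16 g/cm³, 95% organic
matter, 59% carbon).

**Accounting.** The annual ledger yields
`NEP = Growth − R_h` and `NECB = NEP − Management − FireEmissions`
(negative NECB = net source).

Because the refuge's vegetation/age maps and fire perimeters are not
published, a seeded synthetic generator reproduces the documented composition
(54,000 ha; 61% maple-gum, 15% pond pine, 12% cypress-gum, 3% cedar) and the
two catastrophic fire perimeters (2,400 ha in 2008; 2,500 ha in 2011 with 85%
overlap) with exact areas and 8-connectivity.

## Worked example

```bash
peatlucas run --seed 1 --out run_out
```

prints

```
NEP  =     1.39 Tg C over 30 years
NECB =    -0.40 Tg C over 30 years
```

i.e. over 1985–2015 the undisturbed biology is a net sink (positive NEP), but
fire emissions flip the landscape to a net carbon source (negative NECB). The
per-event fire summary written to `run_out/fire_summary.csv`:

```
           name   year  agb_loss_tg  bgb_loss_tg  total_loss_tg  soil_elevation_loss_m
      South One 2008.0     0.225544     0.430464       0.656008                    0.2
   Lateral West 2011.0     0.087256     0.992832       1.080088                    0.5
     Cumulative    NaN     0.335560     1.423296       1.758856                    0.7
```

The 2008 fire consumes far more above-ground fuel than the 2011 fire (the
hurricane-killed deadwood was still on the ground), while the 2011 repeat
fire dominates below-ground losses (50 cm of peat plus roots on the overlap).
The elevation column converts peat carbon loss back into the equivalent soil
surface drop: 0.20 m + 0.50 m = 0.70 m cumulatively.

Other entry points: `peatlucas spinup` (growth curves), `peatlucas synth`
(write the synthetic landscape and perimeters), `peatlucas report LEDGER.csv`.

As a library:

```python
from peatlucas import load_species_params, spinup_all, StateClass

params = load_species_params()           # validated parameter tables
curves = spinup_all(params, years=300)   # cold-start growth curves
curves[StateClass.ATLANTIC_WHITE_CEDAR].pool("live_wood")[100]  # -> 92.3 t C/ha
```

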