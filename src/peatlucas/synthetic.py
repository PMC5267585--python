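"""Seeded synthetic landscapes and disturbance perimeters.

The refuge's vegetation map, age map, moisture-zone delineation and mapped
fire perimeters are not published, so this module generates stand-ins with
the documented composition (about 54,000 ha; 3% Atlantic white cedar, 12%
cypress-gum, 61% maple-gum, 15% pond pine, remainder marsh/open water),
spatially clustered patches, a contiguous Dry zone containing the disturbance
scar, and 8-connected fire perimeters with controlled areas and pairwise
overlap. Everything is deterministic per seed.

Patches are grown by seeded region growing: random nuclei per class expand a
cell at a time into unassigned territory, with the class to grow chosen in
proportion to its remaining quota, so the final cell counts hit the target
proportions exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .landscape import Landscape, initialize_stocks
from .params import (
    SoilParams,
    SpeciesParams,
    StateClass,
    Stratum,
)
from .spinup import GrowthCurve

_NEIGH8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


DEFAULT_PROPORTIONS = {
    StateClass.ATLANTIC_WHITE_CEDAR: 0.03,
    StateClass.CYPRESS_GUM: 0.12,
    StateClass.MAPLE_GUM: 0.61,
    StateClass.POND_PINE: 0.15,
    StateClass.MARSH: 0.06,
    StateClass.OPEN_WATER: 0.03,
}


@dataclass
class LandscapeConfig:
    """Configuration of the synthetic landscape generator."""

    total_area_ha: int = 54_000
    class_proportions: dict = field(default_factory=lambda: dict(DEFAULT_PROPORTIONS))
    dry_fraction: float = 0.20
    age_range: tuple[int, int] = (20, 80)  # uniform forest ages, inclusive
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.class_proportions.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"class proportions must sum to 1, got {total}")
        if any(v < 0 or v > 1 for v in self.class_proportions.values()):
            raise ValueError("class proportions must be in [0, 1]")
        if not 0 <= self.dry_fraction <= 1:
            raise ValueError("dry_fraction must be in [0, 1]")


def grid_shape(n_cells: int) -> tuple[int, int]:
    """A near-square grid holding exactly ``n_cells`` (54,000 -> 225 x 240)."""
    r = int(round(math.sqrt(n_cells)))
    for rows in range(r, max(0, r - 60), -1):
        if rows > 0 and n_cells % rows == 0:
            return rows, n_cells // rows
    # fall back to a padded grid; callers treat extra cells as void
    return r, math.ceil(n_cells / r)


def _exact_counts(n: int, proportions: dict) -> dict:
    """Largest-remainder apportionment of n cells to classes."""
    raw = {k: v * n for k, v in proportions.items()}
    counts = {k: int(math.floor(v)) for k, v in raw.items()}
    short = n - sum(counts.values())
    for k in sorted(raw, key=lambda k: raw[k] - counts[k], reverse=True)[:short]:
        counts[k] += 1
    return {k: c for k, c in counts.items() if c > 0}


def _region_grow_classes(
    shape: tuple[int, int], counts: dict, rng: np.random.Generator
) -> np.ndarray:
    """Assign every cell a class via competitive seeded region growing."""
    nr, nc = shape
    state = np.zeros(shape, dtype=np.int16)
    classes = list(counts)
    remaining = {k: counts[k] for k in classes}
    frontiers: dict[StateClass, list[tuple[int, int]]] = {k: [] for k in classes}

    def plant_nucleus(cls) -> bool:
        free = np.nonzero(state == 0)
        if len(free[0]) == 0:
            return False
        i = rng.integers(len(free[0]))
        r, c = int(free[0][i]), int(free[1][i])
        state[r, c] = int(cls)
        remaining[cls] -= 1
        frontiers[cls].append((r, c))
        return True

    # a handful of nuclei per class, scaled with its quota
    for cls in classes:
        n_nuclei = max(1, counts[cls] // 4000)
        for _ in range(n_nuclei):
            if remaining[cls] > 0:
                plant_nucleus(cls)

    active = [k for k in classes if remaining[k] > 0]
    while active:
        weights = np.array([remaining[k] for k in active], dtype=float)
        cls = active[rng.choice(len(active), p=weights / weights.sum())]
        grown = False
        frontier = frontiers[cls]
        while frontier and not grown:
            j = rng.integers(len(frontier))
            r, c = frontier[j]
            free = [
                (r + dr, c + dc)
                for dr, dc in _NEIGH8
                if 0 <= r + dr < nr and 0 <= c + dc < nc and state[r + dr, c + dc] == 0
            ]
            if not free:
                frontier[j] = frontier[-1]
                frontier.pop()
                continue
            rr, cc = free[rng.integers(len(free))]
            state[rr, cc] = int(cls)
            remaining[cls] -= 1
            frontier.append((rr, cc))
            grown = True
        if not grown:  # isolated quota: start a new patch
            grown = plant_nucleus(cls)
        if not grown or remaining[cls] == 0:
            active = [k for k in classes if remaining[k] > 0]
    return state


def grow_mask(
    allowed: np.ndarray,
    n_cells: int,
    rng: np.random.Generator,
    seeds: list[tuple[int, int]] | None = None,
) -> np.ndarray:
    """Grow an 8-connected mask of exactly ``n_cells`` within ``allowed``."""
    nr, nc = allowed.shape
    if int(np.count_nonzero(allowed)) < n_cells:
        raise ValueError("not enough allowed cells to grow the requested mask")
    mask = np.zeros(allowed.shape, dtype=bool)
    if n_cells == 0:
        return mask
    if not seeds:
        rr, cc = np.nonzero(allowed)
        i = rng.integers(len(rr))
        seeds = [(int(rr[i]), int(cc[i]))]
    frontier: list[tuple[int, int]] = []
    count = 0
    for r, c in seeds:
        if allowed[r, c] and not mask[r, c] and count < n_cells:
            mask[r, c] = True
            frontier.append((r, c))
            count += 1
    while count < n_cells:
        if not frontier:
            raise ValueError("allowed region exhausted before reaching target area")
        j = rng.integers(len(frontier))
        r, c = frontier[j]
        free = [
            (r + dr, c + dc)
            for dr, dc in _NEIGH8
            if 0 <= r + dr < nr
            and 0 <= c + dc < nc
            and allowed[r + dr, c + dc]
            and not mask[r + dr, c + dc]
        ]
        if not free:
            frontier[j] = frontier[-1]
            frontier.pop()
            continue
        rr, cc = free[rng.integers(len(free))]
        mask[rr, cc] = True
        frontier.append((rr, cc))
        count += 1
    return mask


@dataclass
class PerimeterSpec:
    """Area and overlap constraints for a synthetic disturbance perimeter."""

    area_ha: float
    overlap_with: np.ndarray | None = None
    overlap_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.area_ha < 0:
            raise ValueError("area_ha must be non-negative")
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction must be in [0, 1]")


def generate_fire_perimeter(
    landscape: Landscape,
    spec: PerimeterSpec,
    rng: np.random.Generator,
    within: np.ndarray | None = None,
    anchor: tuple[int, int] | None = None,
) -> np.ndarray:
    """A connected mask of round(area_ha) cells with the requested overlap.

    With an overlap constraint, round(overlap_fraction x area) cells are grown
    inside the prior perimeter first and the remainder grown outward from its
    edge, so the achieved overlap is exact and the union stays 8-connected.
    """
    n = int(round(spec.area_ha / landscape.cell_area_ha))
    allowed = landscape.mask.copy()
    if within is not None:
        allowed &= within
    if n > int(np.count_nonzero(allowed)):
        raise ValueError("perimeter area exceeds the eligible landscape area")
    seeds = [anchor] if anchor is not None else None
    if spec.overlap_with is None:
        return grow_mask(allowed, n, rng, seeds=seeds)

    n_in = int(round(spec.overlap_fraction * n))
    n_out = n - n_in
    inside_allowed = allowed & spec.overlap_with
    if int(np.count_nonzero(inside_allowed)) < n_in:
        raise ValueError("overlap target infeasible: prior perimeter too small")
    inner = grow_mask(inside_allowed, n_in, rng, seeds=seeds)
    if n_out == 0:
        return inner
    # grow the remainder outward from the inner patch's boundary
    outside_allowed = allowed & ~spec.overlap_with
    rr, cc = np.nonzero(inner)
    edge_seeds = []
    nr, nc = allowed.shape
    for r, c in zip(rr, cc):
        for dr, dc in _NEIGH8:
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < nr and 0 <= c2 < nc and outside_allowed[r2, c2]:
                edge_seeds.append((r2, c2))
    if not edge_seeds:
        raise ValueError("overlap target infeasible: no exit from prior perimeter")
    outer = grow_mask(outside_allowed, n_out, rng, seeds=[edge_seeds[rng.integers(len(edge_seeds))]])
    return inner | outer


def is_8_connected(mask: np.ndarray) -> bool:
    """Flood-fill connectivity check for a boolean mask."""
    from scipy import ndimage

    n = int(np.count_nonzero(mask))
    if n == 0:
        return True
    labeled, n_comp = ndimage.label(mask, structure=np.ones((3, 3)))
    return n_comp == 1


def generate_landscape(
    config: LandscapeConfig,
    species_params: dict[StateClass, SpeciesParams] | None = None,
    soil: SoilParams | None = None,
    curves: dict[StateClass, GrowthCurve] | None = None,
    rng: np.random.Generator | None = None,
) -> Landscape:
    """Generate a clustered synthetic landscape matching the configuration.

    Class areas hit their targets exactly in cell count; forest ages are drawn
    uniformly from ``config.age_range``; the Dry stratum is one contiguous
    region. Stocks are initialized when species parameters are supplied.
    """
    rng = rng or np.random.default_rng(config.seed)
    soil = soil or SoilParams()
    shape = grid_shape(config.total_area_ha)
    counts = _exact_counts(config.total_area_ha, config.class_proportions)
    land = Landscape.blank(*shape, soil)
    land.state[:] = _region_grow_classes(shape, counts, rng)

    fm = land.forested_mask
    lo, hi = config.age_range
    land.age[fm] = rng.integers(lo, hi + 1, size=int(np.count_nonzero(fm)))

    n_dry = int(round(config.dry_fraction * config.total_area_ha))
    if n_dry > 0:
        dry = grow_mask(land.mask, n_dry, rng)
        land.stratum[:] = int(Stratum.WET)
        land.stratum[dry] = int(Stratum.DRY)
    else:
        land.stratum[:] = int(Stratum.WET)

    if species_params is not None:
        initialize_stocks(land, species_params, soil, curves=curves)
    return land


# ---------------------------------------------------------------------------
# Reference historic scenario (1985-2015 reconstruction)
# ---------------------------------------------------------------------------

#: reconstructed event parameters: hurricane windthrow 2003 (625 ha of cedar),
#: salvage+replant 316 ha spread over 2004-2007, the 2400-ha 2008 fire
#: (80% of above-ground fuels + 20 cm of peat) and the 2500-ha 2011 repeat
#: fire (remaining fuels + 50 cm of peat + roots on the 85% overlap).
HURRICANE_YEAR = 2003
HURRICANE_AREA_HA = 625
REMOVAL_YEARS = (2004, 2005, 2006, 2007)
REMOVAL_TOTAL_HA = 316
SOUTH_ONE_YEAR = 2008
SOUTH_ONE_AREA_HA = 2400
SOUTH_ONE_AGB_FRACTION = 0.80
SOUTH_ONE_PEAT_CM = 20.0
LATERAL_WEST_YEAR = 2011
LATERAL_WEST_AREA_HA = 2500
LATERAL_WEST_OVERLAP = 0.85
LATERAL_WEST_PEAT_CM = 50.0
SCAR_AGE = 100

#: four additional smaller fires (years/areas are stand-ins for the unpublished
#: regional fire record; their emissions are reported but are reconstructions)
OTHER_FIRES = ((1987, 400), (1995, 300), (2001, 250), (2014, 150))


def _split_mask(mask: np.ndarray, sizes: list[int]) -> list[np.ndarray]:
    """Partition a mask's cells (row-major order) into disjoint chunks."""
    rr, cc = np.nonzero(mask)
    if sum(sizes) > len(rr):
        raise ValueError("cannot split mask: not enough cells")
    out = []
    start = 0
    for s in sizes:
        chunk = np.zeros_like(mask)
        chunk[rr[start : start + s], cc[start : start + s]] = True
        out.append(chunk)
        start += s
    return out


def default_schedule(masks: dict, include_other_fires: bool = True) -> "EventSchedule":
    """The reconstructed historic event schedule over the generated perimeters.

    ``masks`` must contain 'hurricane', 'removal', 'south_one', 'lateral_west'
    and optionally 'other_<year>' perimeter masks.
    """
    from .scenario import DisturbanceEvent, EventSchedule
    from .stockflow import FireConsumptionSpec

    events = [
        DisturbanceEvent(
            year=HURRICANE_YEAR,
            kind="hurricane",
            name="Hurricane Isabel",
            area_ha=HURRICANE_AREA_HA,
            mask=masks["hurricane"],
        )
    ]
    n = len(REMOVAL_YEARS)
    per_year = [REMOVAL_TOTAL_HA // n] * n
    per_year[-1] += REMOVAL_TOTAL_HA - sum(per_year)
    for chunk_mask, year, area in zip(
        _split_mask(masks["removal"], per_year), REMOVAL_YEARS, per_year
    ):
        events.append(
            DisturbanceEvent(
                year=year,
                kind="deadwood_removal",
                name=f"Deadwood salvage {year}",
                area_ha=area,
                mask=chunk_mask,
            )
        )
    events.append(
        DisturbanceEvent(
            year=SOUTH_ONE_YEAR,
            kind="fire",
            name="South One",
            area_ha=SOUTH_ONE_AREA_HA,
            mask=masks["south_one"],
            consumption=FireConsumptionSpec.uniform_agb(
                SOUTH_ONE_AGB_FRACTION, SOUTH_ONE_PEAT_CM, include_roots=False
            ),
        )
    )
    events.append(
        DisturbanceEvent(
            year=LATERAL_WEST_YEAR,
            kind="fire",
            name="Lateral West",
            area_ha=LATERAL_WEST_AREA_HA,
            mask=masks["lateral_west"],
            consumption=None,  # non-repeat cells burn at drawn severity
            repeat_consumption=FireConsumptionSpec.uniform_agb(
                1.0, LATERAL_WEST_PEAT_CM, include_roots=True
            ),
            post_state_repeat=StateClass.MARSH,
        )
    )
    if include_other_fires:
        for year, area in OTHER_FIRES:
            key = f"other_{year}"
            if key in masks:
                events.append(
                    DisturbanceEvent(
                        year=year,
                        kind="fire",
                        name=f"Other fire {year}",
                        area_ha=area,
                        mask=masks[key],
                    )
                )
    return EventSchedule(events=events)


def generate_reference_scenario(
    config: LandscapeConfig | None = None,
    species_params: dict[StateClass, SpeciesParams] | None = None,
    soil: SoilParams | None = None,
    curves: dict[StateClass, GrowthCurve] | None = None,
    include_other_fires: bool = True,
):
    """Build the full reconstructed study: landscape, perimeters and schedule.

    Returns ``(landscape, schedule, masks)`` where the landscape is the 1985
    initial state: synthetic composition and ages, with the disturbance-scar
    region overridden to Atlantic white cedar at age 100 and all stocks derived
    from the spin-up growth curves. Deterministic per ``config.seed``.
    """
    from .landscape import rollback_ages
    from .params import load_species_params
    from .spinup import spinup_all

    config = config or LandscapeConfig()
    soil = soil or SoilParams()
    species_params = species_params or load_species_params()
    curves = curves or spinup_all(species_params)
    rng = np.random.default_rng(config.seed)

    land = generate_landscape(config, rng=rng)
    dry = land.stratum == int(Stratum.DRY)

    # anchor the first catastrophic perimeter well inside the dry zone
    from scipy import ndimage

    dist = ndimage.distance_transform_cdt(dry, metric="chessboard")
    anchor = np.unravel_index(int(np.argmax(dist)), dry.shape)

    masks: dict[str, np.ndarray] = {}
    masks["south_one"] = generate_fire_perimeter(
        land, PerimeterSpec(SOUTH_ONE_AREA_HA), rng, within=dry, anchor=anchor
    )
    masks["lateral_west"] = generate_fire_perimeter(
        land,
        PerimeterSpec(
            LATERAL_WEST_AREA_HA,
            overlap_with=masks["south_one"],
            overlap_fraction=LATERAL_WEST_OVERLAP,
        ),
        rng,
        within=dry,
    )
    masks["hurricane"] = grow_mask(masks["south_one"], HURRICANE_AREA_HA, rng)
    masks["removal"] = grow_mask(masks["hurricane"], REMOVAL_TOTAL_HA, rng)
    masks["scar"] = masks["south_one"] | masks["lateral_west"]

    if include_other_fires:
        outside = land.forested_mask & ~masks["scar"]
        for year, area in OTHER_FIRES:
            masks[f"other_{year}"] = generate_fire_perimeter(
                land, PerimeterSpec(area), rng, within=outside
            )

    land = rollback_ages(
        land,
        years=0,
        species_params=species_params,
        soil=soil,
        curves=curves,
        scar_mask=masks["scar"],
        scar_age=SCAR_AGE,
        scar_class=StateClass.ATLANTIC_WHITE_CEDAR,
    )
    schedule = default_schedule(masks, include_other_fires=include_other_fires)
    return land, schedule, masks
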