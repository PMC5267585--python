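"""Historic-run orchestration: the annual loop coupling the transition layer
to the stock-flow layer, the per-year carbon ledger, and the ecosystem
accounting derived from it.

Accounting conventions:

* Growth is the sum of NPP inflows from the atmosphere (Tg C/yr).
* Heterotrophic respiration R_h is every non-fire emission to the atmosphere
  (detritus decomposition plus the steady-state upper-peat emission).
* NEP = Growth - R_h; NECB = NEP - Management - FireEmissions. Negative NECB
  means the landscape was a net source over the period.
* Fire emissions are ledgered separately from R_h (never double-counted) and
  split above-ground (live leaf/wood, litter, deadwood fuels) versus
  below-ground (peat and roots).

Within a year the operation order is: targeted transitions (random group
order), probabilistic transitions, stock flows, age increment. Cells whose
age was reset during the year report age 0 at year end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .landscape import Landscape
from .params import (
    FORESTED_CLASSES,
    FireSeveritySpec,
    Severity,
    SoilParams,
    SpeciesParams,
    StateClass,
    peat_carbon_per_cm,
)
from .stockflow import (
    DEFAULT_SEVERITY_CONSUMPTION,
    FireConsumptionSpec,
    annual_flows,
    apply_deadwood_harvest,
    apply_fire_consumption,
    apply_hurricane_transfer,
)
from .transitions import (
    ADJACENCY_REFRESH_YEARS,
    FireHistory,
    TransitionPathway,
    apply_probabilistic_transitions,
    assign_fire_severity,
    compute_adjacency_multiplier,
    default_succession_pathways,
    detect_repeat_catastrophic,
    select_target_cells,
)

T_PER_TG = 1e6


@dataclass
class DisturbanceEvent:
    """A year-stamped, area-targeted disturbance or management action."""

    year: int
    kind: str  # "fire" | "hurricane" | "deadwood_removal"
    name: str
    area_ha: float
    mask: np.ndarray
    consumption: FireConsumptionSpec | None = None  # fires: applied to burned cells
    repeat_consumption: FireConsumptionSpec | None = None  # repeat-catastrophic cells
    post_state_repeat: StateClass = StateClass.MARSH
    replant_class: StateClass | None = StateClass.ATLANTIC_WHITE_CEDAR

    def __post_init__(self) -> None:
        if self.kind not in ("fire", "hurricane", "deadwood_removal"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.area_ha < 0:
            raise ValueError("area_ha must be non-negative")


@dataclass
class EventSchedule:
    """Ordered disturbance events for a historic run."""

    events: list[DisturbanceEvent] = field(default_factory=list)

    def for_year(self, year: int) -> list[DisturbanceEvent]:
        return [e for e in self.events if e.year == year]

    def validate_span(self, start_year: int, years: int) -> None:
        for e in self.events:
            if not start_year <= e.year < start_year + years:
                raise ValueError(
                    f"event {e.name!r} year {e.year} outside simulation span"
                )

    def __len__(self) -> int:
        return len(self.events)


@dataclass
class ModelConfig:
    """Parameter bundle for a historic run."""

    species_params: dict[StateClass, SpeciesParams]
    soil: SoilParams = field(default_factory=SoilParams)
    severity: FireSeveritySpec = field(default_factory=FireSeveritySpec)
    pathways: list[TransitionPathway] = field(default_factory=default_succession_pathways)
    peat_mode: str = "steady_state"
    severity_consumption: dict = field(
        default_factory=lambda: dict(DEFAULT_SEVERITY_CONSUMPTION)
    )


@dataclass
class AnnualLedger:
    """Per-year aggregated stocks and categorized fluxes (Tg C)."""

    frame: pd.DataFrame
    fire_events: list[dict] = field(default_factory=list)
    start_year: int = 0

    @property
    def fire_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.fire_events)

    def closure_errors(self) -> np.ndarray:
        """Per-year |dC - (Growth - R_h - Fire - Management)| in Tg."""
        f = self.frame
        delta = f.total_carbon_tg.diff()
        delta.iloc[0] = f.total_carbon_tg.iloc[0] - f.initial_carbon_tg.iloc[0]
        rhs = f.growth_tg - f.rh_tg - f.fire_total_tg - f.management_tg
        return np.abs((delta - rhs).to_numpy())


# ---------------------------------------------------------------------------
# Event application
# ---------------------------------------------------------------------------


def _burn_subset(
    land: Landscape,
    subset: np.ndarray,
    spec: FireConsumptionSpec,
    soil: SoilParams,
) -> tuple[float, float, float, int]:
    """Apply consumption to the masked cells; returns (agb_t, bgb_t, peat_t, peat_cells)."""
    if not np.any(subset):
        return 0.0, 0.0, 0.0, 0
    s = land.stocks[:, subset]
    up = land.upper_peat_depth[subset]
    dp = land.deep_peat_depth[subset]
    new, up2, dp2, flows = apply_fire_consumption(s, up, dp, spec, soil)
    land.stocks[:, subset] = new
    land.upper_peat_depth[subset] = up2
    land.deep_peat_depth[subset] = dp2
    agb = sum(f.total() for f in flows if f.category == "FireEmissionAGB")
    bgb = sum(f.total() for f in flows if f.category == "FireEmissionBGB")
    peat = sum(
        f.total()
        for f in flows
        if f.category == "FireEmissionBGB" and f.from_pool in ("upper_peat", "deep_peat")
    )
    n_peat = int(np.count_nonzero(subset)) if spec.peat_depth_cm > 0 else 0
    return agb, bgb, peat, n_peat


def _convert_to_marsh(land: Landscape, subset: np.ndarray, to_class: StateClass) -> None:
    """Class change with carbon conservation: residual live pools go to dead."""
    if not np.any(subset):
        return
    new, _ = apply_hurricane_transfer(land.stocks[:, subset])
    land.stocks[:, subset] = new
    land.state[subset] = int(to_class)
    land.age[subset] = 0


def _apply_fire_event(
    land: Landscape,
    ev: DisturbanceEvent,
    config: ModelConfig,
    rng: np.random.Generator,
    year: int,
    history: FireHistory,
    reset_this_year: np.ndarray,
) -> dict:
    eligible = ev.mask & land.forested_mask
    burn = select_target_cells(eligible, ev.area_ha, rng, land.cell_area_ha, label=ev.name)
    n_burned = int(np.count_nonzero(burn))
    record = {
        "year": year,
        "name": ev.name,
        "kind": "fire",
        "area_ha": n_burned * land.cell_area_ha,
        "agb_tg": 0.0,
        "bgb_tg": 0.0,
        "total_tg": 0.0,
        "peat_area_ha": 0.0,
        "peat_emission_tg": 0.0,
        "management_tg": 0.0,
    }
    if n_burned == 0:
        return record

    repeat = detect_repeat_catastrophic(land, burn, year)
    sev_grid = np.zeros(land.shape, dtype=np.int8)
    rr, cc = np.nonzero(burn)
    sev_grid[rr, cc] = assign_fire_severity(n_burned, config.severity, rng)

    agb = bgb = peat = 0.0
    peat_cells = 0

    regular = burn & ~repeat
    if ev.consumption is not None:
        a, b, p, n = _burn_subset(land, regular, ev.consumption, config.soil)
        agb, bgb, peat, peat_cells = agb + a, bgb + b, peat + p, peat_cells + n
    else:
        for label, sev in (("low", Severity.LOW), ("med", Severity.MED), ("high", Severity.HIGH)):
            subset = regular & (sev_grid == int(sev))
            a, b, p, n = _burn_subset(land, subset, config.severity_consumption[label], config.soil)
            agb, bgb, peat, peat_cells = agb + a, bgb + b, peat + p, peat_cells + n

    if np.any(repeat):
        spec = ev.repeat_consumption or ev.consumption
        if spec is None:
            spec = FireConsumptionSpec.uniform_agb(1.0, 0.0, True)
        a, b, p, n = _burn_subset(land, repeat, spec, config.soil)
        agb, bgb, peat, peat_cells = agb + a, bgb + b, peat + p, peat_cells + n

    # age resets: high severity or repeat catastrophic
    resets = repeat | (burn & (sev_grid == int(Severity.HIGH)))
    land.age[resets] = 0
    reset_this_year |= resets

    # repeat-catastrophic cells convert (default: to marsh)
    _convert_to_marsh(land, repeat, ev.post_state_repeat)

    land.last_fire_year[burn] = year
    land.last_fire_severity[burn] = sev_grid[burn]
    history.record(year, ev.name, burn, sev_grid)

    scale = land.cell_area_ha / T_PER_TG
    record.update(
        agb_tg=agb * scale,
        bgb_tg=bgb * scale,
        total_tg=(agb + bgb) * scale,
        peat_area_ha=peat_cells * land.cell_area_ha,
        peat_emission_tg=peat * scale,
    )
    return record


def _apply_hurricane_event(
    land: Landscape,
    ev: DisturbanceEvent,
    rng: np.random.Generator,
    year: int,
    reset_this_year: np.ndarray,
) -> dict:
    eligible = ev.mask & land.forested_mask
    hit = select_target_cells(eligible, ev.area_ha, rng, land.cell_area_ha, label=ev.name)
    if np.any(hit):
        new, _ = apply_hurricane_transfer(land.stocks[:, hit])
        land.stocks[:, hit] = new
        land.age[hit] = 0
        reset_this_year |= hit
    return {
        "year": year,
        "name": ev.name,
        "kind": "hurricane",
        "area_ha": float(np.count_nonzero(hit) * land.cell_area_ha),
        "agb_tg": 0.0,
        "bgb_tg": 0.0,
        "total_tg": 0.0,
        "peat_area_ha": 0.0,
        "peat_emission_tg": 0.0,
        "management_tg": 0.0,
    }


def _apply_removal_event(
    land: Landscape,
    ev: DisturbanceEvent,
    rng: np.random.Generator,
    year: int,
    reset_this_year: np.ndarray,
) -> dict:
    eligible = ev.mask & land.forested_mask & (land.stocks[4] > 1e-9)
    hit = select_target_cells(eligible, ev.area_ha, rng, land.cell_area_ha, label=ev.name)
    removed = 0.0
    if np.any(hit):
        new, flows = apply_deadwood_harvest(land.stocks[:, hit])
        land.stocks[:, hit] = new
        removed = sum(f.total() for f in flows)
        if ev.replant_class is not None:
            land.state[hit] = int(ev.replant_class)
            land.age[hit] = 0
            reset_this_year |= hit
    return {
        "year": year,
        "name": ev.name,
        "kind": "deadwood_removal",
        "area_ha": float(np.count_nonzero(hit) * land.cell_area_ha),
        "agb_tg": 0.0,
        "bgb_tg": 0.0,
        "total_tg": 0.0,
        "peat_area_ha": 0.0,
        "peat_emission_tg": 0.0,
        "management_tg": removed * land.cell_area_ha / T_PER_TG,
    }


# ---------------------------------------------------------------------------
# Annual loop
# ---------------------------------------------------------------------------


def run_historic(
    landscape: Landscape,
    schedule: EventSchedule,
    config: ModelConfig,
    seed: int = 0,
    start_year: int = 1985,
    years: int = 30,
) -> tuple[AnnualLedger, Landscape]:
    """Run the coupled simulation for ``years`` annual steps.

    The landscape is copied; the ledger aggregates cell fluxes (1 ha cells) to
    Tg C. Identical seeds produce identical ledgers and final landscapes.
    """
    schedule.validate_span(start_year, years)
    land = landscape.copy()
    land.current_year = start_year
    rng = np.random.default_rng(seed)
    history = FireHistory(land.shape)

    mg = StateClass.MAPLE_GUM
    adjacency = {mg: compute_adjacency_multiplier(land, mg)}

    rows: list[dict] = []
    fire_events: list[dict] = []
    initial_carbon = land.total_carbon() / T_PER_TG

    for step in range(years):
        year = start_year + step
        land.current_year = year
        reset_this_year = np.zeros(land.shape, dtype=bool)
        growth_t = rh_t = fire_agb_t = fire_bgb_t = mgmt_t = 0.0

        # 1. targeted transitions, in random group order
        todays = schedule.for_year(year)
        for idx in rng.permutation(len(todays)):
            ev = todays[idx]
            if ev.kind == "fire":
                rec = _apply_fire_event(land, ev, config, rng, year, history, reset_this_year)
                fire_agb_t += rec["agb_tg"] * T_PER_TG
                fire_bgb_t += rec["bgb_tg"] * T_PER_TG
            elif ev.kind == "hurricane":
                rec = _apply_hurricane_event(land, ev, rng, year, reset_this_year)
            else:
                rec = _apply_removal_event(land, ev, rng, year, reset_this_year)
                mgmt_t += rec["management_tg"] * T_PER_TG
            fire_events.append(rec)

        # 2. probabilistic transitions (adjacency on a 5-year cadence)
        if step % ADJACENCY_REFRESH_YEARS == 0:
            adjacency[mg] = compute_adjacency_multiplier(land, mg)
        apply_probabilistic_transitions(land, config.pathways, adjacency, rng)

        # 3. stock flows, per species
        for cls in FORESTED_CLASSES:
            sel = land.class_mask(cls)
            if not np.any(sel):
                continue
            new, flows = annual_flows(
                land.stocks[:, sel], config.species_params[cls], peat_mode=config.peat_mode
            )
            land.stocks[:, sel] = new
            for f in flows:
                if f.from_pool == "atmosphere":
                    growth_t += f.total()
                elif f.to_pool == "atmosphere":
                    rh_t += f.total()

        # 4. ages advance on forested cells not reset this year
        aging = land.forested_mask & ~reset_this_year
        land.age[aging] += 1

        total_c = land.total_carbon() / T_PER_TG
        rows.append(
            {
                "year": year,
                "growth_tg": growth_t / T_PER_TG,
                "rh_tg": rh_t / T_PER_TG,
                "nep_tg": (growth_t - rh_t) / T_PER_TG,
                "fire_agb_tg": fire_agb_t / T_PER_TG,
                "fire_bgb_tg": fire_bgb_t / T_PER_TG,
                "fire_total_tg": (fire_agb_t + fire_bgb_t) / T_PER_TG,
                "management_tg": mgmt_t / T_PER_TG,
                "total_carbon_tg": total_c,
                "initial_carbon_tg": initial_carbon,
                "forested_area_ha": float(
                    np.count_nonzero(land.forested_mask) * land.cell_area_ha
                ),
            }
        )

    ledger = AnnualLedger(
        frame=pd.DataFrame(rows), fire_events=fire_events, start_year=start_year
    )
    return ledger, land


# ---------------------------------------------------------------------------
# Accounting
# ---------------------------------------------------------------------------


def compute_nep(ledger: AnnualLedger, span: tuple[int, int] | None = None) -> float:
    """Net ecosystem production over the span (Tg C): sum Growth - sum R_h."""
    f = _span(ledger, span)
    return float(f.growth_tg.sum() - f.rh_tg.sum())


def compute_necb(ledger: AnnualLedger, span: tuple[int, int] | None = None) -> float:
    """Net ecosystem carbon balance (Tg C): NEP - Management - FireEmissions.

    Negative values denote a net carbon source.
    """
    f = _span(ledger, span)
    return float(
        f.growth_tg.sum() - f.rh_tg.sum() - f.management_tg.sum() - f.fire_total_tg.sum()
    )


def _span(ledger: AnnualLedger, span: tuple[int, int] | None) -> pd.DataFrame:
    f = ledger.frame
    if span is None:
        return f
    lo, hi = span
    return f[(f.year >= lo) & (f.year <= hi)]


def summarize_fire_events(ledger: AnnualLedger, soil: SoilParams) -> pd.DataFrame:
    """Per-fire AGB/BGB losses and the soil-elevation equivalent of peat loss.

    Elevation equivalent (m) = peat carbon emitted / (carbon per cm x burned
    peat area) / 100. A cumulative row sums the events.
    """
    pcc = peat_carbon_per_cm(soil)
    rows = []
    for rec in ledger.fire_events:
        if rec["kind"] != "fire":
            continue
        area = rec["peat_area_ha"]
        elev_m = (
            rec["peat_emission_tg"] * T_PER_TG / (pcc * area) / 100.0 if area > 0 else 0.0
        )
        rows.append(
            {
                "name": rec["name"],
                "year": rec["year"],
                "agb_loss_tg": rec["agb_tg"],
                "bgb_loss_tg": rec["bgb_tg"],
                "total_loss_tg": rec["total_tg"],
                "soil_elevation_loss_m": elev_m,
            }
        )
    df = pd.DataFrame(rows)
    if not df.empty:
        total = {
            "name": "Cumulative",
            "year": pd.NA,
            "agb_loss_tg": df.agb_loss_tg.sum(),
            "bgb_loss_tg": df.bgb_loss_tg.sum(),
            "total_loss_tg": df.total_loss_tg.sum(),
            "soil_elevation_loss_m": df.soil_elevation_loss_m.sum(),
        }
        df = pd.concat([df, pd.DataFrame([total])], ignore_index=True)
    return df


def re_amass_time(peat_depth_cm: float, rate: float, soil: SoilParams | None = None) -> int:
    """Years to re-accumulate a peat column at a given rate, to the nearest decade.

    The carbon in ``peat_depth_cm`` of peat divided by the accumulation rate
    (t C/ha/yr).
    """
    if rate <= 0:
        raise ValueError("accumulation rate must be positive")
    if peat_depth_cm < 0:
        raise ValueError("peat depth must be non-negative")
    soil = soil or SoilParams()
    years = peat_depth_cm * peat_carbon_per_cm(soil) / rate
    return int(math.floor(years / 10.0 + 0.5)) * 10
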