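"""Annual carbon flows between the eight ecosystem pools (gain-loss method).

Each simulated year, carbon moves between pools at rates that are either
proportional multipliers of the start-of-year "from" stock (growth partition,
litterfall, mortality, humification, detritus emission) or absolute species
rates (upper->deep peat accumulation). The update is simultaneous: all flows
are computed from start-of-year stocks and applied at once, with outflows
scaled down proportionally if they would drive a pool negative.

The upper peat layer (acrotelm) is modelled at steady state by default: its
emission to the atmosphere balances the humification inflow net of the
deep-peat accumulation, so it neither gains nor loses carbon between fires.
An alternative "multiplier" mode instead applies the published upper-peat
multipliers, for sensitivity runs.

All functions operate on stock arrays of shape ``(N_POOLS, ...)`` so the same
code path serves a single cell (shape ``(8,)``) and a whole masked landscape
(shape ``(8, n)``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import (
    AGB_FIRE_POOLS,
    ATMOSPHERE,
    HARVESTED_WOOD,
    N_POOLS,
    POOL_INDEX,
    POOLS,
    SoilParams,
    SpeciesParams,
    peat_carbon_per_cm,
)

LL = POOL_INDEX["live_leaf"]
LW = POOL_INDEX["live_wood"]
LR = POOL_INDEX["live_root"]
LIT = POOL_INDEX["leaf_litter"]
DW = POOL_INDEX["deadwood"]
DR = POOL_INDEX["dead_root"]
UP = POOL_INDEX["upper_peat"]
DP = POOL_INDEX["deep_peat"]


@dataclass
class Flow:
    """One directed transfer between pools for a single annual step."""

    from_pool: str
    to_pool: str
    category: str  # Growth | Litterfall | Mortality | Humification | Emission |
    # PeatAccumulation | FireEmissionAGB | FireEmissionBGB | ManagementRemoval
    amount: np.ndarray  # t C/ha, same trailing shape as the stocks

    def total(self) -> float:
        return float(np.sum(self.amount))


@dataclass
class FireConsumptionSpec:
    """What a fire removes from a cell.

    ``agb_fractions`` maps above-ground pool name -> consumed fraction;
    ``peat_depth_cm`` of peat is combusted (upper layer first, then deep);
    ``include_roots`` burns live and dead roots entirely (repeat-catastrophic
    behaviour).
    """

    agb_fractions: dict = field(default_factory=dict)
    peat_depth_cm: float = 0.0
    include_roots: bool = False

    @classmethod
    def uniform_agb(
        cls, fraction: float, peat_depth_cm: float = 0.0, include_roots: bool = False
    ) -> "FireConsumptionSpec":
        if not 0.0 <= fraction <= 1.0:
            raise ValueError("agb fraction must be in [0, 1]")
        return cls(
            agb_fractions={p: fraction for p in AGB_FIRE_POOLS},
            peat_depth_cm=peat_depth_cm,
            include_roots=include_roots,
        )


#: default consumption for ordinary (non-catastrophic) fires by severity
DEFAULT_SEVERITY_CONSUMPTION = {
    "low": FireConsumptionSpec(agb_fractions={"leaf_litter": 0.5}),
    "med": FireConsumptionSpec(agb_fractions={"leaf_litter": 1.0, "deadwood": 0.5}),
    "high": FireConsumptionSpec.uniform_agb(0.8),
}


def _as_stocks(stocks: np.ndarray) -> np.ndarray:
    stocks = np.asarray(stocks, dtype=float)
    if stocks.shape[0] != N_POOLS:
        raise ValueError(f"stocks must have leading dimension {N_POOLS}")
    if np.any(stocks < -1e-12):
        raise ValueError("negative stock on entry")
    return stocks


def annual_flows(
    stocks: np.ndarray,
    params: SpeciesParams,
    peat_mode: str = "steady_state",
) -> tuple[np.ndarray, list[Flow]]:
    """One annual flow step for cells of a single forested species.

    Returns the updated stocks and the list of flows (per-cell densities).
    """
    s = _as_stocks(stocks)
    if peat_mode not in ("steady_state", "multiplier"):
        raise ValueError(f"unknown peat_mode {peat_mode!r}")
    one = np.ones(s.shape[1:], dtype=float)

    flows: list[Flow] = []

    def add(frm: str, to: str, category: str, amount: np.ndarray) -> None:
        flows.append(Flow(frm, to, category, np.maximum(amount, 0.0)))

    # growth: NPP partitioned into the three live pools
    add(ATMOSPHERE, "live_leaf", "Growth", params.f_leaf * params.npp_total * one)
    add(ATMOSPHERE, "live_wood", "Growth", params.f_wood * params.npp_total * one)
    add(ATMOSPHERE, "live_root", "Growth", params.f_root * params.npp_total * one)

    # turnover of live pools into detritus
    add("live_leaf", "leaf_litter", "Litterfall", params.m_litterfall_leaf * s[LL])
    add("live_wood", "deadwood", "Mortality", params.m_mortality_wood * s[LW])
    add("live_root", "dead_root", "Litterfall", params.m_litterfall_root * s[LR])

    # humification of detritus into the upper peat
    humif = (
        params.m_humif_litter * s[LIT]
        + params.m_humif_deadwood * s[DW]
        + params.m_humif_deadroot * s[DR]
    )
    add("leaf_litter", "upper_peat", "Humification", params.m_humif_litter * s[LIT])
    add("deadwood", "upper_peat", "Humification", params.m_humif_deadwood * s[DW])
    add("dead_root", "upper_peat", "Humification", params.m_humif_deadroot * s[DR])

    # detritus decomposition losses to the atmosphere
    add("leaf_litter", ATMOSPHERE, "Emission", params.m_emis_litter * s[LIT])
    add("deadwood", ATMOSPHERE, "Emission", params.m_emis_deadwood * s[DW])
    add("dead_root", ATMOSPHERE, "Emission", params.m_emis_deadroot * s[DR])

    # peat layer
    if peat_mode == "steady_state":
        accum = params.peat_accumulation * one
        emis_up = np.maximum(humif - accum, 0.0)
    else:
        accum = params.m_accum_upper_peat * s[UP]
        emis_up = params.m_emis_upper_peat * s[UP]
    add("upper_peat", "deep_peat", "PeatAccumulation", accum)
    add("upper_peat", ATMOSPHERE, "Emission", emis_up)

    return _apply_flows(s, flows), flows


def _apply_flows(stocks: np.ndarray, flows: list[Flow]) -> np.ndarray:
    """Apply a simultaneous set of flows, scaling outflows that overdraw."""
    out_total = np.zeros_like(stocks)
    for f in flows:
        if f.from_pool in POOL_INDEX:
            out_total[POOL_INDEX[f.from_pool]] += f.amount
    # proportional rescale where total outflow exceeds the start-of-year stock
    scale = np.ones_like(stocks)
    over = out_total > stocks
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(out_total > 0, stocks / np.maximum(out_total, 1e-300), 1.0)
    scale[over] = ratio[over]
    new = stocks.copy()
    for f in flows:
        if f.from_pool in POOL_INDEX:
            i = POOL_INDEX[f.from_pool]
            f.amount = f.amount * scale[i]
            new[i] -= f.amount
        if f.to_pool in POOL_INDEX:
            new[POOL_INDEX[f.to_pool]] += f.amount
    return np.maximum(new, 0.0)


def apply_fire_consumption(
    stocks: np.ndarray,
    upper_depth_cm: np.ndarray,
    deep_depth_cm: np.ndarray,
    spec: FireConsumptionSpec,
    soil: SoilParams,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[Flow]]:
    """Combust pools according to ``spec``.

    Returns (new stocks, new upper depth, new deep depth, flows). Above-ground
    fuel losses are ledgered as FireEmissionAGB; peat and root losses as
    FireEmissionBGB. Peat is consumed by depth, upper layer first; a request
    exceeding the remaining column is clamped.
    """
    s = _as_stocks(stocks)
    upper = np.asarray(upper_depth_cm, dtype=float).copy()
    deep = np.asarray(deep_depth_cm, dtype=float).copy()
    pcc = peat_carbon_per_cm(soil)
    flows: list[Flow] = []

    for pool, frac in spec.agb_fractions.items():
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"consumed fraction for {pool} must be in [0, 1]")
        amount = frac * s[POOL_INDEX[pool]]
        flows.append(Flow(pool, ATMOSPHERE, "FireEmissionAGB", amount))

    depth = float(spec.peat_depth_cm)
    if depth < 0:
        raise ValueError("peat_depth_cm must be non-negative")
    if depth > 0:
        want = np.minimum(depth, upper + deep)
        from_upper = np.minimum(want, upper)
        from_deep = want - from_upper
        up_amount = np.minimum(from_upper * pcc, s[UP])
        dp_amount = np.minimum(from_deep * pcc, s[DP])
        flows.append(Flow("upper_peat", ATMOSPHERE, "FireEmissionBGB", up_amount))
        flows.append(Flow("deep_peat", ATMOSPHERE, "FireEmissionBGB", dp_amount))
        upper = upper - from_upper
        deep = deep - from_deep

    if spec.include_roots:
        flows.append(Flow("live_root", ATMOSPHERE, "FireEmissionBGB", s[LR].copy()))
        flows.append(Flow("dead_root", ATMOSPHERE, "FireEmissionBGB", s[DR].copy()))

    return _apply_flows(s, flows), upper, deep, flows


def apply_hurricane_transfer(stocks: np.ndarray) -> tuple[np.ndarray, list[Flow]]:
    """Move live pools into the corresponding dead pools (windthrow).

    Total cell carbon is unchanged; the transition layer handles the age
    reset.
    """
    s = _as_stocks(stocks)
    flows = [
        Flow("live_wood", "deadwood", "Mortality", s[LW].copy()),
        Flow("live_leaf", "leaf_litter", "Litterfall", s[LL].copy()),
        Flow("live_root", "dead_root", "Litterfall", s[LR].copy()),
    ]
    return _apply_flows(s, flows), flows


def apply_deadwood_harvest(stocks: np.ndarray) -> tuple[np.ndarray, list[Flow]]:
    """Salvage: the entire deadwood stock leaves the ecosystem as wood products."""
    s = _as_stocks(stocks)
    flows = [Flow("deadwood", HARVESTED_WOOD, "ManagementRemoval", s[DW].copy())]
    return _apply_flows(s, flows), flows


def mass_balance(
    stocks_before: np.ndarray,
    stocks_after: np.ndarray,
    flows: list[Flow],
    tol: float = 1e-9,
) -> bool:
    """Check the gain-loss identity for one step on one cell (or cell set).

    The change in total ecosystem carbon must equal atmosphere inflows minus
    atmosphere outflows minus wood-product removals, within ``tol`` t C/ha.
    """
    before = np.sum(np.asarray(stocks_before, dtype=float), axis=0)
    after = np.sum(np.asarray(stocks_after, dtype=float), axis=0)
    net = np.zeros_like(before, dtype=float)
    for f in flows:
        if f.from_pool == ATMOSPHERE:
            net = net + f.amount
        if f.to_pool in (ATMOSPHERE, HARVESTED_WOOD):
            net = net - f.amount
    return bool(np.all(np.abs((after - before) - net) <= tol))


def flows_by_category(flows: list[Flow]) -> dict[str, float]:
    """Sum flow amounts by ledger category (t C/ha totals)."""
    out: dict[str, float] = {}
    for f in flows:
        out[f.category] = out.get(f.category, 0.0) + f.total()
    return out


# ---------------------------------------------------------------------------
# Single-cell convenience API
# ---------------------------------------------------------------------------


@dataclass
class Cell:
    """A single simulation cell (1 ha): class, age and carbon state."""

    state_class: "object"
    stratum: "object"
    age: int = 0
    stocks: np.ndarray = field(default_factory=lambda: np.zeros(N_POOLS))
    upper_peat_depth: float = 40.0
    deep_peat_depth: float = 60.0
    last_fire_year: int | None = None
    last_fire_severity: str | None = None

    def stock(self, pool: str) -> float:
        return float(self.stocks[POOL_INDEX[pool]])

    def total_carbon(self) -> float:
        return float(np.sum(self.stocks))


def step_flows(
    cell: Cell, params: SpeciesParams, peat_mode: str = "steady_state"
) -> tuple[Cell, list[Flow]]:
    """Annual flow step on a single cell; returns the updated cell and flows."""
    new, flows = annual_flows(cell.stocks, params, peat_mode=peat_mode)
    out = Cell(
        state_class=cell.state_class,
        stratum=cell.stratum,
        age=cell.age,
        stocks=new,
        upper_peat_depth=cell.upper_peat_depth,
        deep_peat_depth=cell.deep_peat_depth,
        last_fire_year=cell.last_fire_year,
        last_fire_severity=cell.last_fire_severity,
    )
    return out, flows


def mature_cell(params: SpeciesParams, stratum, age: int = 100) -> Cell:
    """A cell initialized at the mature-stand stock densities."""
    stocks = np.array([params.init_stocks[p] for p in POOLS])
    return Cell(state_class=params.name, stratum=stratum, age=age, stocks=stocks)
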