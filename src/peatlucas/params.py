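"""Model parameters: state classes, carbon pools, soil and species parameters.

All species-level rates are loaded from the CSV tables shipped with the
package (``peatlucas/data``), which transcribe the field-literature parameter
set for the four forested communities of the Great Dismal Swamp: Atlantic
white cedar (AWC), cypress-gum (CG), maple-gum (MG) and pond pine (PP).
Annual flows are expressed as proportional multipliers of the "from" stock
(e.g. leaf-litter humification = 0.23 x leaf-litter density), except the
upper->deep peat accumulation, which is an absolute species rate in
t C/ha/yr. Loading validates internal consistency of the tables (partition
closure, pond-pine averaging, multiplier x mature-stock == calibrated
literature flow).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import IntEnum
from importlib import resources

import pandas as pd


class StateClass(IntEnum):
    """Land-cover / vegetation type of a simulation cell."""

    ATLANTIC_WHITE_CEDAR = 1
    CYPRESS_GUM = 2
    MAPLE_GUM = 3
    POND_PINE = 4
    MARSH = 5
    OPEN_WATER = 6
    UPLAND_PINE = 7


#: void / nodata code used in state grids
VOID = 0

#: classes that carry an age, receive NPP and participate in annual flows
FORESTED_CLASSES = (
    StateClass.ATLANTIC_WHITE_CEDAR,
    StateClass.CYPRESS_GUM,
    StateClass.MAPLE_GUM,
    StateClass.POND_PINE,
)

#: short labels used in the parameter tables
CLASS_ABBREV = {
    StateClass.ATLANTIC_WHITE_CEDAR: "AWC",
    StateClass.CYPRESS_GUM: "CG",
    StateClass.MAPLE_GUM: "MG",
    StateClass.POND_PINE: "PP",
    StateClass.MARSH: "MARSH",
    StateClass.OPEN_WATER: "OPEN_WATER",
    StateClass.UPLAND_PINE: "UPLAND_PINE",
}
ABBREV_CLASS = {v: k for k, v in CLASS_ABBREV.items()}


class Stratum(IntEnum):
    """Moisture zone; constant per cell over a historic run."""

    DRY = 0
    WET = 1


# ---------------------------------------------------------------------------
# Carbon pools
# ---------------------------------------------------------------------------

#: per-cell ecosystem pools, in storage order (t C/ha densities)
POOLS = (
    "live_leaf",
    "live_wood",
    "live_root",
    "leaf_litter",
    "deadwood",
    "dead_root",
    "upper_peat",
    "deep_peat",
)
POOL_INDEX = {name: i for i, name in enumerate(POOLS)}
N_POOLS = len(POOLS)

#: external (unbounded) pools
ATMOSPHERE = "atmosphere"
HARVESTED_WOOD = "harvested_wood_products"

#: pools treated as above-ground fuel by fire events
AGB_FIRE_POOLS = ("live_leaf", "live_wood", "leaf_litter", "deadwood")

#: reporting aggregation for stock plots/tables: above-ground includes the
#: live pools plus surface detritus; below-ground is dead root plus peat.
AGB_REPORT_POOLS = ("live_wood", "live_leaf", "live_root", "leaf_litter", "deadwood")
BGB_REPORT_POOLS = ("dead_root", "upper_peat", "deep_peat")


class Severity(IntEnum):
    """Burn severity label; NONE is the unburned sentinel."""

    NONE = 0
    LOW = 1
    MED = 2
    HIGH = 3


# ---------------------------------------------------------------------------
# Soil
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SoilParams:
    """Peat column parameters.

    Defaults are the on-site means: bulk density 0.16 g/cm^3, 95% organic
    matter, 59% carbon, with a standardized 100-cm column split into an upper
    (acrotelm, 0-40 cm) and a deep (catotelm, 41-100 cm) layer.
    """

    bulk_density: float = 0.16  # g/cm^3
    organic_fraction: float = 0.95
    carbon_fraction: float = 0.59
    upper_depth_cm: float = 40.0
    total_depth_cm: float = 100.0

    def __post_init__(self) -> None:
        if self.bulk_density <= 0:
            raise ValueError("bulk_density must be positive")
        for name in ("organic_fraction", "carbon_fraction"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if not 0 <= self.upper_depth_cm <= self.total_depth_cm:
            raise ValueError("upper_depth_cm must lie within the column")

    @property
    def deep_depth_cm(self) -> float:
        return self.total_depth_cm - self.upper_depth_cm

    def carbon_per_cm(self) -> float:
        """t C/ha stored per cm of peat depth.

        1 g/cm^3 over 1 cm of a hectare is 100 t, hence the factor 100.
        """
        return self.bulk_density * self.organic_fraction * self.carbon_fraction * 100.0


def peat_carbon_per_cm(soil: SoilParams) -> float:
    """Carbon density of peat per cm of depth (t C/ha/cm)."""
    return soil.carbon_per_cm()


# ---------------------------------------------------------------------------
# Fire severity proportions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FireSeveritySpec:
    """Proportions of burned cells falling in each severity class."""

    p_high: float = 0.163
    p_med: float = 0.409
    p_low: float = 0.428

    def __post_init__(self) -> None:
        total = self.p_high + self.p_med + self.p_low
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"severity proportions must sum to 1, got {total}")
        if min(self.p_high, self.p_med, self.p_low) < 0:
            raise ValueError("severity proportions must be non-negative")


# ---------------------------------------------------------------------------
# Species parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpeciesParams:
    """Per-forest-type NPP, partition fractions and flow multipliers."""

    name: StateClass
    npp_total: float  # t C/ha/yr
    f_leaf: float
    f_wood: float
    f_root: float
    m_litterfall_leaf: float
    m_mortality_wood: float
    m_litterfall_root: float
    m_humif_litter: float
    m_humif_deadwood: float
    m_humif_deadroot: float
    m_emis_litter: float
    m_emis_deadwood: float
    m_emis_deadroot: float
    m_emis_upper_peat: float  # multiplier mode only
    m_accum_upper_peat: float  # multiplier mode only
    peat_accumulation: float  # absolute rate, t C/ha/yr (default mode)
    init_stocks: dict = field(default_factory=dict)  # pool -> t C/ha (mature)
    age_class_bounds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not math.isclose(self.f_leaf + self.f_wood + self.f_root, 1.0, abs_tol=1e-9):
            raise ValueError(
                f"NPP partition fractions for {self.name.name} do not sum to 1"
            )


def _data_frame(filename: str) -> pd.DataFrame:
    with resources.files("peatlucas.data").joinpath(filename).open() as fh:
        return pd.read_csv(fh)


def load_initial_stocks() -> pd.DataFrame:
    """Mature-stand stock densities and NPP by species (t C/ha)."""
    return _data_frame("initial_stocks.csv").set_index("stock")


def load_flow_multipliers() -> pd.DataFrame:
    return _data_frame("flow_multipliers.csv")


def load_flow_literature() -> pd.DataFrame:
    return _data_frame("flow_literature.csv")


def load_fire_severity() -> FireSeveritySpec:
    df = _data_frame("fire_severity.csv").set_index("severity")
    return FireSeveritySpec(
        p_high=float(df.loc["high", "proportion"]),
        p_med=float(df.loc["med", "proportion"]),
        p_low=float(df.loc["low", "proportion"]),
    )


def load_peat_accumulation() -> dict[StateClass, float]:
    df = _data_frame("peat_accumulation.csv")
    return {
        ABBREV_CLASS[row.species]: float(row.rate_t_c_per_ha_yr)
        for row in df.itertuples()
    }


def load_age_classes() -> dict[StateClass, dict]:
    df = _data_frame("age_classes.csv")
    out = {}
    for row in df.itertuples():
        out[ABBREV_CLASS[row.species]] = {
            "young": (row.young_min, row.young_max),
            "intermediate": (row.intermediate_min, row.intermediate_max),
            "mature": (row.mature_min, row.mature_max),
        }
    return out


def _multiplier(df: pd.DataFrame, frm: str, to: str, abbrev: str) -> float:
    row = df[(df.from_pool == frm) & (df.to_pool == to)]
    if len(row) != 1:
        raise KeyError(f"flow {frm}->{to} not found")
    return float(row.iloc[0][abbrev])


def load_species_params(validate: bool = True) -> dict[StateClass, SpeciesParams]:
    """Load the four forested species' parameter sets from packaged tables."""
    stocks = load_initial_stocks()
    mult = load_flow_multipliers()
    accum = load_peat_accumulation()
    ages = load_age_classes()

    out: dict[StateClass, SpeciesParams] = {}
    for cls in FORESTED_CLASSES:
        ab = CLASS_ABBREV[cls]
        init = {pool: float(stocks.loc[pool, ab]) for pool in POOLS}
        out[cls] = SpeciesParams(
            name=cls,
            npp_total=float(stocks.loc["npp", ab]),
            f_leaf=_multiplier(mult, "atmosphere", "live_leaf", ab),
            f_wood=_multiplier(mult, "atmosphere", "live_wood", ab),
            f_root=_multiplier(mult, "atmosphere", "live_root", ab),
            m_litterfall_leaf=_multiplier(mult, "live_leaf", "leaf_litter", ab),
            m_mortality_wood=_multiplier(mult, "live_wood", "deadwood", ab),
            m_litterfall_root=_multiplier(mult, "live_root", "dead_root", ab),
            m_humif_litter=_multiplier(mult, "leaf_litter", "upper_peat", ab),
            m_humif_deadwood=_multiplier(mult, "deadwood", "upper_peat", ab),
            m_humif_deadroot=_multiplier(mult, "dead_root", "upper_peat", ab),
            m_emis_litter=_multiplier(mult, "leaf_litter", "atmosphere", ab),
            m_emis_deadwood=_multiplier(mult, "deadwood", "atmosphere", ab),
            m_emis_deadroot=_multiplier(mult, "dead_root", "atmosphere", ab),
            m_emis_upper_peat=_multiplier(mult, "upper_peat", "atmosphere", ab),
            m_accum_upper_peat=_multiplier(mult, "upper_peat", "deep_peat", ab),
            peat_accumulation=accum[cls],
            init_stocks=init,
            age_class_bounds=ages[cls],
        )
    if validate:
        check_parameter_integrity(out)
    return out


def check_flow_calibration(tol: float = 0.01) -> pd.DataFrame:
    """Cross-check multipliers against the calibrated literature flows.

    For every biomass flow (the two peat rows are known to be internally
    inconsistent and are skipped), multiplier x mature from-stock must equal
    the literature flow density plus its calibration delta, within ``tol``
    t C/ha. Returns the comparison table; raises if any row fails.
    """
    stocks = load_initial_stocks()
    mult = load_flow_multipliers()
    lit = load_flow_literature()
    rows = []
    for _, m in mult.iterrows():
        if m.from_pool == "upper_peat":
            continue  # peat rows: see package methods note
        lrow = lit[(lit.from_pool == m.from_pool) & (lit.to_pool == m.to_pool)].iloc[0]
        for cls in FORESTED_CLASSES:
            ab = CLASS_ABBREV[cls]
            frm = "npp" if m.from_pool == "atmosphere" else m.from_pool
            computed = float(m[ab]) * float(stocks.loc[frm, ab])
            calibrated = float(lrow[ab]) + float(lrow[f"{ab}_delta"])
            rows.append(
                {
                    "from_pool": m.from_pool,
                    "to_pool": m.to_pool,
                    "species": ab,
                    "computed": computed,
                    "calibrated": calibrated,
                    "abs_err": abs(computed - calibrated),
                }
            )
    table = pd.DataFrame(rows)
    bad = table[table.abs_err > tol]
    if not bad.empty:
        raise ValueError(f"flow calibration mismatch:\n{bad}")
    return table


def check_parameter_integrity(params: dict[StateClass, SpeciesParams]) -> None:
    """Load-time sanity checks on the packaged parameter set."""
    # partition closure is asserted by SpeciesParams itself; check PP averaging
    pp = params[StateClass.POND_PINE]
    others = [
        params[c]
        for c in (
            StateClass.ATLANTIC_WHITE_CEDAR,
            StateClass.CYPRESS_GUM,
            StateClass.MAPLE_GUM,
        )
    ]
    for pool in POOLS:
        if pool in ("upper_peat", "deep_peat"):
            continue
        mean = sum(o.init_stocks[pool] for o in others) / 3.0
        if abs(mean - pp.init_stocks[pool]) > 0.01:
            raise ValueError(f"pond pine {pool} stock is not the 3-species mean")
    check_flow_calibration()


def stock_summary(stocks: pd.DataFrame | None = None) -> dict:
    """Aggregate statistics of the mature-stand stock table.

    Returns average live biomass (leaf+wood+root), per-species live biomass,
    and average above-ground (leaf+wood) biomass, in t C/ha.
    """
    if stocks is None:
        stocks = load_initial_stocks()
    abbrevs = [CLASS_ABBREV[c] for c in FORESTED_CLASSES]
    live = {
        ab: float(
            stocks.loc["live_leaf", ab]
            + stocks.loc["live_wood", ab]
            + stocks.loc["live_root", ab]
        )
        for ab in abbrevs
    }
    above = {
        ab: float(stocks.loc["live_leaf", ab] + stocks.loc["live_wood", ab])
        for ab in abbrevs
    }
    return {
        "live_biomass": live,
        "mean_live_biomass": sum(live.values()) / len(live),
        "max_live_biomass": max(live.values()),
        "min_live_biomass": min(live.values()),
        "aboveground_biomass": above,
        "mean_aboveground_biomass": sum(above.values()) / len(above),
    }
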