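"""The simulation landscape: a grid of 1-ha cells with class, stratum, age
and per-pool carbon state, plus readers/writers for the plain-text formats
the simulator touches (CSV cell tables and ESRI ASCII grids).

Grid convention: row-major, origin top-left, 0-based indices. State grids use
the integer codes of :class:`peatlucas.params.StateClass`, with 0 as the
void/nodata code; stratum grids use 0=Dry, 1=Wet.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .params import (
    CLASS_ABBREV,
    FORESTED_CLASSES,
    N_POOLS,
    POOL_INDEX,
    POOLS,
    VOID,
    SoilParams,
    SpeciesParams,
    StateClass,
    Stratum,
    peat_carbon_per_cm,
)
from .spinup import AgeLookup, GrowthCurve

#: sentinel for "never burned"
NO_FIRE = np.int32(-(10**6))

FORESTED_CODES = np.array([int(c) for c in FORESTED_CLASSES])


class LandscapeFormatError(ValueError):
    """Raised when input grids/tables are malformed or inconsistent."""


@dataclass
class Landscape:
    """Array-of-grids representation of the simulation landscape."""

    state: np.ndarray  # (nr, nc) int16 StateClass codes, 0 = void
    stratum: np.ndarray  # (nr, nc) int8, 0=Dry 1=Wet
    age: np.ndarray  # (nr, nc) int32, years (0 for non-forested)
    stocks: np.ndarray  # (N_POOLS, nr, nc) float64, t C/ha
    upper_peat_depth: np.ndarray  # (nr, nc) cm
    deep_peat_depth: np.ndarray  # (nr, nc) cm
    last_fire_year: np.ndarray = field(default=None)  # (nr, nc) int32
    last_fire_severity: np.ndarray = field(default=None)  # (nr, nc) int8
    current_year: int = 0
    cell_area_ha: float = 1.0

    def __post_init__(self) -> None:
        nr, nc = self.state.shape
        if self.last_fire_year is None:
            self.last_fire_year = np.full((nr, nc), NO_FIRE, dtype=np.int32)
        if self.last_fire_severity is None:
            self.last_fire_severity = np.zeros((nr, nc), dtype=np.int8)
        for name in ("stratum", "age", "upper_peat_depth", "deep_peat_depth"):
            arr = getattr(self, name)
            if arr.shape != (nr, nc):
                raise LandscapeFormatError(f"{name} grid shape mismatch")
        if self.stocks.shape != (N_POOLS, nr, nc):
            raise LandscapeFormatError("stocks array shape mismatch")

    # -- basic views ---------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.state.shape

    @property
    def mask(self) -> np.ndarray:
        """Non-void cells."""
        return self.state != VOID

    @property
    def forested_mask(self) -> np.ndarray:
        return np.isin(self.state, FORESTED_CODES)

    @property
    def area_ha(self) -> float:
        return float(np.count_nonzero(self.mask) * self.cell_area_ha)

    def class_mask(self, cls: StateClass) -> np.ndarray:
        return self.state == int(cls)

    def total_carbon(self) -> float:
        """Total ecosystem carbon on the landscape, t C."""
        return float(np.sum(self.stocks[:, self.mask]) * self.cell_area_ha)

    def pool_totals(self) -> dict[str, float]:
        m = self.mask
        return {p: float(np.sum(self.stocks[i][m])) for i, p in enumerate(POOLS)}

    def copy(self) -> "Landscape":
        return Landscape(
            state=self.state.copy(),
            stratum=self.stratum.copy(),
            age=self.age.copy(),
            stocks=self.stocks.copy(),
            upper_peat_depth=self.upper_peat_depth.copy(),
            deep_peat_depth=self.deep_peat_depth.copy(),
            last_fire_year=self.last_fire_year.copy(),
            last_fire_severity=self.last_fire_severity.copy(),
            current_year=self.current_year,
            cell_area_ha=self.cell_area_ha,
        )

    # -- constructors --------------------------------------------------

    @classmethod
    def blank(cls, n_rows: int, n_cols: int, soil: SoilParams | None = None) -> "Landscape":
        soil = soil or SoilParams()
        pcc = peat_carbon_per_cm(soil)
        stocks = np.zeros((N_POOLS, n_rows, n_cols))
        stocks[POOL_INDEX["upper_peat"]] = soil.upper_depth_cm * pcc
        stocks[POOL_INDEX["deep_peat"]] = soil.deep_depth_cm * pcc
        return cls(
            state=np.zeros((n_rows, n_cols), dtype=np.int16),
            stratum=np.zeros((n_rows, n_cols), dtype=np.int8),
            age=np.zeros((n_rows, n_cols), dtype=np.int32),
            stocks=stocks,
            upper_peat_depth=np.full((n_rows, n_cols), soil.upper_depth_cm),
            deep_peat_depth=np.full((n_rows, n_cols), soil.deep_depth_cm),
        )


# ---------------------------------------------------------------------------
# Stock initialization
# ---------------------------------------------------------------------------


def initialize_stocks(
    landscape: Landscape,
    species_params: dict[StateClass, SpeciesParams],
    soil: SoilParams,
    curves: dict[StateClass, GrowthCurve] | None = None,
) -> None:
    """Set per-pool carbon densities in place.

    Forested cells take either the mature-stand literature densities (default)
    or, when growth ``curves`` are given, the spin-up pool densities at each
    cell's age. Non-forested cells carry only the passive peat column; upland
    pine is carried but inert. Void cells hold no carbon.
    """
    pcc = peat_carbon_per_cm(soil)
    landscape.stocks[:] = 0.0
    m = landscape.mask
    landscape.stocks[POOL_INDEX["upper_peat"]][m] = soil.upper_depth_cm * pcc
    landscape.stocks[POOL_INDEX["deep_peat"]][m] = soil.deep_depth_cm * pcc
    landscape.upper_peat_depth[:] = soil.upper_depth_cm
    landscape.deep_peat_depth[:] = soil.deep_depth_cm

    biomass_pools = [p for p in POOLS if p not in ("upper_peat", "deep_peat")]
    for cls in FORESTED_CLASSES:
        sel = landscape.class_mask(cls)
        if not np.any(sel):
            continue
        p = species_params[cls]
        if curves is None:
            for pool in biomass_pools:
                landscape.stocks[POOL_INDEX[pool]][sel] = p.init_stocks[pool]
        else:
            curve = curves[cls]
            ages = np.clip(landscape.age[sel], 0, len(curve.ages) - 1)
            for pool in biomass_pools:
                landscape.stocks[POOL_INDEX[pool]][sel] = curve.pool(pool)[ages]


# ---------------------------------------------------------------------------
# Age editing
# ---------------------------------------------------------------------------


def biomass_to_age(biomass: float, lookup: AgeLookup) -> int:
    """Age whose growth-curve biomass first reaches ``biomass``.

    Biomass beyond the curve maximum returns the equilibrium age.
    """
    return int(lookup(biomass))


def rollback_ages(
    landscape: Landscape,
    years: int,
    species_params: dict[StateClass, SpeciesParams],
    soil: SoilParams,
    curves: dict[StateClass, GrowthCurve],
    scar_mask: np.ndarray | None = None,
    scar_age: int = 100,
    scar_class: StateClass = StateClass.ATLANTIC_WHITE_CEDAR,
) -> Landscape:
    """Rewind forested ages by ``years`` (floored at 0) to set a historic start.

    Cells inside ``scar_mask`` are overridden to ``scar_class`` at
    ``scar_age`` — the reconstruction rule for areas whose present-day cover
    no longer reflects the historic stand. All forested stocks are re-derived
    from the growth curves at the new ages (the literature densities describe
    mature stands only).
    """
    if years < 0:
        raise ValueError("years must be non-negative")
    out = landscape.copy()
    fm = out.forested_mask
    out.age[fm] = np.maximum(out.age[fm] - years, 0)
    if scar_mask is not None:
        sel = scar_mask & out.mask
        out.state[sel] = int(scar_class)
        out.age[sel] = scar_age
    initialize_stocks(out, species_params, soil, curves=curves)
    return out


def summarize_composition(landscape: Landscape) -> pd.DataFrame:
    """Per-class area (ha) and percentage of total landscape area."""
    total = landscape.area_ha
    if total == 0:
        raise ValueError("landscape is empty")
    rows = []
    for cls in StateClass:
        area = float(np.count_nonzero(landscape.class_mask(cls)) * landscape.cell_area_ha)
        if area > 0:
            rows.append(
                {
                    "state_class": cls.name,
                    "area_ha": area,
                    "percent": 100.0 * area / total,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cell-table I/O (CSV)
# ---------------------------------------------------------------------------


def landscape_to_cell_table(landscape: Landscape) -> pd.DataFrame:
    """Flat (row, col, state_class, stratum, age) table of non-void cells."""
    rr, cc = np.nonzero(landscape.mask)
    return pd.DataFrame(
        {
            "row": rr,
            "col": cc,
            "state_class": [
                CLASS_ABBREV[StateClass(int(s))] for s in landscape.state[rr, cc]
            ],
            "stratum": [Stratum(int(s)).name for s in landscape.stratum[rr, cc]],
            "age": landscape.age[rr, cc],
        }
    )


def landscape_from_cell_table(
    table: pd.DataFrame,
    species_params: dict[StateClass, SpeciesParams] | None = None,
    soil: SoilParams | None = None,
    curves: dict[StateClass, GrowthCurve] | None = None,
    shape: tuple[int, int] | None = None,
) -> Landscape:
    """Build a landscape from a flat cell table.

    ``state_class`` accepts either the short labels (AWC, CG, MG, PP, MARSH,
    OPEN_WATER, UPLAND_PINE) or integer codes; ``stratum`` accepts DRY/WET or
    0/1. Stocks are initialized from the mature densities, or from growth
    curves when given.
    """
    required = {"row", "col", "state_class", "stratum", "age"}
    missing = required - set(table.columns)
    if missing:
        raise LandscapeFormatError(f"cell table missing columns: {sorted(missing)}")
    soil = soil or SoilParams()
    if shape is None:
        shape = (int(table.row.max()) + 1, int(table.col.max()) + 1) if len(table) else (0, 0)
    if len(table) == 0:
        return Landscape.blank(max(shape[0], 1), max(shape[1], 1), soil)

    land = Landscape.blank(*shape, soil)

    def parse_class(v):
        if isinstance(v, str):
            key = v.strip().upper()
            if key not in {CLASS_ABBREV[c] for c in StateClass}:
                raise LandscapeFormatError(f"unknown state class code: {v!r}")
            return int({CLASS_ABBREV[c]: c for c in StateClass}[key])
        code = int(v)
        if code not in [int(c) for c in StateClass]:
            raise LandscapeFormatError(f"unknown state class code: {v!r}")
        return code

    def parse_stratum(v):
        if isinstance(v, str):
            key = v.strip().upper()
            if key not in ("DRY", "WET"):
                raise LandscapeFormatError(f"unknown stratum: {v!r}")
            return int(Stratum[key])
        return int(v)

    rows = table.row.to_numpy(dtype=int)
    cols = table.col.to_numpy(dtype=int)
    land.state[rows, cols] = [parse_class(v) for v in table.state_class]
    land.stratum[rows, cols] = [parse_stratum(v) for v in table.stratum]
    land.age[rows, cols] = table.age.to_numpy(dtype=int)
    # ages only apply to forested classes
    land.age[~land.forested_mask] = 0
    land.stocks[:, ~land.mask] = 0.0
    if species_params is not None:
        initialize_stocks(land, species_params, soil, curves=curves)
    return land


def write_cell_table(landscape: Landscape, path: str | Path) -> None:
    landscape_to_cell_table(landscape).to_csv(path, index=False)


def read_cell_table(path: str | Path, **kwargs) -> Landscape:
    return landscape_from_cell_table(pd.read_csv(path), **kwargs)


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O
# ---------------------------------------------------------------------------

_ASC_NODATA = -9999


def write_ascii_grid(
    array: np.ndarray,
    path: str | Path,
    cellsize: float = 100.0,
    xllcorner: float = 0.0,
    yllcorner: float = 0.0,
    nodata: int = _ASC_NODATA,
) -> None:
    """Write a single-band integer grid in ESRI ASCII format."""
    nr, nc = array.shape
    header = (
        f"ncols {nc}\nnrows {nr}\nxllcorner {xllcorner}\nyllcorner {yllcorner}\n"
        f"cellsize {cellsize}\nNODATA_value {nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, array.astype(int), fmt="%d")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read an ESRI ASCII grid; returns (array, header metadata)."""
    meta: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        ):
            meta[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    arr = np.loadtxt(lines[n_header:])
    arr = np.atleast_2d(arr)
    if arr.shape != (int(meta["nrows"]), int(meta["ncols"])):
        raise LandscapeFormatError("ASCII grid body does not match header shape")
    return arr, meta


def write_landscape(landscape: Landscape, directory: str | Path) -> None:
    """Write state/age/stratum grids plus a class-code legend sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    state = landscape.state.astype(int).copy()
    state[~landscape.mask] = _ASC_NODATA
    write_ascii_grid(state, directory / "state.asc")
    age = landscape.age.astype(int).copy()
    age[~landscape.mask] = _ASC_NODATA
    write_ascii_grid(age, directory / "age.asc")
    stratum = landscape.stratum.astype(int).copy()
    stratum[~landscape.mask] = _ASC_NODATA
    write_ascii_grid(stratum, directory / "stratum.asc")
    legend = {CLASS_ABBREV[c]: int(c) for c in StateClass}
    legend["VOID"] = VOID
    with open(directory / "legend.json", "w") as fh:
        json.dump({"state_codes": legend, "stratum_codes": {"DRY": 0, "WET": 1}}, fh, indent=2)


def load_landscape(
    state_raster: str | Path,
    age_raster: str | Path,
    stratum_raster: str | Path,
    species_params: dict[StateClass, SpeciesParams] | None = None,
    soil: SoilParams | None = None,
    curves: dict[StateClass, GrowthCurve] | None = None,
) -> Landscape:
    """Assemble a landscape from state/age/stratum ASCII grids.

    Grids must share shape and cell size; nodata cells become void. Unknown
    class codes raise a validation error listing the offending codes.
    """
    soil = soil or SoilParams()
    state, ms = read_ascii_grid(state_raster)
    age, ma = read_ascii_grid(age_raster)
    stratum, mst = read_ascii_grid(stratum_raster)
    if not (state.shape == age.shape == stratum.shape):
        raise LandscapeFormatError("state/age/stratum grids have mismatched shapes")
    if not (ms.get("cellsize") == ma.get("cellsize") == mst.get("cellsize")):
        raise LandscapeFormatError("grids have mismatched cell sizes")
    nodata = ms.get("nodata_value", _ASC_NODATA)
    state = state.astype(int)
    valid = state != int(nodata)
    known = set(int(c) for c in StateClass) | {VOID}
    codes = set(np.unique(state[valid]).tolist())
    unknown = sorted(codes - known)
    if unknown:
        raise LandscapeFormatError(f"unknown state class codes: {unknown}")

    land = Landscape.blank(*state.shape, soil)
    land.state[valid] = state[valid]
    a = age.astype(int)
    a[a == int(ma.get("nodata_value", _ASC_NODATA))] = 0
    land.age[valid] = a[valid]
    land.age[~land.forested_mask] = 0
    st = stratum.astype(int)
    st[st == int(mst.get("nodata_value", _ASC_NODATA))] = 0
    land.stratum[valid] = st[valid]
    # void cells carry nothing
    land.stocks[:, ~valid] = 0.0
    if species_params is not None:
        initialize_stocks(land, species_params, soil, curves=curves)
    return land
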