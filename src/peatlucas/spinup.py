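"""Cold-start spin-up: forest growth curves and the biomass->age lookup.

Starting every biomass pool at zero ("cold start") and iterating the annual
flow step under constant NPP produces a deterministic growth curve per
species. Because the NPP inflow is constant and each live pool loses a fixed
fraction per year, live wood follows the discrete single-pool recursion

    W(t+1) = W(t) + I - m W(t),   I = f_wood * NPP,

whose closed form is W(t) = (I/m) (1 - (1-m)^t) with fixed point I/m. The
resulting curves are strictly concave (no inflection): constant NPP cannot
reproduce the sigmoid shape of inventory-derived chronosequences, and the
curves should be read as equilibria-consistent interpolators, not juvenile
growth models.

The monotone live-tree segment of each curve is inverted into an age lookup
used to assign initial stand ages from biomass, and to re-derive stocks when
ages are edited (e.g. rolled back to a historic start year).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import N_POOLS, POOL_INDEX, POOLS, SpeciesParams, StateClass
from .stockflow import annual_flows


@dataclass
class GrowthCurve:
    """Per-age pool densities from a cold-start spin-up of one species."""

    species: StateClass
    ages: np.ndarray  # 0..years
    stocks: np.ndarray  # (N_POOLS, years+1) t C/ha
    include_roots: bool = False  # whether live_tree includes live roots

    @property
    def live_tree(self) -> np.ndarray:
        """Live-tree biomass by age: leaf + wood (+ roots if configured)."""
        b = self.stocks[POOL_INDEX["live_leaf"]] + self.stocks[POOL_INDEX["live_wood"]]
        if self.include_roots:
            b = b + self.stocks[POOL_INDEX["live_root"]]
        return b

    def pool(self, name: str) -> np.ndarray:
        return self.stocks[POOL_INDEX[name]]

    def stocks_at_age(self, age: int) -> np.ndarray:
        age = int(np.clip(age, 0, len(self.ages) - 1))
        return self.stocks[:, age].copy()

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"age": self.ages})
        for i, pool in enumerate(POOLS):
            df[pool] = self.stocks[i]
        df["live_tree"] = self.live_tree
        df.insert(0, "species", self.species.name)
        return df


def run_spinup(
    params: SpeciesParams,
    years: int = 300,
    peat_mode: str = "steady_state",
    include_roots: bool = False,
) -> GrowthCurve:
    """Iterate the annual flow step from zero biomass for ``years`` steps.

    Peat pools start at their standard column densities (the peat column
    exists regardless of stand age); all six biomass pools start at zero.
    Deterministic: no randomness enters the flow step.
    """
    stocks = np.zeros((N_POOLS, years + 1))
    s = np.zeros(N_POOLS)
    s[POOL_INDEX["upper_peat"]] = params.init_stocks["upper_peat"]
    s[POOL_INDEX["deep_peat"]] = params.init_stocks["deep_peat"]
    stocks[:, 0] = s
    for t in range(years):
        s, _ = annual_flows(s, params, peat_mode=peat_mode)
        stocks[:, t + 1] = s
    return GrowthCurve(
        species=params.name,
        ages=np.arange(years + 1),
        stocks=stocks,
        include_roots=include_roots,
    )


def live_wood_closed_form(params: SpeciesParams, ages: np.ndarray) -> np.ndarray:
    """Analytic live-wood trajectory of the cold-start recursion.

    W(t) = (I/m)(1 - (1-m)^t) with I = f_wood * NPP and m the wood mortality
    multiplier. Serves as an independent oracle for the iterated spin-up.
    """
    ages = np.asarray(ages, dtype=float)
    inflow = params.f_wood * params.npp_total
    m = params.m_mortality_wood
    return (inflow / m) * (1.0 - (1.0 - m) ** ages)


def find_equilibrium(
    curve: GrowthCurve, tol: float = 1e-3
) -> tuple[int, float, bool]:
    """Smallest age where the annual relative live-tree increase drops below tol.

    Returns (age, biomass at that age, converged). If the threshold is never
    crossed the final age is returned with ``converged=False``.
    """
    b = curve.live_tree
    if len(b) < 2:
        raise ValueError("curve must span at least two ages")
    prev = b[:-1]
    delta = b[1:] - prev
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(prev > 0, delta / np.maximum(prev, 1e-300), np.inf)
    rel = np.where(delta == 0, 0.0, rel)  # constant curve converges immediately
    hits = np.nonzero(rel < tol)[0]
    if len(hits) == 0:
        return int(curve.ages[-1]), float(b[-1]), False
    age = int(curve.ages[hits[0] + 1])
    return age, float(b[age]), True


@dataclass
class AgeLookup:
    """Monotone inverse of a growth curve's live-tree biomass."""

    species: StateClass
    ages: np.ndarray
    biomass: np.ndarray  # strictly increasing segment, biomass[i] at ages[i]
    equilibrium_age: int

    def __call__(self, biomass) -> np.ndarray | int:
        """Smallest age whose curve biomass >= the input biomass.

        Biomass above the curve maximum maps to the equilibrium age.
        """
        b = np.asarray(biomass, dtype=float)
        if np.any(b < 0):
            raise ValueError("biomass must be non-negative")
        idx = np.searchsorted(self.biomass, b, side="left")
        ages = np.where(
            idx >= len(self.biomass), self.equilibrium_age, self.ages[np.minimum(idx, len(self.ages) - 1)]
        )
        if np.isscalar(biomass) or b.ndim == 0:
            return int(ages)
        return ages.astype(int)


def build_age_lookup(curve: GrowthCurve, tol: float = 1e-3) -> AgeLookup:
    """Invert the strictly increasing segment of a growth curve."""
    eq_age, _, _ = find_equilibrium(curve, tol=tol)
    b = curve.live_tree
    # strictly increasing prefix (constant NPP curves are monotone by
    # construction; guard against numerically flat tails)
    end = len(b)
    for i in range(1, len(b)):
        if b[i] <= b[i - 1]:
            end = i
            break
    seg = b[:end]
    if np.any(np.diff(seg) <= 0):
        raise ValueError("growth curve is not monotone on its initial segment")
    return AgeLookup(
        species=curve.species,
        ages=curve.ages[:end],
        biomass=seg,
        equilibrium_age=eq_age,
    )


def spinup_all(
    species_params: dict[StateClass, SpeciesParams],
    years: int = 300,
    peat_mode: str = "steady_state",
) -> dict[StateClass, GrowthCurve]:
    """Growth curves for every forested species."""
    return {
        cls: run_spinup(p, years=years, peat_mode=peat_mode)
        for cls, p in species_params.items()
    }


def curves_to_frame(curves: dict[StateClass, GrowthCurve]) -> pd.DataFrame:
    return pd.concat([c.to_frame() for c in curves.values()], ignore_index=True)
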