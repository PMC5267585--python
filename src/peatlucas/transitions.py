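"""State-and-transition layer: probabilistic succession with age gating and
neighborhood adjacency, area-targeted disturbance/management events, burn
severity assignment, and repeat-catastrophic fire detection.

Alternative succession (young Atlantic white cedar or pond pine stands losing
ground to maple-gum) is probabilistic: each eligible cell (matching class and
stratum, age at most 5 years) converts with probability p multiplied by an
adjacency factor — the fraction of its eight neighbors already in the target
class, so conversion can only spread from existing stands. Adjacency grids
are refreshed on a five-year cadence.

Known events (fires, hurricane windthrow, salvage/replant) are area targets:
a prescribed number of hectares inside a spatial mask, fulfilled exactly when
enough eligible cells exist and logged as a shortfall otherwise.

Within the Dry stratum, a cell burning again within five years of a previous
fire is a repeat catastrophic fire: its age resets and (by default) the cell
converts to marsh.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .landscape import NO_FIRE, Landscape
from .params import FireSeveritySpec, Severity, StateClass, Stratum

log = logging.getLogger(__name__)

#: years: a second fire within this window (exclusive) is repeat catastrophic
REPEAT_FIRE_WINDOW = 5

#: adjacency grids are refreshed every this many simulated years
ADJACENCY_REFRESH_YEARS = 5

#: age gate for alternative succession (inclusive)
SUCCESSION_AGE_MAX = 5


@dataclass(frozen=True)
class TransitionPathway:
    """A probabilistic class-change pathway."""

    from_class: StateClass
    to_class: StateClass
    stratum: Stratum | None  # None = any
    probability: float
    age_max: int | None = SUCCESSION_AGE_MAX
    age_reset: bool = False
    adjacency_class: StateClass | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("transition probability must be in [0, 1]")


def default_succession_pathways() -> list[TransitionPathway]:
    """Alternative succession to maple-gum, gated by adjacency and age.

    Dry-zone probabilities 0.80 (cedar) / 0.50 (pond pine); wet-zone 0.04 /
    0.01.
    """
    mg = StateClass.MAPLE_GUM
    return [
        TransitionPathway(StateClass.ATLANTIC_WHITE_CEDAR, mg, Stratum.DRY, 0.80, adjacency_class=mg),
        TransitionPathway(StateClass.POND_PINE, mg, Stratum.DRY, 0.50, adjacency_class=mg),
        TransitionPathway(StateClass.ATLANTIC_WHITE_CEDAR, mg, Stratum.WET, 0.04, adjacency_class=mg),
        TransitionPathway(StateClass.POND_PINE, mg, Stratum.WET, 0.01, adjacency_class=mg),
    ]


_NEIGHBOR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=float)


def compute_adjacency_multiplier(
    landscape: Landscape, target_class: StateClass
) -> np.ndarray:
    """Fraction of each cell's 8-neighborhood occupied by ``target_class``.

    Edge cells normalize by their in-grid, non-void neighbor count; cells with
    no matching neighbor get 0 and are blocked from transitioning.
    """
    if landscape.area_ha == 0:
        raise ValueError("landscape is empty")
    match = (landscape.state == int(target_class)).astype(float)
    count = ndimage.convolve(match, _NEIGHBOR_KERNEL, mode="constant", cval=0.0)
    valid = landscape.mask.astype(float)
    denom = ndimage.convolve(valid, _NEIGHBOR_KERNEL, mode="constant", cval=0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        mult = np.where(denom > 0, count / np.maximum(denom, 1.0), 0.0)
    return mult


def apply_probabilistic_transitions(
    landscape: Landscape,
    pathways: list[TransitionPathway],
    adjacency: dict[StateClass, np.ndarray],
    rng: np.random.Generator,
) -> list[dict]:
    """Execute probabilistic pathways in place; returns an event log.

    Each eligible cell transitions with probability p x adjacency multiplier;
    transitioned cells adopt the target class and keep their age unless the
    pathway resets it. Carbon stocks ride along unchanged.
    """
    events: list[dict] = []
    for pw in pathways:
        eligible = landscape.class_mask(pw.from_class)
        if pw.stratum is not None:
            eligible &= landscape.stratum == int(pw.stratum)
        if pw.age_max is not None:
            eligible &= landscape.age <= pw.age_max
        if not np.any(eligible):
            continue
        p = np.full(landscape.shape, pw.probability)
        if pw.adjacency_class is not None:
            p = p * adjacency[pw.adjacency_class]
        draw = rng.random(landscape.shape)
        hit = eligible & (draw < p)
        n = int(np.count_nonzero(hit))
        if n == 0:
            continue
        landscape.state[hit] = int(pw.to_class)
        if pw.age_reset:
            landscape.age[hit] = 0
        events.append(
            {
                "transition_type": "AlternativeSuccession",
                "from_class": pw.from_class.name,
                "to_class": pw.to_class.name,
                "n_cells": n,
            }
        )
    return events


def assign_fire_severity(
    n_cells: int, spec: FireSeveritySpec, rng: np.random.Generator
) -> np.ndarray:
    """Independently label each burned cell high/med/low severity.

    Returns an int array of :class:`Severity` values of length ``n_cells``.
    """
    labels = rng.choice(
        [int(Severity.HIGH), int(Severity.MED), int(Severity.LOW)],
        size=n_cells,
        p=[spec.p_high, spec.p_med, spec.p_low],
    )
    return labels.astype(np.int8)


def detect_repeat_catastrophic(
    landscape: Landscape,
    burn_mask: np.ndarray,
    current_year: int,
    window: int = REPEAT_FIRE_WINDOW,
) -> np.ndarray:
    """Cells in ``burn_mask`` whose new fire is a repeat catastrophic fire.

    True where the cell is in the Dry stratum and burned previously within
    ``window`` years (exclusive) of ``current_year``.
    """
    since = current_year - landscape.last_fire_year
    prior = (landscape.last_fire_year != NO_FIRE) & (since > 0) & (since < window)
    return burn_mask & prior & (landscape.stratum == int(Stratum.DRY))


def select_target_cells(
    eligible: np.ndarray,
    area_ha: float,
    rng: np.random.Generator,
    cell_area_ha: float = 1.0,
    label: str = "",
) -> np.ndarray:
    """Choose cells to fulfil an area target: uniform without replacement.

    Fulfils min(target, eligible area); a shortfall is logged as a warning.
    Returns a boolean mask of selected cells.
    """
    rr, cc = np.nonzero(eligible)
    n_eligible = len(rr)
    n_target = int(round(area_ha / cell_area_ha))
    n = min(n_target, n_eligible)
    if n < n_target:
        log.warning(
            "target %s: only %d of %d ha eligible; fulfilling %d ha",
            label or "<unnamed>", n_eligible, n_target, n,
        )
    chosen = np.zeros_like(eligible, dtype=bool)
    if n == 0:
        return chosen
    if n == n_eligible:
        chosen[rr, cc] = True
        return chosen
    idx = rng.choice(n_eligible, size=n, replace=False)
    chosen[rr[idx], cc[idx]] = True
    return chosen


class FireHistory:
    """Per-cell record of (year, severity) fire events.

    Backed by the landscape's last-fire grids for vectorized queries, plus an
    append-only event list for reporting.
    """

    def __init__(self, shape: tuple[int, int]):
        self._events: list[tuple[int, str, np.ndarray, np.ndarray]] = []
        self.shape = shape

    def record(
        self, year: int, name: str, mask: np.ndarray, severities: np.ndarray
    ) -> None:
        if self._events and year < self._events[-1][0]:
            raise ValueError("fire records must be non-decreasing in year")
        self._events.append((year, name, mask.copy(), severities.copy()))

    def records_for_cell(self, row: int, col: int) -> list[tuple[int, str]]:
        out = []
        for year, _name, mask, sev in self._events:
            if mask[row, col]:
                out.append((year, Severity(int(sev[row, col])).name))
        return out

    def __len__(self) -> int:
        return len(self._events)
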