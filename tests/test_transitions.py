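"""Adjacency, probabilistic succession, severity draws and repeat-fire rules."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from peatlucas import FireSeveritySpec, StateClass, Stratum
from peatlucas.landscape import landscape_from_cell_table
from peatlucas.params import Severity
from peatlucas.transitions import (
    TransitionPathway,
    apply_probabilistic_transitions,
    assign_fire_severity,
    compute_adjacency_multiplier,
    default_succession_pathways,
    detect_repeat_catastrophic,
    select_target_cells,
)

AWC = StateClass.ATLANTIC_WHITE_CEDAR
MG = StateClass.MAPLE_GUM


def grid_landscape(species_params, soil, classes, stratum="DRY", age=3):
    """Landscape from a 2-D array of class abbreviations."""
    rows = []
    for r, line in enumerate(classes):
        for c, cls in enumerate(line):
            rows.append(
                {"row": r, "col": c, "state_class": cls, "stratum": stratum, "age": age}
            )
    return landscape_from_cell_table(pd.DataFrame(rows), species_params, soil)


class TestAdjacency:
    def test_saturated_blocked_and_half_neighborhoods(self, species_params, soil):
        grid = [
            ["MG", "MG", "MG", "AWC", "AWC"],
            ["MG", "AWC", "MG", "AWC", "AWC"],
            ["MG", "MG", "MG", "AWC", "AWC"],
            ["AWC", "AWC", "AWC", "AWC", "AWC"],
            ["AWC", "AWC", "AWC", "AWC", "AWC"],
        ]
        land = grid_landscape(species_params, soil, grid)
        mult = compute_adjacency_multiplier(land, MG)
        assert mult[1, 1] == 1.0  # all 8 neighbors maple-gum
        assert mult[4, 4] == 0.0  # no maple-gum anywhere nearby
        # cell (1,3): neighbors are (0,2..4),(1,2),(1,4),(2,2..4) -> MG at (0,2),(1,2),(2,2)
        assert mult[1, 3] == pytest.approx(3 / 8)

    def test_edge_cells_normalize_by_ingrid_neighbors(self, species_params, soil):
        land = grid_landscape(species_params, soil, [["AWC", "MG"], ["MG", "MG"]])
        mult = compute_adjacency_multiplier(land, MG)
        assert mult[0, 0] == pytest.approx(1.0)  # all 3 in-grid neighbors match


class TestProbabilisticSuccession:
    def _uniform_awc(self, species_params, soil, stratum, age, n=60):
        grid = [["AWC"] * n for _ in range(n)]
        land = grid_landscape(species_params, soil, grid, stratum=stratum, age=age)
        return land

    @pytest.mark.parametrize(
        "stratum,expected_p", [("DRY", 0.80), ("WET", 0.04)]
    )
    def test_conversion_rates_by_stratum(self, species_params, soil, stratum, expected_p):
        land = self._uniform_awc(species_params, soil, stratum, age=3)
        adjacency = {MG: np.ones(land.shape)}  # isolate the base probability
        rng = np.random.default_rng(3)
        apply_probabilistic_transitions(land, default_succession_pathways(), adjacency, rng)
        frac = np.count_nonzero(land.state == int(MG)) / land.area_ha
        n = int(land.area_ha)
        se = np.sqrt(expected_p * (1 - expected_p) / n)
        assert abs(frac - expected_p) < 4 * se

    def test_age_gate_blocks_established_stands(self, species_params, soil):
        land = self._uniform_awc(species_params, soil, "DRY", age=6, n=20)
        adjacency = {MG: np.ones(land.shape)}
        apply_probabilistic_transitions(
            land, default_succession_pathways(), adjacency, np.random.default_rng(0)
        )
        assert np.all(land.state == int(AWC))

    def test_zero_adjacency_blocks_transition(self, species_params, soil):
        land = self._uniform_awc(species_params, soil, "DRY", age=3, n=20)
        adjacency = {MG: compute_adjacency_multiplier(land, MG)}  # no MG anywhere
        apply_probabilistic_transitions(
            land, default_succession_pathways(), adjacency, np.random.default_rng(0)
        )
        assert np.all(land.state == int(AWC))

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            TransitionPathway(AWC, MG, Stratum.DRY, probability=1.2)


class TestFireSeverity:
    def test_degenerate_spec_all_high(self, rng):
        labels = assign_fire_severity(500, FireSeveritySpec(1.0, 0.0, 0.0), rng)
        assert np.all(labels == int(Severity.HIGH))

    def test_high_count_within_binomial_bounds(self, rng):
        n = 10_000
        labels = assign_fire_severity(n, FireSeveritySpec(), rng)
        high = int(np.sum(labels == int(Severity.HIGH)))
        sd = np.sqrt(n * 0.163 * (1 - 0.163))
        assert abs(high - n * 0.163) < 3 * sd

    def test_proportions_match_expected_chisquare(self, rng):
        """Label frequencies are consistent with the published proportions."""
        n = 100_000
        labels = assign_fire_severity(n, FireSeveritySpec(), rng)
        observed = [
            int(np.sum(labels == int(s)))
            for s in (Severity.HIGH, Severity.MED, Severity.LOW)
        ]
        expected = [n * p for p in (0.163, 0.409, 0.428)]
        _, pvalue = stats.chisquare(observed, expected)
        assert pvalue > 0.01


class TestRepeatCatastrophic:
    def _land(self, species_params, soil, stratum):
        return grid_landscape(species_params, soil, [["AWC"] * 3] * 3, stratum=stratum)

    def test_dry_cell_reburned_within_window(self, species_params, soil):
        land = self._land(species_params, soil, "DRY")
        land.last_fire_year[1, 1] = 2008
        burn = np.ones(land.shape, dtype=bool)
        repeat = detect_repeat_catastrophic(land, burn, current_year=2011)
        assert repeat[1, 1] and repeat.sum() == 1

    def test_seven_year_gap_is_not_repeat(self, species_params, soil):
        land = self._land(species_params, soil, "DRY")
        land.last_fire_year[1, 1] = 2004
        repeat = detect_repeat_catastrophic(
            land, np.ones(land.shape, dtype=bool), current_year=2011
        )
        assert not repeat.any()

    def test_wet_stratum_never_repeat(self, species_params, soil):
        land = self._land(species_params, soil, "WET")
        land.last_fire_year[1, 1] = 2008
        repeat = detect_repeat_catastrophic(
            land, np.ones(land.shape, dtype=bool), current_year=2011
        )
        assert not repeat.any()


class TestTargetSelection:
    def test_exact_area_fulfilled(self, rng):
        eligible = np.zeros((20, 20), dtype=bool)
        eligible[:10] = True
        chosen = select_target_cells(eligible, 50, rng)
        assert chosen.sum() == 50
        assert np.all(eligible[chosen])

    def test_shortfall_clamped_and_warned(self, rng, caplog):
        eligible = np.zeros((10, 10), dtype=bool)
        eligible[0, :3] = True  # 3 ha available
        with caplog.at_level("WARNING"):
            chosen = select_target_cells(eligible, 50, rng, label="test-fire")
        assert chosen.sum() == 3
        assert any("test-fire" in r.message for r in caplog.records)

    def test_deterministic_given_seed(self):
        eligible = np.ones((30, 30), dtype=bool)
        a = select_target_cells(eligible, 100, np.random.default_rng(5))
        b = select_target_cells(eligible, 100, np.random.default_rng(5))
        assert np.array_equal(a, b)
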