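"""Annual flow step, disturbance flows and the gain-loss mass balance."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from peatlucas import SoilParams, StateClass, Stratum
from peatlucas.params import N_POOLS, POOL_INDEX, peat_carbon_per_cm
from peatlucas.stockflow import (
    Cell,
    FireConsumptionSpec,
    annual_flows,
    apply_deadwood_harvest,
    apply_fire_consumption,
    apply_hurricane_transfer,
    flows_by_category,
    mass_balance,
    mature_cell,
    step_flows,
)

AWC = StateClass.ATLANTIC_WHITE_CEDAR


def flow_amount(flows, frm, to):
    return sum(float(np.sum(f.amount)) for f in flows if f.from_pool == frm and f.to_pool == to)


class TestAnnualFlows:
    def test_awc_growth_into_live_leaf(self, species_params):
        cell = mature_cell(species_params[AWC], Stratum.DRY)
        _, flows = step_flows(cell, species_params[AWC])
        assert flow_amount(flows, "atmosphere", "live_leaf") == pytest.approx(3.04, abs=0.01)

    def test_awc_leaf_litterfall_at_mature_stocks(self, species_params):
        # 0.340 x 5.42 — the calibrated litterfall density
        cell = mature_cell(species_params[AWC], Stratum.DRY)
        _, flows = step_flows(cell, species_params[AWC])
        assert flow_amount(flows, "live_leaf", "leaf_litter") == pytest.approx(1.843, abs=0.001)

    def test_cold_start_gains_exactly_npp(self, species_params):
        p = species_params[AWC]
        before = np.zeros(N_POOLS)
        after, flows = annual_flows(before, p)
        assert np.sum(after) - np.sum(before) == pytest.approx(p.npp_total, abs=1e-9)
        cats = flows_by_category(flows)
        assert cats["Growth"] == pytest.approx(p.npp_total, abs=1e-12)
        # with no detritus and no humification there is nothing to respire
        assert cats.get("Emission", 0.0) == 0.0

    def test_steady_state_upper_peat_constant(self, species_params):
        cell = mature_cell(species_params[AWC], Stratum.DRY)
        up0 = cell.stock("upper_peat")
        for _ in range(10):
            cell, _ = step_flows(cell, species_params[AWC])
        assert cell.stock("upper_peat") == pytest.approx(up0, abs=1e-9)

    def test_live_wood_fixed_point(self, species_params):
        """Iterating the step converges live wood to f_wood x NPP / m."""
        p = species_params[AWC]
        s = np.zeros(N_POOLS)
        for _ in range(3000):
            s, _ = annual_flows(s, p)
        expected = p.f_wood * p.npp_total / p.m_mortality_wood
        assert s[POOL_INDEX["live_wood"]] == pytest.approx(expected, rel=1e-6)
        assert expected == pytest.approx(104.9, abs=0.1)

    def test_negative_stock_rejected(self, species_params):
        s = np.zeros(N_POOLS)
        s[0] = -1.0
        with pytest.raises(ValueError):
            annual_flows(s, species_params[AWC])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(stocks=st.lists(st.floats(0, 500), min_size=N_POOLS, max_size=N_POOLS))
    def test_nonnegativity_and_conservation(self, species_params, stocks):
        """No pool goes negative and the gain-loss identity holds for any
        non-negative starting state."""
        p = species_params[AWC]
        before = np.array(stocks)
        after, flows = annual_flows(before, p)
        assert np.all(after >= 0)
        assert mass_balance(before, after, flows, tol=1e-9)


class TestFireConsumption:
    def test_peat_depth_converts_to_carbon(self, soil):
        stocks = np.zeros((N_POOLS, 1))
        stocks[POOL_INDEX["upper_peat"]] = 40 * peat_carbon_per_cm(soil)
        stocks[POOL_INDEX["deep_peat"]] = 60 * peat_carbon_per_cm(soil)
        spec = FireConsumptionSpec.uniform_agb(0.80, peat_depth_cm=20.0)
        new, up, dp, flows = apply_fire_consumption(
            stocks, np.array([40.0]), np.array([60.0]), spec, soil
        )
        bgb = sum(f.total() for f in flows if f.category == "FireEmissionBGB")
        assert bgb == pytest.approx(20 * peat_carbon_per_cm(soil), abs=1e-9)
        assert up[0] == 20.0 and dp[0] == 60.0

    def test_zero_spec_is_noop(self, species_params, soil):
        cell = mature_cell(species_params[AWC], Stratum.DRY)
        stocks = cell.stocks.reshape(N_POOLS, 1)
        new, up, dp, flows = apply_fire_consumption(
            stocks, np.array([40.0]), np.array([60.0]),
            FireConsumptionSpec.uniform_agb(0.0, 0.0), soil,
        )
        assert np.allclose(new, stocks)
        assert sum(f.total() for f in flows) == 0.0

    def test_repeat_fire_spec_empties_column_to_30cm(self, species_params, soil):
        """Remaining fuels + 50 cm of peat + roots: upper layer exhausted,
        deep layer reduced to 30 cm."""
        cell = mature_cell(species_params[AWC], Stratum.DRY)
        stocks = cell.stocks.reshape(N_POOLS, 1)
        spec = FireConsumptionSpec.uniform_agb(1.0, 50.0, include_roots=True)
        new, up, dp, flows = apply_fire_consumption(
            stocks, np.array([20.0]), np.array([60.0]), spec, soil
        )
        assert up[0] == 0.0 and dp[0] == pytest.approx(30.0)
        for pool in ("live_leaf", "live_wood", "leaf_litter", "deadwood",
                     "live_root", "dead_root"):
            assert new[POOL_INDEX[pool], 0] == 0.0
        assert mass_balance(stocks, new, flows)

    def test_depth_request_clamped_to_column(self, soil):
        stocks = np.zeros((N_POOLS, 1))
        stocks[POOL_INDEX["upper_peat"]] = 10 * peat_carbon_per_cm(soil)
        spec = FireConsumptionSpec(peat_depth_cm=25.0)
        new, up, dp, flows = apply_fire_consumption(
            stocks, np.array([10.0]), np.array([0.0]), spec, soil
        )
        assert up[0] == 0.0
        bgb = sum(f.total() for f in flows if f.category == "FireEmissionBGB")
        assert bgb == pytest.approx(10 * peat_carbon_per_cm(soil))


class TestHurricaneAndHarvest:
    def test_hurricane_moves_live_to_dead_and_conserves(self, species_params):
        cell = mature_cell(species_params[AWC], Stratum.DRY)
        before = cell.stocks.copy()
        after, flows = apply_hurricane_transfer(before)
        assert flow_amount(flows, "live_wood", "deadwood") == pytest.approx(103.87)
        assert flow_amount(flows, "live_leaf", "leaf_litter") == pytest.approx(5.42)
        assert flow_amount(flows, "live_root", "dead_root") == pytest.approx(5.46)
        assert np.sum(after) == pytest.approx(np.sum(before), abs=1e-9)
        assert after[POOL_INDEX["live_wood"]] == 0.0

    def test_hurricane_on_bare_cell_is_noop(self):
        s = np.zeros(N_POOLS)
        after, flows = apply_hurricane_transfer(s)
        assert np.all(after == 0) and sum(f.total() for f in flows) == 0

    def test_harvest_transfers_all_deadwood(self):
        s = np.zeros(N_POOLS)
        s[POOL_INDEX["deadwood"]] = 110.0
        after, flows = apply_deadwood_harvest(s)
        assert after[POOL_INDEX["deadwood"]] == 0.0
        assert flows[0].category == "ManagementRemoval"
        assert flows[0].total() == pytest.approx(110.0)
        assert mass_balance(s, after, flows)


class TestMassBalance:
    def test_detects_perturbed_record(self, species_params):
        p = species_params[AWC]
        before = np.array([p.init_stocks[k] for k in
                           ("live_leaf", "live_wood", "live_root", "leaf_litter",
                            "deadwood", "dead_root", "upper_peat", "deep_peat")])
        after, flows = annual_flows(before, p)
        assert mass_balance(before, after, flows)
        flows[0].amount = flows[0].amount + 1e-3
        assert not mass_balance(before, after, flows)
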