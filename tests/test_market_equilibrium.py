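"""Tests of the elasticity-calibrated partial-equilibrium market model."""

import numpy as np
import pytest
from scipy.integrate import quad

from swinecon import (
    Elasticities,
    LinearCurve,
    MarketObservation,
    calibrate,
    consumer_surplus_change,
    consumer_surplus_level,
    pass_through,
    policy_comparison,
    producer_surplus_change,
    sensitivity_grid,
    shift_supply,
    solve_equilibrium,
)
from swinecon.market_equilibrium import (
    CurveSideError,
    DEMAND,
    GRID_DEMAND,
    GRID_SUPPLY,
    NoEquilibriumError,
    SUPPLY,
)

OBS = MarketObservation()  # Q0 = 9,463.032 Mkg, P0 = 2.2026 $/kg
EL = Elasticities()  # (-1.078, 0.417)


class TestCalibrate:
    def test_curves_pass_through_observation(self):
        demand, supply = calibrate(OBS, EL)
        assert demand.quantity_at(OBS.P0) == pytest.approx(OBS.Q0, rel=1e-12)
        assert supply.quantity_at(OBS.P0) == pytest.approx(OBS.Q0, rel=1e-12)

    def test_published_equation_coefficients(self):
        # printed forms: Qd = 19,664.182 - 0.005P, Qs = 5,518.525 + 0.002P
        # (P per 1,000 tonnes; the supply intercept implies eps_s ~ 0.4168)
        demand, supply = calibrate(OBS, EL)
        assert demand.intercept == pytest.approx(19_664.182, rel=1e-4)
        assert demand.slope / 1e6 == pytest.approx(-0.00463, abs=5e-5)
        assert supply.intercept == pytest.approx(5_518.525, rel=5e-4)

    def test_elasticity_recovered_from_slope(self):
        demand, supply = calibrate(OBS, EL)
        assert demand.slope * OBS.P0 / OBS.Q0 == pytest.approx(EL.epsilon_d, rel=1e-12)
        assert supply.slope * OBS.P0 / OBS.Q0 == pytest.approx(EL.epsilon_s, rel=1e-12)

    def test_sign_invariants_enforced(self):
        with pytest.raises(ValueError):
            Elasticities(epsilon_d=0.5, epsilon_s=0.4)
        with pytest.raises(ValueError):
            LinearCurve(100.0, 1.0, DEMAND)
        with pytest.raises(ValueError):
            MarketObservation(Q0=-1.0, P0=2.2)


class TestShiftSupply:
    def test_published_shifted_intercept(self):
        # printed shifted supply: Q's = 5,764.72 + 0.002P
        _, supply = calibrate(OBS, EL)
        shifted = shift_supply(supply, 0.1375)
        assert shifted.intercept == pytest.approx(5_764.72, rel=5e-4)
        assert shifted.slope == supply.slope

    def test_zero_shift_is_identity(self):
        _, supply = calibrate(OBS, EL)
        assert shift_supply(supply, 0.0) == supply

    def test_shift_composes_linearly(self):
        _, supply = calibrate(OBS, EL)
        twice = shift_supply(shift_supply(supply, 0.1375 / 2), 0.1375 / 2)
        once = shift_supply(supply, 0.1375)
        assert twice.intercept == pytest.approx(once.intercept, rel=1e-12)

    def test_demand_curve_rejected(self):
        demand, _ = calibrate(OBS, EL)
        with pytest.raises(CurveSideError):
            shift_supply(demand, 0.1)


class TestSolveEquilibrium:
    def test_unshifted_recovers_observation(self):
        demand, supply = calibrate(OBS, EL)
        P, Q = solve_equilibrium(demand, supply)
        assert P == pytest.approx(OBS.P0, rel=1e-9)
        assert Q == pytest.approx(OBS.Q0, rel=1e-9)

    def test_curves_agree_on_quantity(self):
        demand, supply = calibrate(OBS, EL)
        shifted = shift_supply(supply, 0.1375)
        P, Q = solve_equilibrium(demand, shifted)
        assert shifted.quantity_at(P) == pytest.approx(Q, rel=1e-9)

    def test_published_price_drop(self):
        demand, supply = calibrate(OBS, EL)
        P1, _ = solve_equilibrium(demand, shift_supply(supply, 0.1375))
        assert OBS.P0 - P1 == pytest.approx(0.038, abs=5e-4)

    def test_price_change_matches_pass_through_oracle(self):
        demand, supply = calibrate(OBS, EL)
        P1, _ = solve_equilibrium(demand, shift_supply(supply, 0.1375))
        assert P1 - OBS.P0 == pytest.approx(-0.1375 * pass_through(EL), rel=1e-9)

    def test_randomized_solver_vs_closed_form(self):
        """1,000 random calibrations: solver == -dC * es/(es+|ed|) to 1e-9."""
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            obs = MarketObservation(
                Q0=rng.uniform(100.0, 50_000.0), P0=rng.uniform(0.5, 10.0)
            )
            el = Elasticities(
                epsilon_d=-rng.uniform(0.05, 5.0), epsilon_s=rng.uniform(0.05, 5.0)
            )
            dC = rng.uniform(0.0, 0.3 * obs.P0)
            demand, supply = calibrate(obs, el)
            P1, _ = solve_equilibrium(demand, shift_supply(supply, dC))
            assert P1 - obs.P0 == pytest.approx(-dC * pass_through(el), rel=1e-9, abs=1e-12)

    def test_no_equilibrium_detected(self):
        demand = LinearCurve(1000.0, -10.0, DEMAND)
        supply = LinearCurve(2000.0, 5.0, SUPPLY)  # supply above demand everywhere
        with pytest.raises(NoEquilibriumError):
            solve_equilibrium(demand, supply)


class TestPassThrough:
    def test_published_elasticities(self):
        assert pass_through(EL) == pytest.approx(0.2789, abs=1e-4)

    def test_symmetric_elasticities_split_evenly(self):
        assert pass_through(Elasticities(-0.7, 0.7)) == pytest.approx(0.5)

    def test_inelastic_supply_bears_everything(self):
        assert pass_through(Elasticities(-1.0, 1e-9)) == pytest.approx(0.0, abs=1e-8)


class TestConsumerSurplus:
    def test_published_change(self):
        c = policy_comparison()
        assert c.delta_CS == pytest.approx(366, rel=0.01)

    def test_zero_price_change(self):
        assert consumer_surplus_change(0.0, 9000.0, 9000.0) == 0.0

    def test_trapezoid_equals_quadrature_of_demand(self):
        demand, supply = calibrate(OBS, EL)
        P1, Q1 = solve_equilibrium(demand, shift_supply(supply, 0.1375))
        trapezoid = consumer_surplus_change(P1 - OBS.P0, OBS.Q0, Q1)
        integral, _ = quad(demand.quantity_at, P1, OBS.P0)
        assert trapezoid == pytest.approx(integral, rel=1e-6)

    def test_published_level(self):
        demand, _ = calibrate(OBS, EL)
        level = consumer_surplus_level(demand, OBS.P0, OBS.Q0)
        assert level == pytest.approx(9_668, rel=5e-3)

    def test_zero_quantity_level(self):
        demand, _ = calibrate(OBS, EL)
        assert consumer_surplus_level(demand, OBS.P0, 0.0) == 0.0

    def test_price_at_choke_rejected(self):
        demand, _ = calibrate(OBS, EL)
        with pytest.raises(ValueError):
            consumer_surplus_level(demand, demand.choke_price + 0.1, 100.0)

    def test_level_difference_equals_change(self):
        c = policy_comparison()
        assert c.CS1 - c.CS0 == pytest.approx(c.delta_CS, rel=1e-6)


class TestProducerSurplus:
    def test_published_change(self):
        c = policy_comparison()
        assert c.delta_PS == pytest.approx(1_311, rel=0.01)

    def test_identical_regimes_zero(self):
        assert producer_surplus_change(2.2, 9463.0, 0.2, 2.2, 9463.0, 0.2) == 0.0

    def test_total_welfare(self):
        c = policy_comparison()
        assert c.delta_W == pytest.approx(1_677, rel=0.01)
        assert c.delta_W == c.delta_CS + c.delta_PS  # exact additivity


class TestPolicyComparison:
    def test_published_quantity_rise(self):
        c = policy_comparison()
        assert c.delta_Q == pytest.approx(177.5, rel=5e-3)

    def test_published_revenue_rise(self):
        c = policy_comparison()
        assert c.revenue1 - c.revenue0 == pytest.approx(21.5, rel=0.02)

    def test_zero_cost_shift_is_identity(self):
        c = policy_comparison(delta_C=0.0)
        for attr in ("delta_P", "delta_Q", "delta_CS", "delta_PS", "delta_W"):
            assert getattr(c, attr) == pytest.approx(0.0, abs=1e-9)
        assert c.P1 == pytest.approx(c.P0, rel=1e-12)

    def test_signs_under_positive_shift(self):
        c = policy_comparison()
        assert c.delta_P < 0 < c.delta_Q


class TestSensitivityGrid:
    def test_grid_extremes(self):
        s = sensitivity_grid().summary()
        assert s["delta_W_min"] / 1e3 == pytest.approx(1.4795, rel=5e-3)
        assert s["delta_W_max"] / 1e3 == pytest.approx(1.9187, rel=5e-3)
        assert s["delta_PS_min"] / 1e3 == pytest.approx(0.9233, rel=5e-3)
        assert s["delta_CS_min"] / 1e3 == pytest.approx(0.0887, rel=5e-3)

    def test_single_cell_grid_equals_policy_comparison(self):
        g = sensitivity_grid(
            demand_elasticities=[EL.epsilon_d], supply_elasticities=[EL.epsilon_s]
        )
        assert g.cells[(EL.epsilon_d, EL.epsilon_s)] == policy_comparison()

    def test_price_drop_monotone_in_elasticities(self):
        g = sensitivity_grid()
        for ed in GRID_DEMAND:
            drops = [abs(g.cells[(ed, es)].delta_P) for es in sorted(GRID_SUPPLY)]
            assert drops == sorted(drops)  # |dP| increases in eps_s
        for es in GRID_SUPPLY:
            drops = [
                abs(g.cells[(ed, es)].delta_P)
                for ed in sorted(GRID_DEMAND, key=abs)
            ]
            assert drops == sorted(drops, reverse=True)  # decreases in |eps_d|

    def test_cs_change_monotone_in_supply_elasticity(self):
        g = sensitivity_grid()
        for ed in GRID_DEMAND:
            cs = [g.cells[(ed, es)].delta_CS for es in sorted(GRID_SUPPLY)]
            assert cs == sorted(cs)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            sensitivity_grid(demand_elasticities=[], supply_elasticities=[0.2])


def test_printed_form_uses_per_1000_tonne_units():
    demand, _ = calibrate(OBS, EL)
    text = demand.printed_form()
    assert text.startswith("Q_d = 19,664.18")
    assert "- 0.005P" in text
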