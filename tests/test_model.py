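"""Rubisco-limited demand, supply chain and the intersection solvers."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mesocon import (ConductancePair, InfeasibleSupplyError, KineticConstants,
                     PhotoParams, rubisco_limited_assimilation,
                     solve_assimilation, solve_assimilation_bisect,
                     supply_chain_cc, supply_chain_ci)


class TestDemand:
    def test_zero_at_compensation_point(self, params):
        assert rubisco_limited_assimilation(params.gamma_star, params) == 0.0

    def test_hand_evaluated_value(self, params):
        # (100 * (300-35)) / (300 + 404.9*(1+210/278.4))
        assert rubisco_limited_assimilation(300.0, params) == pytest.approx(
            26.2293, abs=1e-4)

    def test_linear_in_vcmax(self, params):
        doubled = params.with_(Vcmax=2 * params.Vcmax)
        assert rubisco_limited_assimilation(250.0, doubled) == pytest.approx(
            2 * rubisco_limited_assimilation(250.0, params), rel=1e-12)

    def test_negative_below_gamma_star(self, params):
        assert rubisco_limited_assimilation(20.0, params) < 0

    def test_rejects_nonpositive_co2(self, params):
        with pytest.raises(ValueError):
            rubisco_limited_assimilation(0.0, params)

    def test_kinetic_constants_validated(self):
        with pytest.raises(ValueError):
            KineticConstants(Kc=-1.0)


class TestSupplyChain:
    def test_no_flux_no_drawdown(self):
        assert supply_chain_ci(0.0, 380.0, 0.25) == 380.0

    def test_arithmetic(self):
        assert supply_chain_ci(20.0, 380.0, 0.25) == pytest.approx(300.0)
        cc, ok = supply_chain_cc(20.0, 300.0, 0.4)
        assert cc == pytest.approx(250.0) and ok

    def test_respiration_raises_ci_above_ambient(self):
        assert supply_chain_ci(-2.0, 380.0, 0.25) > 380.0

    def test_infeasible_drawdown_flagged_not_clipped(self):
        cc, ok = supply_chain_cc(20.0, 40.0, 0.4)
        assert cc == pytest.approx(-10.0) and not ok

    def test_zero_conductance_with_flux(self):
        with pytest.raises(InfeasibleSupplyError):
            supply_chain_ci(5.0, 380.0, 0.0)


class TestSolver:
    def test_infinite_conductances_equal_closed_form(self, params):
        sol = solve_assimilation(380.0,
                                 ConductancePair(math.inf, math.inf), params)
        assert sol.A == rubisco_limited_assimilation(380.0, params)
        assert sol.Ci == 380.0 and sol.Cc == 380.0

    def test_finite_gs_matches_bisection(self, params):
        pair = ConductancePair(0.25 * 1.6, math.inf)  # gs_co2 = 0.25
        sol = solve_assimilation(380.0, pair, params)
        oracle = solve_assimilation_bisect(380.0, pair, params)
        assert sol.A == pytest.approx(oracle.A, rel=1e-9)

    def test_conservation_through_resistor_chain(self, params):
        pair = ConductancePair(0.45, 0.4)
        sol = solve_assimilation(380.0, pair, params)
        assert sol.A == pytest.approx(pair.gs_co2 * (380.0 - sol.Ci),
                                      rel=1e-9)
        assert sol.A == pytest.approx(pair.gm_co2 * (sol.Ci - sol.Cc),
                                      rel=1e-9)

    def test_halving_gm_decreases_assimilation(self, params):
        a_full = solve_assimilation(380.0, ConductancePair(0.45, 0.4),
                                    params).A
        a_half = solve_assimilation(380.0, ConductancePair(0.45, 0.2),
                                    params).A
        assert a_half < a_full

    @given(gs=st.floats(0.05, 1.0), gm=st.floats(0.02, 1.0),
           vcmax=st.floats(20.0, 150.0), ca=st.floats(100.0, 1500.0))
    def test_quadratic_agrees_with_bisection_oracle(self, gs, gm, vcmax, ca):
        params = PhotoParams(gamma_star=35.0, Rd=2.0, Vcmax=vcmax)
        pair = ConductancePair(gs, gm)
        sol = solve_assimilation(ca, pair, params)
        oracle = solve_assimilation_bisect(ca, pair, params)
        assert sol.A == pytest.approx(oracle.A, rel=1e-9, abs=1e-9)

    @given(gs=st.floats(0.05, 1.0), gm=st.floats(0.02, 1.0),
           vcmax=st.floats(20.0, 150.0))
    def test_monotone_in_each_driver(self, gs, gm, vcmax):
        params = PhotoParams(gamma_star=35.0, Rd=2.0, Vcmax=vcmax)
        base = solve_assimilation(380.0, ConductancePair(gs, gm), params).A
        eps = 1.01
        assert solve_assimilation(380.0, ConductancePair(gs * eps, gm),
                                  params).A >= base
        assert solve_assimilation(380.0, ConductancePair(gs, gm * eps),
                                  params).A >= base
        assert solve_assimilation(380.0, ConductancePair(gs, gm),
                                  params.with_(Vcmax=vcmax * eps)).A >= base
        assert solve_assimilation(380.0 * eps, ConductancePair(gs, gm),
                                  params).A >= base

    def test_requires_ca_above_gamma_star(self, params):
        with pytest.raises(ValueError):
            solve_assimilation(30.0, ConductancePair(0.4, 0.4), params)

    def test_zero_total_conductance_infeasible(self, params):
        with pytest.raises(InfeasibleSupplyError):
            solve_assimilation(380.0, ConductancePair(0.0, 0.4), params)


def test_conductance_pair_basis_conversion():
    pair = ConductancePair(gs_h2o=0.48, gm_co2=0.4)
    assert pair.gs_co2 == pytest.approx(0.3)
    assert pair.total_co2 == pytest.approx(1 / (1 / 0.3 + 1 / 0.4))
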