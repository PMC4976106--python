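"""Variable-J mesophyll conductance estimation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from mesocon import ConductancePair, PhotoParams, solve_assimilation
from mesocon.mesophyll import (CEILING, J_DEFICIT, EmptyResponseError,
                               VariableJEstimator, fit_leak, gm_ci_response,
                               harley_gm, harley_gm_day, harley_gm_table)
from mesocon.simulate import (DroughtCampaignConfig, electron_transport_truth,
                              gm_ci_template, simulate_gm_ci_curve)


class TestHarleyPoint:
    def test_hand_arithmetic(self, params):
        # bracket (150+176)/(150-88) = 326/62; 250 - 35*bracket = 65.97...
        est = harley_gm(20.0, 250.0, 150.0, params)
        assert est.valid
        assert est.gm == pytest.approx(0.3032, abs=2e-4)
        assert est.Cc == pytest.approx(250.0 - 20.0 / est.gm, rel=1e-12)

    def test_zero_flux_limit(self):
        p = PhotoParams(gamma_star=35.0, Rd=0.0, Vcmax=100.0)
        est = harley_gm(0.0, 250.0, 150.0, p)
        assert est.gm == 0.0 and est.valid

    def test_singular_denominator_flagged(self, params):
        est = harley_gm(20.0, 250.0, 4 * 22.0, params)
        assert not est.valid and est.reason == J_DEFICIT

    def test_ceiling_flagged(self, params):
        # drawdown barely positive -> absurdly large gm
        jf = 150.0
        bracket = (jf + 8 * 22.0) / (jf - 4 * 22.0)
        ci = params.gamma_star * bracket + 0.01
        est = harley_gm(20.0, ci, jf, params)
        assert not est.valid and est.reason == CEILING

    def test_flux_identity_for_valid_estimates(self, params):
        est = harley_gm(18.0, 280.0, 160.0, params)
        assert est.valid
        assert est.gm * (280.0 - est.Cc) == pytest.approx(18.0, rel=1e-12)

    @given(gs=st.floats(0.1, 0.6), gm=st.floats(0.03, 0.8),
           vcmax=st.floats(30.0, 120.0))
    def test_forward_inverse_consistency(self, gs, gm, vcmax):
        """Observations generated by the forward model invert to the
        generating gm to 1e-6 relative without noise."""
        p = PhotoParams(gamma_star=35.0, Rd=2.1, Vcmax=vcmax)
        sol = solve_assimilation(380.0, ConductancePair(gs, gm), p)
        jf = electron_transport_truth(sol.A, sol.Cc, p)
        est = harley_gm(sol.A, sol.Ci, jf, p)
        assert est.valid
        assert est.gm == pytest.approx(gm, rel=1e-6)


class TestDayEstimator:
    def test_jackknife_is_identity_on_constant_readings(self, params):
        a = np.full(4, 20.0)
        ci = np.full(4, 250.0)
        jf = np.full(4, 150.0)
        plain = harley_gm_day(a, ci, jf, params, jackknife=False)
        jack = harley_gm_day(a, ci, jf, params, jackknife=True)
        assert jack.gm == pytest.approx(plain.gm, rel=1e-12)

    def test_jackknife_reduces_nonlinearity_bias(self, params, rng):
        # high-gm state: small drawdown, strong inversion convexity
        gm_true, gs = 0.73, 0.50
        p = params.with_(Vcmax=108.0)
        sol = solve_assimilation(380.0, ConductancePair(gs, gm_true), p)
        jf = electron_transport_truth(sol.A, sol.Cc, p)
        plain_est, jack_est = [], []
        for _ in range(800):
            a = sol.A + rng.normal(0, 0.3, 4)
            ci = 380.0 - a / (gs / 1.6)
            jfs = jf + rng.normal(0, 2.0, 4)
            plain = harley_gm_day(a, ci, jfs, p, jackknife=False)
            jack = harley_gm_day(a, ci, jfs, p, jackknife=True)
            if plain.valid and jack.valid:
                plain_est.append(plain.gm)
                jack_est.append(jack.gm)
        bias_plain = abs(np.mean(plain_est) - gm_true)
        bias_jack = abs(np.mean(jack_est) - gm_true)
        assert bias_jack < bias_plain


class TestGmCiResponse:
    def test_constant_gm_gives_flat_response(self, params):
        gm_true, gs = 0.3, 0.45
        rows = []
        for ca in (100, 200, 300, 380, 500, 700, 1000):
            sol = solve_assimilation(float(ca),
                                     ConductancePair(gs, gm_true), params)
            rows.append({"Ca": ca, "Ci": sol.Ci, "A": sol.A,
                         "Jf": electron_transport_truth(sol.A, sol.Cc,
                                                        params)})
        table, summary = gm_ci_response(pd.DataFrame(rows), params)
        valid = table[table["valid"]]
        assert np.allclose(valid["gm"], gm_true, rtol=1e-9)
        assert summary.fold_drop == pytest.approx(1.0, rel=1e-9)

    def test_three_phase_template_recovery(self, params):
        """Peak location recovered within one setpoint spacing and the
        peak-to-plateau fold drop matches the generating ~16x template."""
        curve = simulate_gm_ci_curve(params, gs_h2o=0.45, gm_peak=0.5)
        table, summary = gm_ci_response(curve, params)
        valid = table[table["valid"]]
        truth_peak_ci = float(
            valid["Ci"][np.argmax(gm_ci_template(valid["Ci"].to_numpy(),
                                                 0.5))])
        spacing = np.diff(np.sort(valid["Ci"])).max()
        assert abs(summary.ci_at_peak - truth_peak_ci) <= spacing
        assert 200.0 <= summary.ci_at_peak <= 400.0
        truth_fold = (gm_ci_template(truth_peak_ci, 0.5)
                      / gm_ci_template(valid["Ci"].max(), 0.5))
        assert summary.fold_drop == pytest.approx(truth_fold, rel=0.15)

    def test_all_invalid_curve_raises(self, params):
        bad = pd.DataFrame({"Ca": [380.0], "Ci": [250.0], "A": [20.0],
                            "Jf": [50.0]})  # deep J deficit
        with pytest.raises(EmptyResponseError):
            gm_ci_response(bad, params)


def test_monotone_degradation_with_noise(params, rng):
    """Median |gm error| strictly increases with the A-channel noise."""
    gm_true, gs = 0.16, 0.37
    sol = solve_assimilation(380.0, ConductancePair(gs, gm_true), params)
    jf = electron_transport_truth(sol.A, sol.Cc, params)
    medians = []
    for sigma in (0.1, 0.4, 1.0):
        errors = []
        for _ in range(500):
            a = sol.A + rng.normal(0, sigma)
            ci = 380.0 - a / (gs / 1.6)
            est = harley_gm(a, ci, jf, params)
            if est.valid:
                errors.append(abs(est.gm - gm_true))
        medians.append(np.median(errors))
    assert medians[0] < medians[1] < medians[2]


def test_leak_fit_recovers_generating_line():
    ca = np.array([50.0, 200.0, 380.0, 700.0, 1200.0])
    records = pd.DataFrame({"Ca": ca, "A": 0.2 + 0.0003 * ca})
    leak = fit_leak(records)
    assert leak.k0 == pytest.approx(0.2, abs=1e-12)
    assert leak.k1 == pytest.approx(0.0003, abs=1e-15)
    assert np.allclose(leak.apply(records["A"], ca), 0.0, atol=1e-12)


def test_transformer_appends_columns(params):
    records = pd.DataFrame({"A": [20.0], "Ci": [250.0], "Jf": [150.0]})
    out = VariableJEstimator(params=params).fit_transform(records)
    assert {"gm", "Cc", "valid", "reason"} <= set(out.columns)
    assert out.loc[0, "valid"]
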