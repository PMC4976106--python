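"""Closed-form Vcmax estimation on the A/Ci initial slope."""

import numpy as np
import pytest
from scipy.optimize import brentq, curve_fit

from mesocon import PhotoParams
from mesocon.aci import InsufficientDataError, VcmaxRegression, fit_vcmax


def demand_points(params, vcmax=100.0, n=6, lo=60.0, hi=280.0):
    ci = np.linspace(lo, hi, n)
    f = (ci - params.gamma_star) / (ci + params.kinetics.effective_km)
    return ci, vcmax * f


class TestClosedForm:
    def test_noiseless_recovery_is_exact(self, params):
        ci, a = demand_points(params)
        fit = fit_vcmax(ci, a, params, use_rd=False)
        assert fit.vcmax == pytest.approx(100.0, rel=1e-12)
        assert fit.rss == pytest.approx(0.0, abs=1e-18)

    def test_matches_iterative_least_squares(self, params):
        """Independent oracles: curve_fit (noiseless, converges exactly)
        and iterative root-finding on the least-squares gradient (noisy —
        the objective itself is too flat near the optimum for value-based
        iteration to resolve 1e-10)."""
        km = params.kinetics.effective_km

        def model(c, v):
            return v * (c - params.gamma_star) / (c + km)

        ci, a_clean = demand_points(params)
        popt, _ = curve_fit(model, ci, a_clean, p0=[50.0])
        assert fit_vcmax(ci, a_clean, params,
                         use_rd=False).vcmax == pytest.approx(popt[0],
                                                              rel=1e-10)

        local = np.random.default_rng(8)
        f = (ci - params.gamma_star) / (ci + km)
        for _ in range(10):
            a = a_clean + local.normal(0, 0.5, a_clean.size)
            root = brentq(lambda v: float(np.sum(f * (v * f - a))),
                          10.0, 300.0, xtol=1e-13, rtol=8.9e-16)
            assert fit_vcmax(ci, a, params,
                             use_rd=False).vcmax == pytest.approx(root,
                                                                  rel=1e-10)

    def test_invariant_to_point_duplication(self, params, rng):
        ci, a = demand_points(params)
        a = a + rng.normal(0, 0.5, a.size)
        single = fit_vcmax(ci, a, params)
        doubled = fit_vcmax(np.tile(ci, 2), np.tile(a, 2), params)
        assert doubled.vcmax == pytest.approx(single.vcmax, rel=1e-12)

    def test_monte_carlo_bias_below_one_percent(self, params, rng):
        estimates = []
        ci, a_true = demand_points(params)
        for _ in range(1000):
            a = a_true + rng.normal(0, 0.5, a_true.size)
            estimates.append(fit_vcmax(ci, a, params, use_rd=False).vcmax)
        assert abs(np.mean(estimates) - 100.0) < 1.0

    def test_insufficient_points_rejected(self, params):
        with pytest.raises(InsufficientDataError):
            fit_vcmax([100.0, 150.0], [5.0, 8.0], params)

    def test_points_below_gamma_star_excluded(self, params):
        ci, a = demand_points(params)
        ci = np.append(ci, 20.0)  # below the compensation point
        a = np.append(a, -3.0)
        fit = fit_vcmax(ci, a, params, use_rd=False)
        assert fit.vcmax == pytest.approx(100.0, rel=1e-12)
        assert fit.n_points == 6

    def test_estimator_interface_roundtrip(self, params):
        ci, a = demand_points(params)
        reg = VcmaxRegression(params=params, use_rd=False).fit(ci, a)
        assert np.allclose(reg.predict(ci), a, rtol=1e-12)
        assert set(reg.get_params()) == {"params", "ci_ceiling", "use_rd",
                                         "basis"}


class TestCampaignMagnitudes:
    def test_well_watered_estimates_in_healthy_wheat_band(
            self, noisy_campaign):
        """Ci-basis fits on well-watered synthetic curves land in the
        88-108 umol m-2 s-1 range reported for healthy wheat."""
        from mesocon.pipeline import PipelineOptions, run_pipeline
        res = run_pipeline(noisy_campaign.records, PipelineOptions())
        ww_days = res.day_table[res.day_table["stress_class"] == "WW"]
        merged = res.vcmax_table.merge(ww_days[["genotype", "day"]],
                                       on=["genotype", "day"])
        mean_ww = merged["vcmax"].mean()
        assert 80.0 <= mean_ww <= 110.0

    def test_drought_template_reproduces_2p5_fold_decline(
            self, noiseless_result, noiseless_campaign):
        """Fitted WW:SS ratio matches the ~2.5-fold carboxylation decline
        of the drought template (chloroplast-basis fits, noiseless)."""
        truth = noiseless_campaign.truth
        rwc = truth[truth["protocol_tag"] == "aci"].groupby(
            ["genotype", "day"])["rwc_true"].first().reset_index()
        vc = noiseless_result.vcmax_table.merge(rwc, on=["genotype", "day"])
        ww = vc[vc["rwc_true"] >= 85.0]["vcmax"].mean()
        ss = vc[vc["rwc_true"] <= 55.0]["vcmax"].mean()
        assert ww / ss == pytest.approx(2.5, rel=0.15)
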