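"""RWC, stress classes, WUEi, summaries and empirical regressions."""

import numpy as np
import pandas as pd
import pytest

from mesocon.water import (EmpiricalRegression, LeafWaterSample, StressClass,
                           classify, cv_from_summary, fit_empirical,
                           fold_change, group_summary, rwc, wue_intrinsic)


class TestRWC:
    def test_full_turgor(self):
        assert rwc(LeafWaterSample(FW=0.36, TW=0.36, DW=0.06)) == 100.0

    def test_boundary_sample_assigned_to_wetter_class(self):
        value = rwc(LeafWaterSample(FW=0.30, TW=0.36, DW=0.06))
        assert value == pytest.approx(80.0)
        assert classify(value) is StressClass.WW
        assert classify(60.0) is StressClass.MS

    def test_dry_sample_out_of_range(self):
        value = rwc(LeafWaterSample(FW=0.06, TW=0.36, DW=0.06))
        assert value == 0.0
        assert classify(value) is StressClass.OUT_OF_RANGE

    def test_class_intervals(self):
        assert classify(92.0) is StressClass.WW
        assert classify(70.0) is StressClass.MS
        assert classify(45.0) is StressClass.SS
        assert classify(39.9) is StressClass.OUT_OF_RANGE

    def test_mass_ordering_enforced(self):
        with pytest.raises(ValueError):
            LeafWaterSample(FW=0.5, TW=0.4, DW=0.06)


class TestWUE:
    def test_values(self):
        assert wue_intrinsic(0.0, 0.5) == 0.0
        assert wue_intrinsic(28.64, 0.50) == pytest.approx(57.28)

    def test_ratio_homogeneity(self):
        assert wue_intrinsic(2 * 28.64, 2 * 0.50) == pytest.approx(
            wue_intrinsic(28.64, 0.50))

    def test_requires_open_stomata(self):
        with pytest.raises(ValueError):
            wue_intrinsic(10.0, 0.0)


class TestSummaries:
    def test_printed_summary_cells_recompute(self):
        # internally consistent dispersion/mean cells of the reference
        # campaign's pooled class table
        assert round(cv_from_summary(27.26, 1.93), 2) == 0.07
        assert round(cv_from_summary(17.22, 3.10), 2) == 0.18
        assert round(cv_from_summary(0.49, 0.19), 2) == 0.39
        assert fold_change(0.49, 0.14) == pytest.approx(3.5, abs=0.001)

    def test_constant_group(self):
        records = pd.DataFrame({"stress_class": ["WW"] * 4,
                                "x": [5.0] * 4})
        out = group_summary(records, ["x"])
        assert out.loc[0, "cv"] == 0.0
        assert fold_change(out.loc[0, "mean"], out.loc[0, "mean"]) == 1.0

    def test_sparse_cells_reported_missing(self):
        records = pd.DataFrame({"stress_class": ["WW", "WW", "SS"],
                                "x": [1.0, 2.0, 3.0]})
        out = group_summary(records, ["x"]).set_index("stress_class")
        assert np.isnan(out.loc["SS", "mean"])
        assert out.loc["SS", "n"] == 1

    def test_se_basis_option(self):
        records = pd.DataFrame({"stress_class": ["WW"] * 4,
                                "x": [1.0, 2.0, 3.0, 4.0]})
        sd = group_summary(records, ["x"], cv_basis="sd").loc[0, "dispersion"]
        se = group_summary(records, ["x"], cv_basis="se").loc[0, "dispersion"]
        assert se == pytest.approx(sd / 2.0)


class TestEmpiricalFits:
    def test_through_origin_cubic_recovers_generating_coefficients(self):
        gs = np.linspace(0.05, 0.55, 40)
        gm = 0.426 * gs - 2.129 * gs ** 2 + 6.189 * gs ** 3
        reg = fit_empirical(gs, gm, family="polynomial3_through_origin")
        assert np.allclose(reg.coef_, [0.426, -2.129, 6.189], atol=1e-8)
        assert reg.r_squared_ == pytest.approx(1.0, abs=1e-12)

    def test_logarithmic_family_exact(self):
        x = np.linspace(0.5, 5.0, 20)
        reg = fit_empirical(x, np.log(x), family="logarithmic")
        assert reg.r_squared_ == pytest.approx(1.0, abs=1e-12)
        assert reg.coef_[1] == pytest.approx(1.0, abs=1e-10)

    def test_quadratic_prediction_roundtrip(self):
        x = np.linspace(0.0, 10.0, 15)
        y = 1.0 + 0.5 * x - 0.02 * x ** 2
        reg = fit_empirical(x, y, family="polynomial2")
        assert np.allclose(reg.predict(x), y, atol=1e-10)

    def test_noise_strictly_lowers_expected_r_squared(self, rng):
        x = np.linspace(0.05, 0.55, 30)
        y = 0.426 * x + 6.189 * x ** 3
        means = []
        for sigma in (0.005, 0.05):
            r2 = [fit_empirical(x, y + rng.normal(0, sigma, x.size),
                                family="polynomial3_through_origin"
                                ).r_squared_ for _ in range(200)]
            means.append(np.mean(r2))
        assert means[1] < means[0]

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            fit_empirical([1, 2, 3], [1, 2, 3], family="exponential")

    def test_rank_deficient_design_rejected(self):
        with pytest.raises(ValueError):
            fit_empirical([2.0, 2.0, 2.0, 2.0], [1.0, 2.0, 3.0, 4.0],
                          family="polynomial2")
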