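"""The five regression-to-expression transforms and their CI bands.

Expected values are recomputed from the embedded raw input columns and
compared against the tabulated reference columns; ratio columns carry a 0.01
absolute tolerance (the source tables round the baseline to 3 decimals),
response columns a 0.5% relative tolerance.
"""

import numpy as np
import pytest

from commonbase import (
    BaselinePolicy,
    ExtrapolationError,
    ExtrapolationWarning,
    ValidationError,
    case_a_curve,
    case_b_predict,
    case_c_curve,
    case_d_curve,
    case_e_predict,
    choose_baseline,
    ddcq_to_ratio,
    fit_ols,
    example_table,
)


class TestChooseBaseline:
    def test_mean_is_default(self, hormone_fit):
        bl = choose_baseline(hormone_fit)
        assert bl.x0 == pytest.approx(9.85)
        assert bl.policy is BaselinePolicy.MEAN

    def test_max_policy(self, hormone_fit):
        assert choose_baseline(hormone_fit, "max").x0 == 10.9

    def test_min_policy(self, hormone_fit):
        assert choose_baseline(hormone_fit, "min").x0 == 8.7

    def test_custom_inside_range(self, hormone_fit):
        assert choose_baseline(hormone_fit, "custom", custom_value=9.0).x0 == 9.0

    def test_custom_outside_range_is_extrapolation(self, hormone_fit):
        with pytest.raises(ExtrapolationError, match="range"):
            choose_baseline(hormone_fit, "custom", custom_value=100.0)

    def test_raw_scale_override_for_log_fits(self, density_fit):
        t = example_table(6)
        bl = choose_baseline(density_fit, x_values=t["cells_per_nl"])
        assert bl.x0 == pytest.approx(139.8, abs=0.005)


class TestCaseA:
    def test_tabulated_ratio_at_offset_x(self, hormone_fit):
        bl = choose_baseline(hormone_fit)
        curve = case_a_curve(hormone_fit, bl, [8.85])
        assert curve.r_hat[0] == pytest.approx(0.73, abs=0.005)
        assert curve.ci_low[0] == pytest.approx(0.69, abs=0.005)
        assert curve.ci_high[0] == pytest.approx(0.76, abs=0.005)

    @pytest.mark.parametrize(
        "x, r, lo, hi",
        [(8.7, 0.692, 0.651, 0.734), (9.9, 1.016, 1.014, 1.019), (10.9, 1.399, 1.327, 1.479)],
    )
    def test_tabulated_curve_rows(self, hormone_fit, x, r, lo, hi):
        bl = choose_baseline(hormone_fit)
        curve = case_a_curve(hormone_fit, bl, [x])
        assert curve.r_hat[0] == pytest.approx(r, abs=0.01)
        assert curve.ci_low[0] == pytest.approx(lo, abs=0.01)
        assert curve.ci_high[0] == pytest.approx(hi, abs=0.01)

    @pytest.mark.parametrize(
        "x, r, lo, hi", [(8.7, 0.495, 0.440, 0.553), (10.9, 1.0, 1.0, 1.0)]
    )
    def test_max_baseline_curve_rows(self, hormone_fit, x, r, lo, hi):
        bl = choose_baseline(hormone_fit, "max")
        curve = case_a_curve(hormone_fit, bl, [x])
        assert curve.r_hat[0] == pytest.approx(r, abs=0.01)
        assert curve.ci_low[0] == pytest.approx(lo, abs=0.01)
        assert curve.ci_high[0] == pytest.approx(hi, abs=0.01)

    def test_extrapolation_refused_then_warned(self, hormone_fit):
        bl = choose_baseline(hormone_fit)
        with pytest.raises(ExtrapolationError):
            case_a_curve(hormone_fit, bl, [12.0])
        with pytest.warns(ExtrapolationWarning):
            case_a_curve(hormone_fit, bl, [12.0], allow_extrapolation=True)

    def test_transform_consistency_with_ratio_helper(self, hormone_fit):
        bl = choose_baseline(hormone_fit)
        xs = np.linspace(8.7, 10.9, 9)
        curve = case_a_curve(hormone_fit, bl, xs)
        direct = [float(ddcq_to_ratio(hormone_fit.m * (x - bl.x0))) for x in xs]
        np.testing.assert_allclose(curve.r_hat, direct, rtol=0, atol=1e-15)

    def test_baseline_shift_rescales_by_constant(self, hormone_fit):
        xs = np.linspace(8.7, 10.9, 7)
        c_mean = case_a_curve(hormone_fit, choose_baseline(hormone_fit), xs)
        c_max = case_a_curve(hormone_fit, choose_baseline(hormone_fit, "max"), xs)
        factor = 10.0 ** (hormone_fit.m * (10.9 - 9.85))
        np.testing.assert_allclose(c_max.r_hat, c_mean.r_hat * factor, rtol=1e-12)

    def test_null_as_unity_flattens_point_estimate(self):
        rng = np.random.default_rng(3)
        x = np.linspace(0, 1, 12)
        y = rng.normal(0.5, 0.3, size=12)  # no trend
        fit = fit_ols(x, y)
        bl = choose_baseline(fit)
        curve = case_a_curve(fit, bl, x, null_as_unity=True)
        assert curve.null_slope
        np.testing.assert_array_equal(curve.r_hat, 1.0)
        assert np.all(curve.ci_low <= 1.0) and np.all(curve.ci_high >= 1.0)


class TestCaseB:
    def test_tabulated_huddling_increase(self, huddling_fit):
        bl = choose_baseline(huddling_fit)
        resp = case_b_predict(huddling_fit, bl, [1.5])
        increase_s = (resp.y_hat[0] - resp.y0_hat) * 60.0
        assert increase_s == pytest.approx(73.0, abs=0.5)
        assert (resp.ci_low[0] - resp.y0_hat) * 60.0 == pytest.approx(61.3, abs=0.5)
        assert (resp.ci_high[0] - resp.y0_hat) * 60.0 == pytest.approx(84.6, abs=0.5)

    @pytest.mark.parametrize(
        "ratio, y, lo, hi",
        [(0.666, 8.628, 8.433, 8.823), (1.447, 10.956, 10.778, 11.133)],
    )
    def test_tabulated_response_rows(self, huddling_fit, ratio, y, lo, hi):
        bl = choose_baseline(huddling_fit)
        resp = case_b_predict(huddling_fit, bl, [ratio])
        assert resp.y_hat[0] == pytest.approx(y, abs=0.01)
        assert resp.ci_low[0] == pytest.approx(lo, abs=0.01)
        assert resp.ci_high[0] == pytest.approx(hi, abs=0.01)

    def test_unit_ratio_predicts_baseline_response(self, huddling_fit):
        bl = choose_baseline(huddling_fit)
        resp = case_b_predict(huddling_fit, bl, [1.0])
        assert resp.y_hat[0] == resp.y0_hat
        assert resp.ci_low[0] == resp.ci_high[0] == resp.y0_hat

    def test_nonpositive_ratio_rejected(self, huddling_fit):
        bl = choose_baseline(huddling_fit)
        with pytest.raises(ValidationError):
            case_b_predict(huddling_fit, bl, [0.0])

    def test_axis_swap_identity(self, hormone_fit, huddling_fit):
        # The huddling dataset is the hormone dataset with axes swapped,
        # so the OLS identity m_xy * m_yx = r2 ties the two slopes together.
        assert hormone_fit.m * huddling_fit.m == pytest.approx(
            hormone_fit.r2, abs=1e-3
        )


class TestCaseC:
    def test_tabulated_gene_b_ratio(self, gene_gene_fit):
        bl = choose_baseline(gene_gene_fit)
        curve = case_c_curve(gene_gene_fit, bl, [1.1])
        assert gene_gene_fit.m == pytest.approx(0.367, abs=1e-3)
        assert curve.r_hat[0] == pytest.approx(1.036, abs=0.002)
        assert curve.ci_low[0] == pytest.approx(1.027, abs=0.002)
        assert curve.ci_high[0] == pytest.approx(1.044, abs=0.002)

    @pytest.mark.parametrize(
        "ra, rb, lo, hi",
        [(0.666, 0.861, 0.831, 0.893), (1.447, 1.145, 1.108, 1.184)],
    )
    def test_tabulated_curve_rows(self, gene_gene_fit, ra, rb, lo, hi):
        bl = choose_baseline(gene_gene_fit)
        curve = case_c_curve(gene_gene_fit, bl, [ra])
        assert curve.r_hat[0] == pytest.approx(rb, abs=0.01)
        assert curve.ci_low[0] == pytest.approx(lo, abs=0.01)
        assert curve.ci_high[0] == pytest.approx(hi, abs=0.01)

    def test_identity_power_under_unit_slope(self):
        x = np.linspace(0.2, 0.8, 6)
        fit = fit_ols(x, x)  # gene regressed on itself, noise-free
        bl = choose_baseline(fit)
        ratios = np.array([0.5, 0.9, 1.0, 1.3, 2.0])
        curve = case_c_curve(fit, bl, ratios)
        np.testing.assert_allclose(curve.r_hat, ratios, rtol=1e-12)

    def test_composition_with_case_a(self, gene_gene_fit):
        # Case C is case A with the input axis mapped through R_A -> ddCq_A.
        bl = choose_baseline(gene_gene_fit)
        ras = np.array([0.7, 0.9, 1.0, 1.2, 1.4])
        via_c = case_c_curve(gene_gene_fit, bl, ras)
        xs = bl.x0 - np.log10(ras)  # invert R_A = 10**(x0 - x)
        via_a = case_a_curve(gene_gene_fit, bl, xs, allow_extrapolation=True)
        np.testing.assert_allclose(via_c.r_hat, via_a.r_hat, rtol=1e-12)
        np.testing.assert_allclose(via_c.ci_low, via_a.ci_low, rtol=1e-12)


class TestCaseD:
    def fit_and_baseline(self):
        t = example_table(6)
        fit = fit_ols(np.log10(t["cells_per_nl"]), t["delta_cq_w"])
        bl = choose_baseline(fit, x_values=t["cells_per_nl"])
        return fit, bl

    def test_tabulated_ratio_at_low_density(self):
        fit, bl = self.fit_and_baseline()
        assert fit.m == pytest.approx(-0.116, abs=1e-3)
        assert fit.ci_low == pytest.approx(-0.123, abs=1e-3)
        assert fit.ci_high == pytest.approx(-0.109, abs=1e-3)
        curve = case_d_curve(fit, bl, [70.0])
        assert curve.r_hat[0] == pytest.approx(0.923, abs=0.003)

    @pytest.mark.parametrize(
        "x, r, lo, hi",
        [(385.61, 1.125, 1.117, 1.133), (23.12, 0.812, 0.801, 0.822)],
    )
    def test_tabulated_curve_rows(self, x, r, lo, hi):
        fit, bl = self.fit_and_baseline()
        curve = case_d_curve(fit, bl, [x])
        assert curve.r_hat[0] == pytest.approx(r, abs=0.01)
        assert curve.ci_low[0] == pytest.approx(lo, abs=0.01)
        assert curve.ci_high[0] == pytest.approx(hi, abs=0.01)

    def test_unit_ratio_at_baseline(self):
        fit, bl = self.fit_and_baseline()
        curve = case_d_curve(fit, bl, [bl.x0])
        assert curve.r_hat[0] == 1.0
        assert curve.ci_low[0] == curve.ci_high[0] == 1.0

    def test_nonpositive_density_rejected(self):
        fit, bl = self.fit_and_baseline()
        with pytest.raises(ValidationError):
            case_d_curve(fit, bl, [-5.0])


class TestCaseE:
    def fit_and_baseline(self):
        t = example_table(7)
        fit = fit_ols(t["delta_cq_w"], np.log10(t["length_mm"]))
        return fit, choose_baseline(fit)

    def test_tabulated_length_at_higher_expression(self):
        fit, bl = self.fit_and_baseline()
        assert fit.m == pytest.approx(7.878, abs=0.005)
        resp = case_e_predict(fit, bl, [1.1])
        assert resp.y_hat[0] == pytest.approx(14.7, abs=0.1)
        assert resp.ci_low[0] == pytest.approx(14.2, abs=0.1)
        assert resp.ci_high[0] == pytest.approx(15.2, abs=0.1)

    @pytest.mark.parametrize(
        "ratio, y, lo, hi",
        [(1.180, 8.423, 7.931, 8.944), (0.849, 112.724, 106.246, 119.616)],
    )
    def test_tabulated_response_rows(self, ratio, y, lo, hi):
        fit, bl = self.fit_and_baseline()
        resp = case_e_predict(fit, bl, [ratio])
        assert resp.y_hat[0] == pytest.approx(y, rel=5e-3)
        assert resp.ci_low[0] == pytest.approx(lo, rel=5e-3)
        assert resp.ci_high[0] == pytest.approx(hi, rel=5e-3)

    def test_unit_ratio_gives_baseline_length(self):
        fit, bl = self.fit_and_baseline()
        resp = case_e_predict(fit, bl, [1.0])
        assert resp.y_hat[0] == resp.y0_hat
        # Tabulated baseline length, at its printed rounding.
        assert resp.y0_hat == pytest.approx(31.094, rel=2e-3)


class TestBandInvariants:
    def all_curves(self, hormone_fit, huddling_fit, gene_gene_fit):
        t6 = example_table(6)
        fit_d = fit_ols(np.log10(t6["cells_per_nl"]), t6["delta_cq_w"])
        t7 = example_table(7)
        fit_e = fit_ols(t7["delta_cq_w"], np.log10(t7["length_mm"]))
        xs = np.linspace(8.7, 10.9, 11)
        ratios = np.array([0.5, 0.8, 1.0, 1.25, 2.0])
        return [
            case_a_curve(hormone_fit, choose_baseline(hormone_fit), xs),
            case_b_predict(huddling_fit, choose_baseline(huddling_fit), ratios),
            case_c_curve(gene_gene_fit, choose_baseline(gene_gene_fit), ratios),
            case_d_curve(
                fit_d,
                choose_baseline(fit_d, x_values=t6["cells_per_nl"]),
                np.geomspace(23.12, 385.61, 9),
            ),
            case_e_predict(fit_e, choose_baseline(fit_e), ratios),
        ]

    def test_band_ordered_on_both_sides_of_baseline(
        self, hormone_fit, huddling_fit, gene_gene_fit
    ):
        for curve in self.all_curves(hormone_fit, huddling_fit, gene_gene_fit):
            point = curve.r_hat if hasattr(curve, "r_hat") else curve.y_hat
            assert np.all(curve.ci_low <= point + 1e-15)
            assert np.all(point <= curve.ci_high + 1e-15)

    def test_anchored_at_baseline_with_degenerate_band(self, hormone_fit):
        bl = choose_baseline(hormone_fit)
        curve = case_a_curve(hormone_fit, bl, [bl.x0])
        assert curve.r_hat[0] == 1.0
        assert curve.ci_low[0] == curve.ci_high[0] == 1.0

    def test_expression_curves_are_positive(
        self, hormone_fit, huddling_fit, gene_gene_fit
    ):
        for curve in self.all_curves(hormone_fit, huddling_fit, gene_gene_fit):
            if hasattr(curve, "r_hat"):
                assert np.all(curve.r_hat > 0)
                assert np.all(curve.ci_low > 0)
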