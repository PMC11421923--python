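"""Dose–response fits, LD quantiles, breeder's-equation algebra and Monte
Carlo propagation."""

import numpy as np
import pandas as pd
import pytest

from coralherit import (HISTORICAL_LD, LDEstimate, LogisticDoseResponse,
                        dhw_to_degC, fit_logistic_survivorship,
                        generate_survivorship, ld_quantile, mc_propagate,
                        project_response, response_to_selection,
                        selection_coefficient)
from coralherit.selection import SeparationError


def _mcap_lds():
    rec = HISTORICAL_LD["Montipora capitata"]
    return (LDEstimate(p=0.2, ld=rec[1970][0], se=rec[1970][1]),
            LDEstimate(p=0.2, ld=rec[2017][0], se=rec[2017][1]))


class TestLogisticFit:
    def test_symmetric_data_puts_ld50_at_center(self):
        doses = np.array([2.0, 4.0, 6.0, 8.0])
        n = np.full(4, 100)
        dead = np.array([10, 40, 60, 90])  # symmetric around 5
        fit = LogisticDoseResponse().fit(doses, n, dead)
        assert ld_quantile(fit, 0.5).ld == pytest.approx(5.0, abs=1e-6)

    def test_recovers_generating_coefficients_within_3se(self):
        t = generate_survivorship(-3.0, 0.5, np.arange(0, 21, 2), 200, seed=4)
        fit = fit_logistic_survivorship(t)
        se = np.sqrt(np.diag(fit.cov_))
        assert abs(fit.coef_[0] - (-3.0)) < 3 * se[0]
        assert abs(fit.coef_[1] - 0.5) < 3 * se[1]

    def test_agrees_with_statsmodels_glm(self):
        """Independent cross-check against the GLM binomial fit."""
        import statsmodels.api as sm

        t = generate_survivorship(-2.0, 0.3, np.arange(0, 25, 3), 80, seed=9)
        ours = fit_logistic_survivorship(t)
        X = sm.add_constant(t["dhw"].to_numpy())
        glm = sm.GLM(np.column_stack([t["n_dead"],
                                      t["n_exposed"] - t["n_dead"]]),
                     X, family=sm.families.Binomial()).fit()
        assert np.allclose(ours.coef_, glm.params, atol=1e-8)
        assert np.allclose(ours.cov_, glm.cov_params(), rtol=1e-4)

    def test_doubling_counts_keeps_point_halves_variance(self):
        t = generate_survivorship(-1.0, 0.4, np.arange(0, 15, 2), 50, seed=3)
        fit1 = fit_logistic_survivorship(t)
        t2 = t.copy()
        t2["n_exposed"] *= 2
        t2["n_dead"] *= 2
        fit2 = fit_logistic_survivorship(t2)
        assert np.allclose(fit1.coef_, fit2.coef_, atol=1e-9)
        assert np.allclose(fit2.cov_, fit1.cov_ / 2, rtol=1e-6)

    def test_complete_separation_detected(self):
        doses = np.array([0.0, 1.0, 10.0, 11.0])
        n = np.full(4, 50)
        dead = np.array([0, 0, 50, 50])
        with pytest.raises(SeparationError):
            LogisticDoseResponse().fit(doses, n, dead)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="distinct doses"):
            LogisticDoseResponse().fit([1.0, 1.0], [10, 10], [2, 3])
        with pytest.raises(ValueError, match="both outcomes"):
            LogisticDoseResponse().fit([1.0, 2.0], [10, 10], [0, 0])

    def test_dose_shift_and_scale_equivariance(self):
        t = generate_survivorship(-2.5, 0.6, np.arange(0, 12), 100, seed=6)
        base = ld_quantile(fit_logistic_survivorship(t), 0.5)
        shifted = t.copy()
        shifted["dhw"] = shifted["dhw"] + 5.0
        ld_shift = ld_quantile(fit_logistic_survivorship(shifted), 0.5)
        assert ld_shift.ld == pytest.approx(base.ld + 5.0, abs=1e-6)
        scaled = t.copy()
        scaled["dhw"] = scaled["dhw"] * 2.0
        ld_scale = ld_quantile(fit_logistic_survivorship(scaled), 0.5)
        assert ld_scale.ld == pytest.approx(base.ld * 2.0, rel=1e-6)


class TestLDQuantile:
    def test_logit_half_is_zero(self):
        fit = LogisticDoseResponse()
        fit.coef_ = np.array([0.0, 1.0])
        fit.cov_ = np.eye(2) * 0.01
        assert ld_quantile(fit, 0.5).ld == pytest.approx(0.0)

    def test_closed_form_ld20(self):
        fit = LogisticDoseResponse()
        fit.coef_ = np.array([-2.0, 1.0])
        fit.cov_ = np.eye(2) * 0.01
        # (logit(0.2) - (-2))/1 = 2 + ln(0.25)
        assert ld_quantile(fit, 0.2).ld == pytest.approx(2 + np.log(0.25))

    def test_zero_slope_undefined(self):
        fit = LogisticDoseResponse()
        fit.coef_ = np.array([0.5, 0.0])
        fit.cov_ = np.eye(2)
        with pytest.raises(ZeroDivisionError):
            ld_quantile(fit, 0.5)

    def test_delta_method_se_matches_monte_carlo(self):
        """Delta-method LD50 SE vs pushforward of Gaussian coefficient
        draws, within 5% on a realistic fit."""
        t = generate_survivorship(-3.0, 0.5, np.arange(0, 21, 2), 200, seed=4)
        fit = fit_logistic_survivorship(t)
        ld = ld_quantile(fit, 0.5)
        rng = np.random.default_rng(0)
        draws = rng.multivariate_normal(fit.coef_, fit.cov_, size=100_000)
        mc_ld = (np.log(0.5 / 0.5) - draws[:, 0]) / draws[:, 1]
        assert ld.se == pytest.approx(np.std(mc_ld), rel=0.05)


class TestBreedersEquation:
    def test_identical_lds_give_zero_response(self):
        ld = LDEstimate(p=0.5, ld=10.0, se=1.0)
        r = response_to_selection(ld, ld, 1970, 2017)
        assert r.value == 0.0

    def test_mcap_printed_ld20s_give_20dhw_over_50yr(self):
        early, late = _mcap_lds()
        r = response_to_selection(early, late, 1970, 2017, horizon=50)
        assert r.value == pytest.approx(20.07, abs=0.01)

    def test_pacuta_printed_ld50s_give_18p3dhw(self):
        rec = HISTORICAL_LD["Pocillopora acuta"]
        early = LDEstimate(0.5, *rec[1970])
        late = LDEstimate(0.5, *rec[2017])
        r = response_to_selection(early, late, 1970, 2017, horizon=50)
        assert r.value == pytest.approx(18.31, abs=0.01)

    def test_invalid_year_order_rejected(self):
        ld = LDEstimate(p=0.5, ld=10.0, se=1.0)
        with pytest.raises(ValueError):
            response_to_selection(ld, ld, 2017, 1970)

    def test_degenerate_h2_one_returns_s_equals_r(self):
        early, late = _mcap_lds()
        r = response_to_selection(early, late, 1970, 2017)
        s, aux = selection_coefficient(r, (1.0, 0.0), n_draws=5000, seed=1)
        assert np.array_equal(s.draws, aux["R"])

    def test_s_point_arithmetic_with_fixed_h2(self):
        early, late = _mcap_lds()
        r = response_to_selection(early, late, 1970, 2017)
        s, _ = selection_coefficient(r, (0.56, 0.0), n_draws=200_000, seed=2)
        assert s.mean == pytest.approx(r.value / 0.56, abs=0.1)

    def test_identity_r_equals_h2_times_s_per_draw(self):
        early, late = _mcap_lds()
        r = response_to_selection(early, late, 1970, 2017)
        s, aux = selection_coefficient(r, (0.56, 0.08), n_draws=20_000, seed=3)
        np.testing.assert_allclose(aux["h2"] * s.draws, aux["R"],
                                   rtol=1e-14, atol=0)

    def test_round_trip_projection_reproduces_r_draws(self):
        early, late = _mcap_lds()
        r = response_to_selection(early, late, 1970, 2017)
        s, aux = selection_coefficient(r, (0.56, 0.08), n_draws=10_000, seed=4)
        proj = project_response((0.56, 0.08), s, paired_h2=aux["h2"])
        np.testing.assert_allclose(proj.R.draws, aux["R"], rtol=1e-14, atol=0)

    def test_zero_h2_projects_zero_response(self):
        early, late = _mcap_lds()
        r = response_to_selection(early, late, 1970, 2017)
        s, _ = selection_coefficient(r, (0.56, 0.08), n_draws=5000, seed=5)
        proj = project_response((0.0, 0.0), s, seed=6)
        assert proj.R.mean == 0.0
        assert proj.R.ci_upper == 0.0

    def test_projection_interval_widens_with_h2_uncertainty(self):
        early, late = _mcap_lds()
        r = response_to_selection(early, late, 1970, 2017)
        s, _ = selection_coefficient(r, (0.56, 0.08), n_draws=20_000, seed=7)
        widths = []
        for sd in (0.02, 0.06, 0.12):
            proj = project_response((0.4, sd), s, seed=8)
            widths.append(proj.R.ci_upper - proj.R.ci_lower)
        assert widths[0] < widths[1] < widths[2]


class TestMonteCarlo:
    def test_identity_on_standard_normal(self):
        res = mc_propagate(lambda x: x, {"x": (0.0, 1.0)}, n_draws=200_000,
                           seed=0)
        assert res.mean == pytest.approx(0.0, abs=0.01)
        assert res.ci_lower == pytest.approx(-1.96, abs=0.03)
        assert res.ci_upper == pytest.approx(1.96, abs=0.03)

    def test_linear_combination_sd_matches_closed_form(self):
        a, b, sx, sy = 2.0, -3.0, 1.5, 0.5
        res = mc_propagate(lambda x, y: a * x + b * y,
                           {"x": (0.0, sx), "y": (1.0, sy)},
                           n_draws=100_000, seed=1)
        assert res.sd == pytest.approx(np.hypot(a * sx, b * sy), rel=0.02)

    def test_constant_function_zero_width(self):
        res = mc_propagate(lambda x: 0 * x + 7.0, {"x": (0.0, 1.0)},
                           n_draws=1000, seed=2)
        assert res.sd == pytest.approx(0.0, abs=1e-12)
        assert res.ci_lower == res.ci_upper == 7.0

    def test_nonfinite_outputs_abort(self):
        with pytest.raises(RuntimeError, match="non-finite"):
            mc_propagate(lambda x: 1.0 / (x - x), {"x": (0.0, 1.0)},
                         n_draws=1000, seed=3)

    def test_accepts_raw_draw_arrays(self):
        draws = np.random.default_rng(4).normal(5.0, 2.0, 50_000)
        res = mc_propagate(lambda x: x, {"x": draws}, n_draws=50_000, seed=5)
        assert res.mean == pytest.approx(5.0, abs=0.05)


class TestDhwConversion:
    TABLE = [(1.0, 10.0), (2.0, 30.0)]

    def test_linear_midpoint(self):
        degc, flag = dhw_to_degC(20.0, self.TABLE)
        assert degc == pytest.approx(1.5)
        assert flag == "ok"

    def test_out_of_range_flagged_not_extrapolated(self):
        degc, flag = dhw_to_degC(5.0, self.TABLE)
        assert flag == "below_table"
        assert degc == 1.0
        degc, flag = dhw_to_degC(50.0, self.TABLE)
        assert flag == "above_table"
        assert degc == 2.0

    def test_knots_round_trip_exactly(self):
        table = [(1.0, 10.0), (1.4, 18.0), (1.8, 30.0)]
        for degc, dhw in table:
            got, flag = dhw_to_degC(dhw, table)
            assert got == pytest.approx(degc, abs=1e-12)
            assert flag == "ok"

    def test_non_monotone_table_rejected(self):
        with pytest.raises(ValueError, match="monotone"):
            dhw_to_degC(5.0, [(1.0, 10.0), (2.0, 8.0)])
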