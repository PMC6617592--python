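"""%DM, CV, RGR, regression identities and the normalised covariance matrix."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from swardscan import (coefficient_of_variation, growth_series, linear_fit,
                       load_cultivar_regressions, load_cultivar_traits,
                       normalized_covariance, percent_dm,
                       relative_growth_rate)
from swardscan.errors import ParameterError, SingularFitError


class TestPercentDM:
    @pytest.mark.parametrize("fw,dw,expected", [
        (525.00, 154.15, 0.29),   # cultivar 1 of the bundled trial
        (498.39, 141.70, 0.28),   # cultivar 5
        (100.0, 0.0, 0.00),
    ])
    def test_fraction_rounds_to_table_value(self, fw, dw, expected):
        assert round(percent_dm(fw, dw).fraction, 2) == expected

    def test_percent_is_fraction_times_100(self):
        res = percent_dm(400.0, 120.0)
        assert res.percent == pytest.approx(100.0 * res.fraction)
        assert res.fraction == pytest.approx(0.30)

    def test_dw_exceeding_fw_rejected(self):
        with pytest.raises(ParameterError, match="dw_g"):
            percent_dm(100.0, 150.0)

    def test_nonpositive_fw_rejected(self):
        with pytest.raises(ParameterError):
            percent_dm(0.0, 0.0)


class TestCoefficientOfVariation:
    def test_two_point_closed_form(self):
        mean, sd, cv = coefficient_of_variation([1.0, 3.0])
        assert mean == 2.0
        assert sd == pytest.approx(math.sqrt(2.0))
        assert cv == pytest.approx(70.7107, abs=1e-3)

    def test_constant_vector_zero_cv(self):
        assert coefficient_of_variation([5.0] * 6).cv_percent == 0.0

    def test_errors(self):
        with pytest.raises(ParameterError):
            coefficient_of_variation([1.0])
        with pytest.raises(ParameterError, match="zero mean"):
            coefficient_of_variation([-1.0, 1.0])

    @given(st.floats(0.01, 1000.0))
    def test_scale_invariance(self, c):
        base = np.array([3.0, 7.0, 11.0, 4.0])
        assert coefficient_of_variation(c * base).cv_percent == \
            pytest.approx(coefficient_of_variation(base).cv_percent,
                          rel=1e-9)


class TestRelativeGrowthRate:
    def test_no_growth_is_zero(self):
        assert relative_growth_rate(120.0, 120.0, 0.0, 7.0) == 0.0

    def test_log_identity(self):
        assert relative_growth_rate(1.0, math.e, 0.0, 1.0) == \
            pytest.approx(1.0)

    def test_doubling_in_ten_days(self):
        assert relative_growth_rate(100.0, 200.0, 0.0, 10.0) == \
            pytest.approx(math.log(2.0) / 10.0)  # 0.0693

    def test_domain_errors(self):
        with pytest.raises(ParameterError):
            relative_growth_rate(0.0, 10.0, 0.0, 1.0)
        with pytest.raises(ParameterError):
            relative_growth_rate(10.0, 10.0, 5.0, 5.0)

    @given(st.floats(1.0, 500.0), st.floats(1.0, 500.0),
           st.floats(1.0, 500.0), st.floats(0.5, 20.0), st.floats(0.5, 20.0))
    def test_duration_weighted_additivity(self, y1, y2, y3, dt12, dt23):
        """RGR over t1->t3 is the duration-weighted mean of the segments."""
        t1, t2, t3 = 0.0, dt12, dt12 + dt23
        r12 = relative_growth_rate(y1, y2, t1, t2)
        r23 = relative_growth_rate(y2, y3, t2, t3)
        r13 = relative_growth_rate(y1, y3, t1, t3)
        assert r13 == pytest.approx((dt12 * r12 + dt23 * r23) / (t3 - t1),
                                    rel=1e-9, abs=1e-12)


class TestLinearFit:
    def test_exact_line(self):
        x = np.array([0.0, 1.0, 2.0, 5.0])
        fit = linear_fit(x, 2.0 * x + 1.0)
        assert fit.slope == pytest.approx(2.0)
        assert fit.y_intercept == pytest.approx(1.0)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.x_intercept == pytest.approx(-0.5)

    def test_noise_free_recovery_to_machine_precision(self, rng):
        x = rng.uniform(50.0, 150.0, 30)
        fit = linear_fit(x, 251_687.0 * x - 24_786_555.0)
        assert fit.slope == pytest.approx(251_687.0, rel=1e-12)
        assert fit.y_intercept == pytest.approx(-24_786_555.0, rel=1e-9)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_x_intercept_identity(self, rng):
        x = rng.uniform(0.0, 10.0, 20)
        y = 3.0 * x + rng.normal(0.0, 1.0, 20)
        fit = linear_fit(x, y)
        assert fit.x_intercept * fit.slope + fit.y_intercept == \
            pytest.approx(0.0, abs=1e-9)

    def test_singular_cases(self):
        with pytest.raises(SingularFitError):
            linear_fit([1.0], [2.0])
        with pytest.raises(SingularFitError):
            linear_fit([3.0, 3.0, 3.0], [1.0, 2.0, 3.0])


class TestBundledRegressionTable:
    def test_x_intercepts_reproduced_from_slope_and_intercept(self):
        reg = load_cultivar_regressions()
        computed = -reg["y_intercept"] / reg["slope"]
        # the table prints 4 significant figures; allow half a ULP of the
        # coarsest printed precision (one decimal place)
        assert np.all(np.abs(computed - reg["x_intercept"]) <= 0.051)

    def test_exact_two_decimal_rows(self):
        reg = load_cultivar_regressions().set_index("cultivar")
        for cv, expected in [(1, 98.48), (7, 99.51), (12, 92.61)]:
            row = reg.loc[cv]
            assert round(-row["y_intercept"] / row["slope"], 2) == expected


class TestGrowthSeries:
    def test_two_point_series(self):
        gs = growth_series("e1", [(0.0, 100.0), (10.0, 200.0)])
        assert gs.rgr_per_day[0] == pytest.approx(math.log(2.0) / 10.0)
        assert gs.pct_per_day[0] == pytest.approx(10.0)

    def test_flat_series_all_zero(self):
        gs = growth_series("e1", [(0.0, 5.0), (2.0, 5.0), (6.0, 5.0)])
        np.testing.assert_allclose(gs.rgr_per_day, 0.0)

    def test_contraction_reported_as_negative(self):
        gs = growth_series("e1", [(0.0, 100.0), (2.0, 80.0), (5.0, 120.0)])
        assert gs.rgr_per_day[0] < 0.0 < gs.rgr_per_day[1]

    def test_non_increasing_times_rejected(self):
        with pytest.raises(ParameterError, match="strictly increasing"):
            growth_series("e1", [(0.0, 1.0), (0.0, 2.0)])


class TestNormalizedCovariance:
    def test_identical_columns_correlate_to_one(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        assert normalized_covariance(df).loc["a", "b"] == pytest.approx(1.0)

    def test_negated_column_correlates_to_minus_one(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [-1.0, -2.0, -3.0]})
        assert normalized_covariance(df).loc["a", "b"] == pytest.approx(-1.0)

    def test_matches_definition_oracle(self, rng):
        arr = rng.normal(size=(5, 2))
        corr = normalized_covariance(arr)
        a, b = arr[:, 0], arr[:, 1]
        expected = (np.mean((a - a.mean()) * (b - b.mean()))
                    / (a.std() * b.std()))
        assert corr.iloc[0, 1] == pytest.approx(expected)
        assert np.all(corr.to_numpy() <= 1.0 + 1e-12)
        assert np.all(corr.to_numpy() >= -1.0 - 1e-12)

    def test_zero_variance_column_flagged_undefined(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 4.0, 4.0]})
        corr = normalized_covariance(df)
        assert np.isnan(corr.loc["a", "b"])
        assert corr.loc["a", "a"] == pytest.approx(1.0)


def test_bundled_trait_table_internally_consistent():
    """DW/FW reproduces the printed %DM column at its 2-dp precision."""
    tr = load_cultivar_traits()
    recomputed = (tr["dw_g"] / tr["fw_g"]).round(2)
    np.testing.assert_allclose(recomputed, tr["pdm"], atol=1e-12)
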