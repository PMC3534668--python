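"""Robust usage-vs-year regression, inverse prediction, cohort z-scores."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq

from stemnet import outliers
from stemnet.outliers import OutlierConfig, RegressionModel


def _clean_data(rng, n=50, a=506.0, b=-0.25, sigma=0.0):
    # intercept keeps log-usage well above 0 across 1998-2011 so counts stay >= 1
    years = rng.integers(1998, 2012, size=n).astype(float)
    log_u = a + b * years + rng.normal(0, sigma, size=n)
    return years, np.exp(log_u)


class TestRobustRegression:
    def test_noiseless_line_recovered_exactly(self, rng):
        years, usage = _clean_data(rng)
        model = outliers.fit_robust_loglinear(years, usage)
        assert model.intercept == pytest.approx(506.0, abs=1e-6)
        assert model.slope == pytest.approx(-0.25, abs=1e-8)

    def test_resists_gross_outlier_better_than_ols(self, rng):
        years, usage = _clean_data(rng, sigma=0.1)
        clean_slope = np.polyfit(years, np.log(usage), 1)[0]
        years_c = np.append(years, 2010.0)
        usage_c = np.append(usage, usage.max() * 1000.0)  # one gross outlier
        robust = outliers.fit_robust_loglinear(years_c, usage_c)
        ols_slope = np.polyfit(years_c, np.log(usage_c), 1)[0]
        assert abs(robust.slope - clean_slope) < 0.02
        assert abs(robust.slope - clean_slope) < abs(ols_slope - clean_slope)

    def test_monte_carlo_recovery_within_three_se(self):
        rng = np.random.default_rng(77)
        n, sigma, b = 500, 0.5, -0.25
        years, usage = _clean_data(rng, n=n, b=b, sigma=sigma)
        model = outliers.fit_robust_loglinear(years, usage)
        se_slope = sigma / (years.std() * np.sqrt(n))
        assert abs(model.slope - b) < 3 * se_slope

    def test_single_year_is_rank_error(self):
        with pytest.raises(ValueError, match="distinct"):
            outliers.fit_robust_loglinear([2005.0] * 10, np.arange(1, 11))

    def test_year_shift_equivariance(self, rng):
        years, usage = _clean_data(rng, sigma=0.2)
        m0 = outliers.fit_robust_loglinear(years, usage)
        m1 = outliers.fit_robust_loglinear(years + 7.0, usage)
        assert m1.slope == pytest.approx(m0.slope, abs=1e-6)
        assert m1.intercept == pytest.approx(m0.intercept - 7.0 * m0.slope, abs=1e-4)


class TestInversePrediction:
    def test_forward_inverse_identity(self):
        model = RegressionModel(intercept=500.0, slope=-0.25, scale=0.1, n=100)
        for year in (1999.0, 2004.5, 2011.0):
            usage = np.exp(model.predict_log_usage(year))
            assert outliers.predict_first_pub_year(model, usage) == pytest.approx(
                year, abs=1e-8
            )

    def test_doubling_usage_predicts_earlier_year(self):
        model = RegressionModel(intercept=500.0, slope=-0.25, scale=0.1, n=100)
        y1 = outliers.predict_first_pub_year(model, 10.0)
        y2 = outliers.predict_first_pub_year(model, 20.0)
        assert y2 < y1

    def test_matches_root_solve_oracle(self, rng):
        model = RegressionModel(intercept=480.0, slope=-0.24, scale=0.1, n=50)
        for usage in (2.0, 17.0, 300.0):
            predicted = float(outliers.predict_first_pub_year(model, usage))
            oracle = brentq(
                lambda y: model.predict_log_usage(y) - np.log(usage), 1000.0, 3000.0
            )
            assert predicted == pytest.approx(oracle, abs=1e-8)

    def test_zero_slope_rejected(self):
        model = RegressionModel(intercept=1.0, slope=0.0, scale=0.1, n=10)
        with pytest.raises(ZeroDivisionError):
            outliers.predict_first_pub_year(model, 5.0)


class TestCohortZ:
    def test_direct_arithmetic_example(self):
        # cohort log-usages {1,1,1,2}: mean 1.25, sd 0.5 -> last z = 1.5
        years = [2005] * 4
        usage = np.exp([1.0, 1.0, 1.0, 2.0])
        z = outliers.cohort_zscores(years, usage)
        assert z[-1] == pytest.approx(1.5)
        assert z[0] == pytest.approx(-0.5)

    def test_all_equal_cohort_is_degenerate_zero(self):
        with pytest.warns(RuntimeWarning, match="degenerate"):
            z = outliers.cohort_zscores([2005] * 3, [4, 4, 4])
        assert (z == 0).all()

    def test_standardization_identity_per_cohort(self, rng):
        years = np.repeat([2003, 2007], 20)
        usage = rng.integers(1, 100, size=40)
        z = outliers.cohort_zscores(years, usage)
        for yr in (2003, 2007):
            zc = z[years == yr]
            assert zc.mean() == pytest.approx(0.0, abs=1e-12)
            assert zc.std(ddof=1) == pytest.approx(1.0, abs=1e-12)


class TestFlags:
    @pytest.mark.parametrize(
        "gap,z,expect_gap,expect_z",
        [(4.5, 0.0, True, False), (3.9, 1.9, False, False),
         (4.0, 2.1, True, True), (10.0, 2.0, True, False)],
    )
    def test_threshold_application(self, gap, z, expect_gap, expect_z):
        report = pd.DataFrame({"year_gap": [gap], "cohort_z": [z]})
        out = outliers.flag_outliers(report, OutlierConfig())
        assert bool(out.loc[0, "flag_gap"]) is expect_gap
        assert bool(out.loc[0, "flag_z"]) is expect_z
        assert bool(out.loc[0, "is_outlier"]) is (expect_gap and expect_z)

    def test_nonpositive_thresholds_rejected(self):
        with pytest.raises(ValueError):
            OutlierConfig(z_threshold=-1).validate()


class TestFullReport:
    def test_report_covers_all_used_lines(self, synth_tables):
        usage, meta = synth_tables
        counts = usage.groupby("line_id").size()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            report, model = outliers.outlier_report(meta, counts)
        assert len(report) == len(counts)
        assert model.slope < 0  # later lines are used less
        assert (report["year_gap"].to_numpy()[:-1]
                >= report["year_gap"].to_numpy()[1:]).all()
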