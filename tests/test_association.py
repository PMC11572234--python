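"""Statistical stage: transforms, OLS/logistic fits, results table."""

import numpy as np
import pandas as pd
import pytest

from wmhshape.association import (
    RegressionResult,
    build_results_table,
    derive_volumes,
    fit_linear,
    fit_logistic,
    run_association_analysis,
    significance_stars,
    transform_predictor,
)
from wmhshape.synthetic_data import CohortSimConfig, simulate_cohort


def small_cohort(n=400, seed=0):
    return derive_volumes(simulate_cohort(CohortSimConfig(n=n, seed=seed)))


class TestDeriveVolumes:
    def test_delta_wmh_from_reference_means(self):
        df = pd.DataFrame(
            {
                "wmh_baseline_ml": [16.56],
                "wmh_followup_ml": [22.32],
                "icv_baseline_ml": [1400.0],
                "icv_followup_ml": [1420.0],
            }
        )
        out = derive_volumes(df)
        assert out.loc[0, "delta_wmh_ml"] == pytest.approx(5.76)
        assert out.loc[0, "icv_mean_ml"] == pytest.approx(1410.0)

    def test_equal_volumes_give_zero_change(self):
        df = pd.DataFrame(
            {
                "wmh_baseline_ml": [10.0],
                "wmh_followup_ml": [10.0],
                "icv_baseline_ml": [1500.0],
                "icv_followup_ml": [1500.0],
            }
        )
        assert derive_volumes(df).loc[0, "delta_wmh_ml"] == 0.0

    def test_missing_timepoint_propagates_nan(self):
        df = pd.DataFrame(
            {
                "wmh_baseline_ml": [10.0, np.nan],
                "wmh_followup_ml": [12.0, 15.0],
                "icv_baseline_ml": [1500.0] * 2,
                "icv_followup_ml": [1500.0] * 2,
            }
        )
        out = derive_volumes(df)
        assert np.isnan(out.loc[1, "delta_wmh_ml"])


class TestTransforms:
    def test_log100_of_solidity(self):
        x = pd.Series([0.19] * 5 + [0.3] * 5)
        z = transform_predictor(x, "solidity")
        # ln(100 * 0.19) = ln(19) before z-scoring
        raw = np.log(100 * x)
        want = (raw - raw.mean()) / raw.std(ddof=1)
        assert np.allclose(z, want)
        assert np.log(19) == pytest.approx(2.9444, abs=1e-4)

    def test_zscore_mean_zero_sd_one(self):
        rng = np.random.default_rng(0)
        z = transform_predictor(pd.Series(rng.lognormal(1, 0.5, 500)), "fd_pvc")
        assert abs(z.mean()) < 1e-12
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_inversion_flips_sign(self):
        x = pd.Series(np.linspace(1.0, 2.0, 50))
        plain = transform_predictor(x, "convexity", invert=False)
        flipped = transform_predictor(x, "convexity", invert=True)
        assert np.allclose(flipped, -plain)

    def test_inversion_ignored_for_noninverted_markers(self):
        x = pd.Series(np.linspace(1.0, 2.0, 50))
        assert np.allclose(
            transform_predictor(x, "fd_pvc", invert=True),
            transform_predictor(x, "fd_pvc", invert=False),
        )

    def test_nonpositive_before_log_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            transform_predictor(pd.Series([0.1, -0.2, 0.3]), "solidity")

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            transform_predictor(pd.Series([1.0] * 10), "fd_pvc")


def ols_normal_equations(X, y):
    """Closed-form OLS oracle with t-based intervals."""
    from scipy import stats

    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    resid = y - X @ beta
    dof = len(y) - X.shape[1]
    sigma2 = resid @ resid / dof
    se = np.sqrt(np.diag(sigma2 * XtX_inv))
    tcrit = stats.t.ppf(0.975, dof)
    return beta, se, beta - tcrit * se, beta + tcrit * se


class TestLinear:
    def test_matches_normal_equation_oracle_on_tiny_design(self):
        rng = np.random.default_rng(42)
        n = 6
        df = pd.DataFrame(
            {
                "fd_pvc": rng.normal(1.7, 0.15, n),
                "delta_wmh_ml": rng.normal(5, 2, n),
                "age": rng.normal(74, 5, n),
                "sex": [0, 1, 0, 1, 1, 0],
                "icv_mean_ml": rng.normal(1500, 100, n),
            }
        )
        res = fit_linear(df, "fd_pvc")
        z = transform_predictor(df["fd_pvc"], "fd_pvc")
        X = np.column_stack(
            [np.ones(n), z, df["age"], df["sex"], df["icv_mean_ml"]]
        )
        beta, se, lo, hi = ols_normal_equations(X, df["delta_wmh_ml"].to_numpy())
        assert res.estimate == pytest.approx(beta[1], abs=1e-10)
        assert res.ci_low == pytest.approx(lo[1], abs=1e-10)
        assert res.ci_high == pytest.approx(hi[1], abs=1e-10)

    def test_null_predictor_unbiased(self):
        rng = np.random.default_rng(1)
        n = 2000
        df = pd.DataFrame(
            {
                "fd_pvc": rng.normal(1.7, 0.15, n),
                "delta_wmh_ml": rng.normal(5, 7, n),
                "age": rng.normal(74, 5, n),
                "sex": rng.integers(0, 2, n),
                "icv_mean_ml": rng.normal(1500, 100, n),
            }
        )
        res = fit_linear(df, "fd_pvc")
        assert abs(res.estimate) < 0.6  # ~3.8 SE
        assert res.ci_low < 0 < res.ci_high

    def test_too_few_cases_rejected(self):
        df = small_cohort(n=400).head(4)
        with pytest.raises(ValueError, match="complete cases"):
            fit_linear(df, "fd_pvc")


class TestLogistic:
    def test_reciprocal_identity_under_sign_flip(self):
        df = small_cohort(n=600, seed=2)
        a = fit_logistic(df, "fd_pvc", "microbleed", invert=False)
        # manual sign flip via a negated column
        df_neg = df.copy()
        df_neg["fd_pvc"] = -df_neg["fd_pvc"]
        b = fit_logistic(df_neg, "fd_pvc", "microbleed", invert=False)
        assert b.estimate == pytest.approx(1 / a.estimate, rel=1e-10)
        assert b.ci_low == pytest.approx(1 / a.ci_high, rel=1e-10)
        assert b.ci_high == pytest.approx(1 / a.ci_low, rel=1e-10)
        assert b.p_value == pytest.approx(a.p_value, rel=1e-9)

    def test_binary_predictor_matches_cross_product_ratio(self):
        # no covariates: the fitted OR equals the 2x2 table cross-product ratio
        rng = np.random.default_rng(3)
        n = 500
        x = rng.integers(0, 2, n)
        p = np.where(x == 1, 0.4, 0.2)
        y = (rng.uniform(size=n) < p).astype(int)
        df = pd.DataFrame({"marker": x, "new_outcome": y})
        res = fit_logistic(
            df, "marker", "outcome", covariates=(), invert=False, at_risk_only=False
        )
        a = ((x == 1) & (y == 1)).sum()
        b = ((x == 1) & (y == 0)).sum()
        c = ((x == 0) & (y == 1)).sum()
        d = ((x == 0) & (y == 0)).sum()
        want_or = (a * d) / (b * c)
        sd = np.std(x, ddof=1)
        # fitted on the z-scored predictor: OR per SD = OR_raw ** sd
        assert res.estimate == pytest.approx(want_or**sd, rel=1e-6)

    def test_at_risk_exclusion_reduces_n(self):
        df = small_cohort(n=800, seed=4)
        with_excl = fit_logistic(df, "fd_pvc", "microbleed", at_risk_only=True)
        without = fit_logistic(df, "fd_pvc", "microbleed", at_risk_only=False)
        n_baseline_pos = int(df["baseline_microbleed"].sum())
        assert without.n_used - with_excl.n_used == n_baseline_pos

    def test_single_class_outcome_rejected(self):
        df = small_cohort(n=100, seed=5).copy()
        df["new_microbleed"] = 0
        with pytest.raises(ValueError, match="single-class"):
            fit_logistic(df, "fd_pvc", "microbleed")


class TestResultsTable:
    def _mk(self, pred, outcome, model, est, lo, hi, p):
        return RegressionResult(pred, outcome, model, est, lo, hi, p, 100)

    def test_grid_dimensions(self):
        df = small_cohort(n=2000, seed=6)
        results = run_association_analysis(df)
        assert len(results) == 7 * 6
        table = build_results_table(results)
        assert table.shape == (7, 6)

    def test_star_conventions(self):
        assert significance_stars(0.2) == ""
        assert significance_stars(0.04) == "*"
        assert significance_stars(0.004) == "**"
        assert significance_stars(0.0004) == "***"

    def test_cells_formatted_with_stars(self):
        res = [
            self._mk("fd_pvc", "microbleed", "logistic", 1.47, 1.30, 1.65, 0.0001),
            self._mk("fd_pvc", "delta_wmh_ml", "linear", 2.62, 2.31, 2.93, 0.2),
        ]
        table = build_results_table(res)
        assert table.loc["fd_pvc", "microbleed"] == "1.47 (1.30-1.65)***"
        assert table.loc["fd_pvc", "delta_wmh"] == "2.62 (2.31-2.93)"

    def test_missing_cells_stay_empty(self):
        res = [self._mk("fd_pvc", "microbleed", "logistic", 1.5, 1.2, 1.9, 0.01)]
        table = build_results_table(res)
        assert table.loc["fd_pvc", "epvs"] == ""

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError, match="confidence interval"):
            self._mk("x", "y", "linear", 2.0, 2.5, 3.0, 0.05)
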