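"""Association models between baseline WMH markers and 5-year progression.

The analysis follows the cohort study design this package emulates:

* outcome for the linear models is the change in WMH volume
  (follow-up minus baseline, ml), adjusted for age, sex and mean
  intracranial volume (the average of the two timepoints, which improves
  precision);
* outcomes for the logistic models are the five binary new-lesion flags
  (subcortical infarct, microbleed, enlarged perivascular space, cerebellar
  infarct, cortical infarct), adjusted for age and sex;
* predictors are standardized: solidity and baseline WMH volume are
  multiplied by 100 and natural-log transformed (both are right-skewed),
  every predictor is z-scored over the analysis sample, and solidity,
  convexity and eccentricity are inverted (sign-flipped z) for the logistic
  models so that all odds ratios point in the "more irregular / less
  elongated -> higher risk" direction.  Sign-flipping the standardized
  predictor maps OR to 1/OR with identical |z| and p-value.

Estimates are reported per 1 SD of the (transformed) predictor with Wald
95% confidence intervals; no multiple-testing adjustment is applied
(p < 0.05 is the significance convention of the emulated analysis).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "RegressionResult",
    "derive_volumes",
    "transform_predictor",
    "fit_linear",
    "fit_logistic",
    "run_association_analysis",
    "build_results_table",
    "significance_stars",
]

#: Predictors that are log-transformed (x100) before z-scoring.
LOG100_PREDICTORS = ("solidity", "wmh_baseline_ml")

#: Predictors whose direction of effect is inverted for logistic models.
INVERTED_PREDICTORS = ("solidity", "convexity", "eccentricity")

PVC_MARKERS = ("solidity", "convexity", "concavity_index", "fd_pvc")
DEEP_MARKERS = ("eccentricity", "fd_deep")
ALL_PREDICTORS = PVC_MARKERS + DEEP_MARKERS + ("wmh_baseline_ml",)

OUTCOMES = (
    "subcortical_infarct",
    "microbleed",
    "epvs",
    "cerebellar_infarct",
    "cortical_infarct",
)


class SeparationError(RuntimeError):
    """Raised when a logistic fit shows (quasi-)complete separation."""


@dataclass(frozen=True)
class RegressionResult:
    """One cell of the results grid: an estimate with its 95% CI."""

    predictor: str
    outcome: str
    model: str  # "linear" | "logistic"
    estimate: float  # B for linear, OR for logistic
    ci_low: float
    ci_high: float
    p_value: float
    n_used: int

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError("estimate must lie inside its confidence interval")
        if self.model == "logistic" and self.estimate <= 0:
            raise ValueError("odds ratio must be positive")


def derive_volumes(df: pd.DataFrame) -> pd.DataFrame:
    """Add ``delta_wmh_ml`` and ``icv_mean_ml`` columns.

    Rows missing either WMH timepoint get NaN and drop out of the linear
    models by casewise deletion.
    """
    out = df.copy()
    out["delta_wmh_ml"] = out["wmh_followup_ml"] - out["wmh_baseline_ml"]
    out["icv_mean_ml"] = (out["icv_baseline_ml"] + out["icv_followup_ml"]) / 2.0
    return out


def transform_predictor(
    values: pd.Series | np.ndarray, name: str, invert: bool = False
) -> np.ndarray:
    """Standardize one predictor: optional ln(100 x), z-score, optional flip."""
    x = np.asarray(values, dtype=float)
    if name in LOG100_PREDICTORS:
        if np.any(x[~np.isnan(x)] <= 0):
            raise ValueError(f"{name}: log transform requires positive values")
        x = np.log(100.0 * x)
    sd = np.nanstd(x, ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError(f"{name}: zero-variance predictor cannot be z-scored")
    z = (x - np.nanmean(x)) / sd
    if invert and name in INVERTED_PREDICTORS:
        z = -z
    return z


def _complete_cases(df: pd.DataFrame, cols) -> pd.DataFrame:
    return df.dropna(subset=list(cols))


def fit_linear(
    df: pd.DataFrame,
    predictor: str,
    outcome: str = "delta_wmh_ml",
    covariates=("age", "sex", "icv_mean_ml"),
    invert: bool = False,
) -> RegressionResult:
    """OLS of the outcome on one standardized predictor plus covariates.

    The predictor is transformed on the complete-case analysis sample; the
    CI is t-based (B +/- t(.975, df) x SE) and p two-sided.
    """
    cols = [predictor, outcome, *covariates]
    data = _complete_cases(df, cols)
    if len(data) < len(covariates) + 3:
        raise ValueError(
            f"only {len(data)} complete cases for {predictor}/{outcome}"
        )
    z = transform_predictor(data[predictor], predictor, invert=invert)
    X = sm.add_constant(
        pd.DataFrame({predictor: z, **{c: data[c].to_numpy() for c in covariates}})
    )
    fit = sm.OLS(data[outcome].to_numpy(), X).fit()
    ci = fit.conf_int().loc[predictor]
    return RegressionResult(
        predictor=predictor,
        outcome=outcome,
        model="linear",
        estimate=float(fit.params[predictor]),
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        p_value=float(fit.pvalues[predictor]),
        n_used=int(fit.nobs),
    )


def fit_logistic(
    df: pd.DataFrame,
    predictor: str,
    outcome: str,
    covariates=("age", "sex"),
    invert: bool = True,
    at_risk_only: bool = True,
) -> RegressionResult:
    """Logistic model of a new-lesion flag on one standardized predictor.

    ``at_risk_only`` (default) excludes participants already positive for
    that lesion type at baseline, so odds ratios describe genuinely incident
    lesions.  The OR is per 1 SD with Wald CI ``exp(coef +/- 1.96 SE)``.
    """
    outcome_col = f"new_{outcome}" if f"new_{outcome}" in df.columns else outcome
    cols = [predictor, outcome_col, *covariates]
    data = _complete_cases(df, cols)
    if at_risk_only:
        base_col = f"baseline_{outcome}"
        if base_col in data.columns:
            data = data[data[base_col] == 0]
    y = data[outcome_col].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError(f"outcome {outcome} is single-class in the analysis sample")
    z = transform_predictor(data[predictor], predictor, invert=invert)
    X = sm.add_constant(
        pd.DataFrame({predictor: z, **{c: data[c].to_numpy() for c in covariates}})
    )
    try:
        fit = sm.Logit(y, X).fit(disp=0, maxiter=50, tol=1e-8)
    except Exception as exc:
        raise SeparationError(
            f"logistic fit failed for {predictor}/{outcome}: {exc}"
        ) from exc
    se = float(fit.bse[predictor])
    if not np.isfinite(se) or se > 1e3:
        raise SeparationError(
            f"quasi-complete separation for {predictor}/{outcome} (SE={se:.3g})"
        )
    coef = float(fit.params[predictor])
    return RegressionResult(
        predictor=predictor,
        outcome=outcome,
        model="logistic",
        estimate=math.exp(coef),
        ci_low=math.exp(coef - 1.959963984540054 * se),
        ci_high=math.exp(coef + 1.959963984540054 * se),
        p_value=float(fit.pvalues[predictor]),
        n_used=len(data),
    )


def run_association_analysis(
    cohort: pd.DataFrame,
    predictors=ALL_PREDICTORS,
    outcomes=OUTCOMES,
    at_risk_only: bool = True,
    invert_linear: bool = True,
) -> list[RegressionResult]:
    """Fit the full marker x outcome grid (one linear + five logistic each).

    Solidity, convexity and eccentricity are inverted in both model families
    by default, so every estimate reads "more irregular / less elongated ->
    larger effect"; set ``invert_linear=False`` to restrict inversion to the
    logistic models.
    """
    df = derive_volumes(cohort) if "delta_wmh_ml" not in cohort.columns else cohort
    results: list[RegressionResult] = []
    for pred in predictors:
        results.append(fit_linear(df, pred, invert=invert_linear))
        for outcome in outcomes:
            results.append(
                fit_logistic(df, pred, outcome, at_risk_only=at_risk_only)
            )
    return results


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def build_results_table(results) -> pd.DataFrame:
    """Markers x outcomes grid of "estimate (ci-ci)stars" strings.

    Linear estimates are B values (ml per SD); logistic estimates odds
    ratios per SD.  Missing cells stay empty rather than being fabricated.
    """
    grid: dict[str, dict[str, str]] = {}
    for r in results:
        col = "delta_wmh" if r.model == "linear" else r.outcome
        cell = (
            f"{r.estimate:.2f} ({r.ci_low:.2f}-{r.ci_high:.2f})"
            f"{significance_stars(r.p_value)}"
        )
        grid.setdefault(r.predictor, {})[col] = cell
    columns = ["delta_wmh", *OUTCOMES]
    rows = {}
    for pred, cells in grid.items():
        rows[pred] = [cells.get(c, "") for c in columns]
    return pd.DataFrame.from_dict(rows, orient="index", columns=columns)


def results_to_frame(results) -> pd.DataFrame:
    """Tidy numeric version of the results list."""
    return pd.DataFrame(
        [
            {
                "predictor": r.predictor,
                "outcome": "delta_wmh" if r.model == "linear" else r.outcome,
                "model": r.model,
                "estimate": r.estimate,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "p_value": r.p_value,
                "n_used": r.n_used,
            }
            for r in results
        ]
    )
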