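"""Agreement and association statistics for eGFR validation.

Conventions follow standard GFR-equation validation practice:

* bias is estimated − measured (positive = overestimation), summarized as
  the mean with a t-based 95% CI;
* RMSE is the root mean squared error of the individual biases;
* the IQR of the bias is the (25th, 75th) percentile pair;
* P30 / P10 are the percentages of estimates strictly within 30% / 10% of
  the measured value, with Wilson score CIs;
* R² comes from univariable regression of measured on estimated, i.e. the
  squared Pearson correlation;
* the standardized coefficient Sβ of a univariable regression equals the
  Pearson correlation, with its CI from the regression standard error.

Post-donation prediction multiplies the pre-donation estimate by a
compensation factor (default 0.66, the mean −34% change from pre- to
3-month post-donation measured GFR) before comparing with post-donation
measured GFR.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.proportion import proportion_confint

DEFAULT_COMPENSATION_FACTOR = 0.66
DEFAULT_THRESHOLDS = (90.0, 60.0)


class MetricsError(ValueError):
    pass


@dataclasses.dataclass
class AnalysisConfig:
    """Knobs of the validation stage."""

    compensation_factor: float = DEFAULT_COMPENSATION_FACTOR
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if not 0 < self.compensation_factor < 1:
            raise MetricsError("compensation_factor must be in (0, 1)")
        if any(t <= 0 for t in self.thresholds):
            raise MetricsError("thresholds must be positive")
        if not 0 < self.ci_level < 1:
            raise MetricsError("ci_level must be in (0, 1)")


@dataclasses.dataclass
class AgreementReport:
    """Accuracy/precision of one equation against measured GFR."""

    n: int
    mean_bias: float
    bias_ci: tuple[float, float]
    rmse: float
    iqr_bias: tuple[float, float]
    p30: float
    p30_ci: tuple[float, float]
    p10: float
    p10_ci: tuple[float, float]
    r2: float

    def as_row(self) -> dict:
        return {
            "n": self.n, "bias": self.mean_bias,
            "bias_ci_low": self.bias_ci[0], "bias_ci_high": self.bias_ci[1],
            "rmse": self.rmse,
            "iqr_bias_q25": self.iqr_bias[0], "iqr_bias_q75": self.iqr_bias[1],
            "p30": self.p30, "p30_ci_low": self.p30_ci[0], "p30_ci_high": self.p30_ci[1],
            "p10": self.p10, "p10_ci_low": self.p10_ci[0], "p10_ci_high": self.p10_ci[1],
            "r2": self.r2,
        }


@dataclasses.dataclass
class RegressionSummary:
    """Univariable association: standardized beta with CI, R², p, n."""

    sbeta: float
    sbeta_ci: tuple[float, float]
    r2: float
    p_value: float
    n: int


def predict_post(egfr_pre, factor: float = DEFAULT_COMPENSATION_FACTOR):
    """Predicted post-donation GFR: pre-donation estimate × compensation factor."""
    arr = np.asarray(egfr_pre, dtype=float)
    if not factor > 0:
        raise MetricsError("factor must be positive")
    if np.any(arr <= 0):
        raise MetricsError("egfr_pre must be positive")
    out = arr * factor
    return float(out) if np.isscalar(egfr_pre) or arr.ndim == 0 else out


def estimate_compensation_factor(pre, post) -> tuple[float, float]:
    """Mean-of-ratios compensation factor from paired pre/post measured GFR.

    Returns ``(factor, mean_percent_change)`` where factor =
    1 + mean((post−pre)/pre) and the percent change is 100·(factor−1).
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.size < 2:
        raise MetricsError("need paired vectors of equal length >= 2")
    if np.any(np.isnan(pre)) or np.any(np.isnan(post)):
        raise MetricsError("vectors must be pairwise complete")
    if np.any(pre <= 0):
        raise MetricsError("pre-donation values must be positive")
    rel = (post - pre) / pre
    factor = 1.0 + float(np.mean(rel))
    return factor, 100.0 * (factor - 1.0)


def agreement(predicted, observed, ci_level: float = 0.95) -> AgreementReport:
    """Full accuracy/precision report of predicted vs observed GFR.

    P30/P10 use strict inequality (|bias|/observed < 0.30 or 0.10);
    a boundary-exact error counts as a failure.
    """
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape:
        raise MetricsError("predicted and observed must have equal length")
    n = predicted.size
    if n < 2:
        raise MetricsError("need at least 2 pairs")
    if np.any(np.isnan(predicted)) or np.any(np.isnan(observed)):
        raise MetricsError("vectors must be pairwise complete")
    if np.any(observed <= 0):
        raise MetricsError("observed values must be positive")

    bias = predicted - observed
    mean_bias = float(np.mean(bias))
    rmse = float(np.sqrt(np.mean(bias ** 2)))
    q25, q75 = np.percentile(bias, [25, 75])  # linear interpolation

    sd = float(np.std(bias, ddof=1))
    tcrit = stats.t.ppf(0.5 + ci_level / 2, df=n - 1)
    half = tcrit * sd / np.sqrt(n)
    bias_ci = (mean_bias - half, mean_bias + half)

    rel = np.abs(bias) / observed
    k30, k10 = int(np.sum(rel < 0.30)), int(np.sum(rel < 0.10))
    p30_ci = proportion_confint(k30, n, alpha=1 - ci_level, method="wilson")
    p10_ci = proportion_confint(k10, n, alpha=1 - ci_level, method="wilson")

    if np.ptp(predicted) == 0 or np.ptp(observed) == 0:
        r2 = 0.0 if rmse > 0 else 1.0
    else:
        r2 = float(np.corrcoef(predicted, observed)[0, 1] ** 2)

    return AgreementReport(
        n=n, mean_bias=mean_bias, bias_ci=bias_ci, rmse=rmse,
        iqr_bias=(float(q25), float(q75)),
        p30=100.0 * k30 / n, p30_ci=(100 * p30_ci[0], 100 * p30_ci[1]),
        p10=100.0 * k10 / n, p10_ci=(100 * p10_ci[0], 100 * p10_ci[1]),
        r2=r2,
    )


def univariable_regression(x, y, ci_level: float = 0.95) -> RegressionSummary:
    """OLS of y on x after z-scoring both; the slope is the standardized β.

    In the univariable case Sβ equals the Pearson correlation and
    R² = Sβ².  The CI uses the regression standard error, so it may extend
    beyond ±1 (as in published association tables).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise MetricsError("need paired vectors of length >= 3")
    if np.std(x) == 0:
        raise MetricsError("x is constant; standardized regression undefined")
    if np.std(y) == 0:
        raise MetricsError("y is constant; standardized regression undefined")
    zx = (x - x.mean()) / x.std(ddof=1)
    zy = (y - y.mean()) / y.std(ddof=1)
    model = sm.OLS(zy, sm.add_constant(zx)).fit()
    sbeta = float(model.params[1])
    lo, hi = model.conf_int(alpha=1 - ci_level)[1]
    return RegressionSummary(sbeta=sbeta, sbeta_ci=(float(lo), float(hi)),
                             r2=sbeta ** 2, p_value=float(model.pvalues[1]),
                             n=x.size)


def nested_model_test(y, base_predictors, added_predictor) -> tuple[float, float, float]:
    """Partial F-test for adding one predictor to an OLS model.

    Returns ``(r2_base, r2_full, p_improvement)``.  Used to ask whether
    cystatin C adds information to a creatinine + age + sex model of
    measured GFR.
    """
    y = np.asarray(y, dtype=float)
    X_base = np.asarray(base_predictors, dtype=float)
    if X_base.ndim == 1:
        X_base = X_base[:, None]
    added = np.asarray(added_predictor, dtype=float)[:, None]
    X_full = np.hstack([X_base, added])
    n, k_full = X_full.shape
    if n <= k_full + 1:
        raise MetricsError("n must exceed the number of parameters")
    design_full = sm.add_constant(X_full)
    if np.linalg.matrix_rank(design_full) < design_full.shape[1]:
        raise MetricsError("design matrix is rank deficient")
    fit_base = sm.OLS(y, sm.add_constant(X_base)).fit()
    fit_full = sm.OLS(y, design_full).fit()
    _, p, _ = fit_full.compare_f_test(fit_base)
    return float(fit_base.rsquared), float(fit_full.rsquared), float(p)


def threshold_concordance(egfr, mgfr, thresholds=DEFAULT_THRESHOLDS) -> pd.DataFrame:
    """2×2 concordance counts of eGFR vs mGFR around clinical thresholds.

    Ties (value exactly at the threshold) count as ≥ threshold.  Returns
    one row per threshold with the four cell counts.
    """
    egfr = np.asarray(egfr, dtype=float)
    mgfr = np.asarray(mgfr, dtype=float)
    if egfr.shape != mgfr.shape:
        raise MetricsError("paired vectors required")
    rows = []
    for t in thresholds:
        if t <= 0:
            raise MetricsError("thresholds must be positive")
        e_ge, m_ge = egfr >= t, mgfr >= t
        rows.append({
            "threshold": t,
            "both_ge": int(np.sum(e_ge & m_ge)),
            "egfr_ge_mgfr_lt": int(np.sum(e_ge & ~m_ge)),
            "egfr_lt_mgfr_ge": int(np.sum(~e_ge & m_ge)),
            "both_lt": int(np.sum(~e_ge & ~m_ge)),
        })
    return pd.DataFrame(rows)


def bland_altman_data(egfr, mgfr) -> tuple[pd.DataFrame, dict]:
    """Per-pair (mean, difference) plus the 95% limits of agreement.

    Differences are eGFR − mGFR; limits are mean ± 1.96 SD (population SD
    of the differences).
    """
    egfr = np.asarray(egfr, dtype=float)
    mgfr = np.asarray(mgfr, dtype=float)
    if egfr.shape != mgfr.shape or egfr.size == 0:
        raise MetricsError("paired non-empty vectors required")
    diff = egfr - mgfr
    table = pd.DataFrame({"mean_of_pair": (egfr + mgfr) / 2, "difference": diff})
    md = float(np.mean(diff))
    sd = float(np.std(diff))
    summary = {"mean_difference": md, "loa_low": md - 1.96 * sd, "loa_high": md + 1.96 * sd}
    return table, summary
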