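"""ROC analysis, fixed-specificity operating point, and the test battery.

The operating point mirrors the clinical protocol: pick the threshold on
*training* scores whose specificity first reaches 90%, then report
sensitivity, specificity, PPV, NPV and prediction accuracy (PA) of the
rule ``score >= threshold => predict success`` on validation shocks.

Correlated AUCs are compared with the DeLong placement-value Z-test;
proportions with the (uncorrected) chi-square test; group means with the
independent-samples t-test; rank association with Kendall's tau-b; and
the random- vs fixed-effects logistic specification with Hausman's test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

from .errors import InvalidArgumentError, TestUndefinedError, UndefinedRocError

__all__ = [
    "RocCurve", "PerformanceReport", "TestResult",
    "roc_curve", "threshold_at_specificity", "classification_metrics",
    "compare_auc", "compare_proportions", "kendall_tau",
    "t_test_independent", "hausman_specification_test",
]


@dataclass
class RocCurve:
    """ROC points over all distinct score thresholds, plus trapezoidal AUC."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float


@dataclass
class PerformanceReport:
    """Threshold-based metrics (percent) with their confusion counts."""

    feature_set: str
    auc: float
    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    pa: float

    def recompute(self) -> dict[str, float]:
        """Re-derive the five percentages from the stored counts."""
        tp, fp, tn, fn = self.tp, self.fp, self.tn, self.fn
        div = lambda a, b: 100.0 * a / b if b else float("nan")
        return {
            "sensitivity": div(tp, tp + fn),
            "specificity": div(tn, tn + fp),
            "ppv": div(tp, tp + fp),
            "npv": div(tn, tn + fn),
            "pa": div(tp + tn, tp + fp + tn + fn),
        }


@dataclass
class TestResult:
    """Outcome of one statistical test."""

    name: str
    statistic: float
    p_value: float
    df: float | None = None
    flag: str | None = None

    def __post_init__(self) -> None:
        if np.isfinite(self.p_value) and not 0.0 <= self.p_value <= 1.0:
            raise InvalidArgumentError("p-value outside [0, 1]")


def _check_two_classes(labels: np.ndarray) -> None:
    if labels.min() == labels.max():
        raise UndefinedRocError("both outcome classes are required")


def roc_curve(scores, labels) -> RocCurve:
    """ROC over all distinct thresholds; AUC by the trapezoid rule.

    Tied scores contribute half a concordance, which the trapezoid over
    the tie's diagonal segment produces exactly.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_two_classes(labels)
    fpr, tpr, thr = _sk_roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(thresholds=thr, sensitivity=tpr, specificity=1.0 - fpr,
                    auc=auc)


def threshold_at_specificity(curve: RocCurve, target_specificity: float = 0.90) -> float:
    """Training threshold whose specificity first reaches the target.

    Exact equality with the target is rarely attainable on finite data, so
    the rule is: among thresholds with specificity >= target, take the one
    with maximal sensitivity (equivalently the smallest such threshold).
    Classification rule everywhere: ``score >= threshold`` predicts success.
    """
    if not 0.0 < target_specificity < 1.0:
        raise InvalidArgumentError("target specificity must be in (0, 1)")
    ok = curve.specificity >= target_specificity
    if not ok.any():  # cannot happen with the +inf end point, but be safe
        raise InvalidArgumentError("target specificity unattainable")
    best = np.flatnonzero(ok & (curve.sensitivity == curve.sensitivity[ok].max()))
    thr = float(curve.thresholds[best].min())
    if not np.isfinite(thr):
        # only the degenerate predict-nothing-positive point qualifies;
        # return a finite threshold above every observed score
        finite = curve.thresholds[np.isfinite(curve.thresholds)]
        thr = float(finite.max()) + 1.0 if finite.size else 1.0
    return thr


def classification_metrics(scores, labels, threshold: float,
                           feature_set: str = "", auc: float | None = None
                           ) -> PerformanceReport:
    """Confusion counts and percent metrics for ``score >= threshold``."""
    if not np.isfinite(threshold):
        raise InvalidArgumentError("threshold must be finite")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_two_classes(labels)
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    tn = int(np.sum(~pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    if tp + fp == 0:
        warnings.warn("no positive predictions: PPV undefined", stacklevel=2)
    if tn + fn == 0:
        warnings.warn("no negative predictions: NPV undefined", stacklevel=2)
    if auc is None:
        auc = roc_curve(scores, labels).auc
    div = lambda a, b: 100.0 * a / b if b else float("nan")
    return PerformanceReport(
        feature_set=feature_set, auc=float(auc), threshold=float(threshold),
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=div(tp, tp + fn), specificity=div(tn, tn + fp),
        ppv=div(tp, tp + fp), npv=div(tn, tn + fn),
        pa=div(tp + tn, tp + fp + tn + fn),
    )


# ---------------------------------------------------------------------------
# AUC comparison (DeLong)
# ---------------------------------------------------------------------------

def _placements(scores: np.ndarray, labels: np.ndarray):
    """DeLong placement values V10 (per positive) and V01 (per negative)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    # P(pos > neg) + 0.5 P(tie), per case
    v10 = np.array([np.mean((s > neg) + 0.5 * (s == neg)) for s in pos])
    v01 = np.array([np.mean((s < pos) + 0.5 * (s == pos)) for s in neg])
    return v10, v01


def compare_auc(scores_a, scores_b, labels, paired: bool = True) -> TestResult:
    """Z-test for the difference of two AUCs on the same validation shocks.

    ``paired=True`` uses the DeLong covariance-aware placement-value
    method for correlated curves; ``paired=False`` falls back to the
    unpaired normal comparison with independent placement variances.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_two_classes(labels)
    if paired and scores_a.shape != scores_b.shape:
        raise InvalidArgumentError("paired comparison needs aligned scores")
    v10_a, v01_a = _placements(scores_a, labels)
    v10_b, v01_b = _placements(scores_b, labels)
    auc_a, auc_b = v10_a.mean(), v10_b.mean()
    m, n = v10_a.size, v01_a.size
    if paired:
        s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
        s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
        var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
            + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    else:
        var = (v10_a.var(ddof=1) + v10_b.var(ddof=1)) / m \
            + (v01_a.var(ddof=1) + v01_b.var(ddof=1)) / n
    diff = auc_a - auc_b
    if var <= 0:
        z = 0.0 if diff == 0 else np.inf * np.sign(diff)
        p = 1.0 if diff == 0 else 0.0
        return TestResult("delong_z" if paired else "unpaired_z",
                          z, p, flag="zero variance")
    z = diff / np.sqrt(var)
    return TestResult("delong_z" if paired else "unpaired_z",
                      float(z), float(2.0 * stats.norm.sf(abs(z))))


def compare_proportions(successes_a: int, n_a: int,
                        successes_b: int, n_b: int) -> TestResult:
    """2x2 chi-square (no continuity correction) for two proportions."""
    if min(successes_a, successes_b) < 0 or n_a <= 0 or n_b <= 0:
        raise InvalidArgumentError("counts must be nonnegative with positive totals")
    if successes_a > n_a or successes_b > n_b:
        raise InvalidArgumentError("successes cannot exceed totals")
    table = np.array([[successes_a, n_a - successes_a],
                      [successes_b, n_b - successes_b]], dtype=float)
    if np.any(table.sum(axis=0) == 0):
        # a margin is empty: the statistic is 0/0; proportions are equal
        return TestResult("chi2", 0.0, 1.0, df=1, flag="degenerate margin")
    res = stats.chi2_contingency(table, correction=False)
    return TestResult("chi2", float(res.statistic), float(res.pvalue), df=1)


def kendall_tau(x, y) -> TestResult:
    """Kendall's tau-b (tie-corrected) with normal-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise InvalidArgumentError("need two equal-length vectors, n >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant vector: correlation undefined", stacklevel=2)
        return TestResult("kendall_tau_b", 0.0, float("nan"),
                          flag="undefined (constant input)")
    res = stats.kendalltau(x, y)
    return TestResult("kendall_tau_b", float(res.statistic), float(res.pvalue))


def t_test_independent(a, b, *, equal_var: bool = True) -> TestResult:
    """Two-sided independent-samples t-test (pooled variance by default)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InvalidArgumentError("each group needs n >= 2")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        return TestResult("t", 0.0, 1.0, df=a.size + b.size - 2,
                          flag="zero variance, equal means")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return TestResult("t", float(res.statistic), float(res.pvalue),
                      df=float(res.df))


# ---------------------------------------------------------------------------
# Hausman specification test
# ---------------------------------------------------------------------------

def hausman_specification_test(frame: pd.DataFrame, covariate: str,
                               *, groups: str = "patient_id") -> TestResult:
    """Fixed- vs random-effects logistic specification check for one covariate.

    Fits the covariate's slope by conditional (fixed-effects) logistic
    regression and by the random-intercept model, then refers

        H = (b_FE - b_RE)^2 / (var_FE - var_RE)

    to chi-square with 1 df.  The conditional likelihood only uses
    patients with within-patient outcome variation; without any such
    patients the test is undefined.  A negative variance difference (a
    finite-sample artefact) is reported as inconclusive.
    """
    from statsmodels.discrete.conditional_models import ConditionalLogit

    from .models import fit_logistic

    frame = frame.sort_values([groups, "shock_index"]
                              if "shock_index" in frame else [groups])
    g = frame[groups].to_numpy()
    y = frame["outcome"].to_numpy(dtype=float)
    informative = (
        frame.groupby(groups)["outcome"].nunique() > 1
    )
    if not informative.any():
        raise TestUndefinedError(
            "no patient has within-patient outcome variation"
        )
    multi = frame.groupby(groups)["outcome"].size() >= 2
    if (informative & multi).sum() < 2:
        raise TestUndefinedError(
            "need >= 2 patients with >= 2 shocks and outcome variation"
        )

    x = frame[[covariate]].to_numpy(dtype=float)
    with warnings.catch_warnings():
        # patients without outcome variation drop out of the conditional
        # likelihood by construction; silence the bookkeeping notice
        warnings.filterwarnings("ignore", message="Dropped .* groups")
        fe_fit = ConditionalLogit(y, x, groups=g).fit(disp=0)
    b_fe = float(fe_fit.params[0])
    var_fe = float(fe_fit.cov_params().iloc[0, 0]
                   if hasattr(fe_fit.cov_params(), "iloc")
                   else np.asarray(fe_fit.cov_params())[0, 0])

    re_model, _ = fit_logistic(frame, [covariate], random_intercept=True,
                               groups=groups)
    b_re = float(re_model.coef[0])
    var_re = float(re_model.cov_params[1, 1])

    dvar = var_fe - var_re
    if b_fe == b_re:
        return TestResult("hausman", 0.0, 1.0, df=1)
    if dvar <= 0:
        return TestResult("hausman", float("nan"), float("nan"), df=1,
                          flag="inconclusive (nonpositive variance difference)")
    h = (b_fe - b_re) ** 2 / dvar
    return TestResult("hausman", float(h), float(stats.chi2.sf(h, df=1)), df=1)


def performance_table(reports: dict[str, PerformanceReport]) -> pd.DataFrame:
    """Stack reports into the familiar AMSA/C1/C2/C3-by-metric layout."""
    rows = []
    for name, r in reports.items():
        rows.append({
            "feature_set": name, "auc": r.auc,
            "sensitivity_pct": r.sensitivity, "specificity_pct": r.specificity,
            "npv_pct": r.npv, "ppv_pct": r.ppv, "pa_pct": r.pa,
            "tp": r.tp, "fp": r.fp, "tn": r.tn, "fn": r.fn,
            "threshold": r.threshold,
        })
    return pd.DataFrame(rows).set_index("feature_set")
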