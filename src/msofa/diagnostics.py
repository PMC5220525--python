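"""Diagnostic-accuracy evaluation of a severity score against ICU outcome.

The positive class is death; a patient is called positive when their score is
at or above a cut-off.  The module provides the empirical ROC curve with a
placement-value (DeLong-type) standard error, the equivalent Mann-Whitney AUC,
a paired z comparison of two correlated AUCs, Youden-index cut-off selection,
2x2 confusion metrics with the diagnostic odds ratio, prevalence-based
predictive values, Pearson correlation and two-group summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .errors import DegenerateDataError, ValidationError
from .types import Outcome

__all__ = [
    "RocResult",
    "ConfusionSummary",
    "AucComparison",
    "GroupSummary",
    "empirical_roc",
    "auc_mann_whitney",
    "compare_auc",
    "youden_cutoff",
    "confusion_at_cutoff",
    "bayes_predictive_values",
    "pearson_correlation",
    "group_summary",
]


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RocResult:
    """Empirical ROC curve for one score.

    ``thresholds`` ascend; positives are scores >= threshold, so sensitivity is
    non-increasing and specificity non-decreasing along the arrays.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_se: float
    ci95: Tuple[float, float]
    chosen_cutoff: float


@dataclass(frozen=True)
class ConfusionSummary:
    """2x2 counts at one cut-off plus the derived diagnostic metrics."""

    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    youden_j: float
    diagnostic_odds_ratio: float


@dataclass(frozen=True)
class AucComparison:
    """Paired (same-patients) comparison of two AUCs by z statistic."""

    auc_a: float
    auc_b: float
    z: float
    p_value: float


@dataclass(frozen=True)
class GroupSummary:
    """Deceased-vs-survived contrast of one variable."""

    n_deceased: int
    n_survived: int
    mean_deceased: float
    sd_deceased: float
    mean_survived: float
    sd_survived: float
    proportion_deceased: float
    p_value: float


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _as_binary(outcomes) -> np.ndarray:
    """Map outcome labels to 1 = deceased (positive), 0 = survived."""
    out = []
    for o in outcomes:
        if isinstance(o, Outcome):
            out.append(1 if o is Outcome.DECEASED else 0)
        elif isinstance(o, str):
            out.append(1 if Outcome(o) is Outcome.DECEASED else 0)
        else:
            v = int(o)
            if v not in (0, 1):
                raise ValidationError(f"binary outcome expected, got {o!r}")
            out.append(v)
    return np.asarray(out, dtype=int)


def _split(scores, outcomes) -> Tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    y = _as_binary(outcomes)
    if scores.shape[0] != y.shape[0]:
        raise ValidationError(
            f"scores ({scores.shape[0]}) and outcomes ({y.shape[0]}) differ in length"
        )
    pos, neg = scores[y == 1], scores[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise DegenerateDataError(
            "both outcome classes (deceased and survived) must be present"
        )
    return pos, neg


def _placements(pos: np.ndarray, neg: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Placement values: for each case, the fraction of controls it beats
    (ties half), and symmetrically for controls."""
    cmp = (pos[:, None] > neg[None, :]).astype(float)
    cmp += 0.5 * (pos[:, None] == neg[None, :])
    return cmp.mean(axis=1), cmp.mean(axis=0)


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------


def auc_mann_whitney(scores, outcomes) -> float:
    """AUC as the Mann-Whitney concordance: the proportion of
    (deceased, survived) pairs in which the deceased patient scores higher,
    ties counted one half."""
    pos, neg = _split(scores, outcomes)
    v10, _ = _placements(pos, neg)
    return float(v10.mean())


def empirical_roc(scores, outcomes) -> RocResult:
    """Empirical ROC curve over midpoint thresholds.

    Candidate cut-offs are midpoints between consecutive distinct observed
    scores plus sentinels below the minimum and above the maximum.  The AUC is
    the trapezoidal area under the (1 - specificity, sensitivity) polyline and
    equals the Mann-Whitney concordance exactly.  The standard error is the
    DeLong placement-value estimate; the 95% CI is Wald, truncated to [0, 1].
    """
    pos, neg = _split(scores, outcomes)
    all_scores = np.concatenate([pos, neg])
    distinct = np.unique(all_scores)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    thresholds = np.concatenate([[distinct[0] - 1.0], mids, [distinct[-1] + 1.0]])

    sens = np.array([(pos >= t).mean() for t in thresholds])
    spec = np.array([(neg < t).mean() for t in thresholds])

    # polyline vertices sorted by FPR then TPR so vertical steps integrate
    # correctly (ties in scores create simultaneous sens/spec jumps)
    fpr = 1.0 - spec
    order = np.lexsort((sens, fpr))
    auc = float(np.trapezoid(sens[order], fpr[order]))

    v10, v01 = _placements(pos, neg)
    m, n = len(pos), len(neg)
    var = 0.0
    if m > 1:
        var += np.var(v10, ddof=1) / m
    if n > 1:
        var += np.var(v01, ddof=1) / n
    se = math.sqrt(var)
    zc = stats.norm.ppf(0.975)
    ci = (max(0.0, auc - zc * se), min(1.0, auc + zc * se))

    # Youden cut-off; undefined (nan) for an uninformative flat curve.
    j = sens + spec - 1.0
    cutoff = float("nan") if np.all(np.isclose(j, j[0])) else float(thresholds[int(np.argmax(j))])

    return RocResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        auc_se=se,
        ci95=ci,
        chosen_cutoff=cutoff,
    )


def youden_cutoff(roc: RocResult) -> float:
    """Cut-off maximizing Youden's J = sensitivity + specificity - 1.

    Ties break toward the lower threshold (favouring sensitivity).
    """
    j = roc.sensitivity + roc.specificity - 1.0
    if np.all(np.isclose(j, j[0])):
        raise DegenerateDataError("degenerate ROC: Youden index is flat")
    return float(roc.thresholds[int(np.argmax(j))])


def compare_auc(scores_a, scores_b, outcomes) -> AucComparison:
    """Paired comparison of two AUCs measured on the same patients.

    DeLong construction: the variance of each AUC and their covariance come
    from the empirical variances/covariances of the placement values, so the
    correlation induced by sharing patients is accounted for.  Two-sided p
    from the standard normal.  Comparing a score with itself returns z = 0,
    p = 1.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if scores_a.shape != scores_b.shape:
        raise ValidationError("paired score vectors must have equal length")
    y = _as_binary(outcomes)
    pos_a, neg_a = scores_a[y == 1], scores_a[y == 0]
    pos_b, neg_b = scores_b[y == 1], scores_b[y == 0]
    if len(pos_a) == 0 or len(neg_a) == 0:
        raise DegenerateDataError("both outcome classes must be present")

    v10_a, v01_a = _placements(pos_a, neg_a)
    v10_b, v01_b = _placements(pos_b, neg_b)
    auc_a, auc_b = float(v10_a.mean()), float(v10_b.mean())

    m, n = len(pos_a), len(neg_a)
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    var_diff = (
        s10[0, 0] / m + s10[1, 1] / m - 2 * s10[0, 1] / m
        + s01[0, 0] / n + s01[1, 1] / n - 2 * s01[0, 1] / n
    )
    diff = auc_a - auc_b
    if var_diff <= 0 or not np.isfinite(var_diff):
        if abs(diff) < 1e-12:
            return AucComparison(auc_a=auc_a, auc_b=auc_b, z=0.0, p_value=1.0)
        raise DegenerateDataError(
            "non-estimable AUC contrast: placement values carry no variance"
        )
    z = diff / math.sqrt(var_diff)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return AucComparison(auc_a=auc_a, auc_b=auc_b, z=float(z), p_value=p)


# ---------------------------------------------------------------------------
# cut-off metrics
# ---------------------------------------------------------------------------


def confusion_at_cutoff(scores, outcomes, cutoff: float) -> ConfusionSummary:
    """All 2x2 metrics at one cut-off (positive call: score >= cutoff).

    The diagnostic odds ratio (TP*TN)/(FP*FN) is reported as ``inf`` when the
    denominator is zero, ``nan`` when the table is doubly degenerate.
    """
    pos, neg = _split(scores, outcomes)
    tp = int((pos >= cutoff).sum())
    fn = len(pos) - tp
    fp = int((neg >= cutoff).sum())
    tn = len(neg) - fp
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    ppv = tp / (tp + fp) if (tp + fp) else float("nan")
    npv = tn / (tn + fn) if (tn + fn) else float("nan")
    if fp * fn > 0:
        dor = (tp * tn) / (fp * fn)
    elif tp * tn > 0:
        dor = float("inf")
    else:
        dor = float("nan")
    return ConfusionSummary(
        tp=tp, fp=fp, fn=fn, tn=tn,
        sensitivity=sens, specificity=spec, ppv=ppv, npv=npv,
        youden_j=sens + spec - 1.0, diagnostic_odds_ratio=dor,
    )


def bayes_predictive_values(
    sensitivity: float, specificity: float, prevalence: float
) -> Tuple[float, float]:
    """Post-test probabilities from sensitivity, specificity and prevalence.

    PPV = se*p / (se*p + (1-sp)(1-p));  NPV = sp(1-p) / (sp(1-p) + (1-se)p).
    """
    for name, v in (("sensitivity", sensitivity), ("specificity", specificity)):
        if not 0.0 <= v <= 1.0:
            raise ValidationError(f"{name}={v!r} out of [0, 1]")
    if not 0.0 < prevalence < 1.0:
        raise ValidationError(
            f"prevalence={prevalence!r} must lie strictly between 0 and 1"
        )
    se, sp, p = sensitivity, specificity, prevalence
    ppv = se * p / (se * p + (1 - sp) * (1 - p))
    npv = sp * (1 - p) / (sp * (1 - p) + (1 - se) * p)
    return ppv, npv


# ---------------------------------------------------------------------------
# association and group contrasts
# ---------------------------------------------------------------------------


def pearson_correlation(x, y) -> Tuple[float, float]:
    """Product-moment correlation with a two-sided p-value (t transform,
    n-2 degrees of freedom)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D vectors of equal length")
    if len(x) < 3:
        raise ValidationError("pearson correlation needs at least 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateDataError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def group_summary(values, outcomes) -> GroupSummary:
    """Deceased-vs-survived means, SDs, prevalence and Welch t p-value."""
    pos, neg = _split(values, outcomes)
    if len(pos) < 2 or len(neg) < 2:
        raise DegenerateDataError("Welch t-test needs at least 2 per group")
    t_res = stats.ttest_ind(pos, neg, equal_var=False)
    return GroupSummary(
        n_deceased=len(pos),
        n_survived=len(neg),
        mean_deceased=float(pos.mean()),
        sd_deceased=float(pos.std(ddof=1)),
        mean_survived=float(neg.mean()),
        sd_survived=float(neg.std(ddof=1)),
        proportion_deceased=len(pos) / (len(pos) + len(neg)),
        p_value=float(t_res.pvalue),
    )
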