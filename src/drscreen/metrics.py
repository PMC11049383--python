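"""Screening-test performance statistics over a 2×2 confusion matrix.

Point estimates follow the standard contingency-table definitions
(sensitivity TP/(TP+FN), specificity TN/(FP+TN), PPV TP/(TP+FP),
NPV TN/(FN+TN), accuracy (TP+TN)/total, F1 = harmonic mean of PPV and
sensitivity).  Proportion confidence intervals use the Wilson score method;
the AUC interval uses the Hanley–McNeil standard error.  The positive and
negative false discovery rates FP/(TP+FP) and FN/(FN+TN) — sometimes loosely
called type-1 and type-2 error rates in the screening literature — are the
complements of PPV and NPV.

Metrics with a zero denominator are reported as ``None`` (not applicable),
never silently as 0 or 1.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata
from statsmodels.stats.proportion import proportion_confint


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")
        if self.total == 0:
            raise ValueError("confusion matrix is empty")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(predicted, actual) -> ConfusionMatrix:
    """Tally a confusion matrix from parallel boolean label sequences
    (True = positive, i.e. develops retinopathy)."""
    p = np.asarray(predicted, dtype=bool)
    a = np.asarray(actual, dtype=bool)
    if p.shape != a.shape:
        raise ValueError("predicted and actual label sequences differ in length")
    if p.size == 0:
        raise ValueError("empty label sequences")
    return ConfusionMatrix(
        tp=int(np.sum(p & a)),
        fp=int(np.sum(p & ~a)),
        tn=int(np.sum(~p & ~a)),
        fn=int(np.sum(~p & a)),
    )


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def sensitivity(cm: ConfusionMatrix) -> float | None:
    return _ratio(cm.tp, cm.tp + cm.fn)


def specificity(cm: ConfusionMatrix) -> float | None:
    return _ratio(cm.tn, cm.fp + cm.tn)


def ppv(cm: ConfusionMatrix) -> float | None:
    return _ratio(cm.tp, cm.tp + cm.fp)


def npv(cm: ConfusionMatrix) -> float | None:
    return _ratio(cm.tn, cm.fn + cm.tn)


def accuracy(cm: ConfusionMatrix) -> float:
    return (cm.tp + cm.tn) / cm.total


def f1(cm: ConfusionMatrix) -> float | None:
    """F1 from full-precision precision and recall, not their rounded forms."""
    p = ppv(cm)
    r = sensitivity(cm)
    if p is None or r is None or (p + r) == 0:
        return None
    return 2 * p * r / (p + r)


def fdr_positive(cm: ConfusionMatrix) -> float | None:
    return _ratio(cm.fp, cm.tp + cm.fp)


def fdr_negative(cm: ConfusionMatrix) -> float | None:
    return _ratio(cm.fn, cm.fn + cm.tn)


def prevalence(cm: ConfusionMatrix) -> float:
    return (cm.tp + cm.fn) / cm.total


def auc_from_scores(scores, actual) -> float:
    """Area under the ROC curve by the Mann–Whitney formulation: the
    probability that a random positive outscores a random negative, with
    ties counted half.  Identical to the trapezoidal ROC area."""
    s = np.asarray(scores, dtype=float)
    a = np.asarray(actual, dtype=bool)
    n_pos = int(a.sum())
    n_neg = int((~a).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(s)  # average ranks handle ties at the half convention
    return float((ranks[a].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _wilson(successes: int, trials: int, alpha: float) -> tuple[float, float] | None:
    if trials == 0:
        return None
    lo, hi = proportion_confint(successes, trials, alpha=alpha, method="wilson")
    return float(lo), float(hi)


def auc_ci_hanley_mcneil(auc: float, n_pos: int, n_neg: int,
                         alpha: float = 0.05) -> tuple[float, float]:
    """Hanley–McNeil normal-approximation interval for an AUC estimate."""
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    var = (
        auc * (1 - auc)
        + (n_pos - 1) * (q1 - auc**2)
        + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)
    se = np.sqrt(max(var, 0.0))
    z = norm.ppf(1 - alpha / 2)
    return (max(0.0, auc - z * se), min(1.0, auc + z * se))


@dataclass
class MetricsReport:
    """The full statistic set over one confusion matrix, each proportion with
    a 95% Wilson interval; AUC present only when per-record scores were
    supplied."""

    cm: ConfusionMatrix
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    f1: float | None
    accuracy: float
    fdr_positive: float | None
    fdr_negative: float | None
    prevalence: float
    ci: dict[str, tuple[float, float] | None]
    auc: float | None = None
    auc_ci: tuple[float, float] | None = None

    #: Table row order used by the renderers.
    ROW_ORDER = (
        "accuracy", "auc", "sensitivity", "specificity", "f1", "ppv", "npv",
        "fdr_positive", "fdr_negative", "prevalence",
    )

    def value(self, name: str):
        return getattr(self, name)


def metrics_report(
    cm: ConfusionMatrix,
    scores=None,
    actual=None,
    alpha: float = 0.05,
) -> MetricsReport:
    """Compute every screening statistic for ``cm``; when per-record scores
    and true labels are given, add the Mann–Whitney AUC with its
    Hanley–McNeil interval."""
    ci = {
        "sensitivity": _wilson(cm.tp, cm.tp + cm.fn, alpha),
        "specificity": _wilson(cm.tn, cm.fp + cm.tn, alpha),
        "ppv": _wilson(cm.tp, cm.tp + cm.fp, alpha),
        "npv": _wilson(cm.tn, cm.fn + cm.tn, alpha),
        "accuracy": _wilson(cm.tp + cm.tn, cm.total, alpha),
        "fdr_positive": _wilson(cm.fp, cm.tp + cm.fp, alpha),
        "fdr_negative": _wilson(cm.fn, cm.fn + cm.tn, alpha),
        "prevalence": _wilson(cm.tp + cm.fn, cm.total, alpha),
        "f1": None,  # no standard closed-form interval; left unreported
    }
    auc = auc_ci = None
    if scores is not None:
        if actual is None:
            raise ValueError("scores supplied without actual labels")
        auc = auc_from_scores(scores, actual)
        a = np.asarray(actual, dtype=bool)
        auc_ci = auc_ci_hanley_mcneil(auc, int(a.sum()), int((~a).sum()), alpha)
    return MetricsReport(
        cm=cm,
        sensitivity=sensitivity(cm),
        specificity=specificity(cm),
        ppv=ppv(cm),
        npv=npv(cm),
        f1=f1(cm),
        accuracy=accuracy(cm),
        fdr_positive=fdr_positive(cm),
        fdr_negative=fdr_negative(cm),
        prevalence=prevalence(cm),
        ci=ci,
        auc=auc,
        auc_ci=auc_ci,
    )


_ROW_TITLES = {
    "accuracy": "Accuracy",
    "auc": "AUC (area under the curve ROC)",
    "sensitivity": "Sensitivity or recall",
    "specificity": "Specificity",
    "f1": "HM or F1 score",
    "ppv": "Precision or positive predictive value",
    "npv": "Negative predictive value",
    "fdr_positive": "Positive false discovery rate",
    "fdr_negative": "Negative false discovery rate",
    "prevalence": "Prevalence",
}


def render_report(report: MetricsReport, digits: int = 2) -> str:
    """Fixed-width human-readable table of a metrics report (2-dp default)."""
    buf = io.StringIO()
    cm = report.cm
    buf.write(f"True positive   {cm.tp:>10d}\n")
    buf.write(f"False positive  {cm.fp:>10d}\n")
    buf.write(f"True negative   {cm.tn:>10d}\n")
    buf.write(f"False negative  {cm.fn:>10d}\n")
    for name in report.ROW_ORDER:
        val = report.value(name)
        title = _ROW_TITLES[name]
        if val is None:
            if name == "auc":
                continue
            buf.write(f"{title:<42s} n/a\n")
            continue
        line = f"{title:<42s} {val:.{digits}f}"
        interval = report.auc_ci if name == "auc" else report.ci.get(name)
        if interval is not None:
            line += f" (95% CI, {interval[0]:.{digits}f}-{interval[1]:.{digits}f})"
        buf.write(line + "\n")
    return buf.getvalue()


def report_frame(report: MetricsReport):
    """Long-format export of a report: one row per statistic."""
    import pandas as pd

    rows = []
    for name in report.ROW_ORDER:
        val = report.value(name)
        interval = report.auc_ci if name == "auc" else report.ci.get(name)
        rows.append({
            "metric": name,
            "value": np.nan if val is None else val,
            "ci_low": np.nan if interval is None else interval[0],
            "ci_high": np.nan if interval is None else interval[1],
        })
    return pd.DataFrame(rows)
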