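"""Classifier evaluation: 12-metric panel, ROC/PR sweeps, threshold stratification.

Conventions shared across the module:

* Binary classification is strict: predicted pathogenic iff score > t.
  The same strictness applies to the three-way stratification bounds
  (pathogenic iff Pr > pathogenic_cutoff, benign iff Pr < benign_cutoff,
  VUS otherwise).
* Rows with a missing score (NaN) are excluded from every metric and
  counted in the ``missing`` field of the report.
* Undefined ratios (zero denominator) are reported as None, never 0.
* Percentages are kept at full precision internally and rounded to two
  decimals only for tabular output; MCC/AUC/F1/AP are rounded to three.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd


class EvaluationError(ValueError):
    pass


def _clean(scores, labels) -> tuple[np.ndarray, np.ndarray, int]:
    """Aligned scored rows plus the count of unscored rows."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise EvaluationError("scores and labels must be aligned 1-D arrays")
    if scores.size == 0:
        raise EvaluationError("empty input")
    if not np.isin(labels, (0, 1)).all():
        raise EvaluationError("labels must be binary 0/1")
    keep = ~np.isnan(scores)
    return scores[keep], labels[keep].astype(int), int((~keep).sum())


# ---------------------------------------------------------------------------
# Confusion matrix and the metric panel
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise EvaluationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.tn + self.fp


def confusion_at_threshold(scores, labels, t: float) -> ConfusionMatrix:
    """Counts at the strict rule score > t; unscored rows are excluded."""
    s, y, _ = _clean(scores, labels)
    if s.size == 0:
        raise EvaluationError("no scored rows")
    pred = s > t
    return ConfusionMatrix(
        tp=int((pred & (y == 1)).sum()),
        tn=int((~pred & (y == 0)).sum()),
        fp=int((pred & (y == 0)).sum()),
        fn=int((~pred & (y == 1)).sum()),
    )


@dataclass
class MetricReport:
    """The 12-field evaluation panel.

    ``missing`` counts unscored rows; precision/npv/specificity/fpr/recall/
    fnr/accuracy are percentages in [0,100]; mcc in [-1,1]; auc, f1 and
    average_precision in [0,1]. None marks an undefined ratio.
    """

    missing: int | None = None
    precision: float | None = None
    npv: float | None = None
    specificity: float | None = None
    fpr: float | None = None
    recall: float | None = None
    fnr: float | None = None
    accuracy: float | None = None
    mcc: float | None = None
    auc: float | None = None
    f1: float | None = None
    average_precision: float | None = None

    def rounded(self) -> dict:
        """Table-style rounding: percentages to 2 dp, unit-scale to 3 dp."""
        def r2(v):
            return None if v is None else round(v, 2)

        def r3(v):
            return None if v is None else round(v, 3)

        return {
            "missing": self.missing,
            "precision": r2(self.precision),
            "npv": r2(self.npv),
            "specificity": r2(self.specificity),
            "fpr": r2(self.fpr),
            "recall": r2(self.recall),
            "fnr": r2(self.fnr),
            "accuracy": r2(self.accuracy),
            "mcc": r3(self.mcc),
            "auc": r3(self.auc),
            "f1": r3(self.f1),
            "average_precision": r3(self.average_precision),
        }


def metrics_from_confusion(cm: ConfusionMatrix) -> MetricReport:
    """Standard-definition metrics from raw counts.

    precision = TP/(TP+FP); NPV = TN/(TN+FN); specificity = TN/(TN+FP);
    FPR = FP/(TN+FP); recall = TP/(TP+FN); FNR = FN/(TP+FN);
    accuracy = (TP+TN)/total; F1 = 2PR/(P+R);
    MCC = (TP*TN - FP*FN)/sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).
    Ratios with a zero denominator come back as None.
    """
    if cm.total == 0:
        raise EvaluationError("all-zero confusion matrix")

    def ratio(num, den):
        return 100.0 * num / den if den else None

    precision = ratio(cm.tp, cm.tp + cm.fp)
    npv = ratio(cm.tn, cm.tn + cm.fn)
    specificity = ratio(cm.tn, cm.negatives)
    fpr = ratio(cm.fp, cm.negatives)
    recall = ratio(cm.tp, cm.positives)
    fnr = ratio(cm.fn, cm.positives)
    accuracy = 100.0 * (cm.tp + cm.tn) / cm.total
    f1 = None
    if precision is not None and recall is not None and precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall) / 100.0
    mcc_den = (
        (cm.tp + cm.fp) * (cm.tp + cm.fn) * (cm.tn + cm.fp) * (cm.tn + cm.fn)
    )
    mcc = (
        (cm.tp * cm.tn - cm.fp * cm.fn) / math.sqrt(mcc_den) if mcc_den else None
    )
    return MetricReport(
        precision=precision,
        npv=npv,
        specificity=specificity,
        fpr=fpr,
        recall=recall,
        fnr=fnr,
        accuracy=accuracy,
        mcc=mcc,
        f1=f1,
    )


# ---------------------------------------------------------------------------
# ROC / PR sweeps
# ---------------------------------------------------------------------------

@dataclass
class CurveData:
    kind: str  # "roc" | "pr"
    thresholds: np.ndarray  # strictly decreasing
    x: np.ndarray  # FPR (roc) or recall (pr)
    y: np.ndarray  # TPR (roc) or precision (pr)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "x": self.x, "y": self.y}
        )


def _grouped_counts(s: np.ndarray, y: np.ndarray):
    """Distinct scores descending with per-group positive/negative counts."""
    order = np.argsort(-s, kind="mergesort")
    s, y = s[order], y[order]
    uniq, start = np.unique(-s, return_index=True)
    uniq = -uniq  # descending distinct scores
    bounds = np.append(start, len(s))
    tp_g = np.array(
        [int(y[a:b].sum()) for a, b in zip(bounds[:-1], bounds[1:])]
    )
    n_g = np.diff(bounds)
    return uniq, tp_g, n_g - tp_g


def roc_auc(scores, labels) -> tuple[CurveData, float]:
    """ROC sweep with trapezoidal AUC; tied scores form one sweep step.

    The curve starts at (0,0) (threshold = max score: nothing exceeds it
    under the strict > rule) and ends at (1,1) via a final threshold one
    unit below the minimum score. The trapezoidal area equals the
    tie-corrected normalized Mann-Whitney U statistic.
    """
    s, y, _ = _clean(scores, labels)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise EvaluationError("both classes required for a ROC curve")
    uniq, tp_g, fp_g = _grouped_counts(s, y)
    # point at threshold uniq[i]: positives are scores strictly above it,
    # i.e. groups 0..i-1; the appended final threshold admits everything
    cum_tp = np.concatenate(([0], np.cumsum(tp_g)))
    cum_fp = np.concatenate(([0], np.cumsum(fp_g)))
    thresholds = np.concatenate((uniq, [uniq[-1] - 1.0]))
    tpr = cum_tp / n1
    fpr = cum_fp / n0
    auc = float(np.trapezoid(tpr, fpr))
    return CurveData("roc", thresholds, fpr, tpr), auc


def pr_average_precision(scores, labels) -> tuple[CurveData, float]:
    """PR sweep and step-wise average precision.

    AP = sum_k (R_k - R_{k-1}) P_k over distinct descending score
    thresholds, each step admitting its whole tie group.
    """
    s, y, _ = _clean(scores, labels)
    n1 = int(y.sum())
    if n1 == 0:
        raise EvaluationError("at least one positive required for a PR curve")
    uniq, tp_g, fp_g = _grouped_counts(s, y)
    cum_tp = np.cumsum(tp_g)
    cum_fp = np.cumsum(fp_g)
    recall = cum_tp / n1
    precision = cum_tp / (cum_tp + cum_fp)
    prev_r = np.concatenate(([0.0], recall[:-1]))
    ap = float(np.sum((recall - prev_r) * precision))
    return CurveData("pr", uniq, recall, precision), ap


def optimal_threshold(curve: CurveData) -> float:
    """Threshold maximizing Youden's J = TPR - FPR on a ROC sweep.

    Ties are broken toward the smallest threshold.
    """
    if curve.kind != "roc":
        raise EvaluationError("optimal_threshold expects a ROC curve")
    if len(curve.thresholds) < 2:
        raise EvaluationError("degenerate ROC curve")
    j = curve.y - curve.x
    best = float(j.max())
    # thresholds are strictly decreasing: the last maximizer is the smallest
    idx = int(np.flatnonzero(j >= best - 1e-15)[-1])
    return float(curve.thresholds[idx])


# ---------------------------------------------------------------------------
# Composite reports
# ---------------------------------------------------------------------------

def full_report(scores, labels, threshold: float = 0.5) -> MetricReport:
    """The complete 12-metric panel at a fixed classification threshold."""
    _, _, n_missing = _clean(scores, labels)
    cm = confusion_at_threshold(scores, labels, threshold)
    report = metrics_from_confusion(cm)
    report.missing = n_missing
    _, report.auc = roc_auc(scores, labels)
    _, report.average_precision = pr_average_precision(scores, labels)
    return report


@dataclass(frozen=True)
class StratificationPolicy:
    """Three-way cutoffs: pathogenic above, benign below, VUS between.

    Defaults follow the clinical-guideline convention Pr > 0.75 pathogenic,
    Pr < 0.15 benign, 0.15 <= Pr <= 0.75 indeterminate.
    """

    pathogenic_cutoff: float = 0.75
    benign_cutoff: float = 0.15

    def __post_init__(self) -> None:
        if not (0 <= self.benign_cutoff < self.pathogenic_cutoff <= 1):
            raise EvaluationError(
                "require 0 <= benign_cutoff < pathogenic_cutoff <= 1"
            )


@dataclass
class StratifiedReport:
    overall_accuracy: float
    proportion_classified: float
    accuracy_of_recommended: float | None
    proportion_indeterminate: float
    recall: float | None
    precision: float | None
    specificity: float | None
    npv: float | None
    n_total: int
    n_classified: int


def stratified_report(
    scores, labels, policy: StratificationPolicy | None = None
) -> StratifiedReport:
    """Three-way classification report under recommended thresholds.

    Classified rows are those called pathogenic (Pr > pathogenic_cutoff) or
    benign (Pr < benign_cutoff); the rest are indeterminate (VUS). Overall
    accuracy counts indeterminate calls as incorrect; the remaining metrics
    are computed among classified rows only.
    """
    if policy is None:
        policy = StratificationPolicy()
    s, y, _ = _clean(scores, labels)
    if s.size == 0:
        raise EvaluationError("no scored rows")
    pred_path = s > policy.pathogenic_cutoff
    pred_benign = s < policy.benign_cutoff
    classified = pred_path | pred_benign
    correct = (pred_path & (y == 1)) | (pred_benign & (y == 0))
    n = len(s)
    n_cls = int(classified.sum())
    tp = int((pred_path & (y == 1)).sum())
    fp = int((pred_path & (y == 0)).sum())
    tn = int((pred_benign & (y == 0)).sum())
    fn = int((pred_benign & (y == 1)).sum())

    def pct(num, den):
        return 100.0 * num / den if den else None

    return StratifiedReport(
        overall_accuracy=100.0 * correct.sum() / n,
        proportion_classified=100.0 * n_cls / n,
        accuracy_of_recommended=pct(int(correct.sum()), n_cls),
        proportion_indeterminate=100.0 * (n - n_cls) / n,
        recall=pct(tp, tp + fn),
        precision=pct(tp, tp + fp),
        specificity=pct(tn, tn + fp),
        npv=pct(tn, tn + fn),
        n_total=n,
        n_classified=n_cls,
    )


def score_distribution_export(
    scores, labels, threshold: float = 0.5
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Long-format (class, score) table plus per-class misclassification.

    Benign misclassification is FP/(FP+TN) at the strict > threshold;
    pathogenic misclassification is FN/(TP+FN). Suitable for violin plots.
    """
    s, y, _ = _clean(scores, labels)
    table = pd.DataFrame(
        {
            "label_class": np.where(y == 1, "pathogenic", "benign"),
            "score": s,
        }
    )
    cm = confusion_at_threshold(s, y, threshold)
    rates = {
        "benign_misclassification": (
            100.0 * cm.fp / cm.negatives if cm.negatives else None
        ),
        "pathogenic_misclassification": (
            100.0 * cm.fn / cm.positives if cm.positives else None
        ),
    }
    return table, rates


# ---------------------------------------------------------------------------
# Tabular output
# ---------------------------------------------------------------------------

_UNDEF = "."


def write_metric_reports(reports: dict[str, MetricReport], path) -> None:
    """One row per tool, columns in the panel's table order."""
    cols = [
        "missing", "precision", "npv", "specificity", "fpr", "recall",
        "fnr", "accuracy", "mcc", "auc", "f1", "average_precision",
    ]
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("\t".join(["method"] + cols) + "\n")
        for name, rep in reports.items():
            r = rep.rounded()
            fh.write(
                "\t".join(
                    [name]
                    + [_UNDEF if r[c] is None else str(r[c]) for c in cols]
                )
                + "\n"
            )


def write_stratified_reports(reports: dict[str, StratifiedReport], path) -> None:
    cols = [
        "overall_accuracy", "proportion_classified", "accuracy_of_recommended",
        "proportion_indeterminate", "recall", "precision", "specificity", "npv",
    ]
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("\t".join(["method"] + cols) + "\n")
        for name, rep in reports.items():
            cells = [name]
            for c in cols:
                v = getattr(rep, c)
                cells.append(_UNDEF if v is None else str(round(v, 2)))
            fh.write("\t".join(cells) + "\n")


def write_curve(curve: CurveData, path) -> None:
    curve.to_frame().to_csv(path, sep="\t", index=False)
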