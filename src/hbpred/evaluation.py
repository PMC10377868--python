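"""Confusion-matrix metrics, ROC/auROC, and cross-validation summaries.

Conventions: TP and TN count correctly predicted positives (HBPs) and
negatives; FP counts negatives recognised as positives; FN counts positives
identified as negatives. Sensitivity Sn = TP/(TP+FN), specificity
Sp = TN/(TN+FP), overall accuracy OA = (TP+TN)/N, and the Matthews
correlation coefficient

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TN+FN)(TP+FN)(TN+FP)).

A metric whose denominator is zero is reported as NaN with a logged
warning rather than silently coerced to 0, so degenerate folds stay
visible. auROC is computed by trapezoidal integration of the
threshold-swept ROC curve and equals the Mann-Whitney probability that a
random positive outscores a random negative (ties counted one half).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import auc, roc_curve as _sk_roc_curve

logger = logging.getLogger(__name__)

METRIC_NAMES = ("sn", "sp", "oa", "mcc", "auroc")


class EvaluationError(ValueError):
    """Raised on inconsistent evaluation inputs."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n_positives(self) -> int:
        return self.tp + self.fn

    @property
    def n_negatives(self) -> int:
        return self.tn + self.fp

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricReport:
    sn: float
    sp: float
    oa: float
    mcc: float
    auroc: float | None = None

    def as_dict(self) -> dict[str, float]:
        d = {"sn": self.sn, "sp": self.sp, "oa": self.oa, "mcc": self.mcc}
        if self.auroc is not None:
            d["auroc"] = self.auroc
        return d


def confusion(y_true: Sequence[int], y_pred: Sequence[int]) -> ConfusionCounts:
    """Count TP/FP/TN/FN for binary truth and predictions (positive = 1)."""
    t = np.asarray(y_true, dtype=int)
    p = np.asarray(y_pred, dtype=int)
    if t.shape != p.shape:
        raise EvaluationError(
            f"length mismatch: {t.shape[0]} truths vs {p.shape[0]} predictions"
        )
    return ConfusionCounts(
        tp=int(np.sum((t == 1) & (p == 1))),
        fp=int(np.sum((t == 0) & (p == 1))),
        tn=int(np.sum((t == 0) & (p == 0))),
        fn=int(np.sum((t == 1) & (p == 0))),
    )


def _safe_div(num: float, den: float, name: str) -> float:
    if den == 0:
        logger.warning("%s undefined: zero denominator", name)
        return math.nan
    return num / den


def metrics(c: ConfusionCounts) -> MetricReport:
    """Sn, Sp, OA and MCC from confusion counts (auROC not included)."""
    mcc_den = math.sqrt(
        float(c.tp + c.fp) * (c.tn + c.fn) * (c.tp + c.fn) * (c.tn + c.fp)
    )
    return MetricReport(
        sn=_safe_div(c.tp, c.tp + c.fn, "Sn"),
        sp=_safe_div(c.tn, c.tn + c.fp, "Sp"),
        oa=_safe_div(c.tp + c.tn, c.total, "OA"),
        mcc=_safe_div(c.tp * c.tn - c.fp * c.fn, mcc_den, "MCC"),
    )


def roc_points(
    scores: Sequence[float], y_true: Sequence[int]
) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC curve (FPR, TPR arrays) and auROC from a threshold sweep.

    Tied scores are grouped; the area is the trapezoidal integral and
    coincides with the concordance probability. Requires at least one
    member of each class.
    """
    y = np.asarray(y_true, dtype=int)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise EvaluationError("ROC requires both classes present")
    fpr, tpr, _ = _sk_roc_curve(y, s)
    return fpr, tpr, float(auc(fpr, tpr))


def auroc(scores: Sequence[float], y_true: Sequence[int]) -> float:
    """Area under the ROC curve (see :func:`roc_points`)."""
    return roc_points(scores, y_true)[2]


def evaluate_predictions(
    y_true: Sequence[int],
    y_pred: Sequence[int],
    scores: Sequence[float] | None = None,
) -> MetricReport:
    """Full metric battery from labels (and, when given, scores for auROC)."""
    report = metrics(confusion(y_true, y_pred))
    if scores is not None:
        report.auroc = auroc(scores, y_true)
    return report


@dataclass
class CVSummary:
    """Per-fold metrics with their mean and standard deviation."""

    per_fold: pd.DataFrame
    mean: pd.Series = field(init=False)
    std: pd.Series = field(init=False)
    ddof: int = 1

    def __post_init__(self) -> None:
        if len(self.per_fold) < 2:
            raise EvaluationError("cross-validation summary needs >= 2 folds")
        self.mean = self.per_fold.mean()
        self.std = self.per_fold.std(ddof=self.ddof)

    def formatted(self, metric: str) -> str:
        return f"{self.mean[metric]:.3f} ± {self.std[metric]:.3f}"

    def as_dict(self) -> dict:
        return {
            "per_fold": self.per_fold.to_dict(orient="records"),
            "mean": self.mean.to_dict(),
            "std": self.std.to_dict(),
            "ddof": self.ddof,
        }


def cv_summary(per_fold: Iterable[MetricReport | dict], ddof: int = 1) -> CVSummary:
    """Summarise per-fold reports as mean +/- standard deviation per metric.

    ``ddof=1`` (sample standard deviation) is the default; set ``ddof=0``
    for the population form.
    """
    rows = [
        r.as_dict() if isinstance(r, MetricReport) else dict(r) for r in per_fold
    ]
    if not rows:
        raise EvaluationError("empty fold list")
    return CVSummary(per_fold=pd.DataFrame(rows), ddof=ddof)


def render_report_table(rows: Iterable[dict]) -> str:
    """Render evaluation rows as a fixed-layout TSV report.

    Columns: Algorithm, Feature, Sn (%), Sp (%), MCC, OA (%) — percent
    metrics to 1 decimal place, MCC to 3. Byte-stable for identical input.
    """
    lines = ["Algorithm\tFeature\tSn (%)\tSp (%)\tMCC\tOA (%)"]
    for row in rows:
        lines.append(
            "\t".join(
                [
                    str(row["algorithm"]),
                    str(row["feature"]),
                    f"{100 * row['sn']:.1f}",
                    f"{100 * row['sp']:.1f}",
                    f"{row['mcc']:.3f}",
                    f"{100 * row['oa']:.1f}",
                ]
            )
        )
    return "\n".join(lines) + "\n"
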