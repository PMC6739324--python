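"""Binary classification measures for 6mA site prediction.

Threshold metrics (Sn, Sp, ACC, MCC) follow the error-fraction formulation:
with N+ positives of which FN are missed and N- negatives of which FP are
called positive,

    Sn  = 1 - FN/N+
    Sp  = 1 - FP/N-
    ACC = 1 - (FN + FP)/(N+ + N-)
    MCC = (1 - (FN/N+ + FP/N-)) /
          sqrt((1 + (FP - FN)/N+) * (1 + (FN - FP)/N-))

which is algebraically identical to the familiar confusion-matrix MCC
(TP*TN - FP*FN)/sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).

Threshold-free measures (ROC/AUC, precision-recall/average precision) are
computed over grouped score thresholds via scikit-learn, with trapezoidal
integration for AUC and the step-sum definition for AP.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import average_precision_score, precision_recall_curve, roc_curve

from .io import NEGATIVE, POSITIVE

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    """Class sizes and error counts of a hard binary prediction.

    ``fn`` is the number of positives predicted negative; ``fp`` the number
    of negatives predicted positive.
    """

    n_pos: int
    n_neg: int
    fn: int
    fp: int

    def __post_init__(self) -> None:
        if not (0 <= self.fn <= self.n_pos):
            raise ValueError(f"fn={self.fn} outside [0, n_pos={self.n_pos}]")
        if not (0 <= self.fp <= self.n_neg):
            raise ValueError(f"fp={self.fp} outside [0, n_neg={self.n_neg}]")

    @property
    def tp(self) -> int:
        return self.n_pos - self.fn

    @property
    def tn(self) -> int:
        return self.n_neg - self.fp


@dataclass
class EvaluationReport:
    """Scalar measures plus the ROC and precision-recall curves."""

    sn: float
    sp: float
    acc: float
    mcc: float
    f1: float
    auc: Optional[float] = None
    ap: Optional[float] = None
    roc_points: Optional[list[tuple[float, float]]] = None
    pr_points: Optional[list[tuple[float, float]]] = None

    def scalars(self) -> dict[str, float]:
        out = {"sn": self.sn, "sp": self.sp, "acc": self.acc, "mcc": self.mcc, "f1": self.f1}
        if self.auc is not None:
            out["auc"] = self.auc
        if self.ap is not None:
            out["ap"] = self.ap
        return out

    def to_json(self, path: str | Path | None = None, include_curves: bool = True) -> str:
        payload = {k: v for k, v in asdict(self).items() if v is not None}
        if not include_curves:
            payload.pop("roc_points", None)
            payload.pop("pr_points", None)
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    def curves_to_tsv(self, roc_path: str | Path, pr_path: str | Path) -> None:
        if self.roc_points is None or self.pr_points is None:
            raise ValueError("report carries no curves")
        with open(roc_path, "w") as fh:
            fh.write("fpr\ttpr\n")
            for x, y in self.roc_points:
                fh.write(f"{x:.10g}\t{y:.10g}\n")
        with open(pr_path, "w") as fh:
            fh.write("recall\tprecision\n")
            for x, y in self.pr_points:
                fh.write(f"{x:.10g}\t{y:.10g}\n")


def _as_binary(labels: Sequence) -> np.ndarray:
    """Map labels to {0, 1} with the 6mA (positive) class as 1."""
    arr = np.asarray(labels)
    if arr.size == 0:
        raise ValueError("empty labels")
    if arr.dtype.kind in "UO":
        mapping = {POSITIVE: 1, NEGATIVE: 0, "1": 1, "0": 0}
        try:
            return np.array([mapping[str(x)] for x in arr], dtype=int)
        except KeyError as exc:
            raise ValueError(f"unknown label {exc.args[0]!r}") from None
    return arr.astype(int)


def confusion_counts(labels: Sequence, predictions: Sequence) -> ConfusionCounts:
    """Count class sizes and both error types from hard predictions."""
    y = _as_binary(labels)
    p = _as_binary(predictions)
    if y.shape != p.shape:
        raise ValueError(f"labels ({y.size}) and predictions ({p.size}) differ in length")
    return ConfusionCounts(
        n_pos=int((y == 1).sum()),
        n_neg=int((y == 0).sum()),
        fn=int(((y == 1) & (p == 0)).sum()),
        fp=int(((y == 0) & (p == 1)).sum()),
    )


def point_metrics(c: ConfusionCounts) -> tuple[float, float, float, float, float]:
    """Sensitivity, specificity, accuracy, MCC and F1 from counts.

    MCC with a degenerate (zero) denominator is defined as 0 and logged;
    F1 with no predicted and no actual positives is likewise 0.
    """
    if c.n_pos == 0 or c.n_neg == 0:
        raise ValueError("both classes must be represented")
    sn = 1.0 - c.fn / c.n_pos
    sp = 1.0 - c.fp / c.n_neg
    acc = 1.0 - (c.fn + c.fp) / (c.n_pos + c.n_neg)

    denom_sq = (1.0 + (c.fp - c.fn) / c.n_pos) * (1.0 + (c.fn - c.fp) / c.n_neg)
    if denom_sq <= 0:
        logger.info("MCC denominator degenerate (counts %s); defining MCC = 0", c)
        mcc = 0.0
    else:
        mcc = (1.0 - (c.fn / c.n_pos + c.fp / c.n_neg)) / math.sqrt(denom_sq)

    predicted_pos = c.tp + c.fp
    if predicted_pos == 0 or (c.tp == 0 and c.fn == 0):
        f1 = 0.0
    else:
        precision = c.tp / predicted_pos
        recall = sn
        f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return sn, sp, acc, mcc, f1


def roc_auc(labels: Sequence, scores: Sequence[float]) -> tuple[float, list[tuple[float, float]]]:
    """ROC curve and trapezoidal AUC over grouped score thresholds.

    Tied scores collapse into a single threshold step, making the curve
    independent of sample order. Equivalent to the Mann-Whitney statistic
    U/(n_pos*n_neg) with ties counted 1/2.
    """
    y = _as_binary(labels)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("labels and scores differ in length")
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    if y.min() == y.max():
        raise ValueError("both classes must be present to compute a ROC curve")
    fpr, tpr, _ = roc_curve(y, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return auc, list(zip(fpr.tolist(), tpr.tolist()))


def average_precision(
    labels: Sequence, scores: Sequence[float]
) -> tuple[float, list[tuple[float, float]]]:
    """Average precision AP = sum over descending thresholds of
    (R_i - R_{i-1}) * P_i, with the precision-recall curve."""
    y = _as_binary(labels)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("labels and scores differ in length")
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    if y.min() == y.max():
        raise ValueError("both classes must be present to compute precision-recall")
    ap = float(average_precision_score(y, s))
    precision, recall, _ = precision_recall_curve(y, s)
    return ap, list(zip(recall.tolist(), precision.tolist()))


def evaluate_scores(
    labels: Sequence, scores: Sequence[float], threshold: float = 0.5
) -> EvaluationReport:
    """Full report from continuous scores: hard labels at ``threshold``
    (score >= threshold is called positive) plus ROC/AUC and PR/AP."""
    s = np.asarray(scores, dtype=float)
    hard = (s >= threshold).astype(int)
    counts = confusion_counts(labels, hard)
    sn, sp, acc, mcc, f1 = point_metrics(counts)
    auc, roc_points = roc_auc(labels, s)
    ap, pr_points = average_precision(labels, s)
    return EvaluationReport(
        sn=sn, sp=sp, acc=acc, mcc=mcc, f1=f1,
        auc=auc, ap=ap, roc_points=roc_points, pr_points=pr_points,
    )
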