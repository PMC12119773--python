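"""Two-stage probability averaging and the classification metric suite.

Probability averaging beats majority voting by weighing each model's
certainty: e.g. members (0.45,0.55), (0.95,0.05), (0.48,0.52) vote 2-1 for
class 1, but the averaged probabilities (0.627, 0.373) select class 0 because
the dissenting model is far more certain. The two-stage scheme first averages
the fold models within each (crop strategy, view) group, then averages the
group means for the final decision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

from .datatypes import ClassProbabilities

logger = logging.getLogger(__name__)


def average_probabilities(members: list[ClassProbabilities]) -> ClassProbabilities:
    """Arithmetic per-class mean of the member probability vectors."""
    if not members:
        raise ValueError("cannot average an empty member list")
    lengths = {len(m.p) for m in members}
    if len(lengths) != 1:
        raise ValueError("members must share the class count")
    p = np.mean([m.p for m in members], axis=0)
    p = p / p.sum()  # guard accumulated rounding; members are on the simplex
    return ClassProbabilities(p, provenance=("average", len(members)))


def decide(p: ClassProbabilities) -> int:
    """Class with the higher probability; exact tie resolves to class 0."""
    arr = p.p
    if arr[0] == arr.max() and np.sum(arr == arr.max()) > 1:
        logger.warning("probability tie %s; deciding class 0", arr)
        return 0
    return int(np.argmax(arr))


@dataclass
class EnsembleResult:
    averaged_p: ClassProbabilities
    decision: int
    members: list[tuple]
    group_means: dict[tuple, ClassProbabilities] = field(default_factory=dict)


def two_stage_ensemble(
    per_model: dict[tuple, ClassProbabilities]
) -> EnsembleResult:
    """Average fold members within each (crop, view) group, then across groups.

    Keys are (fold, crop, view) tuples; the grid may be partial as long as at
    least one member exists. With a complete balanced grid the result equals
    the flat mean of all members.
    """
    if not per_model:
        raise ValueError("empty model grid")
    groups: dict[tuple, list[ClassProbabilities]] = {}
    for (fold, crop, view), probs in per_model.items():
        groups.setdefault((crop, view), []).append(probs)
    group_means = {g: average_probabilities(ms) for g, ms in groups.items()}
    final = average_probabilities(list(group_means.values()))
    return EnsembleResult(
        averaged_p=final,
        decision=decide(final),
        members=sorted(per_model.keys()),
        group_means=group_means,
    )


def balanced_accuracy(sensitivity: float, specificity: float) -> float:
    """BAC: the arithmetic mean of sensitivity and specificity."""
    return (sensitivity + specificity) / 2.0


def f1_from(precision: float, sensitivity: float) -> float:
    """F1 as the harmonic mean of precision and sensitivity (recall)."""
    if precision + sensitivity == 0:
        return 0.0
    return 2.0 * precision * sensitivity / (precision + sensitivity)


@dataclass
class MetricsReport:
    f1: float
    sensitivity: float
    specificity: float
    precision: float
    accuracy: float
    bac: float
    auc: float | None
    tp: int
    fp: int
    tn: int
    fn: int
    roc: list[tuple[float, float]] = field(default_factory=list)

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("f1", "sensitivity", "specificity", "precision", "accuracy",
              "bac", "auc", "tp", "fp", "tn", "fn")}
        return d


def compute_metrics(
    labels, probs: list[ClassProbabilities]
) -> MetricsReport:
    """Confusion counts from argmax decisions, rates, and Mann-Whitney AUC.

    The AUC scores the positive-class probability (ties count 0.5, matching
    the rank-sum statistic); the ROC sweeps all unique scores. With a
    single-class label vector the AUC is reported as ``None`` with a warning.
    """
    y = np.asarray(labels, dtype=int)
    if y.ndim != 1 or len(y) != len(probs):
        raise ValueError("labels and probs must be 1D and equal length")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary")
    scores = np.array([p.p[1] for p in probs])
    pred = np.array([decide(p) for p in probs])

    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    acc = (tp + tn) / len(y)

    if len(np.unique(y)) < 2:
        logger.warning("single-class labels: AUC undefined, reported as missing")
        auc, roc = None, []
    else:
        auc = float(roc_auc_score(y, scores))
        fpr, tpr, _ = roc_curve(y, scores)
        roc = list(zip(fpr.tolist(), tpr.tolist()))

    return MetricsReport(
        f1=f1_from(prec, sens), sensitivity=sens, specificity=spec,
        precision=prec, accuracy=acc, bac=balanced_accuracy(sens, spec),
        auc=auc, tp=tp, fp=fp, tn=tn, fn=fn, roc=roc,
    )


def confusion_matrix_normalized(report: MetricsReport) -> np.ndarray:
    """Row-normalized 2x2 confusion matrix; rows are true classes (0 then 1).

    An empty row (no cases of that class) is reported as NaN.
    """
    counts = np.array(
        [[report.tn, report.fp], [report.fn, report.tp]], dtype=float
    )
    sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(sums > 0, counts / sums, np.nan)
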