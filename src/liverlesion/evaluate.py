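"""Confusion-matrix metrics, one-vs-rest ROC analysis and the benign/malignant split.

The per-class "specificity" reported alongside the confusion matrix in the
reference protocol is numerically the column-wise positive predictive
value (diagonal count over predicted-column total), not the textbook
TN/(TN+FP) specificity. Both are computed here: the former is named
``specificity_as_printed`` for honest reproduction, the latter
``specificity_tn`` for completeness.

ROC curves are one-vs-rest on the ensemble's class probabilities: the
positive score of a lesion for class k is ``p_k`` (the other four classes
pooled as the rest class); for the benign/malignant problem the malignant
score is ``p_hcc + p_metastasis``. The operating point maximizes Youden's
J = TPR - FPR (lowest threshold on ties).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .classify import FoldResult
from .core import BENIGN_CLASSES, CLASS_ORDER, MALIGNANT_CLASSES


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round half away from zero (report convention), e.g. 0.625 -> 0.63."""
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass
class ConfusionMatrix:
    """K x K integer counts; rows are true classes, columns predicted classes."""

    counts: np.ndarray
    class_order: tuple[str, ...] = CLASS_ORDER

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.class_order)
        if self.counts.shape != (k, k):
            raise ValueError(f"expected a {k}x{k} matrix, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion(
    true_labels: list[str],
    predicted_labels: list[str],
    class_order: tuple[str, ...] = CLASS_ORDER,
) -> ConfusionMatrix:
    """Count (true, predicted) pairs into a confusion matrix."""
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label lists must have equal length")
    index = {c: i for i, c in enumerate(class_order)}
    counts = np.zeros((len(class_order), len(class_order)), dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        if t not in index or p not in index:
            raise ValueError(f"unknown label in pair ({t!r}, {p!r})")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts, class_order)


def confusion_from_folds(folds: list[FoldResult]) -> ConfusionMatrix:
    return confusion([f.true_label for f in folds], [f.predicted_label for f in folds])


def _ratio(num: float, denom: float) -> float:
    return num / denom if denom > 0 else 0.0


@dataclass
class ClassMetrics:
    """Per-class and overall metrics of a confusion matrix (raw, unrounded)."""

    class_order: tuple[str, ...]
    sensitivity: dict[str, float]
    specificity_as_printed: dict[str, float]  # column-wise PPV
    specificity_tn: dict[str, float]  # textbook TN / (TN + FP)
    one_vs_other_accuracy: dict[str, float]
    overall_accuracy: float

    def rounded(self, decimals: int = 2) -> "ClassMetrics":
        rd = lambda d: {k: round_half_up(v, decimals) for k, v in d.items()}
        return ClassMetrics(
            class_order=self.class_order,
            sensitivity=rd(self.sensitivity),
            specificity_as_printed=rd(self.specificity_as_printed),
            specificity_tn=rd(self.specificity_tn),
            one_vs_other_accuracy=rd(self.one_vs_other_accuracy),
            overall_accuracy=round_half_up(self.overall_accuracy, decimals),
        )

    def as_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity_as_printed": self.specificity_as_printed,
            "specificity_tn": self.specificity_tn,
            "one_vs_other_accuracy": self.one_vs_other_accuracy,
            "overall_accuracy": self.overall_accuracy,
        }


def class_metrics(cm: ConfusionMatrix) -> ClassMetrics:
    """Sensitivity, both specificities, one-vs-other accuracy and overall accuracy."""
    counts = cm.counts
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    row_sums = counts.sum(axis=1)
    col_sums = counts.sum(axis=0)
    diag = np.diag(counts)

    sens, spec_printed, spec_tn, ovo = {}, {}, {}, {}
    for i, cls in enumerate(cm.class_order):
        tp = diag[i]
        sens[cls] = _ratio(tp, row_sums[i])
        spec_printed[cls] = _ratio(tp, col_sums[i])
        tn = total - row_sums[i] - col_sums[i] + tp
        fp = col_sums[i] - tp
        spec_tn[cls] = _ratio(tn, tn + fp)
        ovo[cls] = _ratio(tp + tn, total)
    return ClassMetrics(
        class_order=cm.class_order,
        sensitivity=sens,
        specificity_as_printed=spec_printed,
        specificity_tn=spec_tn,
        one_vs_other_accuracy=ovo,
        overall_accuracy=_ratio(float(diag.sum()), total),
    )


def collapse_benign_malignant(cm: ConfusionMatrix) -> ConfusionMatrix:
    """Collapse the 5-class matrix into benign vs malignant blocks."""
    benign = [cm.class_order.index(c) for c in BENIGN_CLASSES]
    malignant = [cm.class_order.index(c) for c in MALIGNANT_CLASSES]
    blocks = np.array(
        [
            [cm.counts[np.ix_(rows, cols)].sum() for cols in (benign, malignant)]
            for rows in (benign, malignant)
        ]
    )
    return ConfusionMatrix(blocks, class_order=("benign", "malignant"))


def benign_malignant_metrics(cm: ConfusionMatrix) -> ClassMetrics:
    """Metrics of the collapsed 2x2 benign/malignant confusion matrix."""
    return class_metrics(collapse_benign_malignant(cm))


@dataclass
class RocCurve:
    """A threshold sweep: TPR/FPR per threshold, AUC and the Youden-optimal cut-off."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    optimal_cutoff: float
    optimal_tpr: float
    optimal_fpr: float

    @property
    def fnr(self) -> np.ndarray:
        return 1.0 - self.tpr

    @property
    def optimal_fnr(self) -> float:
        return 1.0 - self.optimal_tpr


def roc_from_scores(scores: np.ndarray, positive: np.ndarray) -> RocCurve:
    """ROC by sweeping ``score >= threshold`` over the unique scores.

    AUC is the trapezoidal area under (FPR, TPR) including the (0,0) and
    (1,1) endpoints; the optimal cut-off maximizes Youden's J = TPR - FPR,
    taking the lowest threshold on ties.
    """
    scores = np.asarray(scores, dtype=float)
    positive = np.asarray(positive, dtype=bool)
    n_pos = int(positive.sum())
    n_neg = int((~positive).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both positive and negative examples")

    thresholds = np.unique(scores)[::-1]  # descending
    tpr = np.array([(scores[positive] >= t).mean() for t in thresholds])
    fpr = np.array([(scores[~positive] >= t).mean() for t in thresholds])
    full_fpr = np.concatenate(([0.0], fpr, [1.0]))
    full_tpr = np.concatenate(([0.0], tpr, [1.0]))
    auc = float(np.trapezoid(full_tpr, full_fpr))

    youden = tpr - fpr
    best_j = youden.max()
    # ties -> lowest threshold (thresholds are descending, so last argmax)
    best = np.nonzero(np.isclose(youden, best_j))[0][-1]
    return RocCurve(
        thresholds=thresholds,
        tpr=tpr,
        fpr=fpr,
        auc=auc,
        optimal_cutoff=float(thresholds[best]),
        optimal_tpr=float(tpr[best]),
        optimal_fpr=float(fpr[best]),
    )


def roc_one_vs_rest(folds: list[FoldResult], class_label: str) -> RocCurve:
    """One-vs-rest ROC for one class: score = p_class, other classes pooled."""
    if class_label not in CLASS_ORDER:
        raise ValueError(f"unknown class {class_label!r}")
    truth = np.array([f.true_label == class_label for f in folds])
    if not truth.any() or truth.all():
        raise ValueError(f"class {class_label!r} absent from truth (or is the only class)")
    scores = np.array([f.probability(class_label) for f in folds])
    return roc_from_scores(scores, truth)


def roc_benign_malignant(folds: list[FoldResult]) -> RocCurve:
    """Benign-vs-malignant ROC: malignant score = p_hcc + p_metastasis."""
    truth = np.array([f.true_label in MALIGNANT_CLASSES for f in folds])
    if not truth.any() or truth.all():
        raise ValueError("need both benign and malignant lesions for this ROC")
    scores = np.array(
        [sum(f.probability(c) for c in MALIGNANT_CLASSES) for f in folds]
    )
    return roc_from_scores(scores, truth)


def mcnemar_test(correct_a: np.ndarray, correct_b: np.ndarray) -> tuple[float, float]:
    """Chi-square McNemar test on paired correctness indicators.

    Returns (statistic, p-value) of the continuity-corrected chi-square
    test on the discordant pairs. Utility for comparing two classifiers
    (e.g. ablation feature sets) on the same lesions.
    """
    correct_a = np.asarray(correct_a, dtype=bool)
    correct_b = np.asarray(correct_b, dtype=bool)
    if correct_a.shape != correct_b.shape:
        raise ValueError("paired indicators must have equal length")
    b = int((correct_a & ~correct_b).sum())
    c = int((~correct_a & correct_b).sum())
    if b + c == 0:
        return 0.0, 1.0
    stat = (abs(b - c) - 1) ** 2 / (b + c)
    from scipy.stats import chi2

    return float(stat), float(chi2.sf(stat, df=1))
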