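"""Confusion-matrix metrics, ROC/AUC, stratified cross-validation, and
model-comparison reports.

Twelve rate metrics are computed from the confusion matrix: TPR, TNR, PPV,
NPV, ACC, F1, MCC, FPR, FNR, FDR, informedness (TPR+TNR-1) and markedness
(PPV+NPV-1).  Any 0/0 metric is reported as 0 and flagged rather than
raising, so batch reports stay total.  AUC is the trapezoidal sum over the
ROC points swept at descending unique score thresholds (tied scores grouped
into single segments, equivalent to mid-rank handling).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, fields

import numpy as np

from . import svm as svm_mod
from .features import LabeledSet

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "ROCCurve",
    "metrics",
    "roc_auc",
    "stratified_folds",
    "cross_validate",
    "summarize_reports",
    "model_comparison_report",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if v < 0:
                raise ValueError(f"{f.name} must be >= 0")
        if self.TP + self.FP + self.TN + self.FN == 0:
            raise ValueError("confusion matrix is all zero")


@dataclass(frozen=True)
class MetricsReport:
    TPR: float
    TNR: float
    PPV: float
    NPV: float
    ACC: float
    F1: float
    MCC: float
    FPR: float
    FNR: float
    FDR: float
    informedness: float
    markedness: float
    undefined: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float]:
        return {
            f.name: getattr(self, f.name)
            for f in fields(self)
            if f.name != "undefined"
        }


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean 2PR/(P+R); 0 when both inputs are 0."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Evaluate the twelve formulas; 0/0 -> 0 with a flag."""
    undefined: list[str] = []

    def ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return 0.0
        return num / den

    tp, fp, tn, fn = cm.TP, cm.FP, cm.TN, cm.FN
    tpr = ratio(tp, tp + fn, "TPR")
    tnr = ratio(tn, tn + fp, "TNR")
    ppv = ratio(tp, tp + fp, "PPV")
    npv = ratio(tn, tn + fn, "NPV")
    acc = (tp + tn) / (tp + fp + tn + fn)
    f1 = ratio(2 * tp, 2 * tp + fp + fn, "F1")
    mcc_den = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if mcc_den == 0:
        undefined.append("MCC")
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / mcc_den
    fpr = ratio(fp, fp + tn, "FPR")
    fnr = ratio(fn, tp + fn, "FNR")
    fdr = ratio(fp, tp + fp, "FDR")
    return MetricsReport(
        TPR=tpr,
        TNR=tnr,
        PPV=ppv,
        NPV=npv,
        ACC=acc,
        F1=f1,
        MCC=float(mcc),
        FPR=fpr,
        FNR=fnr,
        FDR=fdr,
        informedness=tpr + tnr - 1.0,
        markedness=ppv + npv - 1.0,
        undefined=tuple(undefined),
    )


@dataclass(frozen=True)
class ROCCurve:
    points: tuple[tuple[float, float], ...]  # (FPR, TPR) at descending thresholds
    auc: float


def roc_auc(scores, labels) -> ROCCurve:
    """ROC points and trapezoidal AUC.

    Thresholds sweep the distinct score values in descending order; tied
    scores enter as one group producing a single (possibly diagonal)
    segment.  AUC = sum over segments of TPR_i*dFPR + dTPR*dFPR/2.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D arrays")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == -1).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative label")
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    l_sorted = labels[order]
    points: list[tuple[float, float]] = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    n = len(scores)
    while i < n:
        j = i
        while j < n and s_sorted[j] == s_sorted[i]:
            j += 1
        tp += int((l_sorted[i:j] == 1).sum())
        fp += int((l_sorted[i:j] == -1).sum())
        points.append((fp / n_neg, tp / n_pos))
        i = j
    auc = 0.0
    for (x0, y0), (x1, y1) in zip(points, points[1:]):
        dx = x1 - x0
        auc += y0 * dx + 0.5 * (y1 - y0) * dx
    return ROCCurve(points=tuple(points), auc=float(auc))


def stratified_folds(labels, k: int, seed: int) -> list[np.ndarray]:
    """Seeded stratified fold assignment; returns k arrays of test indices.

    Each class is shuffled independently and dealt round-robin, so folds are
    sized floor(n/k) or ceil(n/k), every sample is tested exactly once, and
    each training fold contains both classes whenever n_class >= k.
    """
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = random.Random(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in np.unique(labels):
        idx = list(np.flatnonzero(labels == cls))
        rng.shuffle(idx)
        for pos, i in enumerate(idx):
            folds[pos % k].append(i)
    return [np.array(sorted(f), dtype=int) for f in folds]


@dataclass
class CVResult:
    fold_reports: list[MetricsReport]
    fold_aucs: list[float]
    summary_mean: dict[str, float]
    summary_sd: dict[str, float]
    scores: np.ndarray  # pooled out-of-fold decision scores
    labels: np.ndarray
    mean_auc: float = field(default=0.0)


def summarize_reports(reports: list[MetricsReport]) -> tuple[dict, dict]:
    keys = reports[0].as_dict().keys()
    mean = {
        key: float(np.mean([r.as_dict()[key] for r in reports])) for key in keys
    }
    sd = {
        key: float(np.std([r.as_dict()[key] for r in reports], ddof=1))
        if len(reports) > 1
        else 0.0
        for key in keys
    }
    return mean, sd


def cross_validate(
    labeled: LabeledSet,
    kernel_spec: svm_mod.KernelSpec | None = None,
    C: float = svm_mod.DEFAULT_C,
    j: float = svm_mod.DEFAULT_J,
    k: int = 5,
    seed: int = 0,
    scale: str = "none",
) -> CVResult:
    """Seeded stratified k-fold cross-validation of the weighted kernel SVM.

    Per-fold metrics come from the positive-score decision rule on the held
    out fold; the summary is mean +/- sd across folds.
    """
    y = labeled.y()
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes required")
    if counts.min() < k:
        raise ValueError(f"need >= k={k} members per class")
    folds = stratified_folds(y, k, seed)
    all_scores = np.zeros(len(y))
    reports: list[MetricsReport] = []
    aucs: list[float] = []
    for test_idx in folds:
        mask = np.ones(len(y), dtype=bool)
        mask[test_idx] = False
        train_set = LabeledSet(
            vectors=[labeled.vectors[i] for i in np.flatnonzero(mask)],
            labels=[labeled.labels[i] for i in np.flatnonzero(mask)],
            catalog=labeled.catalog,
        )
        model = svm_mod.train(train_set, kernel_spec, C=C, j=j, seed=seed, scale=scale)
        scores = model.decision(labeled.matrix()[test_idx])
        all_scores[test_idx] = scores
        pred = np.where(scores > 0, 1, -1)
        truth = y[test_idx]
        cm = ConfusionMatrix(
            TP=int(((pred == 1) & (truth == 1)).sum()),
            FP=int(((pred == 1) & (truth == -1)).sum()),
            TN=int(((pred == -1) & (truth == -1)).sum()),
            FN=int(((pred == -1) & (truth == 1)).sum()),
        )
        reports.append(metrics(cm))
        aucs.append(roc_auc(scores, truth).auc)
    mean, sd = summarize_reports(reports)
    return CVResult(
        fold_reports=reports,
        fold_aucs=aucs,
        summary_mean=mean,
        summary_sd=sd,
        scores=all_scores,
        labels=y.copy(),
        mean_auc=float(np.mean(aucs)),
    )


TABLE_COLUMNS = [
    ("Se", "TPR"),
    ("Sp", "TNR"),
    ("PPV", "PPV"),
    ("NPV", "NPV"),
    ("Accuracy", "ACC"),
    ("Precision", "PPV"),
    ("Recall", "TPR"),
    ("F-measure", "F1"),
    ("MCC", "MCC"),
]


def model_comparison_report(named_results: dict[str, CVResult]) -> str:
    """TSV table of mean +/- sd strings (3 dp) in the canonical column order."""
    if not named_results:
        raise ValueError("no results to report")
    lines = ["Methods\t" + "\t".join(col for col, _ in TABLE_COLUMNS)]
    for name, res in named_results.items():
        cells = [
            f"{res.summary_mean[key]:.3f} ± {res.summary_sd[key]:.3f}"
            for _, key in TABLE_COLUMNS
        ]
        lines.append(name + "\t" + "\t".join(cells))
    return "\n".join(lines) + "\n"
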