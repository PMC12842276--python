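"""Multi-class evaluation metrics for hard-label classifiers.

Per-class metrics derive from one-vs-rest marginalizations of the
confusion matrix:

    accuracy  = (TP + TN) / (TP + TN + FP + FN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 * precision * recall / (precision + recall)

with the 0/0 cases defined as 0 (a class never predicted has precision 0,
hence F1 0). Aggregates are the overall fraction correct and unweighted
(macro) means over classes — with balanced classes macro and weighted
averaging coincide.

ROC/AUC here follows the hard-label one-hot construction: truth and
prediction are binarized one-vs-rest, giving a single operating point and
the three-point curve (0,0) -> (FPR, TPR) -> (1,1). Its trapezoidal area
reduces to (1 + TPR - FPR) / 2, i.e. balanced accuracy; it is a valid
class-wise AUC but, with only one operating point, the "curve" has an
atypical shape by construction. Probability-threshold ROC curves are out
of scope.

Cross-entropy uses natural log with one-hot targets,
L_i = -log p_i(true class), averaged over samples. Uncertainty is via the
percentile bootstrap over prediction rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PredictionSet",
    "ClassCounts",
    "MetricsReport",
    "confusion_matrix",
    "class_counts",
    "basic_metrics",
    "aggregate_report",
    "onehot_roc_auc",
    "cross_entropy",
    "bootstrap_ci",
]

_PROB_EPS = 1e-12


@dataclass(frozen=True)
class PredictionSet:
    """Hard labels plus optional per-sample class-probability rows."""

    true_labels: np.ndarray
    predicted_labels: np.ndarray
    probabilities: np.ndarray | None = None
    n_classes: int | None = None

    def __post_init__(self) -> None:
        yt = np.asarray(self.true_labels, dtype=np.intp)
        yp = np.asarray(self.predicted_labels, dtype=np.intp)
        if yt.shape != yp.shape or yt.ndim != 1:
            raise ValueError("true and predicted labels must be equal-length 1D sequences")
        if len(yt) == 0:
            raise ValueError("empty prediction set")
        k = self.n_classes if self.n_classes is not None else int(max(yt.max(), yp.max())) + 1
        if yt.min() < 0 or yp.min() < 0 or yt.max() >= k or yp.max() >= k:
            raise ValueError(f"labels out of range [0, {k - 1}]")
        object.__setattr__(self, "true_labels", yt)
        object.__setattr__(self, "predicted_labels", yp)
        object.__setattr__(self, "n_classes", k)
        if self.probabilities is not None:
            p = np.asarray(self.probabilities, dtype=np.float64)
            if p.shape != (len(yt), k):
                raise ValueError(f"probabilities must have shape ({len(yt)}, {k})")
            if not np.allclose(p.sum(axis=1), 1.0, atol=1e-6):
                raise ValueError("probability rows must sum to 1 within 1e-6")
            object.__setattr__(self, "probabilities", p)

    def __len__(self) -> int:
        return len(self.true_labels)


@dataclass(frozen=True)
class ClassCounts:
    """One-vs-rest confusion counts for a single class."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    """Confusion matrix, per-class table, and macro aggregates."""

    confusion: np.ndarray
    per_class: dict[str, np.ndarray]  # precision / recall / f1 / auc arrays
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    mean_auc: float
    degenerate_classes: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "per_class": {k: v.tolist() for k, v in self.per_class.items()},
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "mean_auc": self.mean_auc,
            "degenerate_classes": self.degenerate_classes,
        }


def confusion_matrix(preds: PredictionSet) -> np.ndarray:
    """Count matrix with rows = true class, columns = predicted class."""
    k = preds.n_classes
    flat = preds.true_labels * k + preds.predicted_labels
    return np.bincount(flat, minlength=k * k).reshape(k, k)


def class_counts(confusion: np.ndarray, cls: int) -> ClassCounts:
    """One-vs-rest marginalization of a confusion matrix for one class."""
    confusion = np.asarray(confusion)
    tp = int(confusion[cls, cls])
    fn = int(confusion[cls].sum() - tp)
    fp = int(confusion[:, cls].sum() - tp)
    tn = int(confusion.sum() - tp - fn - fp)
    return ClassCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def basic_metrics(counts: ClassCounts) -> dict[str, float]:
    """Accuracy, precision, recall and F1 from one-vs-rest counts."""
    if counts.n == 0:
        raise ValueError("empty counts")
    precision = _safe_div(counts.tp, counts.tp + counts.fp)
    recall = _safe_div(counts.tp, counts.tp + counts.fn)
    return {
        "accuracy": (counts.tp + counts.tn) / counts.n,
        "precision": precision,
        "recall": recall,
        "f1": _safe_div(2 * recall * precision, recall + precision),
    }


def onehot_roc_auc(preds: PredictionSet, cls: int) -> tuple[np.ndarray, float]:
    """Hard-label one-vs-rest ROC for one class and its trapezoidal AUC.

    Returns the three operating points [(0,0), (FPR,TPR), (1,1)] and the
    area (1 + TPR - FPR)/2. If the class never occurs in the truth the
    AUC is undefined and returned as NaN.
    """
    counts = class_counts(confusion_matrix(preds), cls)
    if counts.tp + counts.fn == 0:
        return np.array([[0.0, 0.0], [np.nan, np.nan], [1.0, 1.0]]), float("nan")
    tpr = counts.tp / (counts.tp + counts.fn)
    fpr = _safe_div(counts.fp, counts.fp + counts.tn)
    roc = np.array([[0.0, 0.0], [fpr, tpr], [1.0, 1.0]])
    return roc, (1.0 + tpr - fpr) / 2.0


def aggregate_report(preds: PredictionSet) -> MetricsReport:
    """Full evaluation: confusion, per-class one-vs-rest table, macros.

    Classes absent from the truth have undefined AUC; they are excluded
    from the AUC mean and listed in ``degenerate_classes``.
    """
    k = preds.n_classes
    conf = confusion_matrix(preds)
    per = {m: np.zeros(k) for m in ("precision", "recall", "f1", "auc")}
    degenerate = []
    for c in range(k):
        bm = basic_metrics(class_counts(conf, c))
        per["precision"][c] = bm["precision"]
        per["recall"][c] = bm["recall"]
        per["f1"][c] = bm["f1"]
        _, auc = onehot_roc_auc(preds, c)
        per["auc"][c] = auc
        if np.isnan(auc):
            degenerate.append(c)
    valid_auc = per["auc"][~np.isnan(per["auc"])]
    return MetricsReport(
        confusion=conf,
        per_class=per,
        accuracy=float(np.mean(preds.true_labels == preds.predicted_labels)),
        macro_precision=float(per["precision"].mean()),
        macro_recall=float(per["recall"].mean()),
        macro_f1=float(per["f1"].mean()),
        mean_auc=float(valid_auc.mean()) if len(valid_auc) else float("nan"),
        degenerate_classes=degenerate,
    )


def cross_entropy(preds: PredictionSet) -> float:
    """Mean one-hot cross-entropy, natural log, probabilities clamped to
    [1e-12, 1]."""
    if preds.probabilities is None:
        raise ValueError("cross_entropy requires predicted probabilities")
    p_true = preds.probabilities[np.arange(len(preds)), preds.true_labels]
    return float(-np.mean(np.log(np.clip(p_true, _PROB_EPS, 1.0))))


def bootstrap_ci(
    preds: PredictionSet,
    metric,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Percentile bootstrap interval (lower, upper, point) for a metric.

    ``metric`` maps a :class:`PredictionSet` to a scalar; prediction rows
    (and probability rows, if present) are resampled jointly with
    replacement. Requires n >= 30 for the percentiles to mean much.
    """
    n = len(preds)
    if n < 30:
        raise ValueError("bootstrap_ci requires at least 30 samples")
    rng = np.random.default_rng(seed)
    point = float(metric(preds))
    stats = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        resampled = PredictionSet(
            true_labels=preds.true_labels[idx],
            predicted_labels=preds.predicted_labels[idx],
            probabilities=None if preds.probabilities is None else preds.probabilities[idx],
            n_classes=preds.n_classes,
        )
        stats[b] = metric(resampled)
    alpha = (1.0 - level) / 2.0
    lower, upper = np.quantile(stats, [alpha, 1.0 - alpha])
    return float(lower), float(upper), point
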