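"""Classification metrics: one-vs-rest confusion counts, the standard
ratio metrics, ROC/AUC, and cross-validation fold aggregation.

Multi-class metrics are reduced one-vs-rest per class and then
macro-averaged.  Two accuracies are exposed: the headline ``accuracy``
is the fraction of correct predictions; ``accuracy_ovr_macro`` is the
macro average of the per-class one-vs-rest (TP+TN)/(TP+TN+FP+FN) ratio,
which differs for more than two classes.  The false positive rate used
for ROC curves is FP/(FP+TN) = 1 - specificity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "confusion_counts",
    "classification_metrics",
    "roc_auc_ovr",
    "roc_curve_ovr",
    "summarize_folds",
    "format_mean_std",
]


@dataclass
class ConfusionCounts:
    """Per-class one-vs-rest counts; arrays indexed by class."""

    tp: np.ndarray
    tn: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    n_classes: int
    n_samples: int


@dataclass
class MetricReport:
    """Macro-averaged metrics as fractions in [0, 1], plus per-class values."""

    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    accuracy_ovr_macro: float
    per_class: dict[str, np.ndarray] = field(default_factory=dict)
    auc_per_class: np.ndarray | None = None
    undefined_flags: dict[str, np.ndarray] = field(default_factory=dict)

    def as_dict(self, percent: bool = False) -> dict[str, float]:
        scale = 100.0 if percent else 1.0
        out = {
            k: getattr(self, k) * scale
            for k in ("accuracy", "sensitivity", "specificity", "precision", "f1")
        }
        if self.auc_per_class is not None:
            valid = self.auc_per_class[np.isfinite(self.auc_per_class)]
            if valid.size:
                out["auc_macro"] = float(valid.mean()) * (scale if percent else 1.0)
        return out


def confusion_counts(predicted, actual, n_classes: int) -> ConfusionCounts:
    """One-vs-rest TP/TN/FP/FN per class from integer predictions."""
    predicted = np.asarray(predicted)
    actual = np.asarray(actual)
    if predicted.shape != actual.shape or predicted.ndim != 1:
        raise ValueError("predicted and actual must be 1-D arrays of equal length")
    if predicted.size < 1:
        raise ValueError("need at least one sample")
    if predicted.max() >= n_classes or actual.max() >= n_classes or min(predicted.min(), actual.min()) < 0:
        raise ValueError(f"class indices must lie in [0, {n_classes - 1}]")
    n = predicted.size
    tp = np.empty(n_classes, dtype=int)
    fp = np.empty(n_classes, dtype=int)
    fn = np.empty(n_classes, dtype=int)
    for c in range(n_classes):
        tp[c] = np.sum((predicted == c) & (actual == c))
        fp[c] = np.sum((predicted == c) & (actual != c))
        fn[c] = np.sum((predicted != c) & (actual == c))
    tn = n - tp - fp - fn
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn, n_classes=n_classes, n_samples=n)


def _safe_ratio(num: np.ndarray, den: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """num/den with 0/0 reported as 0 and flagged."""
    den = den.astype(float)
    undefined = den == 0
    out = np.divide(num, den, out=np.zeros(len(den)), where=~undefined)
    return out, undefined


def classification_metrics(counts: ConfusionCounts) -> MetricReport:
    """Per-class sensitivity/specificity/precision/F1 plus macro averages."""
    sens, u_sens = _safe_ratio(counts.tp, counts.tp + counts.fn)
    spec, u_spec = _safe_ratio(counts.tn, counts.tn + counts.fp)
    prec, u_prec = _safe_ratio(counts.tp, counts.tp + counts.fp)
    f1, u_f1 = _safe_ratio(2.0 * prec * sens, prec + sens)
    acc_ovr = (counts.tp + counts.tn) / counts.n_samples
    accuracy = counts.tp.sum() / counts.n_samples  # fraction correct
    return MetricReport(
        accuracy=float(accuracy),
        sensitivity=float(sens.mean()),
        specificity=float(spec.mean()),
        precision=float(prec.mean()),
        f1=float(f1.mean()),
        accuracy_ovr_macro=float(acc_ovr.mean()),
        per_class={
            "sensitivity": sens,
            "specificity": spec,
            "precision": prec,
            "f1": f1,
            "accuracy_ovr": acc_ovr,
        },
        undefined_flags={
            "sensitivity": u_sens,
            "specificity": u_spec,
            "precision": u_prec,
            "f1": u_f1,
        },
    )


def roc_curve_ovr(scores, actual, positive_class: int) -> tuple[np.ndarray, np.ndarray]:
    """One-vs-rest ROC points (fpr, tpr) over score thresholds, ties merged."""
    scores = np.asarray(scores, dtype=float)
    actual = np.asarray(actual)
    s = scores[:, positive_class]
    pos = actual == positive_class
    order = np.argsort(-s, kind="stable")
    s, pos = s[order], pos[order]
    # merge tied thresholds
    distinct = np.r_[np.nonzero(np.diff(s))[0], s.size - 1]
    tp = np.cumsum(pos)[distinct]
    fp = np.cumsum(~pos)[distinct]
    n_pos = pos.sum()
    n_neg = (~pos).sum()
    tpr = np.r_[0.0, tp / max(n_pos, 1)]
    fpr = np.r_[0.0, fp / max(n_neg, 1)]
    return fpr, tpr


def roc_auc_ovr(scores, actual) -> np.ndarray:
    """Per-class one-vs-rest AUC by trapezoidal integration of the ROC
    curve (equivalently the tie-averaged rank statistic).

    ``scores`` rows must sum to 1 (tolerance 1e-5).  A class absent from
    ``actual`` gets AUC NaN (flagged as undefined).
    """
    scores = np.asarray(scores, dtype=float)
    actual = np.asarray(actual)
    if scores.ndim != 2 or scores.shape[0] != actual.size:
        raise ValueError("scores must be (n_samples, n_classes) matching actual")
    if not np.allclose(scores.sum(axis=1), 1.0, atol=1e-5):
        raise ValueError("score rows must sum to 1")
    n_classes = scores.shape[1]
    aucs = np.full(n_classes, np.nan)
    for c in range(n_classes):
        n_pos = int(np.sum(actual == c))
        n_neg = actual.size - n_pos
        if n_pos == 0 or n_neg == 0:
            continue
        fpr, tpr = roc_curve_ovr(scores, actual, c)
        aucs[c] = float(np.trapezoid(tpr, fpr))
    return aucs


def format_mean_std(mean: float, std: float | None, percent: bool = True) -> str:
    """Render a fold aggregate in the conventional "xx.xx ± x.xx" form."""
    scale = 100.0 if percent else 1.0
    if std is None:
        return f"{mean * scale:.2f}"
    return f"{mean * scale:.2f} ± {std * scale:.2f}"


def summarize_folds(fold_reports: list[MetricReport]) -> dict[str, dict]:
    """Mean and sample standard deviation of each metric across folds.

    With a single fold the std is reported as None (flagged unavailable).
    """
    if not fold_reports:
        raise ValueError("no fold reports to summarise")
    out: dict[str, dict] = {}
    for key in ("accuracy", "sensitivity", "specificity", "precision", "f1"):
        vals = np.array([getattr(r, key) for r in fold_reports], dtype=float)
        mean = float(vals.mean())
        std = float(vals.std(ddof=1)) if len(vals) > 1 else None
        out[key] = {
            "mean": mean,
            "std": std,
            "formatted": format_mean_std(mean, std),
        }
    return out
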