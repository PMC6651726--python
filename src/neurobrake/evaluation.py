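"""Confusion-matrix metrics, ROC/AUC, stratified k-fold
cross-validation, and parameter sweeps.

The braking-intention class is the positive class throughout:
sensitivity is braking recall, specificity is normal recall.
Metrics with a zero denominator are reported as ``None`` (undefined),
never as propagating NaNs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

from .core import DatasetTable, LABEL_BRAKING, SessionRecording
from .model import predict
from .pipeline import PipelineConfig, build_dataset, fit_classifier, with_params


@dataclass
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class Metrics:
    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    confusion: ConfusionMatrix


def confusion_metrics(y_true, y_pred) -> Metrics:
    """Accuracy, sensitivity and specificity with braking positive.

    accuracy = (TP+TN)/(TP+TN+FP+FN); sensitivity = TP/(TP+FN);
    specificity = TN/(TN+FP).
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.size == 0:
        raise ValueError("empty label vectors")
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have equal length")
    tn, fp, fn, tp = _sk_confusion(y_true, y_pred, labels=[0, 1]).ravel()
    cm = ConfusionMatrix(tp=int(tp), tn=int(tn), fp=int(fp), fn=int(fn))

    def safe(num, den):
        return num / den if den > 0 else None

    return Metrics(
        accuracy=safe(tp + tn, cm.total),
        sensitivity=safe(tp, tp + fn),
        specificity=safe(tn, tn + fp),
        confusion=cm,
    )


def roc_curve_auc(y_true, scores) -> tuple[np.ndarray, np.ndarray, float]:
    """(fpr, tpr, auc): ROC over all score thresholds, trapezoidal AUC.

    Scores are braking-class probabilities.  Tied scores are handled by
    the threshold sweep, making the AUC equal to the normalized
    Mann-Whitney U statistic with ties counted 1/2.
    """
    y_true = np.asarray(y_true, dtype=int)
    if len(np.unique(y_true)) < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, _ = _sk_roc_curve(y_true, scores, pos_label=LABEL_BRAKING)
    return fpr, tpr, float(np.trapezoid(tpr, fpr))


@dataclass
class FoldResult:
    metrics: Metrics
    auc: float
    n_val: int


@dataclass
class CVResult:
    """Per-fold metrics plus aggregates (mean of folds and pooled)."""

    folds: list[FoldResult]
    pooled: Metrics
    pooled_auc: float

    @property
    def fold_accuracies(self) -> np.ndarray:
        return np.array([f.metrics.accuracy for f in self.folds], dtype=float)

    @property
    def mean_accuracy(self) -> float:
        return float(self.fold_accuracies.mean())

    @property
    def sd_accuracy(self) -> float:
        return float(self.fold_accuracies.std(ddof=1))

    @property
    def mean_auc(self) -> float:
        return float(np.mean([f.auc for f in self.folds]))


def kfold_cv(
    table: DatasetTable,
    k: int = 5,
    config: PipelineConfig | None = None,
    seed: int = 0,
) -> CVResult:
    """Stratified, shuffled k-fold cross-validation of the classifier.

    Folds preserve the class ratio within one sample; standardization
    constants are fit on each training fold only; every sample is
    validated exactly once.  When the table carries provenance groups,
    folds additionally keep all overlapping windows of one braking
    event (or quiet segment) together, so temporal autocorrelation
    cannot leak between train and validation.  Deterministic for a
    fixed seed.
    """
    if config is None:
        config = PipelineConfig()
    counts = np.bincount(table.labels, minlength=2)
    if counts.min() < k:
        raise ValueError(
            f"k={k} exceeds the smaller class count {counts.min()}"
        )
    if table.groups is not None:
        skf = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = skf.split(table.features, table.labels, groups=table.groups)
    else:
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = skf.split(table.features, table.labels)
    folds = []
    pooled_pred = np.empty(table.n_samples, dtype=int)
    pooled_score = np.empty(table.n_samples)
    for train_idx, val_idx in splits:
        tr = DatasetTable(
            features=table.features[train_idx],
            labels=table.labels[train_idx],
            meta=dict(table.meta),
        )
        va_x = table.features[val_idx]
        va_y = table.labels[val_idx]
        net, std = fit_classifier(
            tr,
            DatasetTable(features=va_x, labels=va_y, meta=dict(table.meta)),
            config,
        )
        labels, scores = predict(net, std.transform(va_x))
        _, _, auc = roc_curve_auc(va_y, scores)
        folds.append(
            FoldResult(
                metrics=confusion_metrics(va_y, labels),
                auc=auc,
                n_val=len(val_idx),
            )
        )
        pooled_pred[val_idx] = labels
        pooled_score[val_idx] = scores
    pooled = confusion_metrics(table.labels, pooled_pred)
    _, _, pooled_auc = roc_curve_auc(table.labels, pooled_score)
    return CVResult(folds=folds, pooled=pooled, pooled_auc=pooled_auc)


SWEEPABLE = {
    "ar_order": "ar_order",
    "step_ms": "step_ms",
    "pre_braking_ms": "pre_braking_ms",
    "n_hidden": "n_hidden",
}

#: Parameters whose change alters the labeling, requiring a rebuild of
#: the dataset from the session rather than a re-fit on cached features.
RELABEL_PARAMS = {"step_ms", "pre_braking_ms"}


@dataclass
class SweepResult:
    parameter: str
    values: list
    results: list[CVResult] = field(default_factory=list)

    @property
    def mean_accuracies(self) -> np.ndarray:
        return np.array([r.mean_accuracy for r in self.results])

    @property
    def mean_aucs(self) -> np.ndarray:
        return np.array([r.mean_auc for r in self.results])

    def to_frame(self):
        """Flat per-value summary as a pandas DataFrame."""
        import pandas as pd

        return pd.DataFrame(
            {
                self.parameter: self.values,
                "mean_accuracy": self.mean_accuracies,
                "sd_accuracy": [r.sd_accuracy for r in self.results],
                "mean_auc": self.mean_aucs,
                "pooled_accuracy": [r.pooled.accuracy for r in self.results],
            }
        )


def sweep(
    parameter: str,
    values: list,
    session: SessionRecording,
    config: PipelineConfig | None = None,
    k: int = 5,
    seed: int = 0,
) -> SweepResult:
    """k-fold CV at every value of one pipeline parameter.

    Feature parameters (``ar_order``, ``n_hidden``) reuse the session's
    windowing; parameters that change the label structure (``step_ms``,
    ``pre_braking_ms``) re-run detection and labeling from the session,
    matching the rule that training windows are collected exactly as in
    online testing.
    """
    if parameter not in SWEEPABLE:
        raise ValueError(f"unknown sweep parameter {parameter!r}")
    if not values:
        raise ValueError("empty sweep grid")
    if config is None:
        config = PipelineConfig()
    out = SweepResult(parameter=parameter, values=list(values))
    base_table = None
    for v in values:
        cfg = with_params(config, **{SWEEPABLE[parameter]: v})
        if parameter in RELABEL_PARAMS or parameter == "ar_order":
            table = build_dataset(session, cfg)
        else:
            if base_table is None:
                base_table = build_dataset(session, cfg)
            table = base_table
        out.results.append(kfold_cv(table, k=k, config=cfg, seed=seed))
    return out
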