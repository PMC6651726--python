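"""Quick-look figures: training curves, ROC, and sweep summaries.

Each function draws onto (and returns) a matplotlib Axes so plots can
be composed; none of the analysis code imports this module.
"""

from __future__ import annotations

from .evaluation import SweepResult, roc_curve_auc
from .model import Network


def plot_loss_curves(net: Network, ax=None):
    """Cross-entropy per training iteration (train and validation)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(net.history["train_loss"], label="train")
    if net.history["val_loss"]:
        ax.plot(net.history["val_loss"], label="validation")
    ax.set_xlabel("iteration")
    ax.set_ylabel("cross-entropy")
    ax.legend()
    return ax


def plot_roc(y_true, scores, label=None, ax=None):
    """ROC curve with the AUC in the legend."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    fpr, tpr, auc = roc_curve_auc(y_true, scores)
    name = label or "classifier"
    ax.plot(fpr, tpr, label=f"{name} (AUC {auc:.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend()
    return ax


def plot_sweep(result: SweepResult, metric: str = "accuracy", ax=None):
    """Mean +/- SD of a cross-validated metric over the swept grid."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    if metric == "accuracy":
        y = result.mean_accuracies
        err = [r.sd_accuracy for r in result.results]
    elif metric == "auc":
        y = result.mean_aucs
        err = None
    else:
        raise ValueError("metric must be 'accuracy' or 'auc'")
    ax.errorbar(result.values, y, yerr=err, marker="o", capsize=3)
    ax.set_xlabel(result.parameter)
    ax.set_ylabel(f"mean CV {metric}")
    return ax
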