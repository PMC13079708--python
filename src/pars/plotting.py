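"""Reliability-diagram and ROC plots for screening results."""

from __future__ import annotations

import numpy as np


def plot_reliability(calibration_table, brier: float = None, ax=None):
    """Reliability diagram from a quantile-binned calibration table."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=1)
    ax.plot(calibration_table["mean_predicted"], calibration_table["observed_rate"],
            marker="o", c="C0")
    ax.set_xlabel("mean predicted probability")
    ax.set_ylabel("observed event rate")
    title = "Reliability diagram"
    if brier is not None:
        title += f" (Brier {brier:.4f})"
    ax.set_title(title)
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    return ax


def plot_roc(proba, y, ax=None):
    """ROC curve with the AUC in the legend."""
    import matplotlib.pyplot as plt
    from sklearn.metrics import roc_auc_score, roc_curve

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    fpr, tpr, _ = roc_curve(np.asarray(y, int), np.asarray(proba, float))
    ax.plot(fpr, tpr, c="C0", label=f"AUC = {roc_auc_score(y, proba):.3f}")
    ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=1)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(loc="lower right")
    return ax
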