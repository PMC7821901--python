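"""Static figures: event-triggered averages and decoder ROC curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .events import EventAverage


def plot_event_average(avg: EventAverage, ax=None, label: str | None = None):
    """Mean ± SEM peri-event trace with the onset marked."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    ax.plot(avg.time, avg.mean, color="C0", label=label)
    if avg.sem_defined:
        ax.fill_between(avg.time, avg.mean - avg.sem, avg.mean + avg.sem,
                        color="C0", alpha=0.3, linewidth=0)
    ax.axvline(0.0, color="r", linestyle="--", linewidth=0.8)
    ax.set_xlabel("time from event (s)")
    ax.set_ylabel("ΔF/F")
    if label:
        ax.legend(frameon=False)
    return ax


def plot_roc(curves, aucs, ax=None):
    """Per-split ROC curves with the mean AUC in the title."""
    if ax is None:
        _, ax = plt.subplots(figsize=(3.5, 3.5))
    for (fpr, tpr), auc in zip(curves, aucs):
        ax.plot(fpr, tpr, alpha=0.7, label=f"AUC {auc:.2f}")
    ax.plot([0, 1], [0, 1], "k:", linewidth=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.set_title(f"mean AUC {np.mean(aucs):.3f}")
    ax.legend(frameon=False, fontsize=7)
    return ax
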