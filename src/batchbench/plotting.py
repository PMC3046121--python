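"""Minimal figures for benchmark output: PVCA bars, ROC curves, z boxplots."""
from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def pvca_bars(results: dict, ax=None):
    """Stacked/grouped bar chart of weighted variance proportions.

    ``results`` maps a label (e.g. method name) to a PVCAResult.
    """
    ax = ax or plt.gca()
    labels = list(results)
    factors = list(next(iter(results.values())).weighted_proportions)
    width = 0.8 / len(factors)
    for i, factor in enumerate(factors):
        heights = [results[l].weighted_proportions.get(factor, 0.0) for l in labels]
        ax.bar([x + i * width for x in range(len(labels))], heights,
               width=width, label=factor)
    ax.set_xticks([x + 0.4 for x in range(len(labels))])
    ax.set_xticklabels(labels, rotation=45, ha="right")
    ax.set_ylabel("weighted proportion of variance")
    ax.legend()
    return ax


def roc_curves(curves: dict, ax=None):
    """Overlay ROC curves; ``curves`` maps label -> RocCurve."""
    ax = ax or plt.gca()
    for label, curve in curves.items():
        ax.plot(curve.fpr, curve.tpr, label=f"{label} (AUC {curve.auc:.3f})")
    ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(loc="lower right")
    return ax


def z_boxplots(z_by_method: dict, ax=None):
    """Boxplots of Fisher-z replicate correlation distributions per method."""
    ax = ax or plt.gca()
    labels = list(z_by_method)
    ax.boxplot([z_by_method[l] for l in labels], tick_labels=labels)
    ax.set_ylabel("Fisher z of replicate correlation")
    ax.tick_params(axis="x", rotation=45)
    return ax
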