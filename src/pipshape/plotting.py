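"""Small matplotlib views of the main results: ordination scatter,
cluster tree, and the accumulated blind-test bar chart."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .classify import ClassificationResult
from .validate import DAReport


def plot_pca(result: ClassificationResult, labels=None, ax=None):
    """Scatter of the first two weighted principal components."""
    scores = result.pca.scores
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    if labels is None:
        labels = [result.final_labels[s] for s in scores.index]
    for lab in sorted(set(labels)):
        mask = [l == lab for l in labels]
        ax.scatter(
            scores.iloc[mask, 0], scores.iloc[mask, 1], label=str(lab), s=25
        )
    ev = result.pca.explained_variance
    total = ev.sum()
    ax.set_xlabel(f"PC1 ({100 * ev[0] / total:.0f}%)")
    ax.set_ylabel(f"PC2 ({100 * ev[1] / total:.0f}%)")
    ax.legend(fontsize=8)
    return ax


def plot_da_fractions(report: DAReport, ax=None):
    """Stacked per-seed bars of assigned-label fractions, grouped by
    true label."""
    frac = report.fractions()
    order = np.argsort(report.true_labels, kind="stable")
    if ax is None:
        _, ax = plt.subplots(figsize=(max(6, 0.12 * len(order)), 4))
    bottom = np.zeros(len(order))
    for cls in report.class_names:
        vals = frac[cls].to_numpy()[order]
        ax.bar(np.arange(len(order)), vals, bottom=bottom, width=0.9, label=cls)
        bottom += vals
    ax.set_xticks([])
    ax.set_ylabel("assignment fraction")
    ax.legend(fontsize=7, ncol=min(len(report.class_names), 4))
    return ax
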