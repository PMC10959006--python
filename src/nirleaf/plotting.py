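"""Optional matplotlib views: confusion heatmap, per-iteration class
histograms, and wavelength-importance curves."""

from __future__ import annotations

import numpy as np

from nirleaf.spectra_io import CLASS_NAMES

__all__ = ["confusion_heatmap", "iteration_histogram", "importance_plot"]


def _axes(ax):
    if ax is None:
        import matplotlib.pyplot as plt
        _, ax = plt.subplots()
    return ax


def confusion_heatmap(report, ax=None, cmap: str = "Blues"):
    """Heatmap of a MetricsReport's confusion matrix (rows = true)."""
    ax = _axes(ax)
    M = report.confusion
    im = ax.imshow(M, cmap=cmap)
    for i in range(M.shape[0]):
        for j in range(M.shape[1]):
            ax.text(j, i, str(M[i, j]), ha="center", va="center",
                    color="black" if M[i, j] < M.max() / 2 else "white")
    ax.set_xticks(range(5), CLASS_NAMES)
    ax.set_yticks(range(5), CLASS_NAMES)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    ax.set_title(f"WAP {100 * report.wap:.1f}%  MAP {100 * report.map:.1f}%"
                 f"  WR {100 * report.wr:.1f}%")
    ax.figure.colorbar(im, ax=ax, shrink=0.8)
    return ax


def iteration_histogram(history, ax=None):
    """Grouped bars of rebalanced pseudo-set class counts per iteration."""
    ax = _axes(ax)
    history = list(history)
    width = 0.8 / 5
    for c in range(5):
        xs = [s.iteration + (c - 2) * width for s in history]
        ys = [s.pseudo_counts[c] for s in history]
        ax.bar(xs, ys, width=width, label=CLASS_NAMES[c])
    ax.set_xlabel("iteration")
    ax.set_ylabel("pseudo-labeled samples")
    ax.legend(title="class", fontsize="small")
    return ax


def importance_plot(profile, ax=None):
    """Gini importance (and Pearson r, if present) across wavelengths."""
    ax = _axes(ax)
    ax.plot(profile.wavelengths, profile.gini, color="tab:green",
            label="Gini importance")
    ax.set_xlabel("wavelength (nm)")
    ax.set_ylabel("normalised importance")
    for b in profile.top_bands:
        ax.axvline(profile.wavelengths[b], color="gray", ls=":", lw=0.8)
    if profile.pearson_r is not None:
        ax2 = ax.twinx()
        ax2.plot(profile.wavelengths, profile.pearson_r, color="tab:orange",
                 alpha=0.7, label="Pearson r")
        ax2.set_ylabel("Pearson r")
        ax2.set_ylim(-1, 1)
    ax.legend(loc="upper left", fontsize="small")
    return ax
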