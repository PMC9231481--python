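"""Optional matplotlib figures: Bland-Altman, scree, loading dendrogram."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from scipy.cluster import hierarchy

from .latent import ClusterTree, FactorModel
from .reliability import BlandAltman


def bland_altman_plot(ba: BlandAltman, title: str = "", path=None):
    """Difference-vs-mean scatter with mean and +/-1.96 SD lines, points
    colored by age when available."""
    fig, ax = plt.subplots(figsize=(5, 4))
    color = ba.ages if ba.ages is not None else None
    sc = ax.scatter(ba.means, ba.diffs, c=color, cmap="viridis", s=25)
    if color is not None:
        fig.colorbar(sc, ax=ax, label="age (years)")
    ax.axhline(ba.mean_diff, color="red")
    for y in (ba.loa_low, ba.loa_high):
        ax.axhline(y, color="red", linestyle="--")
    ax.set_xlabel("two-day mean (probit accuracy)")
    ax.set_ylabel("day 2 - day 1")
    ax.set_title(title)
    if path:
        fig.savefig(path, bbox_inches="tight")
        plt.close(fig)
    return fig


def scree_plot(model: FactorModel, path=None):
    fig, ax = plt.subplots(figsize=(5, 4))
    scree = model.scree if model.scree is not None else model.explained_variance
    ax.plot(np.arange(1, len(scree) + 1), scree, "o-")
    ax.set_xlabel("component")
    ax.set_ylabel("explained variance (%)")
    if path:
        fig.savefig(path, bbox_inches="tight")
        plt.close(fig)
    return fig


def loading_dendrogram(tree: ClusterTree, path=None):
    fig, ax = plt.subplots(figsize=(7, 5))
    hierarchy.dendrogram(tree.linkage, labels=tree.labels, ax=ax, leaf_rotation=90)
    ax.set_ylabel("1 - |cos| loading distance")
    fig.tight_layout()
    if path:
        fig.savefig(path, bbox_inches="tight")
        plt.close(fig)
    return fig
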