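"""Minimal plots: cluster embedding and the Waddington landscape."""

from __future__ import annotations

import numpy as np

from .clustering import Embedding2D
from .entropy import Landscape

__all__ = ["plot_embedding", "plot_landscape"]


def plot_embedding(emb: Embedding2D, labels=None, ax=None, s: float = 6.0):
    """Scatter the 2-D embedding, colored by cluster label if given."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    xy = emb.coords
    if labels is None:
        ax.scatter(xy[:, 0], xy[:, 1], s=s, c="0.3", linewidths=0)
    else:
        labels = np.asarray(labels)
        for lab in np.unique(labels):
            m = labels == lab
            ax.scatter(xy[m, 0], xy[m, 1], s=s, label=str(lab), linewidths=0)
        ax.legend(frameon=False, markerscale=2, fontsize=8)
    ax.set_xlabel("dim 1")
    ax.set_ylabel("dim 2")
    return ax


def plot_landscape(land: Landscape, emb: Embedding2D | None = None, ax=None):
    """Filled-contour entropy landscape; valleys are stable states."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5.5, 5))
    cs = ax.contourf(land.grid_x, land.grid_y, land.heights, levels=30,
                     cmap="terrain")
    plt.colorbar(cs, ax=ax, label="cellular entropy ξ")
    if emb is not None:
        ax.scatter(emb.coords[:, 0], emb.coords[:, 1], s=2, c="k", alpha=0.3,
                   linewidths=0)
    return ax
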