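"""Ternary-diagram rendering of pairwise IBD estimates."""

from __future__ import annotations

from typing import Sequence

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .classify import CENTROIDS, ternary_coordinates

__all__ = ["ternary_plot"]

_TRIANGLE = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3) / 2], [0.0, 0.0]])


def ternary_plot(z_values: np.ndarray, labels: Sequence[str] | None = None,
                 show_centroids: bool = True, ax=None):
    """Scatter (Z0, Z1, Z2) triples inside the IBD simplex.

    Corners are Z0 (bottom left), Z1 (bottom right) and Z2 (top); points
    are coloured by label.  Returns the matplotlib figure.
    """
    z = np.atleast_2d(np.asarray(z_values, float))
    if ax is None:
        fig, ax = plt.subplots(figsize=(6, 5.5))
    else:
        fig = ax.figure
    ax.plot(_TRIANGLE[:, 0], _TRIANGLE[:, 1], color="black", lw=1)
    x, y = ternary_coordinates(z[:, 0], z[:, 1], z[:, 2])
    x, y = np.atleast_1d(x), np.atleast_1d(y)
    if labels is None:
        ax.scatter(x, y, s=18, alpha=0.8)
    else:
        labels = np.asarray(labels, dtype=object)
        for lab in dict.fromkeys(labels):
            m = labels == lab
            ax.scatter(x[m], y[m], s=18, alpha=0.8, label=str(lab))
        ax.legend(loc="upper right", fontsize=8, frameon=False)
    if show_centroids:
        for name, c in CENTROIDS.items():
            cx, cy = ternary_coordinates(*c)
            ax.plot(cx, cy, marker="+", color="grey", ms=10, mew=1.5)
    for text, (tx, ty, ha) in {"Z0": (0, -0.04, "center"),
                               "Z1": (1, -0.04, "center"),
                               "Z2": (0.5, np.sqrt(3) / 2 + 0.02, "center")}.items():
        ax.text(tx, ty, text, ha=ha, va="center", fontsize=10)
    ax.set_aspect("equal")
    ax.axis("off")
    return fig
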