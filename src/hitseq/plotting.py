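"""Plot helpers for affinity distributions, coefficient maps and logos.

Thin matplotlib wrappers; all figures are also exportable as TSV through the
corresponding analysis functions, so plotting stays optional.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .specificity import LogoMatrix, affinity_histogram


def plot_affinity_histogram(table, n_bins: int = 100, ax=None, log_counts=True):
    """Histogram of K_A,rel, the classic bimodality view."""
    import matplotlib.pyplot as plt

    counts, edges = affinity_histogram(table, n_bins=n_bins)
    ax = ax or plt.gca()
    ax.bar(edges[:-1], counts, width=np.diff(edges), align="edge",
           color="steelblue", edgecolor="none")
    if log_counts:
        ax.set_yscale("log")
    ax.set_xlabel(r"$K_{A,rel}$")
    ax.set_ylabel("variants")
    return ax


def plot_coefficient_heatmap(matrix: pd.DataFrame, ax=None, cmap="RdBu_r"):
    """Heatmap of pairwise-coupling coefficients (PWCModel.heatmap_matrix)."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    values = matrix.to_numpy(dtype=float)
    vmax = np.abs(values).max() or 1.0
    im = ax.imshow(values, cmap=cmap, vmin=-vmax, vmax=vmax)
    labels = [f"{p}{b}" for p, b in matrix.index]
    ax.set_xticks(range(len(labels)), labels, rotation=90, fontsize=6)
    ax.set_yticks(range(len(labels)), labels, fontsize=6)
    plt.colorbar(im, ax=ax, label="coupling (ln units)")
    return ax


def plot_logo(logo: LogoMatrix, ax=None):
    """Information-scaled letter stack for a top-variant logo."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    colors = {"A": "#2ca02c", "C": "#1f77b4", "G": "#ff7f0e", "U": "#d62728"}
    for pos in logo.frequencies.index:
        heights = logo.frequencies.loc[pos] * logo.information[pos]
        bottom = 0.0
        for base in heights.sort_values().index:
            h = heights[base]
            if h <= 0:
                continue
            ax.bar(pos, h, bottom=bottom, width=0.85, color=colors[base])
            if h > 0.08:
                ax.text(pos, bottom + h / 2, base, ha="center", va="center",
                        fontsize=9, fontweight="bold", color="white")
            bottom += h
    ax.set_xticks(list(logo.frequencies.index))
    ax.set_xlabel("position")
    ax.set_ylabel("bits")
    ax.set_ylim(0, 2)
    return ax
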