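"""Plot hooks: correlation map, kinetic series, 3-D PCA score map.

Thin wrappers returning matplotlib Axes; all styling is left to the caller.
"""
from __future__ import annotations

import numpy as np
import pandas as pd


def plot_correlation_map(cm, ax=None):
    """Heat map of the all-pairs correlation matrix with day boundaries."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    im = ax.imshow(cm.matrix, vmin=-1, vmax=1, cmap="viridis", origin="lower")
    for day, sl in cm.day_slices.items():
        if sl.start:
            ax.axhline(sl.start - 0.5, color="w", lw=0.5)
            ax.axvline(sl.start - 0.5, color="w", lw=0.5)
    ax.figure.colorbar(im, ax=ax, label="Pearson r")
    ax.set_xlabel("spectrum index")
    ax.set_ylabel("spectrum index")
    return ax


def plot_kinetics(series: pd.DataFrame, ax=None):
    """Day-mean +/- sd trace of a band intensity or ratio."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.errorbar(series["day"], series["mean"], yerr=series["sd"], marker="o", capsize=3)
    ax.set_xlabel("culture day")
    ax.set_ylabel(series.attrs.get("quantity", "intensity"))
    return ax


def plot_pca_scores(result, components=(0, 1, 2), ax=None):
    """3-D score scatter coloured by culture day."""
    import matplotlib.pyplot as plt

    i, j, k = components
    if ax is None:
        fig = plt.figure()
        ax = fig.add_subplot(projection="3d")
    days = result.meta["day"].to_numpy()
    sc = ax.scatter(
        result.scores[:, i], result.scores[:, j], result.scores[:, k],
        c=days, cmap="viridis", s=8,
    )
    ax.set_xlabel(f"PC{i + 1} ({100 * result.explained_fraction[i]:.1f}%)")
    ax.set_ylabel(f"PC{j + 1} ({100 * result.explained_fraction[j]:.1f}%)")
    ax.set_zlabel(f"PC{k + 1} ({100 * result.explained_fraction[k]:.1f}%)")
    ax.figure.colorbar(sc, ax=ax, label="day", shrink=0.6)
    return ax


def pca_score_tuples(result, components=(0, 1, 2)) -> pd.DataFrame:
    """(PCi, PCj, PCk, day) tuples for external plotting, as a table."""
    i, j, k = components
    return pd.DataFrame(
        {
            f"PC{i + 1}": result.scores[:, i],
            f"PC{j + 1}": result.scores[:, j],
            f"PC{k + 1}": result.scores[:, k],
            "day": result.meta["day"].to_numpy(),
        }
    )
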