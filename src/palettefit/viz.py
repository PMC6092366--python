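"""Stacked palette bar plots and residual-matrix heatmaps."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

import matplotlib.pyplot as plt

from .core import QMatrix
from .painting import PaletteMatrix

__all__ = ["plot_palette_bars", "plot_residual_matrix"]


def _to_frame(data) -> pd.DataFrame:
    if isinstance(data, (PaletteMatrix, QMatrix)):
        return data.to_dataframe()
    if isinstance(data, pd.DataFrame):
        return data
    arr = np.asarray(data, dtype=float)
    return pd.DataFrame(arr)


def _group_boundaries(labels: Sequence[str]):
    """(boundary positions, (group, center) pairs) for contiguous label runs."""
    bounds, centers = [], []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            bounds.append(i)
            centers.append((labels[start], (start + i) / 2.0))
            start = i
    return bounds[:-1], centers


def plot_palette_bars(data, labels: Sequence[str], out_path) -> Path:
    """One stacked vertical bar per individual, grouped by label.

    Colours are assigned deterministically by column order.  ``data`` may
    be a :class:`PaletteMatrix`, :class:`QMatrix`, DataFrame or array.
    """
    df = _to_frame(data)
    if df.shape[0] == 0:
        raise ValueError("no individuals to plot")
    labels = list(labels)
    if len(labels) != df.shape[0]:
        raise ValueError("labels must match rows")
    cmap = plt.get_cmap("tab20")
    colors = [cmap(j % 20) for j in range(df.shape[1])]

    fig, ax = plt.subplots(figsize=(max(4, 0.12 * len(labels) + 2), 3.2))
    x = np.arange(df.shape[0])
    bottom = np.zeros(df.shape[0])
    for j, col in enumerate(df.columns):
        vals = df[col].to_numpy()
        ax.bar(x, vals, bottom=bottom, width=1.0, color=colors[j],
               linewidth=0, label=str(col))
        bottom += vals
    bounds, centers = _group_boundaries(labels)
    for b in bounds:
        ax.axvline(b - 0.5, color="black", linewidth=0.8)
    ax.set_xticks([c for _, c in centers])
    ax.set_xticklabels([g for g, _ in centers], rotation=90, fontsize=7)
    ax.set_xlim(-0.5, len(labels) - 0.5)
    ax.set_ylim(0, 1)
    ax.set_ylabel("fraction")
    ax.legend(fontsize=6, ncol=2, frameon=False, loc="center left",
              bbox_to_anchor=(1.01, 0.5))
    fig.savefig(out_path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return Path(out_path)


def plot_residual_matrix(residuals, labels: Sequence[str], out_path) -> Path:
    """Diverging heatmap of palette residuals, centred at 0.

    Colour limits are symmetric at the maximum absolute residual; group
    separators and a scale bar are drawn.
    """
    df = _to_frame(residuals)
    if df.shape[0] == 0:
        raise ValueError("no residuals to plot")
    labels = list(labels)
    if len(labels) != df.shape[0]:
        raise ValueError("labels must match rows")
    lim = float(np.max(np.abs(df.to_numpy()))) or 1e-12

    fig, ax = plt.subplots(figsize=(4.5, max(2.5, 0.05 * len(labels) + 1.5)))
    im = ax.imshow(df.to_numpy(), cmap="RdBu_r", vmin=-lim, vmax=lim,
                   aspect="auto", interpolation="nearest")
    bounds, centers = _group_boundaries(labels)
    for b in bounds:
        ax.axhline(b - 0.5, color="black", linewidth=0.8)
    ax.set_yticks([c for _, c in centers])
    ax.set_yticklabels([g for g, _ in centers], fontsize=7)
    ax.set_xticks(np.arange(df.shape[1]))
    ax.set_xticklabels([str(c) for c in df.columns], rotation=90, fontsize=7)
    fig.colorbar(im, ax=ax, label="residual (palette fraction)")
    fig.savefig(out_path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return Path(out_path)
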