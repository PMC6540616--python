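"""Figure-style report assembly: score heatmaps and bar-with-points panels."""

from __future__ import annotations

from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.colors import BoundaryNorm, ListedColormap

from .scoring import clip_score

__all__ = ["HEATMAP_PALETTE", "plot_score_heatmap", "plot_group_bars"]

# 5-bin palette: <0.2 purple, 0.2-0.4 blue, 0.4-0.6 teal, 0.6-0.8 green, >0.8 yellow
HEATMAP_PALETTE = ("#6a0dad", "#1f4fd8", "#008080", "#2e9e3e", "#ffd400")
_BOUNDS = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)


def plot_score_heatmap(scores: pd.DataFrame, path: str | None = None, ax=None):
    """Mutant x ligand interaction-score heatmap with the 5-bin palette.

    ``scores`` is a mutants-by-ligands frame of raw scores; values are
    clipped to [0, 1] for display (raw values are untouched) and binned
    lower-inclusively.  NaN cells render white (no data).
    """
    clipped = scores.map(lambda v: clip_score(v) if pd.notna(v) else np.nan)
    cmap = ListedColormap(HEATMAP_PALETTE)
    cmap.set_bad("white")
    norm = BoundaryNorm(_BOUNDS, cmap.N)
    if ax is None:
        _, ax = plt.subplots(
            figsize=(1.0 + 0.6 * clipped.shape[1], 1.0 + 0.35 * clipped.shape[0])
        )
    ax.imshow(np.ma.masked_invalid(clipped.to_numpy(dtype=float)), cmap=cmap, norm=norm,
              aspect="auto", interpolation="nearest")
    ax.set_xticks(range(clipped.shape[1]), clipped.columns, rotation=45, ha="right")
    ax.set_yticks(range(clipped.shape[0]), clipped.index)
    ax.set_xlabel("ligand")
    if path:
        ax.figure.savefig(path, bbox_inches="tight", dpi=150)
        plt.close(ax.figure)
    return ax


def plot_group_bars(
    groups: Mapping[str, Sequence[float]], path: str | None = None, ax=None, ylabel: str = ""
):
    """Per-condition bars (mean ± SEM) with individual data points overlaid."""
    labels = list(groups)
    rng = np.random.default_rng(0)  # jitter only, cosmetic
    if ax is None:
        _, ax = plt.subplots(figsize=(1.0 + 0.8 * len(labels), 3.2))
    for i, label in enumerate(labels):
        v = np.asarray(groups[label], dtype=float)
        sem = np.std(v, ddof=1) / np.sqrt(v.size) if v.size > 1 else 0.0
        ax.bar(i, v.mean(), yerr=sem, capsize=3, color="#cccccc", edgecolor="black")
        ax.scatter(i + rng.uniform(-0.15, 0.15, v.size), v, s=12, color="black", zorder=3)
    ax.set_xticks(range(len(labels)), labels, rotation=45, ha="right")
    ax.set_ylabel(ylabel)
    if path:
        ax.figure.savefig(path, bbox_inches="tight", dpi=150)
        plt.close(ax.figure)
    return ax
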