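"""Histograms and bivariate dot plots in the image-cytometry idiom."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["histogram", "dotplot"]


def histogram(
    data: pd.DataFrame,
    column: str,
    out_path: str | Path | None = None,
    bins: int = 128,
    log: bool = False,
    ax: plt.Axes | None = None,
) -> plt.Axes:
    """Single-parameter histogram (optionally log-scaled intensities)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    v = data[column].to_numpy(float)
    v = v[np.isfinite(v)]
    if log:
        v = v[v > 0]
        ax.hist(np.log10(v), bins=bins, color="0.3")
        ax.set_xlabel(f"log10 {column}")
    else:
        ax.hist(v, bins=bins, color="0.3")
        ax.set_xlabel(column)
    ax.set_ylabel("cells")
    if out_path is not None:
        ax.figure.savefig(out_path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def dotplot(
    data: pd.DataFrame,
    x_column: str,
    y_column: str,
    out_path: str | Path | None = None,
    color_by: str | None = None,
    gates: Sequence[tuple[str, float, float, float, float]] = (),
    log_y: bool = False,
    ax: plt.Axes | None = None,
) -> plt.Axes:
    """Bivariate dot plot with optional drawn rectangular gate regions.

    ``gates`` entries are ``(name, x_lo, x_hi, y_lo, y_hi)`` rectangles,
    drawn the way DNA x EdU population windows are shown on cytometry plots.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4.5))
    x = data[x_column].to_numpy(float)
    y = data[y_column].to_numpy(float)
    if color_by is not None and color_by in data.columns:
        for value, sub in data.groupby(color_by):
            ax.scatter(sub[x_column], sub[y_column], s=2, alpha=0.5, label=str(value))
        ax.legend(markerscale=4, fontsize=7)
    else:
        ax.scatter(x, y, s=2, alpha=0.4, color="0.2")
    for name, x0, x1, y0, y1 in gates:
        ax.add_patch(
            plt.Rectangle((x0, y0), x1 - x0, y1 - y0, fill=False, edgecolor="crimson", lw=1)
        )
        ax.annotate(name, (x0, y1), fontsize=7, color="crimson")
    if log_y:
        ax.set_yscale("log")
    ax.set_xlabel(x_column)
    ax.set_ylabel(y_column)
    if out_path is not None:
        ax.figure.savefig(out_path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
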