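"""PLA spot / DDR focus proximity statistics.

A proximity-ligation spot reports two epitopes within tens of nanometres;
whether that interaction sits at a DNA-damage focus or in the nucleoplasm is
decided by the distance from the spot to the nearest same-cell reference
focus.  The default adjacency threshold is 1 um (inclusive), centroid to
centroid.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import mannwhitneyu

__all__ = [
    "associate_spots_to_foci",
    "pearson_correlation",
    "median_split_compare",
]


def associate_spots_to_foci(
    pla: pd.DataFrame,
    ref_foci: pd.DataFrame,
    threshold_um: float = 1.0,
    pixel_size_um: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Match each PLA spot to the nearest same-cell reference focus.

    Both inputs are flat focus-record frames (``cell_id``, ``centroid_x_px``,
    ``centroid_y_px``; coordinates convert to um via ``pixel_size_um``, or
    pass ``centroid_x_um``/``centroid_y_um`` directly).  Adjacency is an
    inclusive Euclidean threshold.

    Returns ``(associations, per_cell)``: one association row per PLA spot
    (nearest focus id, distance, adjacency flag; spots in cells without any
    reference focus get no nearest focus), and per-cell counts
    ``n_pla_total`` / ``n_pla_adjacent``.
    """
    if threshold_um <= 0:
        raise ValueError("threshold_um must be > 0")

    def _coords(df: pd.DataFrame) -> np.ndarray:
        if "centroid_x_um" in df.columns:
            return df[["centroid_x_um", "centroid_y_um"]].to_numpy(float)
        if pixel_size_um is None:
            raise ValueError("pixel_size_um required when centroids are in pixels")
        return df[["centroid_x_px", "centroid_y_px"]].to_numpy(float) * pixel_size_um

    pla_xy = _coords(pla)
    ref_xy = _coords(ref_foci)

    ref_ids = (
        ref_foci["focus_id"].to_numpy()
        if "focus_id" in ref_foci.columns
        else np.arange(len(ref_foci))
    )
    pla_ids = (
        pla["focus_id"].to_numpy() if "focus_id" in pla.columns else np.arange(len(pla))
    )
    cells = pla["cell_id"].to_numpy()
    ref_cells = ref_foci["cell_id"].to_numpy()
    trees: dict = {}
    for cid in pd.unique(ref_cells):
        pos = np.flatnonzero(ref_cells == cid)
        trees[cid] = (cKDTree(ref_xy[pos]), pos)

    rows: list[dict] = []
    for i in range(len(pla)):
        entry = {
            "pla_focus_id": pla_ids[i],
            "cell_id": cells[i],
            "nearest_focus_id": None,
            "distance_um": np.nan,
            "adjacent": False,
        }
        hit = trees.get(cells[i])
        if hit is not None:
            tree, pos = hit
            dist, j = tree.query(pla_xy[i])
            entry["nearest_focus_id"] = ref_ids[pos[j]]
            entry["distance_um"] = float(dist)
            entry["adjacent"] = bool(dist <= threshold_um)
        rows.append(entry)
    associations = pd.DataFrame(
        rows, columns=["pla_focus_id", "cell_id", "nearest_focus_id", "distance_um", "adjacent"]
    )

    if len(associations):
        grouped = associations.groupby("cell_id")
        per_cell = pd.DataFrame(
            {
                "n_pla_total": grouped.size(),
                "n_pla_adjacent": grouped["adjacent"].sum().astype(int),
            }
        ).reset_index()
    else:
        per_cell = pd.DataFrame(columns=["cell_id", "n_pla_total", "n_pla_adjacent"])
    return associations, per_cell


def pearson_correlation(table: pd.DataFrame, x_col: str, y_col: str) -> tuple[float, int]:
    """Product-moment correlation between two columns.

    Raises on fewer than 3 finite pairs or on zero variance (an undefined
    correlation is an analysis error here, not a silent NaN).
    """
    x = table[x_col].to_numpy(float)
    y = table[y_col].to_numpy(float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ValueError(f"need >= 3 finite pairs, got {n}")
    # extended-precision accumulation of the textbook formula
    xm = math.fsum(x) / n
    ym = math.fsum(y) / n
    sxx = math.fsum((xi - xm) ** 2 for xi in x)
    syy = math.fsum((yi - ym) ** 2 for yi in y)
    if sxx == 0 or syy == 0:
        raise ValueError("zero variance: correlation undefined")
    sxy = math.fsum((xi - xm) * (yi - ym) for xi, yi in zip(x, y))
    r = sxy / math.sqrt(sxx * syy)
    return float(max(-1.0, min(1.0, r))), int(n)


def median_split_compare(
    table: pd.DataFrame,
    split_col: str,
    compare_cols: Sequence[str],
) -> dict:
    """Split the population at the median of ``split_col`` and compare groups.

    ``below`` holds values <= median (ties go below, deterministically),
    ``above`` strictly greater.  For every compare column the group
    mean/median/SD and a two-sample Mann-Whitney rank-sum p-value are
    reported.
    """
    v = table[split_col].to_numpy(float)
    if len(v) < 4:
        raise ValueError("median split needs at least 4 rows")
    if np.ptp(v[np.isfinite(v)]) == 0:
        raise ValueError(f"all values of {split_col!r} are equal: split undefined")
    med = float(np.median(v))
    below = table.loc[v <= med]
    above = table.loc[v > med]

    result: dict = {
        "median": med,
        "n_below": int(len(below)),
        "n_above": int(len(above)),
        "columns": {},
    }
    for col in compare_cols:
        lo = below[col].to_numpy(float)
        hi = above[col].to_numpy(float)
        stat = {}
        for name, g in (("below", lo), ("above", hi)):
            stat[name] = {
                "mean": float(np.nanmean(g)),
                "median": float(np.nanmedian(g)),
                "sd": float(np.nanstd(g, ddof=1)) if len(g) > 1 else float("nan"),
            }
        u = mannwhitneyu(lo, hi, alternative="two-sided")
        stat["rank_sum_p"] = float(u.pvalue)
        result["columns"][col] = stat
    return result
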