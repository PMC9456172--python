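"""Per-cell measurement database, flow-cytometry-style gating, and the
DNA x EdU six-population cell-cycle classifier.

Measurements are stored in a :class:`CellTable` (a thin wrapper around a
pandas DataFrame) persisted as tab-delimited text, mirroring how image
cytometry databases are shared between analysis and plotting tools.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde
from skimage import measure as skmeasure

from .imaging_io import ChannelImage, image_to_stage
from .segmentation import LabelMask

__all__ = [
    "CellTable",
    "Gate",
    "IntervalGate",
    "PolygonGate",
    "AndGate",
    "OrGate",
    "NotGate",
    "CYCLE_LABELS",
    "measure_cells",
    "measure_foci",
    "foci_fraction",
    "apply_gate",
    "estimate_g1_peak",
    "estimate_edu_threshold",
    "classify_cell_cycle",
    "gallery_crops",
]

#: The six DNA x EdU populations: EdU sign crossed with the DNA-content window.
CYCLE_LABELS = ("2N+", "midN+", "4N+", "2N-", "midN-", "4N-")
UNASSIGNED = "unassigned"


@dataclass
class CellTable:
    """Per-nucleus feature records plus provenance, persisted as tab-text."""

    data: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if "cell_id" in self.data.columns and self.data["cell_id"].duplicated().any():
            raise ValueError("cell_ids must be unique")

    def __len__(self) -> int:
        return len(self.data)

    # -- tab-text database ---------------------------------------------------
    def write(self, path: str | Path) -> Path:
        """Write the table as tab-delimited text (header row, empty fields
        for missing values) plus a JSON provenance sidecar."""
        path = Path(path)
        self.data.to_csv(path, sep="\t", index=False, na_rep="")
        if self.provenance:
            path.with_suffix(path.suffix + ".provenance.json").write_text(
                json.dumps(self.provenance, indent=1, sort_keys=True)
            )
        return path

    @classmethod
    def read(cls, path: str | Path) -> "CellTable":
        path = Path(path)
        try:
            data = pd.read_csv(path, sep="\t")
        except pd.errors.ParserError as exc:  # pragma: no cover
            raise ValueError(f"malformed table header in {path}: {exc}") from exc
        sidecar = path.with_suffix(path.suffix + ".provenance.json")
        provenance = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        return cls(data=data, provenance=provenance)

    def config_hash(self, config: Mapping) -> str:
        digest = hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()
        self.provenance["config_hash"] = digest
        return digest


# ---------------------------------------------------------------------------
# measurement


def measure_cells(
    nuclei: LabelMask,
    images: Sequence[ChannelImage],
    field_id: str = "",
) -> CellTable:
    """Measure shape and per-channel fluorescence for every nucleus.

    Integrated intensity is the sum of pixel values inside the label, mean
    intensity the integrated value over the pixel count; areas convert to
    um^2 through the squared pixel size.  Circularity is ``4*pi*area /
    perimeter^2`` with the Crofton perimeter estimate, clipped at 1 (a
    rasterized disk can overshoot slightly).
    """
    if nuclei.kind != "nucleus":
        raise ValueError("measure_cells requires a nucleus mask")
    for img in images:
        if np.asarray(img.pixels).shape != nuclei.labels.shape:
            raise ValueError(f"channel {img.channel!r} geometry does not match the mask")
    px = nuclei.pixel_size_um
    labels = nuclei.labels
    regions = skmeasure.regionprops(labels)

    rows: list[dict] = []
    for region in regions:
        cy, cx = region.centroid
        perim = region.perimeter_crofton
        circ = min(1.0, 4 * np.pi * region.area / perim**2) if perim > 0 else np.nan
        rows.append(
            {
                "cell_id": f"{field_id}:{region.label}" if field_id else str(region.label),
                "field_id": field_id,
                "label": region.label,
                "centroid_x_px": cx,
                "centroid_y_px": cy,
                "area_um2": region.area * px**2,
                "circularity": circ,
                "on_border": region.label in nuclei.border_labels,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "cell_id", "field_id", "label", "centroid_x_px", "centroid_y_px",
            "area_um2", "circularity", "on_border",
        ],
    )

    for img in images:
        pixels = np.asarray(img.pixels, dtype=float)
        integrated = np.array(
            [pixels[labels == r.label].sum() for r in regions]
        ) if regions else np.array([])
        counts = np.array([r.area for r in regions]) if regions else np.array([])
        table[f"int_{img.channel}"] = integrated
        table[f"mean_{img.channel}"] = integrated / counts if len(counts) else integrated
        meta = img.metadata
        if regions and table.get("centroid_stage_x_um") is None:
            stage = image_to_stage(
                np.column_stack([table["centroid_x_px"], table["centroid_y_px"]]), meta
            )
            table["centroid_stage_x_um"] = stage[:, 0]
            table["centroid_stage_y_um"] = stage[:, 1]

    return CellTable(data=table, provenance={"field_id": field_id})


def measure_foci(
    foci: LabelMask,
    images: Sequence[ChannelImage],
    cells: CellTable,
    nuclei: LabelMask | None = None,
) -> tuple[CellTable, pd.DataFrame]:
    """Aggregate focus measurements per cell and export the flat focus list.

    Augments ``cells`` with, for the focus channel: ``n_foci``, the sum of
    focus integrated intensities, the mean focus area, and the fraction of
    the cell's channel intensity located in foci.  Foci are also returned as
    independent events (one row per focus) without reference to gating.

    Each focus integrated intensity is corrected for the diffuse signal
    underneath it: the parent nucleus' nucleoplasm mean (computed outside
    all foci) times the focus area is subtracted, so the value estimates
    the photons contributed by the spot itself.  The uncorrected sum is
    kept in ``integrated_raw``.
    """
    if foci.kind != "focus":
        raise ValueError("measure_foci requires a focus mask")
    nuclei_labels = nuclei.labels if nuclei is not None else None
    ch = foci.channel
    img = next((im for im in images if im.channel == ch), None)
    if img is None:
        raise ValueError(f"no image provided for focus channel {ch!r}")
    pixels = np.asarray(img.pixels, dtype=float)
    px = foci.pixel_size_um

    # nucleoplasm baseline per nucleus: mean intensity outside any focus
    baseline: dict[int, float] = {}
    if nuclei_labels is not None:
        plasm = (nuclei_labels > 0) & (foci.labels == 0)
        for lab in np.unique(nuclei_labels[nuclei_labels > 0]):
            sel = plasm & (nuclei_labels == lab)
            baseline[int(lab)] = float(pixels[sel].mean()) if sel.any() else 0.0

    focus_rows: list[dict] = []
    label_col = cells.data.set_index("label")["cell_id"] if len(cells.data) else pd.Series(dtype=object)
    for region in skmeasure.regionprops(foci.labels):
        parent = foci.parent_map.get(region.label, 0)
        if parent == 0 or parent not in label_col.index:
            raise ValueError(f"focus {region.label} has no known parent nucleus")
        vals = pixels[tuple(region.coords.T)]
        cy, cx = region.centroid
        raw = float(vals.sum())
        corrected = max(0.0, raw - baseline.get(parent, 0.0) * region.area)
        focus_rows.append(
            {
                "focus_id": f"{ch}:{region.label}",
                "cell_id": label_col.loc[parent],
                "channel": ch,
                "area_um2": region.area * px**2,
                "mean_intensity": float(vals.mean()),
                "integrated_intensity": corrected,
                "integrated_raw": raw,
                "centroid_x_px": cx,
                "centroid_y_px": cy,
            }
        )
    focus_records = pd.DataFrame(
        focus_rows,
        columns=[
            "focus_id", "cell_id", "channel", "area_um2", "mean_intensity",
            "integrated_intensity", "integrated_raw", "centroid_x_px", "centroid_y_px",
        ],
    )

    data = cells.data.copy()
    if len(focus_records):
        grouped = focus_records.groupby("cell_id")
        n = grouped.size()
        integ = grouped["integrated_intensity"].sum()
        mean_area = grouped["area_um2"].mean()
    else:
        n = integ = mean_area = pd.Series(dtype=float)
    data[f"n_foci_{ch}"] = data["cell_id"].map(n).fillna(0).astype(int)
    data[f"foci_int_{ch}"] = data["cell_id"].map(integ).fillna(0.0)
    data[f"mean_focus_area_um2_{ch}"] = data["cell_id"].map(mean_area).fillna(0.0)
    total = data.get(f"int_{ch}")
    if total is not None:
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(total > 0, data[f"foci_int_{ch}"] / total, np.nan)
        data[f"foci_frac_{ch}"] = np.clip(frac, 0.0, 1.0)
    return CellTable(data=data, provenance=dict(cells.provenance)), focus_records


def foci_fraction(cell: Mapping, channel: str) -> float:
    """Fraction of a cell's channel intensity that lies inside its foci.

    Undefined (NaN) when the nuclear integrated intensity is zero; such
    cells are flagged rather than silently dropped.
    """
    total = cell[f"int_{channel}"]
    in_foci = cell[f"foci_int_{channel}"]
    if total <= 0:
        warnings.warn("zero nuclear intensity: foci fraction undefined", stacklevel=2)
        return float("nan")
    return float(min(1.0, max(0.0, in_foci / total)))


# ---------------------------------------------------------------------------
# gating


class Gate:
    """Base class for logical gates over table columns."""

    name: str = ""

    def mask(self, data: pd.DataFrame) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def __and__(self, other: "Gate") -> "AndGate":
        return AndGate(self, other)

    def __or__(self, other: "Gate") -> "OrGate":
        return OrGate(self, other)

    def __invert__(self) -> "NotGate":
        return NotGate(self)


@dataclass
class IntervalGate(Gate):
    """Closed interval gate ``lo <= column <= hi`` (either bound optional)."""

    column: str
    lo: float = -np.inf
    hi: float = np.inf
    name: str = ""

    def mask(self, data: pd.DataFrame) -> np.ndarray:
        if self.column not in data.columns:
            raise KeyError(f"unknown gate column {self.column!r}")
        v = data[self.column].to_numpy(float)
        return (v >= self.lo) & (v <= self.hi)


@dataclass
class PolygonGate(Gate):
    """Two-column polygon gate, as drawn on a bivariate dot plot."""

    x_column: str
    y_column: str
    vertices: Sequence[tuple[float, float]] = ()
    name: str = ""

    def mask(self, data: pd.DataFrame) -> np.ndarray:
        for col in (self.x_column, self.y_column):
            if col not in data.columns:
                raise KeyError(f"unknown gate column {col!r}")
        from matplotlib.path import Path as MplPath

        pts = np.column_stack(
            [data[self.x_column].to_numpy(float), data[self.y_column].to_numpy(float)]
        )
        return MplPath(np.asarray(self.vertices)).contains_points(pts)


@dataclass
class AndGate(Gate):
    a: Gate = None
    b: Gate = None
    name: str = ""

    def mask(self, data: pd.DataFrame) -> np.ndarray:
        return self.a.mask(data) & self.b.mask(data)


@dataclass
class OrGate(Gate):
    a: Gate = None
    b: Gate = None
    name: str = ""

    def mask(self, data: pd.DataFrame) -> np.ndarray:
        return self.a.mask(data) | self.b.mask(data)


@dataclass
class NotGate(Gate):
    a: Gate = None
    name: str = ""

    def mask(self, data: pd.DataFrame) -> np.ndarray:
        return ~self.a.mask(data)


def apply_gate(
    table: CellTable, gate: Gate, stat_columns: Sequence[str] = ()
) -> tuple[CellTable, dict]:
    """Select the sub-population passing ``gate`` plus summary statistics.

    Returns the gated :class:`CellTable` and a summary dict with ``n`` and,
    for each requested column, mean/median/SD over the selected cells.
    """
    mask = gate.mask(table.data)
    subset = table.data.loc[mask].reset_index(drop=True)
    summary: dict = {"n": int(mask.sum())}
    for col in stat_columns:
        if col not in subset.columns:
            raise KeyError(f"unknown summary column {col!r}")
        v = subset[col].to_numpy(float)
        summary[col] = {
            "mean": float(np.nanmean(v)) if len(v) else float("nan"),
            "median": float(np.nanmedian(v)) if len(v) else float("nan"),
            "sd": float(np.nanstd(v, ddof=1)) if len(v) > 1 else float("nan"),
        }
    return CellTable(data=subset, provenance=dict(table.provenance)), summary


# ---------------------------------------------------------------------------
# DNA x EdU cell-cycle classification


def estimate_g1_peak(dna: np.ndarray) -> float:
    """Locate the G1 (2N) peak of a DNA-content distribution.

    Kernel-density estimate, then the leftmost density peak whose height is
    at least a quarter of the tallest peak; this keeps a dominant 4N peak
    (long G2, short G1 populations) from being mistaken for 2N.
    """
    dna = np.asarray(dna, dtype=float)
    dna = dna[np.isfinite(dna) & (dna > 0)]
    if dna.size < 10 or np.ptp(dna) == 0:
        raise ValueError("no detectable DNA peak")
    kde = gaussian_kde(dna)
    grid = np.linspace(dna.min(), dna.max(), 512)
    dens = kde(grid)
    peaks, props = find_peaks(dens, height=0.25 * dens.max())
    if peaks.size == 0:
        return float(grid[np.argmax(dens)])
    return float(grid[peaks[0]])


def estimate_edu_threshold(edu: np.ndarray) -> float:
    """EdU +/- threshold: Otsu on the log-transformed EdU intensity."""
    from skimage.filters import threshold_otsu

    edu = np.asarray(edu, dtype=float)
    edu = edu[np.isfinite(edu) & (edu > 0)]
    if edu.size < 10 or np.ptp(edu) == 0:
        raise ValueError("cannot derive an EdU threshold from a degenerate distribution")
    return float(10 ** threshold_otsu(np.log10(edu)))


def classify_cell_cycle(
    table: CellTable,
    edu_col: str = "int_EdU",
    dna_col: str = "int_DNA",
    options: Mapping | None = None,
) -> CellTable:
    """Assign each cell one of the six DNA x EdU population labels.

    EdU+/- split at ``options['edu_threshold']`` (default: Otsu on log EdU);
    DNA windows around the G1 peak position ``p`` (``options['g1_peak']`` or
    a kernel-density mode estimate):

    ======  =====================
    2N      ``[0.8 p, 1.2 p]``
    midN    ``(1.2 p, 1.6 p)``
    4N      ``[1.6 p, 2.4 p]``
    ======  =====================

    Cells with DNA outside ``[0.8 p, 2.4 p]`` are labelled ``unassigned``
    (never dropped).  The six labels partition the assigned cells.
    """
    opts = dict(options or {})
    data = table.data.copy()
    for col in (edu_col, dna_col):
        if col not in data.columns:
            raise KeyError(f"column {col!r} not in table")
    dna = data[dna_col].to_numpy(float)
    edu = data[edu_col].to_numpy(float)

    p = float(opts.get("g1_peak") or estimate_g1_peak(dna))
    thr = float(opts.get("edu_threshold") or estimate_edu_threshold(edu))

    edu_pos = edu > thr
    win = np.full(len(data), UNASSIGNED, dtype=object)
    win[(dna >= 0.8 * p) & (dna <= 1.2 * p)] = "2N"
    win[(dna > 1.2 * p) & (dna < 1.6 * p)] = "midN"
    win[(dna >= 1.6 * p) & (dna <= 2.4 * p)] = "4N"

    label = np.where(
        win == UNASSIGNED, UNASSIGNED, np.char.add(win.astype(str), np.where(edu_pos, "+", "-"))
    )
    data["cycle_label"] = label
    data["edu_positive"] = edu_pos
    out = CellTable(data=data, provenance=dict(table.provenance))
    out.provenance.update({"g1_peak": p, "edu_threshold": thr})
    return out


# ---------------------------------------------------------------------------
# gallery retrieval


def gallery_crops(
    table: CellTable,
    image: ChannelImage,
    pad_um: float = 2.0,
) -> list[dict]:
    """Retrieve per-cell image crops for visual inspection of a gated set.

    Each crop is centered on the nucleus centroid with ``pad_um`` padding
    beyond the cell's equivalent radius; pixel values are copied without
    rescaling.  Cells clipped by the image edge are flagged.
    """
    pixels = np.asarray(image.pixels)
    px = image.pixel_size_um
    crops: list[dict] = []
    for _, row in table.data.iterrows():
        radius_um = np.sqrt(row["area_um2"] / np.pi)
        half = int(np.ceil((radius_um + pad_um) / px))
        cy, cx = int(round(row["centroid_y_px"])), int(round(row["centroid_x_px"]))
        r0, r1 = cy - half, cy + half + 1
        c0, c1 = cx - half, cx + half + 1
        clipped = r0 < 0 or c0 < 0 or r1 > pixels.shape[0] or c1 > pixels.shape[1]
        crop = pixels[max(r0, 0) : r1, max(c0, 0) : c1].copy()
        crops.append({"cell_id": row["cell_id"], "pixels": crop, "clipped": clipped})
    return crops
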