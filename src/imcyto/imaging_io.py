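"""Image, metadata, localization-table and position-list I/O.

All pixel coordinates are 0-based with the pixel center at integer
coordinates; arrays are indexed ``(row, col)`` internally while every
user-facing ``(x, y)`` pair means ``(col, row)``.  Stage coordinates are in
micrometres, SMLM localization coordinates in nanometres.

Vendor metadata formats are deliberately not parsed: acquisition metadata
comes from a JSON sidecar (``<image>.json``) or from the layout
configuration, which acts as the adapter hook for microscope-specific
set-ups.
"""

from __future__ import annotations

import csv
import json
import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "AcquisitionMetadata",
    "ChannelImage",
    "LocalizationTable",
    "PositionList",
    "read_image_set",
    "write_channel_image",
    "read_channel_image",
    "image_to_stage",
    "stage_to_image",
    "write_position_list",
    "read_position_list",
    "read_localizations",
    "write_localizations",
    "DEFAULT_LOC_DIALECT",
]


@dataclass(frozen=True)
class AcquisitionMetadata:
    """Per-image acquisition metadata needed to map pixels to stage positions."""

    stage_x_um: float
    stage_y_um: float
    pixel_size_um: float
    width_px: int
    height_px: int
    axis_orientation: tuple[int, int] = (1, 1)
    field_id: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.pixel_size_um) or self.pixel_size_um <= 0:
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        if self.width_px < 1 or self.height_px < 1:
            raise ValueError("image dimensions must be >= 1 pixel")
        sx, sy = self.axis_orientation
        if sx not in (-1, 1) or sy not in (-1, 1):
            raise ValueError("axis_orientation entries must be +1 or -1")

    def to_dict(self) -> dict:
        return {
            "stage_x_um": self.stage_x_um,
            "stage_y_um": self.stage_y_um,
            "pixel_size_um": self.pixel_size_um,
            "width_px": self.width_px,
            "height_px": self.height_px,
            "axis_orientation": list(self.axis_orientation),
            "field_id": self.field_id,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "AcquisitionMetadata":
        d = dict(d)
        d["axis_orientation"] = tuple(d.get("axis_orientation", (1, 1)))
        return cls(**d)


@dataclass
class ChannelImage:
    """One 2-D fluorescence plane with its channel name and metadata."""

    pixels: np.ndarray
    channel: str
    metadata: AcquisitionMetadata

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if self.pixels.shape != (self.metadata.height_px, self.metadata.width_px):
            raise ValueError(
                f"pixel array shape {self.pixels.shape} does not match metadata "
                f"({self.metadata.height_px}, {self.metadata.width_px})"
            )
        if np.any(self.pixels < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def pixel_size_um(self) -> float:
        return self.metadata.pixel_size_um

    def with_pixels(self, pixels: np.ndarray) -> "ChannelImage":
        return ChannelImage(pixels=pixels, channel=self.channel, metadata=self.metadata)


#: Column mapping of the default localization-table dialect (header-named,
#: ThunderSTORM-like).  Remap any of the keys via the ``columns`` entry of a
#: dialect dict; declare units with ``unit`` ("nm" or "um").
DEFAULT_LOC_DIALECT: dict = {
    "sep": ",",
    "unit": "nm",
    "columns": {
        "x": "x [nm]",
        "y": "y [nm]",
        "precision": "uncertainty [nm]",
        "photons": "intensity [photons]",
        "frame": "frame",
        "channel": "channel",
    },
}


@dataclass
class LocalizationTable:
    """SMLM molecule list: coordinates in nm plus per-molecule fit info."""

    x_nm: np.ndarray
    y_nm: np.ndarray
    precision_nm: np.ndarray
    photons: np.ndarray
    frame: np.ndarray
    channel: str = ""

    def __post_init__(self) -> None:
        self.x_nm = np.asarray(self.x_nm, dtype=float)
        self.y_nm = np.asarray(self.y_nm, dtype=float)
        n = self.x_nm.size
        if self.y_nm.size != n:
            raise ValueError("x and y must have equal length")
        self.precision_nm = np.broadcast_to(
            np.asarray(self.precision_nm, dtype=float), (n,)
        ).copy()
        self.photons = np.broadcast_to(np.asarray(self.photons, dtype=float), (n,)).copy()
        self.frame = np.broadcast_to(np.asarray(self.frame, dtype=int), (n,)).copy()
        if not (np.all(np.isfinite(self.x_nm)) and np.all(np.isfinite(self.y_nm))):
            raise ValueError("coordinates must be finite")
        if np.any(self.precision_nm < 0):
            raise ValueError("precision_nm must be >= 0")

    def __len__(self) -> int:
        return int(self.x_nm.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x_nm": self.x_nm,
                "y_nm": self.y_nm,
                "precision_nm": self.precision_nm,
                "photons": self.photons,
                "frame": self.frame,
                "channel": self.channel,
            }
        )


@dataclass
class PositionList:
    """Ordered stage positions with unique labels, for re-acquisition."""

    labels: list[str] = field(default_factory=list)
    x_um: list[float] = field(default_factory=list)
    y_um: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("position-list labels must be unique")
        if not (len(self.labels) == len(self.x_um) == len(self.y_um)):
            raise ValueError("labels, x_um and y_um must have equal length")

    def __len__(self) -> int:
        return len(self.labels)


# ---------------------------------------------------------------------------
# image <-> stage coordinate mapping


def image_to_stage(
    pixel_xy: Sequence[float] | np.ndarray, metadata: AcquisitionMetadata
) -> np.ndarray:
    """Convert image pixel coordinates ``(x, y)`` to stage coordinates in um.

    The stage position of the image origin (pixel (0, 0)) plus the signed
    pixel offset scaled by the pixel size:

        stage = origin + orientation * pixel_xy * pixel_size_um

    Out-of-bounds pixels are allowed (a warning is emitted) so that, e.g.,
    padded crop centers can still be relocated.
    """
    p = np.asarray(pixel_xy, dtype=float)
    if not np.all(np.isfinite(p)):
        raise ValueError("pixel coordinates must be finite")
    x, y = p[..., 0], p[..., 1]
    if np.any(x < 0) or np.any(x > metadata.width_px - 1) or np.any(y < 0) or np.any(
        y > metadata.height_px - 1
    ):
        warnings.warn("pixel coordinates outside image bounds", stacklevel=2)
    sx, sy = metadata.axis_orientation
    out = np.empty_like(p)
    out[..., 0] = metadata.stage_x_um + sx * x * metadata.pixel_size_um
    out[..., 1] = metadata.stage_y_um + sy * y * metadata.pixel_size_um
    return out


def stage_to_image(
    stage_xy_um: Sequence[float] | np.ndarray, metadata: AcquisitionMetadata
) -> np.ndarray:
    """Inverse of :func:`image_to_stage`."""
    s = np.asarray(stage_xy_um, dtype=float)
    if not np.all(np.isfinite(s)):
        raise ValueError("stage coordinates must be finite")
    sx, sy = metadata.axis_orientation
    out = np.empty_like(s)
    out[..., 0] = sx * (s[..., 0] - metadata.stage_x_um) / metadata.pixel_size_um
    out[..., 1] = sy * (s[..., 1] - metadata.stage_y_um) / metadata.pixel_size_um
    return out


# ---------------------------------------------------------------------------
# image sets


def write_channel_image(image: ChannelImage, path: str | Path) -> Path:
    """Write a single-plane TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, image.pixels)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = image.metadata.to_dict()
    meta["channel"] = image.channel
    sidecar.write_text(json.dumps(meta, indent=1))
    return path


def read_channel_image(path: str | Path, channel: str | None = None) -> ChannelImage:
    """Read a TIFF written by :func:`write_channel_image` (sidecar metadata)."""
    path = Path(path)
    pixels = tifffile.imread(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"metadata sidecar not found: {sidecar}")
    meta = json.loads(sidecar.read_text())
    ch = channel if channel is not None else meta.pop("channel", "")
    meta.pop("channel", None)
    return ChannelImage(pixels=pixels, channel=ch, metadata=AcquisitionMetadata.from_dict(meta))


def read_image_set(
    paths: Iterable[str | Path],
    layout_config: Mapping,
) -> tuple[dict[str, list[ChannelImage]], list[str]]:
    """Group TIFFs into fields of named channels.

    ``layout_config`` keys:

    pattern
        regex with named groups ``field`` and ``channel`` applied to the file
        name (default ``"(?P<field>.+)_(?P<channel>[^_.]+)\\.tiff?"``).
    channel_map
        optional mapping from the filename channel token to a canonical
        channel name (e.g. ``{"dapi": "DNA"}``).
    required_channels
        channels that every field must provide; fields missing one are
        reported (and still returned).

    Returns ``(fields, problems)`` where ``fields`` maps field id to its list
    of :class:`ChannelImage` and ``problems`` is a list of human-readable
    validation messages (missing mandatory channels).  Unreadable files and
    duplicated channels raise immediately.
    """
    pattern = re.compile(layout_config.get("pattern", r"(?P<field>.+)_(?P<channel>[^_.]+)\.tiff?"))
    channel_map = layout_config.get("channel_map", {})
    required = list(layout_config.get("required_channels", []))

    fields: dict[str, list[ChannelImage]] = {}
    for path in paths:
        path = Path(path)
        m = pattern.fullmatch(path.name)
        if m is None:
            raise ValueError(f"file name {path.name!r} does not match the layout pattern")
        field_id = m.group("field")
        channel = channel_map.get(m.group("channel"), m.group("channel"))
        img = read_channel_image(path, channel=channel)
        if img.metadata.pixel_size_um <= 0:  # pragma: no cover - blocked upstream
            raise ValueError(f"missing pixel size for {path}")
        bucket = fields.setdefault(field_id, [])
        if any(other.channel == channel for other in bucket):
            raise ValueError(f"channel {channel!r} appears twice in field {field_id!r}")
        bucket.append(img)

    problems = []
    for field_id, images in sorted(fields.items()):
        have = {img.channel for img in images}
        for ch in required:
            if ch not in have:
                problems.append(f"field {field_id!r} is missing mandatory channel {ch!r}")
    return fields, problems


# ---------------------------------------------------------------------------
# position lists


def write_position_list(
    positions: PositionList, out_path: str | Path, dialect: str = "csv"
) -> Path:
    """Write a position list; the default dialect is ``label,x_um,y_um`` CSV.

    The dialect hook exists because stage-control software expects
    vendor-specific formats; adapters can register under other names.
    """
    if dialect != "csv":
        raise ValueError(f"unknown position-list dialect {dialect!r}")
    out_path = Path(out_path)
    if len(positions) == 0:
        warnings.warn("writing an empty position list (header only)", stacklevel=2)
    with open(out_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["label", "x_um", "y_um"])
        for label, x, y in zip(positions.labels, positions.x_um, positions.y_um):
            writer.writerow([label, repr(float(x)), repr(float(y))])
    return out_path


def read_position_list(path: str | Path, dialect: str = "csv") -> PositionList:
    if dialect != "csv":
        raise ValueError(f"unknown position-list dialect {dialect!r}")
    labels: list[str] = []
    xs: list[float] = []
    ys: list[float] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if header[:3] != ["label", "x_um", "y_um"]:
            raise ValueError(f"malformed position-list header: {header}")
        for row in reader:
            labels.append(row[0])
            xs.append(float(row[1]))
            ys.append(float(row[2]))
    return PositionList(labels=labels, x_um=xs, y_um=ys)


# ---------------------------------------------------------------------------
# localization tables


def read_localizations(
    path: str | Path, dialect: Mapping | None = None
) -> tuple[LocalizationTable, dict]:
    """Read a delimited localization table, normalizing coordinates to nm.

    ``dialect`` follows :data:`DEFAULT_LOC_DIALECT`; any subset of keys may
    be overridden.  Rows with non-finite coordinates are dropped and counted
    in the returned report dict.
    """
    d = dict(DEFAULT_LOC_DIALECT)
    if dialect:
        d.update({k: v for k, v in dialect.items() if k != "columns"})
        if "columns" in dialect:
            cols = dict(DEFAULT_LOC_DIALECT["columns"])
            cols.update(dialect["columns"])
            d["columns"] = cols
    cols = d["columns"]
    unit = d.get("unit", "nm")
    if unit not in ("nm", "um"):
        raise ValueError(f"unknown coordinate unit {unit!r}")
    scale = 1.0 if unit == "nm" else 1000.0

    df = pd.read_csv(path, sep=d.get("sep", ","))
    for key in ("x", "y"):
        if cols[key] not in df.columns:
            raise ValueError(f"localization table is missing column {cols[key]!r}")
    x = df[cols["x"]].to_numpy(float) * scale
    y = df[cols["y"]].to_numpy(float) * scale
    finite = np.isfinite(x) & np.isfinite(y)
    n_dropped = int((~finite).sum())

    def _col(key: str, default: float) -> np.ndarray:
        name = cols.get(key)
        if name is not None and name in df.columns:
            return df[name].to_numpy(float)[finite]
        return np.full(int(finite.sum()), default)

    precision = _col("precision", 0.0) * scale
    photons = _col("photons", 0.0)
    frame = _col("frame", 0.0).astype(int)
    chan_name = cols.get("channel")
    channel = ""
    if chan_name is not None and chan_name in df.columns:
        uniq = df.loc[finite, chan_name].unique()
        channel = str(uniq[0]) if len(uniq) == 1 else ""
    table = LocalizationTable(
        x_nm=x[finite], y_nm=y[finite], precision_nm=precision,
        photons=photons, frame=frame, channel=channel,
    )
    return table, {"n_read": int(len(df)), "n_dropped_nonfinite": n_dropped}


def write_localizations(
    table: LocalizationTable, path: str | Path, dialect: Mapping | None = None
) -> Path:
    """Write a localization table in the (possibly remapped) default dialect."""
    d = dict(DEFAULT_LOC_DIALECT)
    if dialect:
        d.update(dialect)
    cols = d["columns"]
    scale = 1.0 if d.get("unit", "nm") == "nm" else 1e-3
    df = pd.DataFrame(
        {
            cols["x"]: table.x_nm * scale,
            cols["y"]: table.y_nm * scale,
            cols["precision"]: table.precision_nm * scale,
            cols["photons"]: table.photons,
            cols["frame"]: table.frame,
            cols["channel"]: table.channel,
        }
    )
    df.to_csv(path, sep=d.get("sep", ","), index=False)
    return Path(path)
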