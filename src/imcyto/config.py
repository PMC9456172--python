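"""Analysis configuration schema (pydantic) for end-to-end runs.

The schema is validated in full before any computation starts; channel
names referenced anywhere in the config must be declared in ``channels``.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, model_validator


class LayoutConfig(BaseModel):
    pattern: str = r"(?P<field>.+)_(?P<channel>[^_.]+)\.tiff?"
    channel_map: dict[str, str] = Field(default_factory=dict)
    required_channels: list[str] = Field(default_factory=list)


class IlluminationConfig(BaseModel):
    background_mode: Literal["constant-percentile", "rolling-median", "none"] = "constant-percentile"
    background_percentile: float = 5.0
    flatfield: Literal["none", "estimate"] = "none"


class SegmentationConfig(BaseModel):
    min_area_um2: float = 30.0
    max_area_um2: float = 500.0
    smooth_sigma_px: float = 1.0
    keep_border: bool = True
    split_touching: bool = True


class FocusConfig(BaseModel):
    tophat_radius_um: float = 0.5
    k_sigma: float = 3.0
    min_area_um2: float = 0.05
    max_area_um2: float = 20.0
    split_touching: bool = False


class GateConfig(BaseModel):
    name: str
    column: str
    lo: float = float("-inf")
    hi: float = float("inf")


class CellCycleConfig(BaseModel):
    edu_col: str = "int_EdU"
    dna_col: str = "int_DNA"
    edu_threshold: Optional[float] = None
    g1_peak: Optional[float] = None


class ProximityConfig(BaseModel):
    pla_channel: str
    ref_channel: str
    threshold_um: float = 1.0


class ICCSConfig(BaseModel):
    pixel_size_nm: float = 10.0
    fit_radius_px: int = 10
    estimator: Literal["sqrt", "over_gg", "over_rr"] = "sqrt"


class AnalysisConfig(BaseModel):
    """Top-level configuration for :func:`imcyto.pipeline.run_pipeline`."""

    inputs: list[str] = Field(default_factory=list)
    layout: LayoutConfig = Field(default_factory=LayoutConfig)
    channels: list[str] = Field(default_factory=lambda: ["DNA"])
    dna_channel: str = "DNA"
    focus_channels: dict[str, FocusConfig] = Field(default_factory=dict)
    illumination: IlluminationConfig = Field(default_factory=IlluminationConfig)
    segmentation: SegmentationConfig = Field(default_factory=SegmentationConfig)
    gates: list[GateConfig] = Field(default_factory=list)
    cell_cycle: Optional[CellCycleConfig] = None
    proximity: Optional[ProximityConfig] = None
    iccs: ICCSConfig = Field(default_factory=ICCSConfig)
    output_dir: str = "imcyto_out"
    seed: int = 0

    @model_validator(mode="after")
    def _check_channels(self) -> "AnalysisConfig":
        known = set(self.channels)
        if self.dna_channel not in known:
            raise ValueError(f"dna_channel {self.dna_channel!r} not in channels {sorted(known)}")
        for ch in self.focus_channels:
            if ch not in known:
                raise ValueError(f"focus channel {ch!r} not in channels {sorted(known)}")
        if self.proximity is not None:
            for ch in (self.proximity.pla_channel, self.proximity.ref_channel):
                if ch not in known:
                    raise ValueError(f"proximity channel {ch!r} not in channels {sorted(known)}")
        return self

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.model_dump(mode="json"), sort_keys=True).encode()
        ).hexdigest()

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls.model_validate(data)
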