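"""Configuration-driven end-to-end analysis runs.

Stage order: illumination correction -> nucleus segmentation -> focus
segmentation -> per-cell and per-focus measurement -> gating / cell-cycle
classification -> proximity association -> export.  Any stage failure
aborts with the stage name and the offending field id; all tabular outputs
are stamped with the config hash and package version and are byte-identical
across re-runs with the same config and inputs.
"""

from __future__ import annotations

import glob
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .config import AnalysisConfig
from .cytometry import CellTable, IntervalGate, apply_gate, classify_cell_cycle, measure_cells, measure_foci
from .proximity import associate_spots_to_foci
from .segmentation import FocusParams, correct_illumination, segment_foci, segment_nuclei
from .imaging_io import read_image_set

__all__ = ["run_pipeline", "PipelineError"]

log = logging.getLogger("imcyto.pipeline")


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and field id."""

    def __init__(self, stage: str, field_id: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed on field {field_id!r}: {cause}")
        self.stage = stage
        self.field_id = field_id


def run_pipeline(config: AnalysisConfig) -> dict[str, CellTable]:
    """Run the full analysis described by ``config``.

    Returns the per-field cell tables (key ``"all"`` holds the concatenated
    table that was also written to ``output_dir``).
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()

    paths: list[str] = []
    for entry in config.inputs:
        hits = sorted(glob.glob(entry))
        paths.extend(hits if hits else [entry])

    stage = "read"
    field_id = ""
    try:
        fields, problems = read_image_set(paths, config.layout.model_dump())
    except Exception as exc:
        raise PipelineError(stage, field_id, exc) from exc
    for msg in problems:
        log.warning(msg)

    results: dict[str, CellTable] = {}
    all_focus_records: dict[str, list[pd.DataFrame]] = {}
    for field_id in sorted(fields):
        images = {img.channel: img for img in fields[field_id]}
        try:
            stage = "correct"
            corrected = {
                ch: correct_illumination(
                    img,
                    None,
                    background_mode=config.illumination.background_mode,
                    background_percentile=config.illumination.background_percentile,
                )
                for ch, img in images.items()
            }
            stage = "segment-nuclei"
            nuclei = segment_nuclei(
                corrected[config.dna_channel],
                min_area_um2=config.segmentation.min_area_um2,
                max_area_um2=config.segmentation.max_area_um2,
                smooth_sigma_px=config.segmentation.smooth_sigma_px,
                keep_border=config.segmentation.keep_border,
                split_touching=config.segmentation.split_touching,
            )
            log.info("field %s: %d nuclei", field_id, nuclei.n_objects)

            stage = "measure"
            table = measure_cells(nuclei, list(corrected.values()), field_id=field_id)

            stage = "segment-foci"
            for ch, fcfg in config.focus_channels.items():
                if ch not in corrected:
                    continue
                foci = segment_foci(corrected[ch], nuclei, FocusParams(**fcfg.model_dump()))
                table, records = measure_foci(foci, list(corrected.values()), table, nuclei=nuclei)
                all_focus_records.setdefault(ch, []).append(records)
                log.info("field %s: %d %s foci", field_id, foci.n_objects, ch)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(stage, field_id, exc) from exc
        results[field_id] = table

    stage = "aggregate"
    field_id = ""
    if not results:
        raise PipelineError(stage, field_id, ValueError("no fields produced any cells"))
    combined = CellTable(
        data=pd.concat([t.data for t in results.values()], ignore_index=True),
        provenance={"config_hash": cfg_hash, "version": __version__},
    )

    if config.cell_cycle is not None:
        stage = "classify"
        try:
            combined = classify_cell_cycle(
                combined,
                edu_col=config.cell_cycle.edu_col,
                dna_col=config.cell_cycle.dna_col,
                options={
                    "edu_threshold": config.cell_cycle.edu_threshold,
                    "g1_peak": config.cell_cycle.g1_peak,
                },
            )
        except Exception as exc:
            raise PipelineError(stage, field_id, exc) from exc

    stage = "gate"
    for g in config.gates:
        try:
            subset, summary = apply_gate(combined, IntervalGate(g.column, g.lo, g.hi, name=g.name))
        except Exception as exc:
            raise PipelineError(stage, field_id, exc) from exc
        log.info("gate %s: %d cells", g.name, summary["n"])
        subset.provenance.update({"config_hash": cfg_hash, "version": __version__, "gate": g.name})
        subset.write(out_dir / f"cells_{g.name}.tsv")

    if config.proximity is not None:
        stage = "proximity"
        try:
            pla_records = pd.concat(all_focus_records.get(config.proximity.pla_channel, []),
                                    ignore_index=True)
            ref_records = pd.concat(all_focus_records.get(config.proximity.ref_channel, []),
                                    ignore_index=True)
            # focus centroids come out in pixels; every field shares one pixel size
            px = next(iter(fields.values()))[0].metadata.pixel_size_um
            associations, per_cell = associate_spots_to_foci(
                pla_records, ref_records,
                threshold_um=config.proximity.threshold_um, pixel_size_um=px,
            )
        except Exception as exc:
            raise PipelineError(stage, field_id, exc) from exc
        associations.to_csv(out_dir / "pla_associations.tsv", sep="\t", index=False)
        combined = CellTable(
            data=combined.data.merge(per_cell, on="cell_id", how="left"),
            provenance=combined.provenance,
        )
        for col in ("n_pla_total", "n_pla_adjacent"):
            combined.data[col] = combined.data[col].fillna(0).astype(int)

    stage = "export"
    combined.provenance.update({"config_hash": cfg_hash, "version": __version__})
    combined.write(out_dir / "cells.tsv")
    for ch, frames in all_focus_records.items():
        pd.concat(frames, ignore_index=True).to_csv(
            out_dir / f"foci_{ch}.tsv", sep="\t", index=False
        )
    results["all"] = combined
    return results
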