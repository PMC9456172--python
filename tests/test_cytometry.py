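"""Per-cell measurement, gating algebra, the DNA x EdU classifier and the
tab-text database."""

import numpy as np
import pandas as pd
import pytest

from imcyto.cytometry import (
    CellTable,
    IntervalGate,
    apply_gate,
    classify_cell_cycle,
    estimate_g1_peak,
    foci_fraction,
    gallery_crops,
    measure_cells,
    measure_foci,
)
from imcyto.imaging_io import AcquisitionMetadata, ChannelImage
from imcyto.segmentation import LabelMask
from imcyto.synthetic import SceneSpec, NucleusSpec, simulate_pulse_chase, SimulationParams, synth_microscopy_scene
from conftest import classify_timecourse

PX = 0.5


def image_of(pixels, channel="DNA"):
    h, w = np.asarray(pixels).shape
    return ChannelImage(np.asarray(pixels, float), channel,
                        AcquisitionMetadata(0.0, 0.0, PX, w, h))


def disk_mask(shape=(64, 64), center=(32, 32), radius=10):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


class TestMeasureCells:
    def test_uniform_disk_integrated_and_mean(self):
        mask = disk_mask()
        labels = LabelMask(mask.astype(np.int32), kind="nucleus", pixel_size_um=PX)
        img = image_of(np.where(mask, 7.0, 0.0))
        table = measure_cells(labels, [img])
        row = table.data.iloc[0]
        n_px = mask.sum()
        assert row["int_DNA"] == pytest.approx(7.0 * n_px)
        assert row["mean_DNA"] == pytest.approx(7.0)
        assert row["area_um2"] == pytest.approx(n_px * PX**2)

    def test_disk_circularity_is_near_one(self):
        labels = LabelMask(disk_mask(radius=12).astype(np.int32), kind="nucleus", pixel_size_um=PX)
        table = measure_cells(labels, [image_of(np.ones((64, 64)))])
        assert 0.95 <= table.data["circularity"].iloc[0] <= 1.0

    def test_noise_free_scene_recovers_planted_intensity_exactly(self):
        spec = SceneSpec(shape_px=(128, 128), nuclei=[NucleusSpec(64, 64, 20, 15, 30, 500.0)],
                         poisson_noise=False)
        images, truth = synth_microscopy_scene(spec)
        from imcyto.segmentation import segment_nuclei

        mask = segment_nuclei(images["DNA"], max_area_um2=400.0)
        table = measure_cells(mask, [images["DNA"]])
        planted = truth.cells["int_DNA_planted"].iloc[0]
        assert table.data["int_DNA"].iloc[0] == pytest.approx(planted, rel=0.01)

    def test_geometry_mismatch_rejected(self):
        labels = LabelMask(np.zeros((32, 32), np.int32), kind="nucleus", pixel_size_um=PX)
        with pytest.raises(ValueError, match="geometry"):
            measure_cells(labels, [image_of(np.ones((16, 16)))])


def two_cell_fixture():
    """Two square nuclei; three foci (sums 10/20/30) inside the first."""
    labels = np.zeros((40, 40), np.int32)
    labels[5:15, 5:15] = 1
    labels[25:35, 25:35] = 2
    nuclei = LabelMask(labels, kind="nucleus", pixel_size_um=PX)
    focus_labels = np.zeros((40, 40), np.int32)
    img = np.zeros((40, 40))
    for k, (r, c, total) in enumerate([(6, 6, 10.0), (9, 9, 20.0), (12, 12, 30.0)], start=1):
        focus_labels[r : r + 2, c : c + 2] = k
        img[r : r + 2, c : c + 2] = total / 4.0
    foci = LabelMask(focus_labels, kind="focus", channel="gH2AX",
                     parent_map={1: 1, 2: 1, 3: 1}, pixel_size_um=PX)
    cells = measure_cells(nuclei, [image_of(img, "gH2AX")])
    return nuclei, foci, img, cells


class TestMeasureFoci:
    def test_three_foci_aggregate(self):
        _, foci, img, cells = two_cell_fixture()
        out, records = measure_foci(foci, [image_of(img, "gH2AX")], cells)
        by_label = out.data.set_index("label")
        assert by_label.loc[1, "n_foci_gH2AX"] == 3
        assert by_label.loc[1, "foci_int_gH2AX"] == pytest.approx(60.0)
        assert by_label.loc[1, "mean_focus_area_um2_gH2AX"] == pytest.approx(4 * PX**2)
        assert len(records) == 3
        assert sorted(records["integrated_intensity"]) == [10.0, 20.0, 30.0]

    def test_cell_without_foci_has_zero_aggregates(self):
        _, foci, img, cells = two_cell_fixture()
        out, _ = measure_foci(foci, [image_of(img, "gH2AX")], cells)
        row = out.data.set_index("label").loc[2]
        assert row["n_foci_gH2AX"] == 0
        assert row["foci_int_gH2AX"] == 0.0

    def test_unknown_parent_rejected(self):
        _, foci, img, cells = two_cell_fixture()
        foci.parent_map[2] = 0
        with pytest.raises(ValueError, match="parent"):
            measure_foci(foci, [image_of(img, "gH2AX")], cells)


class TestFociFraction:
    def test_all_signal_in_foci_gives_one(self):
        _, foci, img, cells = two_cell_fixture()
        out, _ = measure_foci(foci, [image_of(img, "gH2AX")], cells)
        assert out.data.set_index("label").loc[1, "foci_frac_gH2AX"] == pytest.approx(1.0)

    def test_no_foci_gives_zero(self):
        nuclei, foci, img, cells = two_cell_fixture()
        img2 = img.copy()
        img2[25:35, 25:35] = 5.0  # give cell 2 some diffuse signal
        cells2 = measure_cells(nuclei, [image_of(img2, "gH2AX")])
        out, _ = measure_foci(foci, [image_of(img2, "gH2AX")], cells2)
        assert out.data.set_index("label").loc[2, "foci_frac_gH2AX"] == 0.0

    def test_zero_nuclear_intensity_is_flagged_undefined(self):
        cell = {"int_gH2AX": 0.0, "foci_int_gH2AX": 0.0}
        with pytest.warns(UserWarning):
            assert np.isnan(foci_fraction(cell, "gH2AX"))

    def test_planted_forty_percent_fraction_recovered(self):
        from imcyto.segmentation import FocusParams, correct_illumination, segment_foci, segment_nuclei
        from imcyto.synthetic import FocusSpec

        # nucleoplasm and focus masses chosen so 40% of photons sit in foci
        nucleus = NucleusSpec(64, 64, 24, 24, 0, 800.0)
        spec = SceneSpec(
            shape_px=(128, 128), pixel_size_um=0.33,
            nuclei=[nucleus],
            foci=[FocusSpec(0, x, y, 1.0, m, "gH2AX")
                  for x, y, m in [(50, 50, 20000), (75, 60, 20000), (60, 80, 20000)]],
            nucleoplasm_levels={"gH2AX": 50.0},
            background={"gH2AX": 10.0, "DNA": 10.0},
            poisson_noise=True, seed=3,
        )
        images, truth = synth_microscopy_scene(spec)
        planted = truth.cells["foci_frac_gH2AX_planted"].iloc[0]
        assert 0.3 < planted < 0.5
        corr = {ch: correct_illumination(im, background_percentile=50)
                for ch, im in images.items()}
        nuclei = segment_nuclei(corr["DNA"], max_area_um2=400.0)
        foci = segment_foci(corr["gH2AX"], nuclei,
                            FocusParams(k_sigma=3.5, min_area_um2=0.45, max_area_um2=15.0))
        cells = measure_cells(nuclei, list(corr.values()))
        out, _ = measure_foci(foci, list(corr.values()), cells, nuclei=nuclei)
        measured = out.data["foci_frac_gH2AX"].iloc[0]
        assert abs(measured - planted) <= 0.05


def random_table(n=200, seed=0):
    rng = np.random.default_rng(seed)
    return CellTable(pd.DataFrame({
        "cell_id": [f"c{i}" for i in range(n)],
        "a": rng.normal(10, 3, n),
        "b": rng.uniform(0, 1, n),
    }))


class TestGating:
    def test_not_gate_is_complement(self):
        t = random_table()
        g = IntervalGate("a", 8, 12)
        inside, _ = apply_gate(t, g)
        outside, _ = apply_gate(t, ~g)
        assert len(inside) + len(outside) == len(t)
        assert set(inside.data["cell_id"]).isdisjoint(outside.data["cell_id"])

    def test_interval_gate_selects_exact_rows(self):
        t = random_table(seed=1)
        subset, summary = apply_gate(t, IntervalGate("a", 9.0, 11.0), stat_columns=["a"])
        v = t.data["a"]
        assert summary["n"] == int(((v >= 9.0) & (v <= 11.0)).sum())
        assert subset.data["a"].between(9.0, 11.0).all()

    def test_logical_and_matches_brute_force(self):
        t = random_table(seed=2)
        g = IntervalGate("a", 8, 12) & IntervalGate("b", 0.25, 0.75)
        subset, _ = apply_gate(t, g)
        brute = t.data[(t.data["a"] >= 8) & (t.data["a"] <= 12)
                       & (t.data["b"] >= 0.25) & (t.data["b"] <= 0.75)]
        assert list(subset.data["cell_id"]) == list(brute["cell_id"])

    def test_unknown_column_rejected(self):
        with pytest.raises(KeyError):
            apply_gate(random_table(), IntervalGate("missing", 0, 1))


class TestCellCycleClassifier:
    def test_pure_g1_population_is_all_2n_negative(self):
        n = 500
        t = CellTable(pd.DataFrame({
            "cell_id": np.arange(n).astype(str),
            "int_DNA": np.full(n, 100.0),
            "int_EdU": np.concatenate([np.full(n - 5, 1.0), np.full(5, 101.0)]),
        }))
        # a handful of EdU+ cells so the threshold is definable; the G1 bulk
        # must all land in 2N-
        out = classify_cell_cycle(t, options={"g1_peak": 100.0})
        assert (out.data["cycle_label"][: n - 5] == "2N-").all()

    def test_high_dna_cell_is_unassigned_not_dropped(self):
        t = CellTable(pd.DataFrame({
            "cell_id": ["a", "b", "c"],
            "int_DNA": [100.0, 300.0, 200.0],
            "int_EdU": [1.0, 1.0, 100.0],
        }))
        out = classify_cell_cycle(t, options={"g1_peak": 100.0, "edu_threshold": 10.0})
        assert len(out.data) == 3
        assert out.data.set_index("cell_id").loc["b", "cycle_label"] == "unassigned"

    def test_six_labels_partition_assigned_cells(self, headline_timecourse):
        _, tables, _ = headline_timecourse
        labeled = classify_cell_cycle(tables[0][1])
        counts = labeled.data["cycle_label"].value_counts()
        six = {"2N+", "midN+", "4N+", "2N-", "midN-", "4N-"}
        assert set(counts.index) <= six | {"unassigned"}
        assert counts.sum() == len(labeled.data)

    def test_simulated_population_classified_against_ground_truth(self):
        params = SimulationParams(n_cells=4000, chase_times_h=(0.0, 1.0, 2.0), seed=11)
        tables, truth = simulate_pulse_chase(params)
        labeled = classify_timecourse(tables)
        acc = (labeled[0][1].data["cycle_label"].to_numpy()
               == truth.per_time[0]["true_label"].to_numpy()).mean()
        assert acc >= 0.95

    def test_degenerate_dna_distribution_rejected(self):
        with pytest.raises(ValueError):
            estimate_g1_peak(np.full(100, 50.0))


class TestTableIO:
    def test_round_trip_preserves_values_and_extra_columns(self, tmp_path):
        t = random_table(seed=3)
        t.data["custom_flag"] = ["x"] * len(t.data)
        t.provenance["config_hash"] = "abc"
        path = t.write(tmp_path / "cells.tsv")
        back = CellTable.read(path)
        pd.testing.assert_frame_equal(back.data, t.data)
        assert back.provenance["config_hash"] == "abc"

    def test_empty_table_writes_header_only(self, tmp_path):
        t = CellTable(pd.DataFrame(columns=["cell_id", "a"]))
        path = t.write(tmp_path / "empty.tsv")
        lines = path.read_text().splitlines()
        assert lines == ["cell_id\ta"]

    def test_missing_values_round_trip_as_empty_fields(self, tmp_path):
        t = CellTable(pd.DataFrame({"cell_id": ["a", "b"], "v": [1.5, np.nan]}))
        path = t.write(tmp_path / "na.tsv")
        assert path.read_text().splitlines()[2].endswith("\t")
        back = CellTable.read(path)
        assert np.isnan(back.data["v"].iloc[1])


class TestGalleryCrops:
    def test_crop_contains_nucleus_and_copies_values(self):
        mask = disk_mask(center=(30, 30), radius=8)
        labels = LabelMask(mask.astype(np.int32), kind="nucleus", pixel_size_um=PX)
        img = image_of(np.random.default_rng(0).uniform(0, 100, (64, 64)))
        table = measure_cells(labels, [img])
        (crop,) = gallery_crops(table, img, pad_um=1.0)
        assert not crop["clipped"]
        half = (crop["pixels"].shape[0] - 1) // 2
        r0 = int(round(table.data["centroid_y_px"][0])) - half
        c0 = int(round(table.data["centroid_x_px"][0])) - half
        assert np.array_equal(
            crop["pixels"], img.pixels[r0 : r0 + crop["pixels"].shape[0],
                                       c0 : c0 + crop["pixels"].shape[1]]
        )
        assert crop["pixels"].shape[0] * PX >= 2 * 8 * PX  # spans the nucleus

    def test_edge_cell_is_clipped_and_flagged(self):
        mask = disk_mask(center=(3, 30), radius=3)
        labels = LabelMask(mask.astype(np.int32), kind="nucleus", pixel_size_um=PX)
        img = image_of(np.ones((64, 64)))
        table = measure_cells(labels, [img])
        (crop,) = gallery_crops(table, img, pad_um=2.0)
        assert crop["clipped"]

    def test_empty_gate_yields_empty_gallery(self):
        t = CellTable(pd.DataFrame(columns=["cell_id", "centroid_x_px",
                                            "centroid_y_px", "area_um2"]))
        img = image_of(np.ones((32, 32)))
        assert gallery_crops(t, img) == []
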