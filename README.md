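# imcyto

Image cytometry for automated fluorescence microscopy of DNA-damage-response
(DDR) studies: segment nuclei and sub-nuclear foci across multichannel
fields, build flow-cytometry-style per-cell databases with logical gating,
follow cell-cycle progression through an EdU pulse-chase, score proximity
between PLA interaction spots and damage foci, and analyze single-molecule
localization (SMLM) data by image cross-correlation spectroscopy (ICCS) and
object-based spot counting.

The package is aimed at groups running high-content imaging of
DDR markers (DAPI/DNA, EdU, γH2A.X, 53BP1, PLA, p53, p21, KI67) who want
the quantitative pipeline — segmentation, per-cell measurement, gating,
kinetics, colocalization — scriptable, testable, and reproducible.  Every
analysis stage has a matching synthetic-data generator with exact ground
truth, so the whole pipeline is verifiable without any microscope.

## What it computes

**Image cytometry.** Fields are corrected for background and illumination
inhomogeneity, nuclei are segmented on the DNA channel (Gaussian smoothing,
Otsu threshold, hole filling, distance-transform watershed, area filter),
and per cell the package measures shape (area in µm², circularity
4πA/P²) and, for every channel, integrated and mean intensity.  Foci/spots
are segmented inside each nucleus with a white top-hat filter and a
per-nucleus adaptive threshold (nucleoplasm mean + k·SD, sigma-clipped);
per cell it reports the focus count, summed focus intensity (nucleoplasm
baseline subtracted), mean focus area, and the fraction of the channel's
nuclear signal located in foci.  Tables persist as tab-delimited text and
support interval/polygon gates with full boolean algebra, as in flow
cytometry.  Gated cells can be retrieved as image crops or converted back
to microscope stage coordinates (`image_to_stage`) to build a position list
for re-acquisition.

**Pulse-chase cell-cycle kinetics.** A brief EdU pulse tags S-phase cells;
over the chase each sample is classified into six populations by EdU sign ×
DNA-content window around the G1 peak p — 2N [0.8p, 1.2p], midN (1.2p, 1.6p),
4N [1.6p, 2.4p] — and the time courses of those populations yield the phase
durations: G2+M from the linear disappearance of the EdU⁻ 4N cohort,
S from the decay of the tagged population's mean DNA deficit, the total
cycle from the return of the tagged DNA distribution to its initial shape,
and G1 exit from the appearance of EdU⁻ midN cells.  At mitosis the
simulator (and the biology) halves the per-cell EdU content.

**Proximity and colocalization.** PLA spots are associated with the nearest
same-cell damage focus (centroid distance, 1 µm adjacency rule by default),
with Pearson correlation and median-split/rank-sum comparisons for the
interaction statistics.  SMLM localization tables are rendered as unit-mass
Gaussian spots (σ = per-molecule precision) and analyzed by ICCS: the auto-
and cross-correlation functions are fitted with Gaussians and the
colocalized fraction is taken as the cross/auto correlation-volume ratio,
f_ICCS = A_rg·w²_rg / √(A_rr·w²_rr · A_gg·w²_gg), globally or in a sliding
window.  A separate object-based branch segments foci in the rendered
reference channel and counts query-channel molecules inside each focus.

## Worked example

Simulate the reference pulse-chase experiment (phase durations 6.0 / 4.5 /
3.5 h, 20-min pulse, hourly sampling, 5000 cells per time point), classify
every sample, and estimate the kinetics:

```python
from imcyto.synthetic import SimulationParams, simulate_pulse_chase
from imcyto.cytometry import classify_cell_cycle
from imcyto.kinetics import estimate_cycle_kinetics

params = SimulationParams(T_G1_h=6.0, T_S_h=4.5, T_G2M_h=3.5, n_cells=5000, seed=1)
tables, truth = simulate_pulse_chase(params)

t0 = classify_cell_cycle(tables[0][1])
opts = {"edu_threshold": t0.provenance["edu_threshold"],
        "g1_peak": t0.provenance["g1_peak"]}
course = [(t, classify_cell_cycle(tbl, options=opts)) for t, tbl in tables]

counts = course[0][1].data["cycle_label"].value_counts()
print("t = 0 h populations:", dict(counts))

est = estimate_cycle_kinetics(course)
print(f"T_G2M = {est.T_G2M_h:.1f} h, T_S = {est.T_S_h:.1f} h, "
      f"T_cycle = {est.T_cycle_h:.1f} h")
```

prints

```
t = 0 h populations: {'2N-': 2173, '4N-': 1134, '4N+': 715, 'midN+': 652, '2N+': 325, 'midN-': 1}
T_G2M = 3.5 h, T_S = 4.5 h, T_cycle = 14.0 h
```

At the pulse, untagged G1 cells dominate (2N⁻), the tagged S-phase cells
spread over 2N+/midN+/4N+ according to how much DNA they had already
replicated, and the untagged G2/M cells sit at 4N⁻.  The estimator then
recovers the planted durations: DNA synthesis takes ~4.5 h and the full
cycle ~14 h, i.e. the population re-acquires its initial DNA×EdU
distribution about 14 h after the pulse.

The same operations are available from the command line (`imcyto segment`,
`measure`, `gate`, `cellcycle`, `kinetics`, `pla`, `relocate`, `render`,
`iccs`, `spots-in-foci`, `simulate ...`), and `imcyto run -c config.yaml`
executes the full configured pipeline with provenance stamping.

## Documentation

`docs/methods.md` describes the population model behind the simulator, the
estimators and their assumptions, all tunable parameters with defaults, and
known limitations.
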