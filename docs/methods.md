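# Methods

This note documents the models, estimators, numerical choices and defaults
behind `imcyto`, and what the synthetic benchmarks do and do not establish
about real microscopy data.

## Image model and segmentation

A field is a set of 2-D channel images sharing acquisition metadata (stage
position of the image origin, pixel size, axis orientation).  Pixel
coordinates are 0-based with the pixel center at integer coordinates;
user-facing `(x, y)` means `(column, row)`.  The pixel→stage map is affine,
`stage = origin + orientation · xy · pixel_size`, and is exactly invertible
(round-trip error < 1e-9 px is enforced by tests).

**Illumination correction.** `output = clip((input − background) /
flatfield, 0)` with the flat-field normalized to mean 1.  Background is
either a constant percentile of the image (default: 5th percentile; for
photon-limited images whose background level is itself the relevant scale,
the 50th percentile of the mostly-background field is the less biased
choice and is what the benchmark configurations use) or a rolling-window
median (default window 64 px).  The flat-field may be supplied as a
reference image or estimated as the smoothed median across ≥ 10 fields.

**Nuclei.** Gaussian smoothing (σ = 1 px) → Otsu threshold → hole filling →
speck removal below the minimum area → distance-transform watershed with
peaks at least one minimum-area-equivalent radius apart → area filter
(defaults 30–500 µm²).  Objects touching the border are flagged and kept by
default.  A signal-free guard rejects thresholds within 3 robust standard
deviations (1.4826·MAD) of the median: on pure noise, Otsu lands inside the
noise band and the spurious foreground percolates; the guard converts such
fields into empty masks.  Its corollary limitation: a field that is almost
entirely confluent nuclei (foreground median) would also be rejected.

**Foci.** White top-hat (structuring disk radius 0.5 µm by default) →
per-nucleus threshold at nucleoplasm mean + k·SD of the top-hat image
(default k = 3; the oracle suites use k = 3.5 with a 0.45 µm² ≈ 4 px
minimum area), where mean/SD are iteratively sigma-clipped at 3σ so that
bright foci do not inflate their own detection threshold → connected
components → optional local-maxima split.  Detected spots are then grown by
1 px (`grow_px`, never across nucleus boundaries or into other spots) so
the measured region recovers the sub-threshold Gaussian tails.  Each focus
is assigned to the nucleus containing its centroid and clipped to it; foci
touching the nuclear boundary are kept.

**Measurement.** Integrated intensity is the raw pixel sum over the object;
mean is integrated/area.  Circularity is 4πA/P² with the Crofton perimeter,
clipped at 1.0 because discretization lets a rasterized disk slightly
exceed the continuum bound.  Focus integrated intensities are additionally
baseline-corrected: the parent nucleus' nucleoplasm mean (computed outside
all foci) times the focus area is subtracted, so the per-cell "intensity in
foci" estimates the photons contributed by the spots themselves; the
uncorrected sum is kept alongside (`integrated_raw`).  The foci fraction is
the corrected focus sum over the cell's nuclear integrated intensity,
clipped to [0, 1]; it is undefined (flagged NaN) for zero nuclear signal.

## DNA × EdU classification

The G1 peak position p is taken from a Gaussian KDE of the DNA distribution:
the leftmost density peak with at least 25% of the maximum height (so a
dominant 4N peak in G2-heavy populations is not mistaken for 2N).  The
EdU± threshold defaults to Otsu on log10 EdU; both can be supplied
explicitly, and time-course analyses anchor both on the t = 0 sample.
Windows: 2N = [0.8p, 1.2p], midN = (1.2p, 1.6p), 4N = [1.6p, 2.4p]; DNA
outside [0.8p, 2.4p] (sub-2N debris, aggregates) is labelled `unassigned`
and excluded from kinetics denominators but never dropped from the table.

## Pulse-chase population model (simulator)

Cells are drawn uniformly over cycle position (an option for the
exponential age distribution of truly exponential growth exists; uniform
keeps population fractions transparent for testing and changes nothing
qualitative at these phase-duration ratios).  Phase layout is G1 → S → G2M
with durations (T_G1, T_S, T_G2M); defaults (6.0, 4.5, 3.5) h.  DNA content
is 2N in G1, linear from 2N to 4N through S, 4N in G2M (2N ≡ 100 arbitrary
units).  The EdU pulse lasts 20 min (1/3 h) ending at fixation; a cell's
EdU signal is proportional to the overlap of its pulse-interval trajectory
with S, scaled to 100 units for a full-pulse overlap on top of a detection
background of 1 unit.  At each division DNA resets to 2N and the *stored*
EdU value is halved exactly (partitioning between daughters); one daughter
is tracked so the cohort size is constant and fractions stay interpretable.
Multiplicative log-normal noise with mean 1 and per-channel CV (default
0.05 for both channels) is applied last, independently per time point.
Optional checkpoint-arrest modifiers: a fraction of pulse-time G1 cells
halts at the G1/S boundary, S transit is slowed by a factor, and a G2 block
disables division entirely.

What the simulator does *not* emulate: population growth (no daughter
duplication), apoptosis and debris, S-phase rate variation within a cell,
EdU dilution other than by division, and cell-to-cell duration variability.
Passing kinetics benchmarks therefore demonstrates estimator correctness
under the stated model, not robustness to biological heterogeneity.

## Kinetics estimators

All estimators work on the labelled population fractions (and the raw DNA
column) of a chase time course that includes t = 0; crossings are linearly
interpolated between samples.

* **T_G2M** — the EdU⁻ G2/M cohort (tracked in the upper half of the 4N
  window, [1.8p, 2.4p], so EdU⁻ G1 cells arriving through late S do not
  refill it prematurely) shrinks linearly as its members divide.  The early
  decline is fitted by least squares over the longest initial run of
  strictly falling points whose decrements do not flatten by more than
  half (flattening marks the onset of refill), and extrapolated to zero;
  the pulse length is added back because cells that overlapped the pulse
  in late S are EdU⁺ and missing from the cohort.
* **T_G1_exit** — first time the EdU⁻ midN fraction exceeds 5% of EdU⁻
  cells: the leading G1 cells have completed G1 and traversed enough of S
  to leave the 2N window.  This is an event time for the fastest cells,
  not the mean G1 duration.
* **T_S** — under constant synthesis, the mean DNA deficit (4N level minus
  mean DNA) of the tagged, not-yet-divided population decays so that its
  square root is linear in time, reaching zero when the cell tagged at the
  very start of S finishes replication — i.e. after exactly T_S.  The 4N
  level is anchored on the mean DNA of t = 0 EdU⁻ 4N cells; "not yet
  divided" is DNA > 1.2p; fit points start once the pulse-time early-S
  cells have cleared the 2N window (first minimum of the 2N⁺ fraction) and
  stop at a 2% deficit floor or when second-cycle S entry re-inflates the
  deficit.
* **T_cycle** — every tagged cell returns to its pulse-time cycle position
  after exactly one period, so the EdU⁺ DNA distribution first re-acquires
  its t = 0 shape at T_cycle.  Measured as the parabola-interpolated
  minimum of the two-sample Kolmogorov–Smirnov distance to the t = 0
  distribution, searched after the distance has clearly departed (≥ 0.4)
  and only within the first near-return segment (< 0.2), so the equally
  deep minimum of a *second* full cycle is not selected.  If the
  distribution never returns (e.g. division block), T_cycle is
  undetermined.

Simple threshold-crossing rules on the 4N window were considered for T_S
and T_cycle and rejected: the 4N gate starting at 1.6p is reached after
only ~60% of S, so gate-occupancy crossings systematically read ~0.6·T_S;
and tagged 2N⁺ cells re-appear as soon as the *fastest* tagged cells divide
(≈ T_G2M after the pulse), so a 2N⁺-appearance crossing measures G2+M, not
the full cycle.  The fitted-decay and distribution-return estimators above
measure the full durations and are noise-robust because they average over
cells.  Recovery across random duration draws (G1 ∈ [4,8], S ∈ [3,6],
G2M ∈ [2,5] h, hourly sampling, 3000 cells) lands within one sampling
interval of truth in ≥ 18/20 seeded runs for each estimated duration.

## PLA proximity statistics

Spot–focus distance is Euclidean, centroid to centroid, within the same
cell; adjacency is inclusive at the threshold (default 1 µm).  Pearson
correlation is the product-moment formula accumulated with compensated
summation; fewer than 3 finite pairs or zero variance raise an error
rather than propagate NaN.  The median split puts ties in the "below"
group (deterministic), and group differences use the two-sided
Mann–Whitney rank-sum test.

## SMLM rendering and ICCS

Each localization is rendered as a unit-mass 2-D Gaussian whose per-pixel
values are exact error-function integrals, with σ = max(precision, one
rendered pixel); total mass is conserved to < 0.1% away from borders.
Correlation functions G_ij(ξ,η) = ⟨δI_i·δI_j⟩/(⟨I_i⟩⟨I_j⟩) are computed by
FFT (periodic boundary) and each is fitted with A·exp(−(ξ²+η²)/w²) + G∞
over lags within the fit radius (default 10 px), excluding zero lag (the
shot-noise point in raw data).  The cross-correlation width is bounded to
[0.8·min(w_rr, w_gg), 3·max(w_rr, w_gg)]: it cannot physically be narrower
than the autocorrelations, and the bound prevents a flat noise background
from fitting as a huge spurious Gaussian.

The default colocalized-fraction estimator is the correlation-volume ratio
f = A_rg·w²_rg / √(A_rr·w²_rr·A_gg·w²_gg).  Rationale: molecules bound in
a complex are separated by a labelling displacement (antibody linkage,
per-channel localization error), which broadens the cross-correlation peak
relative to the autocorrelations and depresses its amplitude by the width
ratio; the volume ratio is invariant to that broadening and equals
N_coloc/N for equal-density channels.  The plain amplitude ratio
A_rg/√(A_rr·A_gg) (exact when widths match) and the one-sided ratios
A_rg/A_gg, A_rg/A_rr are selectable.  f is clipped to [0, 1].  The local
map tiles the field (window ≥ 16 px, default 64, step 32) and runs the
global analysis per tile; tiles below the intensity floor in either
channel, or with failed fits, are undefined (NaN).

Object-based counting renders the reference channel, segments foci in the
rendering with the widefield focus segmenter restricted to the supplied
nucleus mask, counts query molecules whose coordinates fall inside each
focus region, and reports every in-nucleus query molecule's distance to
the nearest focus centroid.

## Synthetic scenes

Nuclei are ellipses of constant DNA level; non-DNA channels add a constant
nucleoplasm level inside nuclei; foci are error-function-integrated
Gaussians of exact photon mass; shading is an optional multiplicative
field; camera noise is Poisson plus clipped Gaussian read noise.  Random
scenes rejection-sample nucleus centers at ≥ 2.2 object diameters of
separation — the regime in which the nucleus segmenter is exact — with
foci at ≥ 6σ mutual separation and peak/nucleoplasm contrast ≈ 13 (well
above the ≥ 5 design condition).  Ground truth records, per nucleus,
planted pixel counts, integrated intensities, focus counts and the exact
in-focus photon fraction of the noise-free rendering.  All generators are
deterministic given their seed.

Benchmark problem sizes — 100 scenes of six nuclei for the segmentation
oracle, 2 × 2000 molecules × 20 seeds per fraction for ICCS recovery,
5000 cells × 21 time points for kinetics — were chosen so the full suite
completes in about a minute while keeping counting noise far below the
tolerances being tested.

## Known limitations

* Segmentation is 2-D only; confocal stacks are handled per plane.
* The nucleus pipeline assumes nuclei are the bright phase of a bimodal
  histogram; densely confluent fields degrade both Otsu and the
  signal-free guard.
* The KDE G1-peak finder needs a visible G1 population; fully arrested
  4N-only populations require the peak to be supplied.
* ICCS assumes spatially stationary patterns within the analyzed window;
  strong density gradients bias the correlation offsets.
* Vendor metadata and position-list formats are not parsed; metadata comes
  from JSON sidecars and position lists use a documented CSV, with dialect
  hooks left for instrument-specific adapters.
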