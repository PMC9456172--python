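"""Ground-truthed synthetic inputs for every pipeline stage.

Four generators, all deterministic given their seed:

* :func:`simulate_pulse_chase` — an asynchronous cell population put through
  a brief EdU pulse and sampled over a chase, with cell-cycle-dependent DNA
  and EdU content and exact EdU halving at mitosis;
* :func:`synth_microscopy_scene` — multichannel fields of elliptical nuclei
  with planted sub-nuclear Gaussian foci, shading and camera noise;
* :func:`synth_pla_scene` — reference foci plus PLA spots at controlled
  distances;
* :func:`synth_localization_patterns` — two-channel SMLM point patterns with
  a known colocalized fraction.

Every generated observable has a ground-truth record, so segmentation,
measurement, classification, kinetics, proximity and colocalization can each
be scored against planted values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import erf

from .cytometry import CellTable
from .imaging_io import AcquisitionMetadata, ChannelImage, LocalizationTable

__all__ = [
    "ArrestModel",
    "SimulationParams",
    "GroundTruth",
    "simulate_pulse_chase",
    "NucleusSpec",
    "FocusSpec",
    "SceneSpec",
    "synth_microscopy_scene",
    "random_scene_spec",
    "synth_pla_scene",
    "pla_scene_from_offsets",
    "synth_localization_patterns",
]

#: DNA content of a G1 (2N) cell, in arbitrary fluorescence units.
DNA_2N = 100.0
#: EdU signal of a full-pulse overlap, and the detection background.
EDU_FULL = 100.0
EDU_BACKGROUND = 1.0


@dataclass(frozen=True)
class ArrestModel:
    """Checkpoint-arrest modifiers applied from the pulse time onward."""

    g1_block_fraction: float = 0.0  # fraction of pulse-time G1 cells that never enter S
    s_slowdown: float = 1.0         # S-phase transit takes s_slowdown times longer
    g2_block: bool = False          # no cell passes the G2/M boundary (division off)

    def __post_init__(self) -> None:
        if not 0.0 <= self.g1_block_fraction <= 1.0:
            raise ValueError("g1_block_fraction must be in [0, 1]")
        if self.s_slowdown < 1.0:
            raise ValueError("s_slowdown must be >= 1")


@dataclass(frozen=True)
class SimulationParams:
    """Pulse-chase experiment design and population model parameters."""

    T_G1_h: float = 6.0
    T_S_h: float = 4.5
    T_G2M_h: float = 3.5
    pulse_duration_h: float = 1.0 / 3.0  # 20-minute EdU pulse
    chase_times_h: tuple[float, ...] = tuple(float(t) for t in range(0, 21))
    n_cells: int = 5000
    noise_cv: Mapping[str, float] | float = 0.05
    arrest: ArrestModel | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("T_G1_h", "T_S_h", "T_G2M_h"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        ts = tuple(self.chase_times_h)
        if any(t < 0 for t in ts):
            raise ValueError("chase times must be >= 0")
        if len(set(ts)) != len(ts) or list(ts) != sorted(ts):
            raise ValueError("chase times must be sorted and unique")
        object.__setattr__(self, "chase_times_h", ts)

    @property
    def T_cycle_h(self) -> float:
        return self.T_G1_h + self.T_S_h + self.T_G2M_h

    def cv(self, channel: str) -> float:
        if isinstance(self.noise_cv, Mapping):
            return float(self.noise_cv.get(channel, 0.0))
        return float(self.noise_cv)


@dataclass
class GroundTruth:
    """Planted values for every generated observable."""

    params: object = None
    cells: pd.DataFrame | None = None          # one row per simulated object
    per_time: list[pd.DataFrame] = field(default_factory=list)
    extra: dict = field(default_factory=dict)


def _true_label(dna: np.ndarray, edu_pos: np.ndarray) -> np.ndarray:
    """Six-population label from true DNA content and true EdU positivity."""
    p = DNA_2N
    win = np.full(dna.shape, "unassigned", dtype=object)
    win[(dna >= 0.8 * p) & (dna <= 1.2 * p)] = "2N"
    win[(dna > 1.2 * p) & (dna < 1.6 * p)] = "midN"
    win[(dna >= 1.6 * p) & (dna <= 2.4 * p)] = "4N"
    return np.where(
        win == "unassigned", "unassigned",
        np.char.add(win.astype(str), np.where(edu_pos, "+", "-")),
    )


def _positions_no_arrest(a0: np.ndarray, t: float, T_c: float) -> tuple[np.ndarray, np.ndarray]:
    age = a0 + t
    divisions = np.floor(age / T_c).astype(int)
    return age % T_c, divisions


def _position_arrested(
    a0: float, t: float, params: SimulationParams, g1_blocked: bool
) -> tuple[float, int]:
    """Cycle position and division count under the arrest model (per cell)."""
    arrest = params.arrest
    T_g1, T_s, T_g2m = params.T_G1_h, params.T_S_h, params.T_G2M_h
    T_c = params.T_cycle_h
    pos = float(a0)
    divisions = 0
    remaining = float(t)
    eps = 1e-9
    while remaining > eps:
        if pos < T_g1:  # in G1
            if g1_blocked:
                # advance to (at most) the G1/S boundary, then stop
                step = min(remaining, T_g1 - eps - pos)
                pos += max(0.0, step)
                break
            step = min(remaining, T_g1 - pos)
            pos += step
            remaining -= step
        elif pos < T_g1 + T_s:  # in S (possibly slowed)
            rate = 1.0 / arrest.s_slowdown
            step_needed = (T_g1 + T_s - pos) / rate
            step = min(remaining, step_needed)
            pos += step * rate
            remaining -= step
        else:  # in G2M
            if arrest.g2_block:
                pos = min(pos + remaining, T_c - eps)
                break
            step = min(remaining, T_c - pos)
            pos += step
            remaining -= step
            if pos >= T_c - eps and remaining > 0:
                pos = 0.0
                divisions += 1
    return pos, divisions


def simulate_pulse_chase(params: SimulationParams) -> tuple[list[tuple[float, CellTable]], GroundTruth]:
    """Simulate a pulse-chase time course over one tracked cohort.

    Cells are drawn uniformly over cycle position.  DNA content is 2N in G1,
    rises linearly to 4N through S and stays 4N in G2/M.  EdU equals the
    time overlap of the pulse interval with the cell's S phase (scaled to
    :data:`EDU_FULL` for a full-pulse overlap, on top of a small detection
    background); at each division the DNA resets to 2N and the stored EdU
    value is exactly halved (one daughter is followed, so cohort size is
    conserved).  Multiplicative log-normal measurement noise (mean one,
    given CV) is applied last, independently per time point.
    """
    rng = np.random.default_rng(params.seed)
    n = int(params.n_cells)
    T_c = params.T_cycle_h
    T_g1, T_s = params.T_G1_h, params.T_S_h
    pulse = params.pulse_duration_h

    a0 = rng.uniform(0.0, T_c, size=n)
    # EdU incorporation: overlap of [a0 - pulse, a0] with the S interval
    overlap = np.clip(np.minimum(a0, T_g1 + T_s) - np.maximum(a0 - pulse, T_g1), 0.0, None)
    edu_signal0 = EDU_BACKGROUND + EDU_FULL * overlap / pulse
    phase = np.where(a0 < T_g1, "G1", np.where(a0 < T_g1 + T_s, "S", "G2M"))

    g1_blocked = np.zeros(n, dtype=bool)
    if params.arrest is not None and params.arrest.g1_block_fraction > 0:
        in_g1 = a0 < T_g1
        g1_blocked = in_g1 & (rng.uniform(size=n) < params.arrest.g1_block_fraction)

    cells_truth = pd.DataFrame(
        {
            "cell_id": np.arange(n),
            "age_at_pulse_h": a0,
            "phase_at_pulse": phase,
            "edu_overlap_h": overlap,
            "edu_t0": edu_signal0,
            "g1_blocked": g1_blocked,
        }
    )

    tables: list[tuple[float, CellTable]] = []
    truth_per_time: list[pd.DataFrame] = []
    cv_dna, cv_edu = params.cv("DNA"), params.cv("EdU")

    for t in params.chase_times_h:
        if params.arrest is None:
            pos, divisions = _positions_no_arrest(a0, float(t), T_c)
        else:
            pos = np.empty(n)
            divisions = np.empty(n, dtype=int)
            for i in range(n):
                pos[i], divisions[i] = _position_arrested(
                    a0[i], float(t), params, bool(g1_blocked[i])
                )

        s_frac = np.clip((pos - T_g1) / T_s, 0.0, 1.0)
        dna_true = DNA_2N * (1.0 + s_frac)
        edu_true = edu_signal0 * 0.5**divisions
        edu_pos_true = overlap > 0

        dna = dna_true.copy()
        edu = edu_true.copy()
        if cv_dna > 0:
            sigma = np.sqrt(np.log1p(cv_dna**2))
            dna = dna * np.exp(rng.normal(0.0, sigma, size=n) - sigma**2 / 2)
        if cv_edu > 0:
            sigma = np.sqrt(np.log1p(cv_edu**2))
            edu = edu * np.exp(rng.normal(0.0, sigma, size=n) - sigma**2 / 2)

        df = pd.DataFrame(
            {
                "cell_id": [f"t{t:g}:{i}" for i in range(n)],
                "int_DNA": dna,
                "int_EdU": edu,
            }
        )
        tables.append((float(t), CellTable(data=df, provenance={"chase_time_h": float(t)})))
        truth_per_time.append(
            pd.DataFrame(
                {
                    "cell_id": df["cell_id"],
                    "dna_true": dna_true,
                    "edu_true": edu_true,
                    "divisions": divisions,
                    "cycle_position_h": pos,
                    "true_label": _true_label(dna_true, edu_pos_true),
                }
            )
        )

    truth = GroundTruth(params=params, cells=cells_truth, per_time=truth_per_time)
    return tables, truth


# ---------------------------------------------------------------------------
# microscopy scenes


@dataclass(frozen=True)
class NucleusSpec:
    cx_px: float
    cy_px: float
    rx_px: float
    ry_px: float
    angle_deg: float = 0.0
    dna_level: float = 1000.0


@dataclass(frozen=True)
class FocusSpec:
    nucleus_index: int
    x_px: float
    y_px: float
    sigma_px: float
    photons: float
    channel: str = "gH2AX"


@dataclass
class SceneSpec:
    """Full description of one synthetic multichannel field."""

    shape_px: tuple[int, int] = (400, 400)
    pixel_size_um: float = 0.33
    nuclei: Sequence[NucleusSpec] = ()
    foci: Sequence[FocusSpec] = ()
    #: diffuse (nucleoplasmic) level per non-DNA channel inside every nucleus
    nucleoplasm_levels: Mapping[str, float] = field(default_factory=dict)
    background: Mapping[str, float] = field(default_factory=dict)
    #: optional multiplicative shading field applied to all channels
    gradient: np.ndarray | None = None
    poisson_noise: bool = False
    read_noise_sd: float = 0.0
    field_id: str = "synthetic"
    seed: int = 0


def _ellipse_mask(shape: tuple[int, int], nuc: NucleusSpec) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    theta = np.deg2rad(nuc.angle_deg)
    dx = cc - nuc.cx_px
    dy = rr - nuc.cy_px
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    return (u / nuc.rx_px) ** 2 + (v / nuc.ry_px) ** 2 <= 1.0


def _add_gaussian_spot(img: np.ndarray, x: float, y: float, sigma: float, mass: float) -> None:
    """Deposit a Gaussian of exact total mass via erf pixel integrals."""
    h, w = img.shape
    half = int(np.ceil(5 * sigma)) + 1
    r0, r1 = max(0, int(y) - half), min(h, int(y) + half + 1)
    c0, c1 = max(0, int(x) - half), min(w, int(x) + half + 1)
    if r0 >= r1 or c0 >= c1:
        raise ValueError("focus planted outside the field")
    inv = 1.0 / (np.sqrt(2.0) * sigma)
    fx = 0.5 * erf((np.arange(c0, c1 + 1) - 0.5 - x) * inv)
    fy = 0.5 * erf((np.arange(r0, r1 + 1) - 0.5 - y) * inv)
    img[r0:r1, c0:c1] += mass * np.outer(np.diff(fy), np.diff(fx))


def synth_microscopy_scene(spec: SceneSpec) -> tuple[dict[str, ChannelImage], GroundTruth]:
    """Render a multichannel field and its exact planted ground truth.

    Returns channel images keyed by channel name and a :class:`GroundTruth`
    whose ``cells`` frame holds, per nucleus: planted pixel count, planted
    integrated DNA, and per focus channel the planted focus count, photon
    sum, and the exact fraction of the channel's in-nucleus photons that
    belong to foci (evaluated on the noise-free rendering).
    """
    h, w = spec.shape_px
    rng = np.random.default_rng(spec.seed)
    for nuc in spec.nuclei:
        if not (0 <= nuc.cx_px < w and 0 <= nuc.cy_px < h):
            raise ValueError("nucleus center outside the field")

    masks = [_ellipse_mask((h, w), nuc) for nuc in spec.nuclei]
    channels: set[str] = {"DNA"}
    channels |= {f.channel for f in spec.foci}
    channels |= set(spec.nucleoplasm_levels)
    channels |= set(spec.background)

    diffuse: dict[str, np.ndarray] = {}
    focal: dict[str, np.ndarray] = {}
    for ch in channels:
        diffuse[ch] = np.zeros((h, w), dtype=float)
        focal[ch] = np.zeros((h, w), dtype=float)

    for nuc, mask in zip(spec.nuclei, masks):
        diffuse["DNA"][mask] += nuc.dna_level
        for ch, level in spec.nucleoplasm_levels.items():
            diffuse[ch][mask] += level
    for f in spec.foci:
        _add_gaussian_spot(focal[f.channel], f.x_px, f.y_px, f.sigma_px, f.photons)

    truth_rows = []
    for k, (nuc, mask) in enumerate(zip(spec.nuclei, masks)):
        row = {
            "nucleus_index": k,
            "cx_px": nuc.cx_px,
            "cy_px": nuc.cy_px,
            "n_pixels": int(mask.sum()),
            "int_DNA_planted": float(diffuse["DNA"][mask].sum() + focal["DNA"][mask].sum()),
        }
        for ch in channels:
            if ch == "DNA":
                continue
            total = float(diffuse[ch][mask].sum() + focal[ch][mask].sum())
            in_foci = float(focal[ch][mask].sum())
            row[f"n_foci_{ch}_planted"] = sum(
                1 for f in spec.foci if f.channel == ch and f.nucleus_index == k
            )
            row[f"int_{ch}_planted"] = total
            row[f"foci_frac_{ch}_planted"] = in_foci / total if total > 0 else np.nan
        truth_rows.append(row)

    meta = AcquisitionMetadata(
        stage_x_um=0.0, stage_y_um=0.0, pixel_size_um=spec.pixel_size_um,
        width_px=w, height_px=h, field_id=spec.field_id,
    )
    images: dict[str, ChannelImage] = {}
    for ch in channels:
        img = diffuse[ch] + focal[ch] + spec.background.get(ch, 0.0)
        if spec.gradient is not None:
            img = img * spec.gradient
        if spec.poisson_noise:
            img = rng.poisson(img).astype(float)
        if spec.read_noise_sd > 0:
            img = np.clip(img + rng.normal(0.0, spec.read_noise_sd, img.shape), 0.0, None)
        images[ch] = ChannelImage(pixels=img, channel=ch, metadata=meta)

    truth = GroundTruth(params=spec, cells=pd.DataFrame(truth_rows))
    return images, truth


def random_scene_spec(
    seed: int,
    n_nuclei: int = 8,
    shape_px: tuple[int, int] = (400, 400),
    pixel_size_um: float = 0.33,
    radius_px: tuple[float, float] = (12.0, 18.0),
    dna_level: float = 1000.0,
    foci_channel: str = "gH2AX",
    foci_per_nucleus: tuple[int, int] = (0, 0),
    focus_sigma_px: float = 1.5,
    focus_photons: float = 4000.0,
    nucleoplasm_level: float = 50.0,
    background: float = 10.0,
    poisson_noise: bool = True,
    min_separation_factor: float = 2.2,
) -> SceneSpec:
    """Draw a random well-separated scene (rejection-sampled centers).

    Separation between nucleus centers is at least ``min_separation_factor``
    times the larger radius, matching the conditions under which the nucleus
    segmenter is expected to be exact.
    """
    rng = np.random.default_rng(seed)
    h, w = shape_px
    r_hi = radius_px[1]
    centers: list[tuple[float, float]] = []
    tries = 0
    while len(centers) < n_nuclei and tries < 20000:
        tries += 1
        cx = rng.uniform(1.5 * r_hi, w - 1.5 * r_hi)
        cy = rng.uniform(1.5 * r_hi, h - 1.5 * r_hi)
        if all(np.hypot(cx - x, cy - y) >= min_separation_factor * 2 * r_hi for x, y in centers):
            centers.append((cx, cy))
    if len(centers) < n_nuclei:
        raise ValueError("could not place the requested nuclei without overlap")

    nuclei = []
    foci = []
    for k, (cx, cy) in enumerate(centers):
        rx = rng.uniform(*radius_px)
        ry = rng.uniform(*radius_px)
        nuclei.append(NucleusSpec(cx, cy, rx, ry, rng.uniform(0, 180), dna_level))
        n_foci = int(rng.integers(foci_per_nucleus[0], foci_per_nucleus[1] + 1))
        placed: list[tuple[float, float]] = []
        attempts = 0
        while len(placed) < n_foci and attempts < 2000:
            attempts += 1
            rad = rng.uniform(0, 0.6) * min(rx, ry)
            ang = rng.uniform(0, 2 * np.pi)
            fx, fy = cx + rad * np.cos(ang), cy + rad * np.sin(ang)
            if all(np.hypot(fx - px_, fy - py_) >= 6 * focus_sigma_px for px_, py_ in placed):
                placed.append((fx, fy))
        for fx, fy in placed:
            foci.append(FocusSpec(k, fx, fy, focus_sigma_px, focus_photons, foci_channel))

    levels = {foci_channel: nucleoplasm_level} if foci else {}
    bg = {"DNA": background}
    if foci:
        bg[foci_channel] = background
    return SceneSpec(
        shape_px=shape_px,
        pixel_size_um=pixel_size_um,
        nuclei=nuclei,
        foci=foci,
        nucleoplasm_levels=levels,
        background=bg,
        poisson_noise=poisson_noise,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# PLA scenes


def pla_scene_from_offsets(
    offsets_um: Sequence[float], cell_id: str = "c0"
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """One reference focus at the origin plus one PLA spot per given offset."""
    ref = pd.DataFrame(
        {"focus_id": ["ref0"], "cell_id": [cell_id], "centroid_x_um": [0.0], "centroid_y_um": [0.0]}
    )
    pla = pd.DataFrame(
        {
            "focus_id": [f"pla{i}" for i in range(len(offsets_um))],
            "cell_id": cell_id,
            "centroid_x_um": list(offsets_um),
            "centroid_y_um": 0.0,
        }
    )
    truth = GroundTruth(
        cells=pd.DataFrame({"pla_focus_id": pla["focus_id"], "true_distance_um": list(offsets_um)})
    )
    return pla, ref, truth


def synth_pla_scene(
    n_cells: int = 20,
    foci_per_cell: tuple[int, int] = (1, 8),
    spots_per_cell: tuple[int, int] = (0, 12),
    cell_extent_um: float = 12.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Random per-cell reference foci and PLA spots with exact geometry.

    Ground truth records each spot's true nearest reference focus and
    distance (computed at generation time from the planted coordinates).
    """
    rng = np.random.default_rng(seed)
    ref_rows, pla_rows, truth_rows = [], [], []
    for c in range(n_cells):
        cid = f"c{c}"
        n_f = int(rng.integers(foci_per_cell[0], foci_per_cell[1] + 1))
        n_s = int(rng.integers(spots_per_cell[0], spots_per_cell[1] + 1))
        fxy = rng.uniform(0, cell_extent_um, size=(n_f, 2))
        for k in range(n_f):
            ref_rows.append(
                {"focus_id": f"{cid}:f{k}", "cell_id": cid,
                 "centroid_x_um": fxy[k, 0], "centroid_y_um": fxy[k, 1]}
            )
        sxy = rng.uniform(0, cell_extent_um, size=(n_s, 2))
        for k in range(n_s):
            spot_id = f"{cid}:p{k}"
            pla_rows.append(
                {"focus_id": spot_id, "cell_id": cid,
                 "centroid_x_um": sxy[k, 0], "centroid_y_um": sxy[k, 1]}
            )
            if n_f:
                d = np.hypot(fxy[:, 0] - sxy[k, 0], fxy[:, 1] - sxy[k, 1])
                j = int(np.argmin(d))
                truth_rows.append(
                    {"pla_focus_id": spot_id, "cell_id": cid,
                     "true_nearest": f"{cid}:f{j}", "true_distance_um": float(d[j])}
                )
            else:
                truth_rows.append(
                    {"pla_focus_id": spot_id, "cell_id": cid,
                     "true_nearest": None, "true_distance_um": np.nan}
                )
    cols = ["focus_id", "cell_id", "centroid_x_um", "centroid_y_um"]
    return (
        pd.DataFrame(pla_rows, columns=cols),
        pd.DataFrame(ref_rows, columns=cols),
        GroundTruth(cells=pd.DataFrame(truth_rows)),
    )


# ---------------------------------------------------------------------------
# SMLM point patterns


def synth_localization_patterns(
    N_r: int,
    N_g: int,
    f_coloc: float,
    domain_nm: float = 10000.0,
    jitter_nm: float = 30.0,
    precision_nm: float = 20.0,
    seed: int = 0,
) -> tuple[LocalizationTable, LocalizationTable, GroundTruth]:
    """Two-channel point patterns with a planted colocalized fraction.

    ``floor(f_coloc * min(N_r, N_g))`` molecule pairs share a position up to
    isotropic Gaussian jitter; all remaining molecules are independent and
    uniform over the square domain.
    """
    if not 0.0 <= f_coloc <= 1.0:
        raise ValueError("f_coloc must be in [0, 1]")
    import warnings as _warnings

    if domain_nm < 10 * precision_nm:
        _warnings.warn("domain is small relative to the localization precision", stacklevel=2)
    rng = np.random.default_rng(seed)
    n_pairs = int(np.floor(f_coloc * min(N_r, N_g)))

    shared = rng.uniform(0, domain_nm, size=(n_pairs, 2))
    jit_r = rng.normal(0, jitter_nm, size=(n_pairs, 2)) if jitter_nm > 0 else 0.0
    jit_g = rng.normal(0, jitter_nm, size=(n_pairs, 2)) if jitter_nm > 0 else 0.0
    red = np.vstack([shared + jit_r, rng.uniform(0, domain_nm, size=(N_r - n_pairs, 2))])
    green = np.vstack([shared + jit_g, rng.uniform(0, domain_nm, size=(N_g - n_pairs, 2))])

    def _table(xy: np.ndarray, channel: str) -> LocalizationTable:
        n = len(xy)
        return LocalizationTable(
            x_nm=xy[:, 0],
            y_nm=xy[:, 1],
            precision_nm=np.full(n, float(precision_nm)),
            photons=rng.uniform(500, 5000, size=n),
            frame=np.arange(n),
            channel=channel,
        )

    locs_r = _table(red, "red")
    locs_g = _table(green, "green")
    truth = GroundTruth(
        extra={
            "f_coloc": f_coloc,
            "n_pairs": n_pairs,
            "pair_positions_nm": shared,
            "domain_nm": domain_nm,
        }
    )
    return locs_r, locs_g, truth
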