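"""Cell-cycle phase-duration estimation from an EdU pulse-chase time course.

A brief EdU pulse permanently tags the cells that were replicating DNA at
time zero.  Following the tagged (EdU+) and untagged (EdU-) populations
through the six DNA x EdU windows over the chase yields the phase durations:

``T_G2M``
    The EdU-negative 4N population (cells caught in G2/M) disappears
    linearly as those cells divide; extrapolating its early decline to zero
    gives the G2+M transit time.  A "core" window (upper half of the 4N
    window) is tracked so that EdU-negative G1 cells arriving in late S do
    not refill the population before the original cohort has emptied.
``T_G1_exit``
    First time the EdU-negative midN fraction exceeds 5% of EdU- cells:
    the leading G1 cells have completed G1 and progressed into S far enough
    to leave the 2N window.
``T_S``
    EdU+ cells drift from their pulse-time DNA content toward 4N as they
    finish replication.  Under a constant synthesis rate the square root of
    the population's mean DNA deficit (4N peak minus mean EdU+ DNA) falls
    linearly in time and reaches zero exactly when the last tagged cell —
    the one that entered S at the moment of fixation — completes synthesis,
    i.e. after ``T_S``.  The estimator extrapolates that root.
``T_cycle``
    The chase time at which the EdU+ DNA-content distribution first returns
    to its time-zero shape: every tagged cell is back at its original cycle
    position after exactly one full cycle.  Measured as the interpolated
    minimum of the Kolmogorov-Smirnov distance to the t=0 distribution,
    searched after the distribution has clearly departed from it.

All crossing times are linearly interpolated between chase samples; a
duration whose crossing never occurs (e.g. under a division block) is
reported as ``None``.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np

from .cytometry import CellTable

__all__ = ["KineticsEstimate", "estimate_cycle_kinetics"]


@dataclass
class KineticsEstimate:
    """Estimated phase durations (hours) and the per-time population table."""

    T_G2M_h: float | None
    T_G1_exit_h: float | None
    T_S_h: float | None
    T_cycle_h: float | None
    fractions: dict = dc_field(default_factory=dict)
    diagnostics: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("T_G2M_h", "T_G1_exit_h", "T_S_h", "T_cycle_h"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive when determined, got {v}")
        if self.T_cycle_h is not None and self.T_S_h is not None:
            if self.T_cycle_h < self.T_S_h:
                raise ValueError("total cycle duration cannot be shorter than S")


def _interp_crossing(
    times: np.ndarray, values: np.ndarray, level: float, direction: str, start: int = 0
) -> float | None:
    """First linearly-interpolated crossing of ``level`` from index ``start``."""
    for i in range(max(start, 1), len(times)):
        a, b = values[i - 1], values[i]
        hit = (a > level >= b) if direction == "down" else (a < level <= b)
        if hit:
            if b == a:
                return float(times[i])
            frac = (level - a) / (b - a)
            return float(times[i - 1] + frac * (times[i] - times[i - 1]))
    return None


def _ks_distance(sample: np.ndarray, reference_sorted: np.ndarray) -> float:
    """Two-sample Kolmogorov-Smirnov distance (no p-value needed)."""
    s = np.sort(sample)
    grid = np.concatenate([s, reference_sorted])
    cdf_s = np.searchsorted(s, grid, side="right") / s.size
    cdf_r = np.searchsorted(reference_sorted, grid, side="right") / reference_sorted.size
    return float(np.abs(cdf_s - cdf_r).max())


def estimate_cycle_kinetics(
    timecourse: Sequence[tuple[float, CellTable]],
    dna_col: str = "int_DNA",
    pulse_duration_h: float = 1.0 / 3.0,
    ks_threshold: float = 0.1,
    midn_fraction: float = 0.05,
    deficit_floor: float = 0.02,
) -> KineticsEstimate:
    """Estimate cell-cycle phase durations from a labelled chase time course.

    ``timecourse`` is a list of ``(chase_time_h, CellTable)`` pairs; tables
    must carry ``cycle_label`` / ``edu_positive`` columns (from
    :func:`~imcyto.cytometry.classify_cell_cycle`) plus the raw DNA column.
    Requires at least three time points including t = 0.  Cells flagged
    ``unassigned`` (sub-2N debris, >4N aggregates) are excluded from all
    denominators.
    """
    if len(timecourse) < 3:
        raise ValueError("kinetics estimation needs at least 3 time points")
    times = np.array([t for t, _ in timecourse], dtype=float)
    if times[0] != 0:
        raise ValueError("the time course must include t = 0")
    if np.any(np.diff(times) <= 0):
        raise ValueError("chase times must be strictly increasing")

    tables = [tbl.data for _, tbl in timecourse]
    for df in tables:
        for col in ("cycle_label", "edu_positive", dna_col):
            if col not in df.columns:
                raise ValueError(f"time-course tables must carry column {col!r}")

    # 4N peak position (2p) from the t0 EdU- 4N cells; G1 peak from provenance
    df0 = tables[0]
    prov = timecourse[0][1].provenance
    p = prov.get("g1_peak")
    g2_dna = df0.loc[(df0["cycle_label"] == "4N-"), dna_col].to_numpy(float)
    if g2_dna.size == 0:
        raise ValueError("no 4N- cells at t = 0: cannot anchor the DNA scale")
    two_p = float(np.mean(g2_dna))
    if p is None:
        p = two_p / 2.0
    p = float(p)

    fractions: dict[str, list[float]] = {lab: [] for lab in
                                         ("2N+", "midN+", "4N+", "2N-", "midN-", "4N-")}
    fractions["unassigned"] = []
    core_4n_neg: list[float] = []
    two_n_pos: list[float] = []
    deficit: list[float] = []

    for df in tables:
        lab = df["cycle_label"]
        assigned = lab != "unassigned"
        edu_pos = df["edu_positive"].to_numpy(bool)
        n_pos = int((assigned & edu_pos).sum())
        n_neg = int((assigned & ~edu_pos).sum())
        for name in fractions:
            if name == "unassigned":
                fractions[name].append(float((~assigned).mean()))
                continue
            denom = n_pos if name.endswith("+") else n_neg
            fractions[name].append(float((lab == name).sum() / denom) if denom else np.nan)

        dna = df[dna_col].to_numpy(float)
        # EdU- cells in the upper half of the 4N window: the G2/M cohort
        core = assigned & ~edu_pos & (dna >= 1.8 * p) & (dna <= 2.4 * p)
        core_4n_neg.append(float(core.sum() / n_neg) if n_neg else np.nan)
        two_n_pos.append(fractions["2N+"][-1])
        # mean DNA deficit of tagged, not-yet-divided cells
        undivided = assigned & edu_pos & (dna > 1.2 * p)
        if undivided.sum() > 0:
            deficit.append(max(0.0, two_p - float(dna[undivided].mean())))
        else:
            deficit.append(np.nan)

    # --- T_G2M: extrapolate the early linear decline of the G2/M cohort ----
    core = np.asarray(core_4n_neg)
    baseline = core[0]
    T_g2m = None
    if baseline > 0:
        pts = [0]
        prev_dec = None
        for i in range(1, len(times)):
            if np.isnan(core[i]) or core[i] >= core[pts[-1]] or core[i] < 0.05 * baseline:
                break
            dec = core[pts[-1]] - core[i]
            if prev_dec is not None and dec < 0.5 * prev_dec:
                break  # decline flattening: EdU- G1 cells are refilling the window
            pts.append(i)
            prev_dec = dec
        if len(pts) >= 2:
            coeff = np.polyfit(times[pts], core[pts], 1)
            if coeff[0] < 0:
                # the EdU- G2 cohort misses cells that overlapped the pulse
                # (those are EdU+), so the extrapolated root is T_G2M - pulse
                T_g2m = float(-coeff[1] / coeff[0] + pulse_duration_h)

    # --- T_G1_exit: midN- upcross --------------------------------------------
    T_g1_exit = _interp_crossing(
        times, np.asarray(fractions["midN-"]), midn_fraction, "up"
    )

    # --- T_S: sqrt-deficit extrapolation -------------------------------------
    T_s = None
    d = np.asarray(deficit) / two_p  # dimensionless deficit fraction
    tp = np.asarray(two_n_pos)
    # start once the pulse-time 2N+ (early-S) cells have left the 2N window,
    # so the undivided filter no longer removes genuine S cells: first time
    # the 2N+ fraction is negligible, or (when post-mitotic re-appearance
    # begins before full clearance) its first local minimum
    tp = np.where(np.isfinite(tp), tp, np.inf)
    rise = np.where(tp >= 0.5)[0]  # strong post-mitotic re-appearance
    m = int(rise[0]) if rise.size else len(tp)
    i0 = int(np.argmin(tp[:m])) if m > 1 else None
    if i0 == 0:
        i0 = None  # 2N+ never cleared: deficit start undefined
    if i0 is not None and i0 >= 1:
        idx = []
        for i in range(i0, len(times)):
            if np.isnan(d[i]) or d[i] < deficit_floor:
                break
            if idx and d[i] >= d[idx[-1]]:
                break  # second-cycle S entry re-inflates the deficit
            idx.append(i)
        if len(idx) == 1 and idx[0] + 1 < len(times) and d[idx[0] + 1] > 0:
            idx.append(idx[0] + 1)  # completion falls between two samples
        if len(idx) >= 2:
            root = np.sqrt(d[idx])
            coeff = np.polyfit(times[idx], root, 1)
            if coeff[0] < 0:
                cand = float(-coeff[1] / coeff[0])
                if 0 < cand <= times[-1]:
                    T_s = cand

    # --- T_cycle: return of the EdU+ DNA distribution to its t0 shape --------
    ref = tables[0]
    ref_dna = np.sort(
        ref.loc[(ref["cycle_label"] != "unassigned") & ref["edu_positive"], dna_col].to_numpy(float)
    )
    ks = np.full(len(times), np.nan)
    for i, df in enumerate(tables):
        sel = (df["cycle_label"] != "unassigned") & df["edu_positive"]
        sample = df.loc[sel, dna_col].to_numpy(float)
        if sample.size and ref_dna.size:
            ks[i] = _ks_distance(sample, ref_dna)
    T_cycle = None
    if np.isfinite(ks).all():
        # search only after the distribution has clearly departed from its
        # t0 shape, so the initial slow drift cannot register as a return;
        # the return time is the (parabola-interpolated) minimum of the KS
        # trace, provided the distribution really comes back (low minimum)
        departed = np.where(ks >= 0.4)[0]
        if departed.size:
            j0 = int(departed[0]) + 1
            # first contiguous segment of near-return values (a later, second
            # full cycle can produce an equally deep minimum)
            low = [j for j in range(j0, len(times)) if ks[j] < 2 * ks_threshold]
            if low:
                seg = [low[0]]
                for j in low[1:]:
                    if j == seg[-1] + 1:
                        seg.append(j)
                    else:
                        break
                jmin = seg[int(np.argmin(ks[seg]))]
                if True:
                    if 0 < jmin < len(times) - 1:
                        a, b, c = ks[jmin - 1], ks[jmin], ks[jmin + 1]
                        denom = a - 2 * b + c
                        shift = 0.5 * (a - c) / denom if denom > 0 else 0.0
                        shift = float(np.clip(shift, -0.5, 0.5))
                        dt = times[jmin + 1] - times[jmin]
                        T_cycle = float(times[jmin] + shift * dt)
                    else:
                        T_cycle = float(times[jmin])

    return KineticsEstimate(
        T_G2M_h=T_g2m,
        T_G1_exit_h=T_g1_exit,
        T_S_h=T_s,
        T_cycle_h=T_cycle,
        fractions={"times_h": times.tolist(), **{k: v for k, v in fractions.items()}},
        diagnostics={
            "g1_peak": p,
            "dna_4n": two_p,
            "ks_to_t0": ks.tolist(),
            "core_4n_neg": core.tolist(),
            "deficit_fraction": d.tolist(),
        },
    )
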