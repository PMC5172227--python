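"""Time-lapse profiling: control-normalized time courses, onset ordering,
and cell-cycle phase duration estimators.

Per-frame trajectory tables are reduced to two condition-level traces:

* a composite morphology value — the summed fractions of cells with
  aberrant nuclear morphology, mitotic cells and dead cells — normalized
  to the control well at every time point, and
* the mean number of 53BP1 foci per interphase cell, likewise normalized.

Conditions are split by which event crosses its threshold first
(mitotic aberrations at 3-fold over control, DNA damage at 1.5-fold);
conditions crossing neither are "mild" and are grouped at the top of the
heat map, and rows are sorted by the first time point with increased DNA
damage.  The heat map colour code is anchored per series: white at the
series mean, blue below (the control level 1 included), red above.

Durations (mitosis, S phase) are estimated per cell as the longest
contiguous run of the corresponding state after median smoothing, times
the frame interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

from .errors import AnalysisWarning, FittingError, InputError
from .schema import S_PATTERN

CONTROL_FLOOR = 1e-3
MITO_THRESHOLD = 3.0
DDR_THRESHOLD = 1.5


@dataclass
class TimeCourse:
    """A per-frame value series with its control-normalized fold."""

    condition: str
    times: np.ndarray
    values: np.ndarray
    folds: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.times) == len(self.values) == len(self.folds)):
            raise InputError("times, values and folds must have equal length")


@dataclass
class OnsetClassification:
    condition: str
    group: str                    # mitosis-first | ddr-first | mild
    t_mito: Optional[float]       # first time morphology fold >= threshold
    t_ddr: Optional[float]        # first time DDR fold >= threshold

    @property
    def sort_key(self) -> float:
        return self.t_ddr if self.t_ddr is not None else float("inf")


@dataclass
class HeatmapSpec:
    """Colour anchoring: white at each series' own mean, blue below
    (control = 1 sits on the blue side), red above."""

    anchors: Dict[str, float]


# --------------------------------------------------------------------------
# Per-frame condition summaries
# --------------------------------------------------------------------------

_INTERPHASE_LIKE = ("interphase", "binucleated")


def condition_fractions(traj: pd.DataFrame) -> pd.DataFrame:
    """Per-frame fractions of aberrant-morphology, mitotic and dead cells."""
    interphase = traj["state"].isin(_INTERPHASE_LIKE)
    out = pd.DataFrame(
        {
            "frac_aberrant": traj.assign(v=(traj["aberrant_flag"].astype(bool) & interphase))
            .groupby("time_h", sort=True)["v"].mean(),
            "frac_mitotic": traj.assign(v=(traj["state"] == "mitotic"))
            .groupby("time_h", sort=True)["v"].mean(),
            "frac_dead": traj.assign(v=(traj["state"] == "dead"))
            .groupby("time_h", sort=True)["v"].mean(),
        }
    )
    out.index.name = "time_h"
    return out.reset_index()


def _check_grids(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape or not np.allclose(a, b):
        raise InputError("condition and control must share one frame grid")


def composite_morphology(
    condition_frac: pd.DataFrame,
    control_frac: pd.DataFrame,
    condition: str = "",
    eps: float = CONTROL_FLOOR,
) -> TimeCourse:
    """Composite morphology-aberration value and its control fold.

    The composite is the unweighted sum of the aberrant, mitotic and dead
    fractions per frame; the fold divides by the control composite floored
    at ``eps`` to avoid early-time division blow-ups.
    """
    t = condition_frac["time_h"].to_numpy(dtype=float)
    _check_grids(t, control_frac["time_h"].to_numpy(dtype=float))
    cols = ["frac_aberrant", "frac_mitotic", "frac_dead"]
    comp = condition_frac[cols].sum(axis=1).to_numpy(dtype=float)
    ctrl = control_frac[cols].sum(axis=1).to_numpy(dtype=float)
    folds = comp / np.maximum(ctrl, eps)
    return TimeCourse(condition=condition, times=t, values=comp, folds=folds)


def _mean_foci_per_interphase(traj: pd.DataFrame) -> pd.Series:
    sub = traj[traj["state"].isin(_INTERPHASE_LIKE)]
    times = np.sort(traj["time_h"].unique())
    means = sub.groupby("time_h")["foci_count"].mean().reindex(times)
    if means.isna().any():
        warnings.warn(
            "frames without interphase cells: value carried forward",
            AnalysisWarning,
        )
        means = means.ffill().bfill()
    return means


def ddr_timecourse(
    condition_traj: pd.DataFrame,
    control_traj: pd.DataFrame,
    condition: str = "",
    eps: float = CONTROL_FLOOR,
) -> TimeCourse:
    """Mean 53BP1 foci per interphase cell per frame, control-normalized."""
    cond = _mean_foci_per_interphase(condition_traj)
    ctrl = _mean_foci_per_interphase(control_traj)
    t = cond.index.to_numpy(dtype=float)
    _check_grids(t, ctrl.index.to_numpy(dtype=float))
    values = cond.to_numpy(dtype=float)
    folds = values / np.maximum(ctrl.to_numpy(dtype=float), eps)
    return TimeCourse(condition=condition, times=t, values=values, folds=folds)


# --------------------------------------------------------------------------
# Onset classification and heat map
# --------------------------------------------------------------------------


def _first_crossing(times: np.ndarray, folds: np.ndarray, threshold: float) -> Optional[float]:
    idx = np.nonzero(folds >= threshold)[0]
    return float(times[idx[0]]) if idx.size else None


def classify_onset(
    morph: TimeCourse,
    ddr: TimeCourse,
    mito_threshold: float = MITO_THRESHOLD,
    ddr_threshold: float = DDR_THRESHOLD,
) -> OnsetClassification:
    """Split conditions by whether mitotic aberrations (>= ``mito_threshold``
    fold over control) or DNA damage (>= ``ddr_threshold`` fold) occurs
    first; conditions crossing neither are "mild".  A tie counts as
    mitosis-first.
    """
    _check_grids(morph.times, ddr.times)
    t_mito = _first_crossing(morph.times, morph.folds, mito_threshold)
    t_ddr = _first_crossing(ddr.times, ddr.folds, ddr_threshold)
    if t_mito is None and t_ddr is None:
        group = "mild"
    elif t_ddr is None or (t_mito is not None and t_mito <= t_ddr):
        group = "mitosis-first"
    else:
        group = "ddr-first"
    return OnsetClassification(
        condition=morph.condition or ddr.condition,
        group=group,
        t_mito=t_mito,
        t_ddr=t_ddr,
    )


_GROUP_ORDER = {"mild": 0, "mitosis-first": 1, "ddr-first": 2}


def build_heatmap(
    timecourses: Sequence[TimeCourse],
    classifications: Sequence[OnsetClassification],
) -> Tuple[pd.DataFrame, HeatmapSpec]:
    """Ordered fold matrix (rows = conditions, columns = time points).

    Rows are grouped mild first (top of the heat map), then the
    mitosis-first and ddr-first groups; within each group rows ascend by
    the first time point with increased DNA damage (never-crossing rows
    last, then by name).  Row order is a deterministic function of the
    classifications.
    """
    if not timecourses:
        raise InputError("no time courses given")
    by_cond = {tc.condition: tc for tc in timecourses}
    cls_by_cond = {c.condition: c for c in classifications}
    missing = set(by_cond) - set(cls_by_cond)
    if missing:
        raise InputError(f"missing classifications for: {sorted(missing)}")

    t0 = timecourses[0].times
    for tc in timecourses:
        _check_grids(t0, tc.times)

    order = sorted(
        by_cond,
        key=lambda c: (
            _GROUP_ORDER[cls_by_cond[c].group],
            cls_by_cond[c].sort_key,
            c,
        ),
    )
    matrix = pd.DataFrame(
        [by_cond[c].folds for c in order], index=order, columns=t0
    )
    spec = HeatmapSpec(anchors={c: float(matrix.loc[c].mean()) for c in order})
    return matrix, spec


def heatmap_colors(matrix: pd.DataFrame, spec: HeatmapSpec) -> np.ndarray:
    """RGB array for the ordered matrix: per row, white at the anchor
    (the series mean), blue below, red above; monotone in the value."""
    import matplotlib
    from matplotlib import colors

    cmap = matplotlib.colormaps["bwr"]
    rgb = np.zeros((matrix.shape[0], matrix.shape[1], 3))
    for i, cond in enumerate(matrix.index):
        row = matrix.loc[cond].to_numpy(dtype=float)
        anchor = spec.anchors[cond]
        lo, hi = row.min(), row.max()
        span = max(anchor - lo, hi - anchor, 1e-12)
        norm = colors.TwoSlopeNorm(vcenter=anchor, vmin=anchor - span, vmax=anchor + span)
        rgb[i] = cmap(norm(row))[:, :3]
        rgb[i][row == anchor] = 1.0  # the anchor itself is exactly white
    return rgb


def plot_heatmap(matrix: pd.DataFrame, spec: HeatmapSpec, path: str) -> None:
    """Render the onset-ordered heat map to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rgb = heatmap_colors(matrix, spec)
    fig, ax = plt.subplots(figsize=(8, 0.3 * len(matrix) + 1.5))
    ax.imshow(rgb, aspect="auto", interpolation="nearest")
    ax.set_yticks(range(len(matrix)))
    ax.set_yticklabels(matrix.index, fontsize=6)
    ticks = np.linspace(0, matrix.shape[1] - 1, 7).astype(int)
    ax.set_xticks(ticks)
    ax.set_xticklabels([f"{matrix.columns[t]:g}" for t in ticks])
    ax.set_xlabel("time (h)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# --------------------------------------------------------------------------
# Duration estimators
# --------------------------------------------------------------------------


def _longest_run(indicator: np.ndarray) -> int:
    best = cur = 0
    for v in indicator:
        cur = cur + 1 if v else 0
        best = max(best, cur)
    return best


def _smooth(indicator: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return indicator.astype(bool)
    return median_filter(indicator.astype(np.uint8), size=window, mode="nearest").astype(bool)


def _per_cell_durations(
    traj: pd.DataFrame, indicator_col_fn, smooth_window: int
) -> List[float]:
    durations: List[float] = []
    for _, sub in traj.groupby("cell_id", sort=True):
        sub = sub.sort_values("frame")
        times = sub["time_h"].to_numpy(dtype=float)
        if len(times) < 2:
            continue
        dt = float(times[1] - times[0])
        ind = _smooth(indicator_col_fn(sub), smooth_window)
        run = _longest_run(ind)
        if run > 0:
            durations.append(run * dt)
    return durations


def mitotic_duration(
    traj: pd.DataFrame, min_cells: int = 25, smooth_window: int = 3
) -> float:
    """Mean mitotic duration in hours.

    Per cell: longest contiguous mitotic-state run (after median smoothing
    against isolated frame misclassifications) times the frame interval.
    A warning is emitted when fewer than ``min_cells`` cells contribute.
    """
    durations = _per_cell_durations(
        traj, lambda s: (s["state"] == "mitotic").to_numpy(), smooth_window
    )
    if not durations:
        raise FittingError("no mitotic cells in trajectories")
    if len(durations) < min_cells:
        warnings.warn(
            f"only {len(durations)} mitotic cells (< {min_cells})", AnalysisWarning
        )
    return float(np.mean(durations))


def estimate_s_phase_duration(traj: pd.DataFrame, smooth_window: int = 3) -> float:
    """Mean S-phase duration in hours.

    The PCNA/EdU S-pattern indicator is median-filtered (window
    ``smooth_window`` frames) and the duration per cell is the longest
    contiguous S run times the frame interval.
    """
    if "replication_pattern" not in traj.columns:
        raise InputError("trajectories lack the replication_pattern channel")
    durations = _per_cell_durations(
        traj,
        lambda s: (s["replication_pattern"] == S_PATTERN).to_numpy(),
        smooth_window,
    )
    if not durations:
        raise FittingError("no S-phase cells in trajectories")
    return float(np.mean(durations))


def replication_asymmetry(
    paired: pd.DataFrame, smooth_window: int = 1
) -> Tuple[pd.DataFrame, dict]:
    """Replication shift between the two nuclei of binucleated cells.

    ``paired`` is long-format with columns cell_id, nucleus (two values
    per cell), frame, time_h, replication_pattern.  The shift per cell is
    the absolute difference of the two nuclei's first S-pattern times in
    hours.  Cells where a nucleus never replicates are excluded and
    counted.  Returns the per-cell table and a summary
    (mean/max shift, n, n_excluded).
    """
    rows = []
    excluded = 0
    for cid, sub in paired.groupby("cell_id", sort=True):
        nuclei = sorted(sub["nucleus"].unique())
        if len(nuclei) != 2:
            raise InputError(f"cell {cid} does not have exactly two nuclei")
        starts = {}
        for nuc in nuclei:
            s = sub[sub["nucleus"] == nuc].sort_values("frame")
            ind = _smooth((s["replication_pattern"] == S_PATTERN).to_numpy(), smooth_window)
            idx = np.nonzero(ind)[0]
            starts[nuc] = float(s["time_h"].to_numpy()[idx[0]]) if idx.size else None
        if starts[nuclei[0]] is None or starts[nuclei[1]] is None:
            excluded += 1
            continue
        rows.append(
            dict(cell_id=cid, shift_h=abs(starts[nuclei[0]] - starts[nuclei[1]]))
        )
    table = pd.DataFrame(rows, columns=["cell_id", "shift_h"])
    summary = dict(
        mean_shift_h=float(table["shift_h"].mean()) if len(table) else float("nan"),
        max_shift_h=float(table["shift_h"].max()) if len(table) else float("nan"),
        n=int(len(table)),
        n_excluded=excluded,
    )
    return table, summary
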