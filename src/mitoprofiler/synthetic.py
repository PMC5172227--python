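"""Synthetic high-content screen generator.

Emulates a fixed-cell RNAi screen of mitotic regulators in U-2-OS cells
(47 targets x 2 siRNAs x 3 replicates, ~700 cells per siRNA condition,
five readouts) together with 30-min-interval, 72-h live-cell trajectories,
and small 16-bit nuclear images with planted foci.  Every generated object
comes with full ground truth (planted effect sizes, cluster archetypes,
per-cell event times, nucleus label maps and focus coordinates) so that
the downstream analysis can be validated by parameter recovery rather
than against undeposited raw screen data.

Baseline single-cell feature distributions are log-normal for intensities,
Normal for shape features and Poisson for focus counts; perturbations are
encoded as standardized mean shifts per readout plus a multiplicative
focus-rate factor.  Default perturbation strengths follow four archetypes
mirroring the four phenotypic clusters the analysis is expected to find
(mild mitotic / strong mitotic, low DDR / strong mitotic + strong DDR /
cytokinesis failure), with a deterministic per-target strength jitter so
that targets form a graded series rather than four exact replicas.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .errors import ConfigurationError, GenerationError
from .schema import (
    ALL_FEATURE_COLUMNS,
    NO_PATTERN,
    READOUTS,
    S_PATTERN,
    STATES,
    TRAJECTORY_COLUMNS,
)

# --------------------------------------------------------------------------
# Effects and configuration
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class TargetEffect:
    """Planted perturbation for one target gene.

    ``shifts`` are standardized mean shifts (units of the baseline s.d.)
    applied to the continuous features of each readout; ``foci_rate``
    multiplies the Poisson rate of 53BP1/gamma-H2AX focus counts.  The
    remaining fields parameterize live-cell trajectories: mitotic duration
    (hours), per-mitosis death and aberration probabilities, probability
    that an aberrant mitosis is a cytokinesis failure (binucleation),
    S-phase extension after the first/second aberrant mitosis (hours), and
    the absolute time at which the DNA-damage response switches on.
    """

    shifts: Dict[str, float] = field(default_factory=dict)
    foci_rate: float = 1.0
    cluster: int = 0
    mitotic_duration_h: float = 1.0
    mitotic_duration_sd_h: float = 0.25
    death_prob: float = 0.005
    aberrant_prob: float = 0.01
    binucleation_prob: float = 0.0
    s_extension_h: Tuple[float, float] = (0.0, 0.0)
    ddr_onset_h: Optional[float] = None

    def shift(self, readout: str) -> float:
        return float(self.shifts.get(readout, 0.0))

    def strength(self, readout: str) -> float:
        """Scalar planted effect magnitude per readout (recovery oracle)."""
        s = abs(self.shift(readout))
        if readout in ("53bp1", "gh2ax"):
            s += math.log(self.foci_rate)
        return s


CONTROL_EFFECT = TargetEffect()

# Four phenotypic archetypes: (shifts per readout, foci rate, trajectory
# parameters).  Cluster 1/2 = mitotic aberrations with low DNA damage,
# cluster 3 = strong mitotic + strong DDR, cluster 4 = cytokinesis-failure
# like (binucleation, delayed replication-stress-born DDR).
_ARCHETYPES: Dict[int, dict] = {
    1: dict(
        shifts={"morphology": 0.5, "53bp1": 0.2, "gh2ax": 0.2, "p53": 0.3, "edu": -0.2},
        foci_rate=1.2, mitotic_duration_h=2.0, death_prob=0.02,
        aberrant_prob=0.08, binucleation_prob=0.0, s_extension_h=(0.0, 0.0),
        ddr_onset_h=None,
    ),
    2: dict(
        shifts={"morphology": 1.4, "53bp1": 0.3, "gh2ax": 0.3, "p53": 0.7, "edu": -0.5},
        foci_rate=1.6, mitotic_duration_h=6.0, death_prob=0.04,
        aberrant_prob=0.25, binucleation_prob=0.0, s_extension_h=(0.0, 0.0),
        ddr_onset_h=30.0,
    ),
    3: dict(
        shifts={"morphology": 1.6, "53bp1": 1.0, "gh2ax": 1.0, "p53": 1.1, "edu": -0.8},
        foci_rate=2.6, mitotic_duration_h=8.0, death_prob=0.08,
        aberrant_prob=0.35, binucleation_prob=0.0, s_extension_h=(0.0, 0.0),
        ddr_onset_h=18.0,
    ),
    4: dict(
        shifts={"morphology": 2.4, "53bp1": 1.4, "gh2ax": 1.4, "p53": 1.4, "edu": -1.2},
        foci_rate=3.4, mitotic_duration_h=4.0, death_prob=0.06,
        aberrant_prob=0.45, binucleation_prob=0.8, s_extension_h=(2.0, 6.0),
        ddr_onset_h=28.0,
    ),
}

#: proportionality constant linking planted mitotic-error strength to the
#: anti-proliferative penalty (cell count multiplier exp(-penalty)).
_PROLIFERATION_PENALTY = 0.3


def default_effect_table(n_targets: int = 47, seed: int = 0) -> Dict[str, TargetEffect]:
    """Build the default per-target effect table.

    Targets cycle through the four archetypes; a deterministic per-target
    factor in [0.75, 1.25] scales shifts, log focus rate and the mitotic
    duration so planted strengths form a graded series.
    """
    rng = np.random.default_rng(seed)
    table: Dict[str, TargetEffect] = {}
    for i in range(n_targets):
        cluster = (i % 4) + 1
        arch = _ARCHETYPES[cluster]
        u = float(rng.uniform(0.75, 1.25))
        shifts = {r: s * u for r, s in arch["shifts"].items()}
        rate = 1.0 + (arch["foci_rate"] - 1.0) * u
        table[f"TGT{i + 1:02d}"] = TargetEffect(
            shifts=shifts,
            foci_rate=rate,
            cluster=cluster,
            mitotic_duration_h=arch["mitotic_duration_h"] * u,
            mitotic_duration_sd_h=0.5,
            death_prob=arch["death_prob"],
            aberrant_prob=min(0.9, arch["aberrant_prob"] * u),
            binucleation_prob=arch["binucleation_prob"],
            s_extension_h=arch["s_extension_h"],
            ddr_onset_h=arch["ddr_onset_h"],
        )
    return table


@dataclass
class ScreenConfig:
    """Study design of a synthetic screen."""

    n_targets: int = 47
    sirnas_per_target: int = 2
    n_replicates: int = 3
    mean_cells_per_sirna: int = 700
    frame_interval: float = 0.5
    duration: float = 72.0
    control_label: str = "MOCK"
    effect_table: Optional[Dict[str, TargetEffect]] = None
    seed: int = 42

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        counts = dict(
            n_targets=self.n_targets,
            sirnas_per_target=self.sirnas_per_target,
            n_replicates=self.n_replicates,
            mean_cells_per_sirna=self.mean_cells_per_sirna,
        )
        for name, v in counts.items():
            if not (isinstance(v, (int, np.integer)) and v >= 1):
                raise ConfigurationError(f"{name} must be an integer >= 1, got {v!r}")
        if not self.frame_interval > 0:
            raise ConfigurationError("frame_interval must be > 0")
        n = self.duration / self.frame_interval
        if self.duration <= 0 or abs(n - round(n)) > 1e-9:
            raise ConfigurationError(
                "duration must be a positive multiple of frame_interval"
            )
        if self.effect_table is not None:
            for target, eff in self.effect_table.items():
                vals = list(eff.shifts.values()) + [eff.foci_rate]
                if not np.all(np.isfinite(vals)):
                    raise ConfigurationError(f"non-finite effect for {target!r}")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration / self.frame_interval)) + 1

    def effects(self) -> Dict[str, TargetEffect]:
        if self.effect_table is None:
            self.effect_table = default_effect_table(self.n_targets, self.seed)
        if len(self.effect_table) != self.n_targets:
            raise ConfigurationError(
                "effect_table must have one entry per target "
                f"({len(self.effect_table)} != {self.n_targets})"
            )
        return self.effect_table


@dataclass
class ScreenGroundTruth:
    """Planted truth accompanying a generated screen."""

    effects: pd.DataFrame          # target, cluster, readout, shift, foci_rate, strength
    cluster_labels: Dict[str, int]
    proliferation: Dict[str, float]  # normalized cell-count multiplier per target
    effect_table: Dict[str, TargetEffect]
    events: Optional[pd.DataFrame] = None  # per-cell trajectory event times


# --------------------------------------------------------------------------
# Fixed-cell feature tables
# --------------------------------------------------------------------------

# Baseline population parameters (intensities in camera units, geometry in
# pixels at 0.32 um/px).  The standard deviations double as the unit of the
# planted standardized shifts.
_MORPH_AREA = (1800.0, 250.0)
_MORPH_PERIM = (160.0, 15.0)
_MORPH_LENGTH = (55.0, 6.0)
_MORPH_FF_SD = 0.15
_MORPH_LOGI = (7.0, 0.25)          # log-normal parameters of average intensity

_53BP1_RATE = 2.0
_53BP1_FOCUS_AREA = (12.0, 3.0)
_53BP1_FOCUS_INT = (5000.0, 1000.0)

_GH2AX_RATE = 1.5
_GH2AX_LOGI = (6.2, 0.3)
_GH2AX_FOCUS_AREA = (8.0, 2.0)
_GH2AX_FOCUS_INT = (4000.0, 900.0)

_P53_LOGI = (6.5, 0.35)

_EDU_S_FRACTION = 0.45
_EDU_HIGH = (3000.0, 400.0)
_EDU_LOW = (300.0, 80.0)
_EDU_SHIFT_PER_SD = 0.15           # shift unit on the S-fraction scale


def _count_features(
    n: np.ndarray,
    area_params: Tuple[float, float],
    int_params: Tuple[float, float],
    rng: np.random.Generator,
    shift: float,
) -> Tuple[np.ndarray, np.ndarray]:
    """Summed focus area / integrated intensity given per-cell focus counts."""
    pos = n > 0
    sq = np.sqrt(np.maximum(n, 1))
    area = np.where(pos, n * area_params[0] + rng.normal(0, 1, n.size) * area_params[1] * sq, 0.0)
    integ = np.where(pos, n * int_params[0] + rng.normal(0, 1, n.size) * int_params[1] * sq, 0.0)
    if shift:
        base_sd_area = math.sqrt(area_params[0] ** 2 * 2 + area_params[1] ** 2 * 2)
        base_sd_int = math.sqrt(int_params[0] ** 2 * 2 + int_params[1] ** 2 * 2)
        area = np.where(pos, area + shift * base_sd_area, area)
        integ = np.where(pos, integ + shift * base_sd_int, integ)
    return np.clip(area, 0.0, None), np.clip(integ, 0.0, None)


def _sample_cells(n: int, effect: TargetEffect, rng: np.random.Generator) -> Dict[str, np.ndarray]:
    """Draw the 24 feature values for ``n`` cells of one condition."""
    out: Dict[str, np.ndarray] = {}

    # -- morphology -------------------------------------------------------
    s = effect.shift("morphology")
    area = np.clip(rng.normal(*_MORPH_AREA, n) + s * _MORPH_AREA[1], 400.0, None)
    perim = np.clip(rng.normal(*_MORPH_PERIM, n) + s * _MORPH_PERIM[1], 40.0, None)
    length = np.clip(rng.normal(*_MORPH_LENGTH, n) + s * _MORPH_LENGTH[1], 20.0, None)
    ff = np.maximum(1.0, 1.0 + np.abs(rng.normal(0, _MORPH_FF_SD, n)) + s * _MORPH_FF_SD)
    breadth = length / ff
    avg_sd = _MORPH_LOGI[1] * math.exp(_MORPH_LOGI[0])
    avg = np.clip(rng.lognormal(*_MORPH_LOGI, n) + s * avg_sd, 50.0, None)
    out["morph_area"] = area
    out["morph_perimeter"] = perim
    out["morph_cell_length"] = length
    out["morph_cell_breadth"] = breadth
    out["morph_form_factor"] = length / breadth
    out["morph_average_intensity"] = avg
    out["morph_integrated_intensity"] = avg * area

    # -- 53BP1 foci -------------------------------------------------------
    s = effect.shift("53bp1")
    n_foci = rng.poisson(_53BP1_RATE * effect.foci_rate, n).astype(float)
    f_area, f_int = _count_features(n_foci, _53BP1_FOCUS_AREA, _53BP1_FOCUS_INT, rng, s)
    out["53bp1_foci_number"] = n_foci
    out["53bp1_foci_area"] = f_area
    out["53bp1_foci_integrated_intensity"] = f_int

    # -- gamma-H2AX -------------------------------------------------------
    s = effect.shift("gh2ax")
    gavg_sd = _GH2AX_LOGI[1] * math.exp(_GH2AX_LOGI[0])
    gavg = np.clip(rng.lognormal(*_GH2AX_LOGI, n) + s * gavg_sd, 10.0, None)
    out["gh2ax_nuclear_average_intensity"] = gavg
    out["gh2ax_nuclear_integrated_intensity"] = gavg * area
    out["gh2ax_min_average_intensity"] = gavg * np.clip(1.0 - np.abs(rng.normal(0.1, 0.05, n)), 0.0, 1.0)
    out["gh2ax_max_average_intensity"] = gavg * (1.0 + np.abs(rng.normal(0.3, 0.1, n)))
    g_foci = rng.poisson(_GH2AX_RATE * effect.foci_rate, n).astype(float)
    g_area, g_int = _count_features(g_foci, _GH2AX_FOCUS_AREA, _GH2AX_FOCUS_INT, rng, s)
    pos = g_foci > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        g_avg = np.where(pos & (g_area > 0), g_int / np.maximum(g_area, 1e-9), 0.0)
    out["gh2ax_foci_count"] = g_foci
    out["gh2ax_foci_area"] = g_area
    out["gh2ax_foci_integrated_intensity"] = g_int
    out["gh2ax_foci_average_intensity"] = g_avg
    out["gh2ax_foci_min_intensity"] = g_avg * np.clip(1.0 - np.abs(rng.normal(0.2, 0.1, n)), 0.0, 1.0)
    out["gh2ax_foci_max_intensity"] = g_avg * (1.0 + np.abs(rng.normal(0.3, 0.1, n)))

    # -- p53 --------------------------------------------------------------
    s = effect.shift("p53")
    pavg_sd = _P53_LOGI[1] * math.exp(_P53_LOGI[0])
    pavg = np.clip(rng.lognormal(*_P53_LOGI, n) + s * pavg_sd, 10.0, None)
    out["p53_average_intensity"] = pavg
    out["p53_integrated_intensity"] = pavg * area

    # -- EdU --------------------------------------------------------------
    # shift acts on the replicating fraction, keeping intensities positive
    s = effect.shift("edu")
    p_s = float(np.clip(_EDU_S_FRACTION + _EDU_SHIFT_PER_SD * s, 0.02, 0.9))
    in_s = rng.uniform(size=n) < p_s
    eavg = np.where(in_s, rng.normal(*_EDU_HIGH, n), rng.normal(*_EDU_LOW, n))
    eavg = np.clip(eavg, 1.0, None)
    out["edu_average_intensity"] = eavg
    out["edu_integrated_intensity"] = eavg * area
    return out


def proliferation_multipliers(effect_table: Dict[str, TargetEffect]) -> Dict[str, float]:
    """Relative cell-count multiplier per target.

    Strong mitotic errors depress proliferation via exp(-penalty); the
    multipliers are normalized to mean 1 across targets so the screen-wide
    mean cell count stays at the configured value while relative
    proliferation differences are preserved.
    """
    raw = {
        t: math.exp(-_PROLIFERATION_PENALTY * e.shift("morphology"))
        for t, e in effect_table.items()
    }
    norm = sum(raw.values()) / len(raw)
    return {t: v / norm for t, v in raw.items()}


def generate_feature_table(config: ScreenConfig) -> Tuple[pd.DataFrame, ScreenGroundTruth]:
    """Generate the per-cell feature table of a full screen plus ground truth.

    One row per cell; control cells are drawn from the baseline
    distributions, treated cells from shifted ones.  Per-condition cell
    counts are Poisson around ``mean_cells_per_sirna`` scaled by the
    target's proliferation multiplier.  Deterministic under a fixed seed.
    """
    config.validate()
    effect_table = config.effects()
    mults = proliferation_multipliers(effect_table)

    conditions: List[Tuple[str, str, TargetEffect, float]] = [
        (config.control_label, config.control_label, CONTROL_EFFECT, 1.0)
    ]
    for target, eff in effect_table.items():
        for j in range(config.sirnas_per_target):
            conditions.append((target, f"{target}_si{j + 1}", eff, mults[target]))

    blocks = [
        (cond, rep)
        for cond in conditions
        for rep in range(1, config.n_replicates + 1)
    ]
    children = np.random.SeedSequence(config.seed).spawn(len(blocks))

    frames = []
    for idx, (((target, sirna, eff, mult), rep), child) in enumerate(zip(blocks, children)):
        rng = np.random.default_rng(child)
        n = max(2, int(rng.poisson(config.mean_cells_per_sirna * mult)))
        feats = _sample_cells(n, eff, rng)
        block = pd.DataFrame(
            {
                "target": target,
                "sirna_id": sirna,
                "replicate": rep,
                "well": f"W{idx:03d}",
                "cell_id": np.arange(n),
            }
        )
        for col in ALL_FEATURE_COLUMNS:
            block[col] = feats[col]
        frames.append(block)
    table = pd.concat(frames, ignore_index=True)

    rows = []
    for target, eff in effect_table.items():
        for readout in READOUTS:
            rows.append(
                dict(
                    target=target,
                    cluster=eff.cluster,
                    readout=readout,
                    shift=eff.shift(readout),
                    foci_rate=eff.foci_rate if readout in ("53bp1", "gh2ax") else 1.0,
                    strength=eff.strength(readout),
                )
            )
    truth = ScreenGroundTruth(
        effects=pd.DataFrame(rows),
        cluster_labels={t: e.cluster for t, e in effect_table.items()},
        proliferation=mults,
        effect_table=effect_table,
    )
    return table, truth


# --------------------------------------------------------------------------
# Nuclear image rendering
# --------------------------------------------------------------------------

FociSpec = Union[int, Sequence[int], Callable[[np.random.Generator], int]]


def render_nucleus_image(
    n_nuclei: int,
    foci_per_nucleus: FociSpec = 3,
    noise_sd: float = 0.0,
    seed: int = 42,
    shape: Tuple[int, int] = (256, 256),
    radius_range: Tuple[float, float] = (12.0, 16.0),
    nucleus_intensity: float = 3000.0,
    focus_amplitude: float = 8000.0,
    focus_sigma: float = 1.0,
    background: float = 0.0,
    max_tries: int = 500,
) -> Tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Render a 16-bit field of ellipsoidal nuclei with Gaussian-blob foci.

    Returns ``(image, label_map, foci)`` where ``foci`` has one row per
    planted focus with columns ``label`` (parent nucleus), ``x`` (column)
    and ``y`` (row).  Nuclei are placed without overlap by rejection
    sampling; a :class:`GenerationError` is raised when placement fails
    within ``max_tries`` attempts per nucleus.
    """
    if n_nuclei < 0:
        raise GenerationError("n_nuclei must be >= 0")
    rng = np.random.default_rng(seed)
    h, w = shape
    img = np.full(shape, float(background))
    labels = np.zeros(shape, dtype=np.int32)
    yy, xx = np.mgrid[0:h, 0:w]

    placed: List[Tuple[float, float, float]] = []  # (cy, cx, rmax)
    foci_rows: List[dict] = []
    for lab in range(1, n_nuclei + 1):
        a = rng.uniform(*radius_range)          # semi-axes in px
        b = rng.uniform(radius_range[0] * 0.8, a)
        theta = rng.uniform(0, np.pi)
        rmax = max(a, b)
        margin = rmax + 2
        if 2 * margin >= min(h, w):
            raise GenerationError("image too small to place nuclei")
        for attempt in range(max_tries):
            cy = rng.uniform(margin, h - margin)
            cx = rng.uniform(margin, w - margin)
            if all(
                math.hypot(cy - py, cx - px) > rmax + pr + 2 for py, px, pr in placed
            ):
                break
        else:
            raise GenerationError(
                f"could not place nucleus {lab} without overlap after {max_tries} tries"
            )
        placed.append((cy, cx, rmax))

        ct, st = math.cos(theta), math.sin(theta)
        u = (xx - cx) * ct + (yy - cy) * st
        v = -(xx - cx) * st + (yy - cy) * ct
        d2 = (u / a) ** 2 + (v / b) ** 2
        inside = d2 < 1.0
        labels[inside] = lab
        img[inside] += nucleus_intensity * np.sqrt(1.0 - d2[inside])

        if callable(foci_per_nucleus):
            k = int(foci_per_nucleus(rng))
        elif isinstance(foci_per_nucleus, (int, np.integer)):
            k = int(foci_per_nucleus)
        else:
            k = int(foci_per_nucleus[lab - 1])
        centers: List[Tuple[float, float]] = []
        for _ in range(k):
            for attempt in range(max_tries):
                r = math.sqrt(rng.uniform()) * 0.7
                phi = rng.uniform(0, 2 * np.pi)
                fu, fv = r * math.cos(phi) * a, r * math.sin(phi) * b
                fy = cy + fu * st + fv * ct
                fx = cx + fu * ct - fv * st
                if all(math.hypot(fy - qy, fx - qx) >= 5.0 for qy, qx in centers):
                    break
            else:
                raise GenerationError("could not place focus without crowding")
            centers.append((fy, fx))
            foci_rows.append(dict(label=lab, x=fx, y=fy))
            win = int(4 * focus_sigma) + 1
            y0, y1 = max(0, int(fy) - win), min(h, int(fy) + win + 1)
            x0, x1 = max(0, int(fx) - win), min(w, int(fx) + win + 1)
            sy, sx = np.mgrid[y0:y1, x0:x1]
            img[y0:y1, x0:x1] += focus_amplitude * np.exp(
                -((sy - fy) ** 2 + (sx - fx) ** 2) / (2 * focus_sigma**2)
            )

    if noise_sd > 0:
        img += rng.normal(0, noise_sd, shape)
    img = np.clip(img, 0, 65535).astype(np.uint16)
    foci = pd.DataFrame(foci_rows, columns=["label", "x", "y"])
    return img, labels, foci


# --------------------------------------------------------------------------
# Live-cell trajectories
# --------------------------------------------------------------------------

_STATE_CODE = {s: i for i, s in enumerate(STATES)}
_BASE_FOCI_RATE = 1.0


@dataclass
class CellTrajectory:
    """Per-frame state of one tracked cell over the full recording."""

    cell_id: int
    states: np.ndarray        # unicode array over schema.STATES
    foci_count: np.ndarray    # int, >= 0
    replication: np.ndarray   # bool: PCNA S-pattern visible
    aberrant: np.ndarray      # bool: aberrant nuclear morphology

    def to_frame(self, frame_interval: float) -> pd.DataFrame:
        n = self.states.size
        return pd.DataFrame(
            {
                "cell_id": self.cell_id,
                "frame": np.arange(n),
                "time_h": np.arange(n) * frame_interval,
                "state": self.states,
                "foci_count": self.foci_count,
                "replication_pattern": np.where(self.replication, S_PATTERN, NO_PATTERN),
                "aberrant_flag": self.aberrant,
            }
        )


def trajectories_to_frame(
    trajectories: Sequence[CellTrajectory], frame_interval: float
) -> pd.DataFrame:
    """Long-format trajectory table (one row per cell per frame)."""
    df = pd.concat(
        [t.to_frame(frame_interval) for t in trajectories], ignore_index=True
    )
    return df[TRAJECTORY_COLUMNS]


def _grid(duration_h: float, interval: float) -> int:
    return max(1, int(round(duration_h / interval)))


def generate_trajectories(
    config: ScreenConfig,
    condition: str,
    n_cells: int,
    seed: int = 42,
    noise_rate: float = 0.05,
    s_duration_mean_h: float = 16.0,
    s_duration_sd_h: float = 1.0,
) -> Tuple[List[CellTrajectory], pd.DataFrame]:
    """Simulate single-cell trajectories for one condition.

    Each cell cycles G1 -> S -> G2 -> M on the frame grid.  The S-phase
    duration is a cell-intrinsic draw from Normal(16 h, 1 h) (control),
    optionally extended after the first/second aberrant mitosis; mitotic
    duration, death probability, aberration/binucleation probabilities and
    the DDR onset time come from the condition's :class:`TargetEffect`.
    53BP1 focus counts are Poisson with rate 1 before and
    ``rate x foci_rate`` after the DDR onset.  Per-frame misclassification
    noise (default 5%) independently corrupts the state label, the
    replication pattern and the aberrant flag; the dead state is absorbing
    and never corrupted.

    Returns the trajectories and a ground-truth event table with one row
    per completed cell-cycle phase plus per-cell death / DDR-onset times.
    """
    if condition == config.control_label:
        eff = CONTROL_EFFECT
    else:
        table = config.effects()
        if condition not in table:
            raise ConfigurationError(f"condition {condition!r} not in effect_table")
        eff = table[condition]
    if not 0.0 <= noise_rate < 1.0:
        raise ConfigurationError("noise_rate must be in [0, 1)")

    dt = config.frame_interval
    n_frames = config.n_frames
    children = np.random.SeedSequence(seed).spawn(n_cells)
    trajs: List[CellTrajectory] = []
    events: List[dict] = []

    for cid, child in enumerate(children):
        rng = np.random.default_rng(child)
        state = np.zeros(n_frames, dtype=np.int8)       # interphase
        s_pat = np.zeros(n_frames, dtype=bool)
        # cell-intrinsic kinetics: one S duration and one mitotic duration
        # per cell, reused every cycle (replication speed and mitotic
        # machinery state are stable cell properties here)
        base_s = _grid(rng.normal(s_duration_mean_h, s_duration_sd_h), dt)
        m_frames_cell = max(
            1, _grid(rng.normal(eff.mitotic_duration_h, eff.mitotic_duration_sd_h), dt)
        )
        binucleated = False
        n_aberrant = 0
        death_frame: Optional[int] = None

        t = _grid(rng.uniform(1.0, 6.0), dt)            # initial G1
        cycle = 0
        # (start_frame, flagged) of each post-mitotic generation; the flag
        # marks aberrant nuclear morphology for that generation
        generations: List[Tuple[int, bool]] = []
        while t < n_frames and death_frame is None:
            cycle += 1
            ext = 0.0
            if n_aberrant >= 1:
                ext = eff.s_extension_h[min(n_aberrant, 2) - 1]
            s_frames = base_s + _grid(ext, dt) if ext else base_s
            s_start = t
            s_end = min(t + s_frames, n_frames)
            s_pat[s_start:s_end] = True
            complete = s_start + s_frames <= n_frames
            events.append(
                dict(
                    cell_id=cid,
                    cycle=cycle,
                    event="s_phase",
                    start_h=s_start * dt,
                    end_h=(s_start + s_frames) * dt if complete else np.nan,
                    duration_h=s_frames * dt if complete else np.nan,
                    complete=complete,
                )
            )
            t = s_start + s_frames
            if t >= n_frames:
                break
            t += _grid(rng.uniform(3.0, 5.0), dt)       # G2
            if t >= n_frames:
                break
            m_frames = m_frames_cell
            m_start = t
            m_end = min(t + m_frames, n_frames)
            state[m_start:m_end] = _STATE_CODE["mitotic"]
            m_complete = m_start + m_frames <= n_frames
            events.append(
                dict(
                    cell_id=cid,
                    cycle=cycle,
                    event="mitosis",
                    start_h=m_start * dt,
                    end_h=(m_start + m_frames) * dt if m_complete else np.nan,
                    duration_h=m_frames * dt if m_complete else np.nan,
                    complete=m_complete,
                )
            )
            t = m_start + m_frames
            if not m_complete:
                break
            if rng.uniform() < eff.death_prob:
                death_frame = t
                break
            aberrant_now = rng.uniform() < eff.aberrant_prob
            if aberrant_now:
                n_aberrant += 1
                if rng.uniform() < eff.binucleation_prob:
                    binucleated = True
            if binucleated:
                state[t:] = _STATE_CODE["binucleated"]
            else:
                state[t:] = _STATE_CODE["interphase"]
            generations.append((t, aberrant_now or binucleated))
            t += _grid(rng.uniform(2.0, 6.0), dt)       # next G1

        if death_frame is not None:
            state[death_frame:] = _STATE_CODE["dead"]
            s_pat[death_frame:] = False

        # aberrant-morphology flag: set for the generation born of an
        # aberrant mitosis (until the next division), and for good once the
        # cell is binucleated; never set on mitotic or dead frames
        aberrant = np.zeros(n_frames, dtype=bool)
        for k, (start, flagged) in enumerate(generations):
            end = generations[k + 1][0] if k + 1 < len(generations) else n_frames
            if flagged:
                aberrant[start:end] = True
        aberrant[state == _STATE_CODE["binucleated"]] = True
        aberrant &= (state == _STATE_CODE["interphase"]) | (
            state == _STATE_CODE["binucleated"]
        )

        ddr_onset = eff.ddr_onset_h
        lam = np.full(n_frames, _BASE_FOCI_RATE)
        if ddr_onset is not None:
            lam[int(round(ddr_onset / dt)):] *= eff.foci_rate
        foci = rng.poisson(lam)
        countable = (state == _STATE_CODE["interphase"]) | (
            state == _STATE_CODE["binucleated"]
        )
        foci[~countable] = 0

        events.append(
            dict(
                cell_id=cid,
                cycle=0,
                event="summary",
                start_h=np.nan,
                end_h=np.nan,
                duration_h=np.nan,
                complete=True,
                death_h=death_frame * dt if death_frame is not None else np.nan,
                first_ddr_focus_h=(
                    ddr_onset
                    if ddr_onset is not None
                    and (death_frame is None or ddr_onset < death_frame * dt)
                    and ddr_onset <= config.duration
                    else np.nan
                ),
                planted_s_duration_h=base_s * dt,
                planted_mitotic_duration_h=m_frames_cell * dt,
                n_aberrant_mitoses=n_aberrant,
                binucleated=binucleated,
            )
        )

        # noise
        if noise_rate > 0:
            alive = state != _STATE_CODE["dead"]
            flip = (rng.uniform(size=n_frames) < noise_rate) & alive
            others = np.array(
                [_STATE_CODE["interphase"], _STATE_CODE["mitotic"], _STATE_CODE["binucleated"]],
                dtype=np.int8,
            )
            for i in np.nonzero(flip)[0]:
                choices = others[others != state[i]]
                state[i] = rng.choice(choices)
            s_flip = (rng.uniform(size=n_frames) < noise_rate) & alive
            s_pat = s_pat ^ s_flip
            a_flip = (rng.uniform(size=n_frames) < noise_rate) & alive
            aberrant = aberrant ^ a_flip

        trajs.append(
            CellTrajectory(
                cell_id=cid,
                states=np.array(STATES)[state],
                foci_count=foci,
                replication=s_pat,
                aberrant=aberrant,
            )
        )

    ev = pd.DataFrame(events)
    return trajs, ev


def generate_binucleate_pairs(
    n_cells: int,
    seed: int = 42,
    frame_interval: float = 0.5,
    duration: float = 72.0,
    s_duration_h: float = 16.0,
    shift_range_h: Tuple[float, float] = (0.0, 6.0),
    start_range_h: Tuple[float, float] = (6.0, 20.0),
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Paired per-nucleus replication traces for binucleated cells.

    Each cell has two nuclei (A, B) whose S-phase starts are shifted by a
    planted offset drawn uniformly from ``shift_range_h`` and rounded to
    the frame grid, emulating the unsynchronized replication of daughter
    nuclei sharing one cytoplasm after cytokinesis failure.

    Returns a long-format table (cell_id, nucleus, frame, time_h,
    replication_pattern) plus the planted shifts.
    """
    rng = np.random.default_rng(seed)
    n_frames = int(round(duration / frame_interval)) + 1
    rows = []
    planted = []
    for cid in range(n_cells):
        start_a = _grid(rng.uniform(*start_range_h), frame_interval)
        shift = _grid(rng.uniform(*shift_range_h), frame_interval) if shift_range_h[1] > 0 else 0
        s_frames = _grid(s_duration_h, frame_interval)
        for nucleus, start in (("A", start_a), ("B", start_a + shift)):
            pat = np.zeros(n_frames, dtype=bool)
            pat[start:min(start + s_frames, n_frames)] = True
            rows.append(
                pd.DataFrame(
                    {
                        "cell_id": cid,
                        "nucleus": nucleus,
                        "frame": np.arange(n_frames),
                        "time_h": np.arange(n_frames) * frame_interval,
                        "replication_pattern": np.where(pat, S_PATTERN, NO_PATTERN),
                    }
                )
            )
        planted.append(dict(cell_id=cid, shift_h=shift * frame_interval))
    return pd.concat(rows, ignore_index=True), pd.DataFrame(planted)
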