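"""Nuclear image analysis: segmentation, focus detection, per-cell features.

The fixed-cell arm of the pipeline turns 16-bit single-channel images into
the per-cell feature table consumed by the scoring module: a DAPI-derived
nuclear mask, white top-hat focus detection with per-nucleus adaptive
thresholding, and the per-readout feature sets (seven nuclear-morphology
features, three 53BP1 focus features, ten gamma-H2AX features, two p53 and
two EdU intensity features).

Conventions: coordinates are 0-based (row, column) pixel indices, areas in
pixels, intensities in raw camera units.  The default pixel size is
0.32 um/px.  Border-touching nuclei are removed to avoid truncated
features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Union

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import perimeter as _perimeter
from skimage.morphology import disk, white_tophat
from skimage.segmentation import clear_border, watershed

from .errors import AnalysisWarning, InputError, ParameterError
from .schema import FEATURES

DEFAULT_PIXEL_SIZE_UM = 0.32


@dataclass
class LabeledMask:
    """Integer nucleus label image (0 = background)."""

    labels: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    @property
    def n_nuclei(self) -> int:
        return int(self.labels.max())

    def label_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]


@dataclass
class FociSet:
    """Detected foci, one row per focus.

    Columns: ``label`` (parent nucleus), ``centroid_row``, ``centroid_col``,
    ``area``, ``integrated_intensity``, ``average_intensity``,
    ``min_intensity``, ``max_intensity``.
    """

    table: pd.DataFrame

    COLUMNS = [
        "label",
        "centroid_row",
        "centroid_col",
        "area",
        "integrated_intensity",
        "average_intensity",
        "min_intensity",
        "max_intensity",
    ]

    @classmethod
    def empty(cls) -> "FociSet":
        return cls(pd.DataFrame(columns=cls.COLUMNS))

    def __len__(self) -> int:
        return len(self.table)

    def for_nucleus(self, label: int) -> pd.DataFrame:
        return self.table[self.table["label"] == label]


def segment_nuclei(
    dapi_image: np.ndarray,
    min_area: int = 80,
    max_area: int = 100_000,
    intensity_threshold: Union[str, float] = "otsu",
    remove_border: bool = True,
) -> LabeledMask:
    """Segment nuclei from a DAPI (or H2B) channel.

    Pixels above ``intensity_threshold`` ("otsu" or a numeric value) form
    the foreground; touching nuclei are split by a watershed on the
    distance transform; components outside ``[min_area, max_area]`` and
    (optionally) objects touching the image border are discarded.
    """
    img = np.asarray(dapi_image)
    if img.ndim != 2:
        raise InputError("expected a 2-D single-channel image")
    if img.max() == img.min():
        warnings.warn(
            "blank or saturated image: empty segmentation", AnalysisWarning
        )
        return LabeledMask(np.zeros(img.shape, dtype=np.int32))

    if intensity_threshold == "otsu":
        thr = threshold_otsu(img)
    else:
        thr = float(intensity_threshold)
    fg = img > thr
    if not fg.any():
        warnings.warn("no foreground above threshold", AnalysisWarning)
        return LabeledMask(np.zeros(img.shape, dtype=np.int32))

    distance = ndimage.distance_transform_edt(fg)
    # one marker per local distance maximum, far enough apart to avoid
    # oversplitting single nuclei
    peaks = peak_local_max(
        distance, min_distance=7, labels=fg, exclude_border=False
    )
    markers = np.zeros(img.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        markers, _ = ndimage.label(fg)
    labels = watershed(-distance, markers, mask=fg)

    if remove_border:
        labels = clear_border(labels)

    # area filter + relabel consecutively
    out = np.zeros(img.shape, dtype=np.int32)
    next_id = 1
    for lab in np.unique(labels):
        if lab == 0:
            continue
        m = labels == lab
        a = int(m.sum())
        if min_area <= a <= max_area:
            out[m] = next_id
            next_id += 1
    return LabeledMask(out)


def _robust_sd(x: np.ndarray) -> float:
    med = np.median(x)
    return 1.4826 * float(np.median(np.abs(x - med)))


def detect_foci(
    channel_image: np.ndarray,
    mask: LabeledMask,
    tophat_radius: int = 5,
    threshold_factor: float = 3.0,
    min_focus_area: int = 2,
    boundary_margin: int = 2,
    floor_fraction: float = 0.1,
) -> FociSet:
    """Detect bright sub-nuclear foci by white top-hat filtering.

    A white top-hat with a disk structuring element of ``tophat_radius``
    isolates structures smaller than the element (and removes any constant
    background); inside each nucleus the response is thresholded at
    ``median + threshold_factor x robust sd`` (robust sd = 1.4826 x MAD),
    floored at ``floor_fraction`` of the nucleus' peak response so the
    threshold cannot collapse on near-noiseless images.  The outermost
    ``boundary_margin`` pixels of each nucleus are excluded: the top-hat
    cannot follow the steep intensity fall-off at the nuclear rim and
    leaves a spurious annular response there.  Connected components of at
    least ``min_focus_area`` pixels become foci; anything outside a
    nucleus is discarded.
    """
    if tophat_radius < 1:
        raise ParameterError("tophat_radius must be >= 1")
    img = np.asarray(channel_image, dtype=float)
    if img.shape != mask.labels.shape:
        raise InputError("channel image and mask shapes differ")

    th = white_tophat(img, footprint=disk(tophat_radius))
    rows: List[dict] = []
    for lab in mask.label_ids():
        nucleus = mask.labels == lab
        if boundary_margin > 0:
            core = ndimage.binary_erosion(
                nucleus, structure=disk(boundary_margin)
            )
            if not core.any():
                core = nucleus
        else:
            core = nucleus
        vals = th[core]
        thr = np.median(vals) + threshold_factor * _robust_sd(vals)
        thr = max(thr, floor_fraction * float(vals.max()))
        binary = core & (th > thr)
        comp, n = ndimage.label(binary)
        for f in range(1, n + 1):
            m = comp == f
            area = int(m.sum())
            if area < min_focus_area:
                continue
            inten = img[m]
            r, c = np.nonzero(m)
            rows.append(
                dict(
                    label=int(lab),
                    centroid_row=float(r.mean()),
                    centroid_col=float(c.mean()),
                    area=area,
                    integrated_intensity=float(inten.sum()),
                    average_intensity=float(inten.mean()),
                    min_intensity=float(inten.min()),
                    max_intensity=float(inten.max()),
                )
            )
    if not rows:
        return FociSet.empty()
    return FociSet(pd.DataFrame(rows, columns=FociSet.COLUMNS))


def _weighted_axes(m: np.ndarray, intensity: np.ndarray) -> tuple[float, float]:
    """Major/minor axis lengths of the intensity-weighted second-moment
    ellipse of one labelled region."""
    r, c = np.nonzero(m)
    w = intensity[m].astype(float)
    w = np.clip(w, 0, None)
    tot = w.sum()
    if tot <= 0:
        w = np.ones_like(w)
        tot = w.sum()
    rc, cc = (w * r).sum() / tot, (w * c).sum() / tot
    mu20 = (w * (r - rc) ** 2).sum() / tot
    mu02 = (w * (c - cc) ** 2).sum() / tot
    mu11 = (w * (r - rc) * (c - cc)).sum() / tot
    cov = np.array([[mu20, mu11], [mu11, mu02]])
    ev = np.linalg.eigvalsh(cov)
    ev = np.clip(ev, 0, None)
    minor, major = 4.0 * np.sqrt(ev)
    return float(major), float(max(minor, 1e-9))


def compute_features(
    mask: LabeledMask,
    channel_images: Dict[str, np.ndarray],
    foci: Optional[Dict[str, FociSet]] = None,
) -> pd.DataFrame:
    """Per-nucleus feature table over the requested readouts.

    ``channel_images`` maps readout name ("morphology", "53bp1", "gh2ax",
    "p53", "edu") to the aligned channel image; ``foci`` maps the focus
    readouts to their detected :class:`FociSet`.  Feature definitions:
    area = pixel count, integrated = pixel sum, average = integrated/area,
    perimeter = boundary contour length, cell length/breadth = major/minor
    axis of the intensity-weighted second-moment ellipse, elliptical form
    factor = length/breadth.  The gamma-H2AX min/max average intensities
    are the per-nucleus extrema of the 3x3 mean-filtered channel.
    """
    foci = foci or {}
    for readout, img in channel_images.items():
        if np.asarray(img).shape != mask.labels.shape:
            raise InputError(f"channel {readout!r} shape differs from mask")
    for readout in channel_images:
        if readout not in FEATURES:
            raise InputError(f"unknown readout {readout!r}")

    records: List[dict] = []
    for lab in mask.label_ids():
        m = mask.labels == lab
        area = int(m.sum())
        rec: dict = {"label": int(lab), "area_px": area}

        if "morphology" in channel_images:
            img = np.asarray(channel_images["morphology"], dtype=float)
            integ = float(img[m].sum())
            avg = integ / area
            major, minor = _weighted_axes(m, img)
            rec.update(
                {
                    "morph_integrated_intensity": integ,
                    "morph_average_intensity": avg,
                    "morph_area": float(area),
                    "morph_perimeter": float(_perimeter(m)),
                    "morph_cell_length": major,
                    "morph_cell_breadth": minor,
                    "morph_form_factor": major / minor,
                }
            )

        if "53bp1" in channel_images:
            fs = foci.get("53bp1", FociSet.empty()).for_nucleus(lab)
            rec.update(
                {
                    "53bp1_foci_number": float(len(fs)),
                    "53bp1_foci_area": float(fs["area"].sum()) if len(fs) else 0.0,
                    "53bp1_foci_integrated_intensity": (
                        float(fs["integrated_intensity"].sum()) if len(fs) else 0.0
                    ),
                }
            )

        if "gh2ax" in channel_images:
            img = np.asarray(channel_images["gh2ax"], dtype=float)
            integ = float(img[m].sum())
            avg = integ / area
            smoothed = ndimage.uniform_filter(img, size=3)
            fs = foci.get("gh2ax", FociSet.empty()).for_nucleus(lab)
            nf = len(fs)
            rec.update(
                {
                    "gh2ax_nuclear_integrated_intensity": integ,
                    "gh2ax_nuclear_average_intensity": avg,
                    "gh2ax_min_average_intensity": float(smoothed[m].min()),
                    "gh2ax_max_average_intensity": float(smoothed[m].max()),
                    "gh2ax_foci_count": float(nf),
                    "gh2ax_foci_area": float(fs["area"].sum()) if nf else 0.0,
                    "gh2ax_foci_integrated_intensity": (
                        float(fs["integrated_intensity"].sum()) if nf else 0.0
                    ),
                    "gh2ax_foci_average_intensity": (
                        float(fs["average_intensity"].mean()) if nf else 0.0
                    ),
                    "gh2ax_foci_min_intensity": (
                        float(fs["min_intensity"].min()) if nf else 0.0
                    ),
                    "gh2ax_foci_max_intensity": (
                        float(fs["max_intensity"].max()) if nf else 0.0
                    ),
                }
            )

        for readout in ("p53", "edu"):
            if readout in channel_images:
                img = np.asarray(channel_images[readout], dtype=float)
                integ = float(img[m].sum())
                rec.update(
                    {
                        f"{readout}_average_intensity": integ / area,
                        f"{readout}_integrated_intensity": integ,
                    }
                )
        records.append(rec)
    return pd.DataFrame(records)


def mitotic_gammaH2AX_score(
    dapi_image: np.ndarray,
    gh2ax_image: np.ndarray,
    mitotic_intensity_threshold: float,
    tophat_radius: int = 5,
    threshold_factor: float = 3.0,
    min_focus_area: int = 2,
    min_object_area: int = 30,
) -> float:
    """Average sum of gamma-H2AX focus intensity per mitotic cell.

    Mitotic cells are identified as DAPI objects whose average intensity
    exceeds ``mitotic_intensity_threshold`` (condensed chromatin is much
    brighter than interphase chromatin).  For each mitotic cell the
    integrated intensities of its detected gamma-H2AX foci are summed; the
    mean of these per-cell sums over all mitotic cells is returned (0 with
    a warning when no mitotic cell is found).
    """
    dapi = np.asarray(dapi_image, dtype=float)
    gh2ax = np.asarray(gh2ax_image, dtype=float)
    if dapi.shape != gh2ax.shape:
        raise InputError("DAPI and gamma-H2AX images must be aligned")

    comp, n = ndimage.label(dapi > 0)
    mitotic = np.zeros(dapi.shape, dtype=np.int32)
    next_id = 1
    for lab in range(1, n + 1):
        m = comp == lab
        if m.sum() < min_object_area:
            continue
        if dapi[m].mean() > mitotic_intensity_threshold:
            mitotic[m] = next_id
            next_id += 1
    if next_id == 1:
        warnings.warn("no mitotic cells above threshold", AnalysisWarning)
        return 0.0

    mask = LabeledMask(mitotic)
    fs = detect_foci(
        gh2ax,
        mask,
        tophat_radius=tophat_radius,
        threshold_factor=threshold_factor,
        min_focus_area=min_focus_area,
    )
    sums = np.zeros(next_id - 1)
    if len(fs):
        per = fs.table.groupby("label")["integrated_intensity"].sum()
        for lab, v in per.items():
            sums[int(lab) - 1] = v
    return float(sums.mean())
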