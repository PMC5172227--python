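"""Feature-table schema shared by the synthetic generator and the image
feature extractor.

One row per segmented cell.  Key columns identify the experimental
condition; feature columns are grouped by readout:

* ``morphology`` — seven DAPI/H2B nuclear-shape and intensity features,
* ``53bp1`` — three DNA-damage focus features,
* ``gh2ax`` — ten nuclear + focus features (focal to pan-nuclear response),
* ``p53`` — two nuclear-intensity features (cellular stress),
* ``edu`` — two nuclear-intensity features (DNA replication).
"""

from __future__ import annotations

KEY_COLUMNS = ["target", "sirna_id", "replicate", "well", "cell_id"]

READOUTS = ("morphology", "53bp1", "gh2ax", "p53", "edu")

FEATURES: dict[str, list[str]] = {
    "morphology": [
        "morph_integrated_intensity",
        "morph_average_intensity",
        "morph_area",
        "morph_perimeter",
        "morph_cell_length",
        "morph_cell_breadth",
        "morph_form_factor",
    ],
    "53bp1": [
        "53bp1_foci_number",
        "53bp1_foci_area",
        "53bp1_foci_integrated_intensity",
    ],
    "gh2ax": [
        "gh2ax_nuclear_integrated_intensity",
        "gh2ax_nuclear_average_intensity",
        "gh2ax_min_average_intensity",
        "gh2ax_max_average_intensity",
        "gh2ax_foci_count",
        "gh2ax_foci_area",
        "gh2ax_foci_integrated_intensity",
        "gh2ax_foci_average_intensity",
        "gh2ax_foci_min_intensity",
        "gh2ax_foci_max_intensity",
    ],
    "p53": [
        "p53_average_intensity",
        "p53_integrated_intensity",
    ],
    "edu": [
        "edu_average_intensity",
        "edu_integrated_intensity",
    ],
}

ALL_FEATURE_COLUMNS = [c for cols in FEATURES.values() for c in cols]

#: Long-format per-frame trajectory table.
TRAJECTORY_COLUMNS = [
    "cell_id",
    "frame",
    "time_h",
    "state",
    "foci_count",
    "replication_pattern",
    "aberrant_flag",
]

STATES = ("interphase", "mitotic", "dead", "binucleated")
S_PATTERN = "S-pattern"
NO_PATTERN = "none"
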