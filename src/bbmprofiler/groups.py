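"""Canonical 2x2 factorial group layout.

Every four-value vector in this package (raw counts, normalized profiles,
template models) is ordered as ``GROUP_ORDER``: control-vehicle,
control-GLP-2, knockout-vehicle, knockout-GLP-2.  A single fixed convention
prevents silent template misalignment.
"""

from __future__ import annotations

GROUP_ORDER: tuple[str, str, str, str] = (
    "ctrl_vehicle",
    "ctrl_glp2",
    "ko_vehicle",
    "ko_glp2",
)

GENOTYPE_LEVELS: tuple[str, str] = ("ctrl", "ko")
TREATMENT_LEVELS: tuple[str, str] = ("vehicle", "glp2")

#: group label -> (genotype, treatment)
GROUP_FACTORS: dict[str, tuple[str, str]] = {
    "ctrl_vehicle": ("ctrl", "vehicle"),
    "ctrl_glp2": ("ctrl", "glp2"),
    "ko_vehicle": ("ko", "vehicle"),
    "ko_glp2": ("ko", "glp2"),
}

N_GROUPS = 4
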