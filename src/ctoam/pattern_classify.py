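"""Distribution-pattern taxonomy for high-density areas.

Each knee's high-density surface map is assigned one label from a
bone-specific taxonomy:

* distal femur — Blank, Anterior-Lateral, Dual Center, Center Connections;
* tibial plateau — Blank, Scatter, Multi-Center, Multi-Center Connections.

The taxonomy names and their bone applicability come from clinical CTOAM
reporting practice; the decision rules below are this package's explicit,
deterministic operationalisation (the geometry thresholds are conventions,
exposed as parameters).  Rules are evaluated in a fixed precedence order so
classification is a total function:

femur:  Blank > Center Connections > Anterior-Lateral > Dual Center
tibia:  Blank > Multi-Center Connections > Multi-Center > Scatter

All laterality tests ("anterior-lateral quadrant", medial/lateral columns)
are anatomical, resolved through the map's side flag, so mirroring an image
left-right together with its side flag leaves the label unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import percent_round_half_away
from .surface_mapping import HighDensityAreas, RegionGrid

FEMUR_LABELS = ("Blank", "Anterior-Lateral", "Dual Center", "Center Connections")
TIBIA_LABELS = ("Blank", "Scatter", "Multi-Center", "Multi-Center Connections")

#: all rows of a combined pattern table, in report order
ALL_LABELS = (
    "Blank",
    "Anterior-Lateral",
    "Dual Center",
    "Center Connections",
    "Scatter",
    "Multi-Center",
    "Multi-Center Connections",
)

#: minimum area of one zone to count as a tibial "center" (mm^2)
BIG_AREA_MM2 = 100.0


@dataclass
class PatternLabel:
    bone: str
    label: str
    evidence: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        allowed = FEMUR_LABELS if self.bone == "distal_femur" else TIBIA_LABELS
        if self.label not in allowed:
            raise ValueError(f"label {self.label!r} not applicable to {self.bone}")


def _anat_column(region: int) -> int:
    """0 = medial, 1 = central, 2 = lateral (region numbering is anatomical)."""
    return (region - 1) % 3


def _columns_of(comp) -> set[int]:
    return {_anat_column(r) for r in comp.regions}


def _in_anterior_lateral_quadrant(centroid: tuple[float, float], grid: RegionGrid) -> bool:
    x0, x1, y0, y1 = grid.bbox
    x_mid = (x0 + x1) / 2.0
    y_mid = (y0 + y1) / 2.0
    cx, cy = centroid
    anterior = cy < y_mid  # low y is anterior by the axis convention
    lateral = cx > x_mid if grid.side == "right" else cx < x_mid
    return anterior and lateral


def classify(
    areas: HighDensityAreas,
    grid: RegionGrid,
    bone: str,
    big_area_mm2: float = BIG_AREA_MM2,
) -> PatternLabel:
    """Assign a distribution-pattern label to one knee.

    Femur rules: *Blank* — no high-density area; *Center Connections* — one
    component bridges the central row from the medial column (region 4) to
    the lateral column (region 6); *Anterior-Lateral* — every component
    centroid lies in the anterior-lateral quadrant of the footprint; *Dual
    Center* — the remaining multi/off-center configurations.

    Tibia rules: *Blank* — none; *Multi-Center Connections* — one component
    spans >= 2 of the three anatomical columns; *Multi-Center* — >= 2
    disjoint components each at least ``big_area_mm2``; *Scatter* — the
    remaining small, spread configurations.
    """
    comps = areas.components
    evidence = {
        "n_components": len(comps),
        "areas_mm2": [round(c.area_mm2, 3) for c in comps],
        "regions": [sorted(c.regions) for c in comps],
    }
    if bone == "distal_femur":
        if not comps:
            label = "Blank"
        elif any({4, 6} <= c.regions for c in comps):
            label = "Center Connections"
        elif all(_in_anterior_lateral_quadrant(c.centroid, grid) for c in comps):
            label = "Anterior-Lateral"
        else:
            label = "Dual Center"
    elif bone == "tibial_plateau":
        if not comps:
            label = "Blank"
        elif any(len(_columns_of(c)) >= 2 for c in comps):
            label = "Multi-Center Connections"
        elif sum(c.area_mm2 >= big_area_mm2 for c in comps) >= 2:
            label = "Multi-Center"
        else:
            label = "Scatter"
    else:
        raise ValueError(f"unknown bone {bone!r}")
    return PatternLabel(bone=bone, label=label, evidence=evidence)


def pattern_table(cohort: list[PatternLabel], n_knees: int | None = None) -> pd.DataFrame:
    """Count pattern labels across a cohort of knees of one bone.

    Emits one row per taxonomy label; labels that do not apply to the
    cohort's bone are marked "/" in both columns, matching report layout.
    Percentages use the same rounding rule as the region frequency table.
    """
    if not cohort:
        raise ValueError("empty cohort")
    bones = {p.bone for p in cohort}
    if len(bones) != 1:
        raise ValueError(f"cohort mixes bones: {sorted(bones)}")
    bone = bones.pop()
    if n_knees is None:
        n_knees = len(cohort)
    if len(cohort) != n_knees:
        raise ValueError("expected one label per knee")
    applicable = FEMUR_LABELS if bone == "distal_femur" else TIBIA_LABELS
    rows = []
    for label in ALL_LABELS:
        if label not in applicable:
            rows.append({"pattern": label, "count": "/", "percent": "/"})
            continue
        c = sum(p.label == label for p in cohort)
        rows.append({"pattern": label, "count": c, "percent": percent_round_half_away(c, n_knees)})
    return pd.DataFrame(rows)
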