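"""Articular-surface density maps, nine-region partition, high-density areas.

The subchondral ROI is collapsed onto the articular surface by a
maximum-intensity projection (MIP) along the inferior-superior axis: every
(x, y) column that intersects the ROI contributes its maximal HU.  The map
footprint is partitioned into nine anatomical regions by an equal-thirds
grid over its bounding box.  Region numbering is a fixed convention:

    rows run anterior (top) to posterior, columns medial to lateral;
    region = (row - 1) * 3 + column, so region 5 is central.

"Medial" is resolved through the ``side`` flag, so the numbering is
anatomically mirrored between left and right knees: for a right knee the
medial column is at low x, for a left knee at high x.  High-density areas
are 8-connected pixel components above a HU cutoff with a minimum surface
area; cohort frequency tables count, per region, the knees in which at
least one such area touches the region.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from ._utils import percent_round_half_away
from .imageio import CTVolume
from .subchondral_roi import SubchondralROI

#: 8-connectivity structuring element for 2D component labelling
CONN8 = np.ones((3, 3), dtype=bool)

#: default HU cutoff for a "high-density" surface pixel: the lower edge of
#: the high density class (bins 9-12 start at 901 HU)
HIGH_DENSITY_THRESHOLD_HU = 901

#: default minimal surface area of a countable high-density zone
MIN_AREA_MM2 = 25.0


@dataclass
class DensityMap2D:
    """Projected subchondral density on the articular surface."""

    values: np.ndarray  # float [x, y]; NaN outside footprint
    footprint: np.ndarray  # bool [x, y]
    pixel_spacing_mm: tuple[float, float]
    bone: str = "unknown"
    side: str = "right"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.footprint = np.asarray(self.footprint, dtype=bool)
        if self.values.shape != self.footprint.shape:
            raise ValueError("values and footprint shapes differ")

    @property
    def pixel_area_mm2(self) -> float:
        return float(self.pixel_spacing_mm[0] * self.pixel_spacing_mm[1])


@dataclass
class RegionGrid:
    """Nine-region partition of a map footprint (labels 1..9, 0 outside)."""

    region_of_pixel: np.ndarray
    side: str
    bbox: tuple[int, int, int, int]  # x0, x1, y0, y1 inclusive

    def regions_present(self) -> set[int]:
        return set(np.unique(self.region_of_pixel[self.region_of_pixel > 0]).tolist())


@dataclass
class HighDensityComponent:
    pixels: np.ndarray  # (n, 2) int array of (x, y)
    area_mm2: float
    centroid: tuple[float, float]
    regions: frozenset[int]


@dataclass
class HighDensityAreas:
    components: list[HighDensityComponent]
    threshold_hu: int
    min_area_mm2: float

    @property
    def regions_touched(self) -> set[int]:
        out: set[int] = set()
        for c in self.components:
            out |= c.regions
        return out


def project_density(vol: CTVolume, roi: SubchondralROI) -> DensityMap2D:
    """Maximum-intensity projection of the ROI along the z axis."""
    if roi.mask.shape != vol.data.shape:
        raise ValueError("ROI grid does not match volume grid")
    if not roi.mask.any():
        raise ValueError("empty ROI: nothing to project")
    sentinel = np.iinfo(np.int16).min
    shielded = np.where(roi.mask, vol.data, sentinel)
    values = shielded.max(axis=2).astype(float)
    footprint = roi.mask.any(axis=2)
    values[~footprint] = np.nan
    return DensityMap2D(
        values=values,
        footprint=footprint,
        pixel_spacing_mm=(vol.spacing_mm[0], vol.spacing_mm[1]),
        bone=roi.bone,
        side=roi.side,
    )


def _thirds_band(idx: np.ndarray, lo: int, hi: int) -> np.ndarray:
    """Band 0/1/2 for indices in [lo, hi] split into three equal-width bands."""
    extent = hi - lo + 1
    return np.minimum((idx - lo) * 3 // extent, 2)


def nine_regions(dmap: DensityMap2D) -> RegionGrid:
    """Partition the footprint bounding box into the 3x3 anatomical grid."""
    fp = dmap.footprint
    if not fp.any():
        raise ValueError("empty footprint")
    xs, ys = np.nonzero(fp)
    x0, x1 = int(xs.min()), int(xs.max())
    y0, y1 = int(ys.min()), int(ys.max())
    if x1 - x0 + 1 < 3 or y1 - y0 + 1 < 3:
        raise ValueError("degenerate footprint: need at least 3 pixels extent per axis")
    xg, yg = np.meshgrid(np.arange(fp.shape[0]), np.arange(fp.shape[1]), indexing="ij")
    col_band = _thirds_band(xg, x0, x1)  # 0 at low x
    row = _thirds_band(yg, y0, y1)  # 0 = anterior
    if dmap.side == "right":
        col_anat = col_band  # low x = medial for right knee
    else:
        col_anat = 2 - col_band
    region = (row * 3 + col_anat + 1).astype(np.int8)
    region[~fp] = 0
    return RegionGrid(region_of_pixel=region, side=dmap.side, bbox=(x0, x1, y0, y1))


def detect_high_density(
    dmap: DensityMap2D,
    threshold_hu: int = HIGH_DENSITY_THRESHOLD_HU,
    min_area_mm2: float = MIN_AREA_MM2,
    regions: RegionGrid | None = None,
) -> HighDensityAreas:
    """Find 8-connected high-density surface areas above the HU cutoff.

    Components smaller than ``min_area_mm2`` are discarded.  Each component
    records every region containing at least one of its pixels.  An empty
    result is valid (the *Blank* pattern).
    """
    if regions is None:
        regions = nine_regions(dmap)
    hot = dmap.footprint & (np.where(dmap.footprint, dmap.values, -np.inf) >= threshold_hu)
    labels, n = ndimage.label(hot, structure=CONN8)
    comps: list[HighDensityComponent] = []
    for lab in range(1, n + 1):
        xs, ys = np.nonzero(labels == lab)
        area = len(xs) * dmap.pixel_area_mm2
        if area < min_area_mm2:
            continue
        touched = frozenset(int(r) for r in np.unique(regions.region_of_pixel[xs, ys]) if r > 0)
        comps.append(
            HighDensityComponent(
                pixels=np.stack([xs, ys], axis=1),
                area_mm2=float(area),
                centroid=(float(xs.mean()), float(ys.mean())),
                regions=touched,
            )
        )
    return HighDensityAreas(components=comps, threshold_hu=int(threshold_hu), min_area_mm2=float(min_area_mm2))


def region_frequency(
    cohort: Sequence[HighDensityAreas | Iterable[int]],
    n_knees: int | None = None,
) -> pd.DataFrame:
    """Per-region frequency of high-density areas across a cohort of knees.

    Each cohort entry is the detection result (or simply the set of region
    indices touched) for one knee.  ``count`` is the number of knees with at
    least one high-density area touching the region; ``percent`` is the
    integer percentage of ``n_knees`` under nearest-integer rounding with
    halves away from zero.
    """
    if n_knees is None:
        n_knees = len(cohort)
    if n_knees < 1:
        raise ValueError("n_knees must be >= 1")
    if len(cohort) != n_knees:
        raise ValueError(f"expected one entry per knee: {len(cohort)} entries for {n_knees} knees")
    counts = np.zeros(9, dtype=int)
    for entry in cohort:
        touched = entry.regions_touched if isinstance(entry, HighDensityAreas) else set(entry)
        for r in touched:
            if not 1 <= int(r) <= 9:
                raise ValueError(f"region index {r} outside 1..9")
            counts[int(r) - 1] += 1
    percent = [percent_round_half_away(int(c), n_knees) for c in counts]
    return pd.DataFrame({"region": np.arange(1, 10), "count": counts, "percent": percent})
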