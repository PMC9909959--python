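"""The 12-interval CTOAM density scheme and %BTV quantification.

Subchondral bone HU values are partitioned into 12 closed integer intervals:
100-200, 201-300, ..., 1101-1200 and 1201-maximum.  Bins 1-4 form the *low*,
5-8 the *medium* and 9-12 the *high* density class.  Voxels below 100 HU are
not bone tissue of interest (BTOI) and enter neither numerator nor
denominator, so the 12 percentages %BTV_i = 100 * V_i / V_BTOI always sum
to 100.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imageio import CTVolume

#: pseudo-colour scale, low (blue) to very high (white)
DEFAULT_COLORS = (
    "#0000b0", "#0040ff", "#00a0ff", "#00e0c0",
    "#40ff80", "#a0ff40", "#ffff00", "#ffc000",
    "#ff8000", "#ff4000", "#e00000", "#ffffff",
)

BIN_CLASSES = ("low",) * 4 + ("medium",) * 4 + ("high",) * 4


@dataclass(frozen=True)
class DensityScheme:
    """12 disjoint integer HU intervals covering [100, +inf).

    ``edges[i] = (lo, hi)`` with ``hi=None`` for the open-ended top bin; an
    integer HU value h belongs to bin i+1 iff lo <= h <= hi.
    """

    edges: tuple[tuple[int, int | None], ...]
    class_of_bin: tuple[str, ...] = BIN_CLASSES
    colors: tuple[str, ...] = DEFAULT_COLORS

    def __post_init__(self) -> None:
        if len(self.edges) != 12:
            raise ValueError(f"scheme must have exactly 12 bins, got {len(self.edges)}")
        los = [lo for lo, _ in self.edges]
        if los[0] != 100:
            raise ValueError("lowest interval must start at 100 HU")
        for (lo, hi), (nlo, _) in zip(self.edges[:-1], self.edges[1:]):
            if hi is None or nlo != hi + 1:
                raise ValueError("intervals must be contiguous integer ranges")
        if self.edges[-1][1] is not None:
            raise ValueError("top interval must be open-ended (1201-maximum)")
        if len(self.class_of_bin) != 12 or len(self.colors) != 12:
            raise ValueError("class_of_bin and colors must have 12 entries")

    @classmethod
    def default(cls) -> "DensityScheme":
        lows = [100] + [201 + 100 * i for i in range(10)] + [1201]
        edges = tuple(
            (lo, (lo + 99 if i > 0 else 200) if i < 11 else None) for i, lo in enumerate(lows)
        )
        return cls(edges=edges)

    @property
    def lower_edges(self) -> np.ndarray:
        return np.array([lo for lo, _ in self.edges], dtype=np.int32)

    @property
    def labels(self) -> list[str]:
        out = []
        for lo, hi in self.edges:
            out.append(f"{lo}-{hi}" if hi is not None else f"{lo}-maximum")
        return out


@dataclass
class BTVProfile:
    """Per-bin subchondral bone volumes and the %BTV_i vector for one knee.

    %BTV_i = 100 * volumes_mm3[i] / total_btoi_mm3, i = 1..12.
    """

    volumes_mm3: np.ndarray
    bone: str = "unknown"
    side: str = "unknown"
    counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.volumes_mm3, dtype=float)
        if v.shape != (12,):
            raise ValueError(f"volumes_mm3 must have 12 entries, got shape {v.shape}")
        if np.any(v < 0):
            raise ValueError("per-bin volumes must be non-negative")
        self.volumes_mm3 = v

    @property
    def total_btoi_mm3(self) -> float:
        return float(self.volumes_mm3.sum())

    @property
    def pct(self) -> np.ndarray:
        total = self.total_btoi_mm3
        if total <= 0:
            raise ValueError("empty BTOI: total subchondral volume is zero")
        return 100.0 * self.volumes_mm3 / total


def bin_voxels(vol: CTVolume, roi, scheme: DensityScheme | None = None) -> np.ndarray:
    """Label every voxel with its density bin.

    Returns an int grid the shape of the volume: 0 for voxels outside the
    ROI or below 100 HU, otherwise the bin index 1..12.  Binning is exact
    integer-interval membership (HU 200 -> bin 1, HU 201 -> bin 2).
    """
    scheme = scheme or DensityScheme.default()
    mask = roi.mask if hasattr(roi, "mask") else np.asarray(roi, dtype=bool)
    if mask.shape != vol.data.shape:
        raise ValueError(f"ROI grid {mask.shape} does not match volume grid {vol.data.shape}")
    if hasattr(roi, "spacing_mm") and roi.spacing_mm is not None:
        if not np.allclose(roi.spacing_mm, vol.spacing_mm):
            raise ValueError("ROI and volume voxel spacing differ")
    h = vol.data
    labels = np.searchsorted(scheme.lower_edges, h, side="right").astype(np.uint8)
    labels[(h < scheme.lower_edges[0]) | ~mask] = 0
    return labels


def btv_profile(
    labels: np.ndarray,
    spacing_mm: tuple[float, float, float],
    bone: str = "unknown",
    side: str = "unknown",
) -> BTVProfile:
    """Turn a bin-label grid into per-bin volumes (mm^3) and %BTV_i."""
    labels = np.asarray(labels)
    counts = np.bincount(labels.ravel(), minlength=13)[1:13]
    if counts.sum() == 0:
        raise ValueError("empty BTOI: no voxel falls in bins 1-12")
    voxel_volume = float(np.prod(spacing_mm))
    return BTVProfile(
        volumes_mm3=counts.astype(float) * voxel_volume,
        bone=bone,
        side=side,
        counts=counts.astype(np.int64),
    )


def class_summary(profile: BTVProfile) -> dict[str, float]:
    """Aggregate %BTV into the low / medium / high density classes.

    The three aggregates sum to 100 by construction.
    """
    pct = profile.pct
    return {
        "low": float(pct[0:4].sum()),
        "medium": float(pct[4:8].sum()),
        "high": float(pct[8:12].sum()),
    }
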