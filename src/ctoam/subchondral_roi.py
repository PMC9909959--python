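"""Extraction of the bone tissue of interest (BTOI).

The BTOI is the subchondral bone between the articular surface and the
epiphyseal line.  Extraction mirrors the interactive mask-edit workflow of
clinical CTOAM software with deterministic operations: HU thresholding
(``bone_mask``), 26-connected region growing (``region_grow``) and clipping
at the epiphyseal boundary (``clip_to_epiphyseal``).  The epiphyseal line is
modelled as a flat plane perpendicular to the inferior-superior axis; it can
be supplied explicitly or auto-detected as the slice of minimum in-mask mean
HU (the growth-plate remnant is less dense than the surrounding bone).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .imageio import CTVolume

#: 26-connectivity structuring element used for all 3D component operations
CONN26 = np.ones((3, 3, 3), dtype=bool)

BONES = ("distal_femur", "tibial_plateau")
SIDES = ("left", "right")


@dataclass
class SubchondralROI:
    """Binary voxel mask of the BTOI for one bone of one knee."""

    mask: np.ndarray
    bone: str
    side: str
    epiphyseal_plane_z: int
    spacing_mm: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("ROI mask must be 3D")
        if not self.mask.any():
            raise ValueError("ROI mask is empty")
        if self.bone not in BONES:
            raise ValueError(f"bone must be one of {BONES}, got {self.bone!r}")
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}, got {self.side!r}")

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())


def bone_mask(vol: CTVolume, threshold_hu: int = 100) -> np.ndarray:
    """Threshold the volume at ``threshold_hu`` (default 100 HU, the lower
    edge of the lowest density interval)."""
    mask = vol.data >= threshold_hu
    if not mask.any():
        raise ValueError(f"empty mask: no voxel reaches {threshold_hu} HU")
    return mask


def region_grow(mask: np.ndarray, seed_voxel: tuple[int, int, int]) -> np.ndarray:
    """Return the 26-connected component of ``mask`` containing ``seed_voxel``."""
    mask = np.asarray(mask, dtype=bool)
    seed = tuple(int(i) for i in seed_voxel)
    if len(seed) != 3:
        raise ValueError("seed_voxel must be a 3-index")
    if not mask[seed]:
        raise ValueError(f"seed voxel {seed} is outside the mask")
    labels, _ = ndimage.label(mask, structure=CONN26)
    return labels == labels[seed]


def largest_component(mask: np.ndarray) -> np.ndarray:
    """Largest 26-connected component (ties broken by lowest label index)."""
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(mask, structure=CONN26)
    if n == 0:
        raise ValueError("empty mask has no components")
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == int(counts.argmax())


def detect_epiphyseal_plane(vol: CTVolume, mask: np.ndarray, min_voxels: int = 10) -> int:
    """Best-effort epiphyseal plane: z slice with minimum in-mask mean HU.

    Only slices holding at least ``min_voxels`` mask voxels are considered.
    Intended as a starting point; the plane should be reviewed/overridden.
    """
    mask = np.asarray(mask, dtype=bool)
    nz = mask.shape[2]
    means = np.full(nz, np.inf)
    for z in range(nz):
        m = mask[:, :, z]
        if m.sum() >= min_voxels:
            means[z] = float(vol.data[:, :, z][m].mean())
    if not np.isfinite(means).any():
        raise ValueError("mask too small to locate an epiphyseal plane")
    return int(np.argmin(means))


def clip_to_epiphyseal(
    mask: np.ndarray,
    plane_z: int,
    bone: str,
    side: str = "right",
    spacing_mm: tuple[float, float, float] | None = None,
) -> SubchondralROI:
    """Clip a bone mask at the epiphyseal plane and keep the articular side.

    The distal femur articulates inferiorly, so voxels with ``z <= plane_z``
    are kept; the tibial plateau articulates superiorly, so ``z >= plane_z``
    are kept.  The result is reduced to its largest 26-connected component
    (the layer-by-layer erase always leaves one body of subchondral bone).
    Idempotent: clipping an already-clipped mask at the same plane is a
    no-op.
    """
    mask = np.asarray(mask, dtype=bool)
    if bone not in BONES:
        raise ValueError(f"bone must be one of {BONES}, got {bone!r}")
    if not (0 <= plane_z < mask.shape[2]):
        raise ValueError(f"plane_z {plane_z} outside grid of depth {mask.shape[2]}")
    z = np.arange(mask.shape[2])
    keep = z <= plane_z if bone == "distal_femur" else z >= plane_z
    clipped = mask & keep[None, None, :]
    if not clipped.any():
        raise ValueError("clipping at the epiphyseal plane emptied the mask")
    clipped = largest_component(clipped)
    return SubchondralROI(
        mask=clipped, bone=bone, side=side, epiphyseal_plane_z=int(plane_z), spacing_mm=spacing_mm
    )


def extract_roi(
    vol: CTVolume,
    bone: str,
    side: str,
    plane_z: int | None = None,
    threshold_hu: int = 100,
) -> SubchondralROI:
    """Full extraction: threshold, grow the main body, clip at the plane.

    ``plane_z=None`` triggers auto-detection (see
    :func:`detect_epiphyseal_plane`).
    """
    mask = largest_component(bone_mask(vol, threshold_hu))
    if plane_z is None:
        plane_z = detect_epiphyseal_plane(vol, mask)
    return clip_to_epiphyseal(mask, plane_z, bone, side, spacing_mm=vol.spacing_mm)
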