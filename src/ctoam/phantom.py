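"""Synthetic CT knee phantoms with exact ground truth.

Because clinical CT of elite athletes is not publicly distributable, every
downstream stage is exercised on stylized digital phantoms: the distal
femur is modelled as two condylar ellipsoids joined by a trochlear bridge
and a shaft, the tibial plateau as two compartment cylinders joined by a
central block.  Geometry is intentionally schematic — it exists to give the
ROI, projection, nine-region and statistics code a realistic *topology*
(two condyles, one articular surface, an epiphyseal boundary), not an
anatomical shape.

Two density profiles emulate the qualitative contrast seen in athletes
versus untrained controls:

* ``control_like`` — a laminar field: HU decays monotonically with depth
  below the articular surface (densest at the subchondral plate).
* ``judo_like`` — the same laminar background plus concentric Gaussian
  high-density foci centred on configurable anatomical regions of the
  articular surface (default: the central row, regions 4, 5, 6 — the
  ligament-insertion / joint-contact zone).

Additive Gaussian HU noise (truncated at the -1024 air floor) completes the
CT-like model.  The generator returns, alongside the volume, a
:class:`PhantomTruth` whose per-bin voxel counts are obtained by a direct
interval scan of the emitted voxels, serving as the oracle for %BTV
recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .imageio import CTVolume
from .subchondral_roi import CONN26

PROFILES = ("control_like", "judo_like")

#: default concentric foci for the judo-like profile: (region 1-9, peak HU
#: amplitude above the laminar background, Gaussian sigma in mm)
DEFAULT_JUDO_FOCI = ((4, 600.0, 4.0), (5, 600.0, 4.0), (6, 600.0, 4.0))

#: inter-subject jitter constants (log-normal sigmas), see make_cohort
JITTER_SIGMA_AMPLITUDE = 0.15
JITTER_SIGMA_BASELINE = 0.05


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic knee phantom.

    Axes follow the package convention (x medial-lateral, y
    anterior-posterior, z inferior-superior).  The default 0.625 mm
    isotropic spacing matches thin-slice clinical knee CT.
    """

    grid_shape: tuple[int, int, int] = (48, 48, 40)
    spacing_mm: tuple[float, float, float] = (0.625, 0.625, 0.625)
    bone: str = "distal_femur"
    side: str = "right"
    profile: str = "control_like"
    shell_thickness_mm: float = 10.0
    baseline_hu: float = 160.0
    laminar_amplitude_hu: float = 300.0
    laminar_decay_mm: float = 3.0
    foci: tuple[tuple[int, float, float], ...] | None = None
    noise_sd_hu: float = 30.0
    seed: int = 0

    def validate(self) -> None:
        if len(self.grid_shape) != 3 or any(int(s) < 8 for s in self.grid_shape):
            raise ValueError(f"grid_shape must be 3 axes of >= 8 voxels, got {self.grid_shape}")
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing_mm must be positive, got {self.spacing_mm}")
        if self.bone not in ("distal_femur", "tibial_plateau"):
            raise ValueError(f"unknown bone {self.bone!r}")
        if self.side not in ("left", "right"):
            raise ValueError(f"unknown side {self.side!r}")
        if self.profile not in PROFILES:
            raise ValueError(f"profile must be one of {PROFILES}, got {self.profile!r}")
        if self.shell_thickness_mm <= self.spacing_mm[2]:
            raise ValueError(
                "degenerate geometry: shell_thickness_mm "
                f"({self.shell_thickness_mm}) must exceed one voxel of z spacing "
                f"({self.spacing_mm[2]})"
            )
        for focus in self.resolved_foci():
            r, amp, sigma = focus
            if not 1 <= int(r) <= 9:
                raise ValueError(f"focus region_index {r} outside 1..9")
            if amp < 0:
                raise ValueError(f"focus amplitude must be >= 0, got {amp}")
            if sigma <= 0:
                raise ValueError(f"focus sigma must be positive, got {sigma}")
        if self.noise_sd_hu < 0:
            raise ValueError("noise_sd_hu must be >= 0")

    def resolved_foci(self) -> tuple[tuple[int, float, float], ...]:
        """Foci actually applied: the judo-like profile uses the explicit
        list (or the default); the control-like laminar profile has none."""
        if self.profile != "judo_like":
            return ()
        if self.foci is not None:
            return tuple((int(r), float(a), float(s)) for r, a, s in self.foci)
        return DEFAULT_JUDO_FOCI


@dataclass
class PhantomTruth:
    """Ground truth emitted with every phantom."""

    roi_mask: np.ndarray
    per_bin_voxels: np.ndarray  # 12 ints, from a direct interval scan
    epiphyseal_plane_z: int
    foci_regions: frozenset[int]


# ---------------------------------------------------------------------------
# geometry


def _ellipsoid(xg, yg, zg, center, radii) -> np.ndarray:
    cx, cy, cz = center
    rx, ry, rz = radii
    return ((xg - cx) / rx) ** 2 + ((yg - cy) / ry) ** 2 + ((zg - cz) / rz) ** 2 <= 1.0


def _grids(shape):
    nx, ny, nz = shape
    return np.meshgrid(
        np.arange(nx, dtype=float), np.arange(ny, dtype=float), np.arange(nz, dtype=float),
        indexing="ij",
    )


def _femur_geometry(shape):
    """Two condylar ellipsoids + anterior trochlear bridge + shaft."""
    nx, ny, nz = shape
    xg, yg, zg = _grids(shape)
    condyle_l = _ellipsoid(xg, yg, zg, (0.30 * nx, 0.55 * ny, 0.52 * nz), (0.24 * nx, 0.33 * ny, 0.48 * nz))
    condyle_r = _ellipsoid(xg, yg, zg, (0.70 * nx, 0.55 * ny, 0.52 * nz), (0.24 * nx, 0.33 * ny, 0.48 * nz))
    bridge = (
        (xg >= 0.30 * nx) & (xg <= 0.70 * nx)
        & (yg >= 0.18 * ny) & (yg <= 0.45 * ny)
        & (zg >= 0.25 * nz)
    )
    shaft = (
        (xg >= 0.30 * nx) & (xg <= 0.70 * nx)
        & (yg >= 0.30 * ny) & (yg <= 0.70 * ny)
        & (zg >= 0.60 * nz)
    )
    return condyle_l | condyle_r | bridge | shaft


def _tibia_geometry(shape):
    """Two compartment cylinders + central block, flat plateau on top."""
    nx, ny, nz = shape
    xg, yg, zg = _grids(shape)
    top = 0.85 * nz
    in_z = (zg >= 0.05 * nz) & (zg <= top)
    comp_l = (((xg - 0.30 * nx) / (0.26 * nx)) ** 2 + ((yg - 0.52 * ny) / (0.38 * ny)) ** 2) <= 1.0
    comp_r = (((xg - 0.70 * nx) / (0.26 * nx)) ** 2 + ((yg - 0.52 * ny) / (0.38 * ny)) ** 2) <= 1.0
    block = (xg >= 0.35 * nx) & (xg <= 0.65 * nx) & (yg >= 0.40 * ny) & (yg <= 0.70 * ny)
    return (comp_l | comp_r | block) & in_z


def _surface_and_depth(bone: np.ndarray, spec: PhantomSpec):
    """Per-column articular surface index and per-voxel depth (mm)."""
    nz = bone.shape[2]
    footprint = bone.any(axis=2)
    if spec.bone == "distal_femur":
        surf = bone.argmax(axis=2)  # first bone voxel from below
    else:
        surf = nz - 1 - bone[:, :, ::-1].argmax(axis=2)  # last bone voxel
    surf = np.where(footprint, surf, -1)
    z = np.arange(nz)
    dz = spec.spacing_mm[2]
    if spec.bone == "distal_femur":
        depth = (z[None, None, :] - surf[:, :, None]) * dz
    else:
        depth = (surf[:, :, None] - z[None, None, :]) * dz
    return footprint, surf, depth


def _region_centers(footprint: np.ndarray, side: str) -> dict[int, tuple[float, float]]:
    """Centre pixel (x, y) of each of the nine anatomical regions.

    Uses the same equal-thirds bounding-box convention (and the same
    left/right mirroring of the medial column) as the surface-mapping
    partition, so foci seeded "in region r" are recovered in region r.
    """
    xs, ys = np.nonzero(footprint)
    x0, x1 = xs.min(), xs.max()
    y0, y1 = ys.min(), ys.max()
    wx = (x1 - x0 + 1) / 3.0
    wy = (y1 - y0 + 1) / 3.0
    centers = {}
    for region in range(1, 10):
        row = (region - 1) // 3  # 0 = anterior
        col_anat = (region - 1) % 3  # 0 = medial
        col_band = col_anat if side == "right" else 2 - col_anat
        centers[region] = (x0 + (col_band + 0.5) * wx, y0 + (row + 0.5) * wy)
    return centers


# ---------------------------------------------------------------------------
# generation


def make_phantom(spec: PhantomSpec) -> tuple[CTVolume, PhantomTruth]:
    """Generate one phantom volume and its ground truth.

    Deterministic for a fixed spec (the spec's ``seed`` drives all noise).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    nx, ny, nz = (int(s) for s in spec.grid_shape)
    shape = (nx, ny, nz)
    bone = _femur_geometry(shape) if spec.bone == "distal_femur" else _tibia_geometry(shape)
    footprint, surf, depth = _surface_and_depth(bone, spec)

    hu = np.zeros(shape, dtype=float)  # soft-tissue background at 0 HU
    laminar = spec.baseline_hu + spec.laminar_amplitude_hu * np.exp(
        -np.maximum(depth, 0.0) / spec.laminar_decay_mm
    )
    hu[bone] = laminar[bone]

    foci = spec.resolved_foci()
    if foci:
        centers = _region_centers(footprint, spec.side)
        sx, sy, sz = spec.spacing_mm
        xg, yg, zg = _grids(shape)
        for region, amp, sigma in foci:
            cx, cy = centers[region]
            cz_idx = surf[int(round(cx)) % nx, int(round(cy)) % ny]
            if cz_idx < 0:  # column outside footprint: use median surface height
                cz_idx = int(np.median(surf[footprint]))
            d2 = (
                ((xg - cx) * sx) ** 2
                + ((yg - cy) * sy) ** 2
                + ((zg - float(cz_idx)) * sz) ** 2
            )
            hu[bone] += amp * np.exp(-d2[bone] / (2.0 * sigma**2))

    if spec.noise_sd_hu > 0:
        hu += rng.normal(0.0, spec.noise_sd_hu, size=shape)

    vol = CTVolume(data=hu, spacing_mm=spec.spacing_mm)  # rounds + clamps at -1024

    shell_vox = int(round(spec.shell_thickness_mm / spec.spacing_mm[2]))
    if spec.bone == "distal_femur":
        plane_z = int(surf[footprint].min()) + shell_vox
    else:
        plane_z = int(surf[footprint].max()) - shell_vox
    plane_z = int(np.clip(plane_z, 0, nz - 1))

    truth = PhantomTruth(
        roi_mask=_truth_roi(vol.data, plane_z, spec.bone),
        per_bin_voxels=np.zeros(12, dtype=np.int64),
        epiphyseal_plane_z=plane_z,
        foci_regions=frozenset(r for r, _, _ in foci),
    )
    truth.per_bin_voxels = _interval_scan(vol.data[truth.roi_mask])
    return vol, truth


def _truth_roi(hu: np.ndarray, plane_z: int, bone: str) -> np.ndarray:
    """Ground-truth BTOI: bone voxels (>=100 HU) of the main body, on the
    articular side of the epiphyseal plane, largest connected body kept."""
    mask = hu >= 100
    mask = _largest(mask)
    z = np.arange(mask.shape[2])
    keep = z <= plane_z if bone == "distal_femur" else z >= plane_z
    clipped = mask & keep[None, None, :]
    if not clipped.any():
        raise ValueError("degenerate phantom: epiphyseal clipping emptied the bone mask")
    return _largest(clipped)


def _largest(mask: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(mask, structure=CONN26)
    if n == 0:
        raise ValueError("empty mask")
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == int(counts.argmax())


def _interval_scan(values: np.ndarray) -> np.ndarray:
    """Direct per-interval count of HU values (the truth-side oracle).

    Deliberately a plain closed-interval comparison per bin, independent of
    the binning code used by the analysis path.
    """
    edges = [(100, 200)] + [(201 + 100 * i, 300 + 100 * i) for i in range(10)] + [(1201, None)]
    counts = np.zeros(12, dtype=np.int64)
    for i, (lo, hi) in enumerate(edges):
        if hi is None:
            counts[i] = int(np.count_nonzero(values >= lo))
        else:
            counts[i] = int(np.count_nonzero((values >= lo) & (values <= hi)))
    return counts


# ---------------------------------------------------------------------------
# cohorts


def make_cohort(
    n_per_group: int = 15,
    base_spec: PhantomSpec | None = None,
    seed: int = 0,
    profiles: tuple[str, str] = PROFILES,
) -> tuple[list[tuple[CTVolume, PhantomTruth]], list[tuple[CTVolume, PhantomTruth]]]:
    """Generate a control-like and a judo-like cohort (default 15 + 15).

    Per-subject seeds are derived from the master seed through a
    ``SeedSequence`` over (seed, group, subject), so cohorts are reproducible
    and subjects independent.  Inter-subject variability: multiplicative
    log-normal jitter on the laminar amplitude and every focus amplitude
    (sigma 0.15) and on the baseline HU (sigma 0.05).

    ``profiles`` selects the density profile of each group; passing
    ``("control_like", "control_like")`` yields two independent cohorts
    drawn from one distribution (the null configuration used for
    calibration studies).
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    base = base_spec or PhantomSpec()
    groups: list[list[tuple[CTVolume, PhantomTruth]]] = []
    for g, profile in enumerate(profiles):
        cohort = []
        for i in range(n_per_group):
            ss = np.random.SeedSequence([int(seed), g, i])
            phantom_seed = int(ss.generate_state(1)[0] % (2**31))
            jitter = np.random.default_rng(ss.spawn(1)[0])
            lam = base.laminar_amplitude_hu * jitter.lognormal(0.0, JITTER_SIGMA_AMPLITUDE)
            baseline = base.baseline_hu * jitter.lognormal(0.0, JITTER_SIGMA_BASELINE)
            spec = replace(base, profile=profile, seed=phantom_seed,
                           laminar_amplitude_hu=lam, baseline_hu=baseline)
            foci = spec.resolved_foci()
            if foci:
                jittered = tuple(
                    (r, a * jitter.lognormal(0.0, JITTER_SIGMA_AMPLITUDE), s) for r, a, s in foci
                )
                spec = replace(spec, foci=jittered)
            cohort.append(make_phantom(spec))
        groups.append(cohort)
    controls, judos = groups
    return controls, judos


# ---------------------------------------------------------------------------
# persistence


def save_phantom(vol: CTVolume, truth: PhantomTruth, out_dir: str | Path, stem: str) -> dict[str, str]:
    """Write volume + ROI mask as NIfTI and the truth scalars as JSON."""
    from .imageio import write_mask, write_volume

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    vol_path = out_dir / f"{stem}.nii.gz"
    roi_path = out_dir / f"{stem}_roi.nii.gz"
    truth_path = out_dir / f"{stem}_truth.json"
    write_volume(vol, vol_path)
    write_mask(truth.roi_mask, vol.spacing_mm, roi_path)
    truth_path.write_text(
        json.dumps(
            {
                "per_bin_voxels": truth.per_bin_voxels.tolist(),
                "epiphyseal_plane_z": truth.epiphyseal_plane_z,
                "foci_regions": sorted(truth.foci_regions),
                "roi_voxel_count": int(truth.roi_mask.sum()),
            },
            indent=2,
        )
    )
    return {"volume": str(vol_path), "roi": str(roi_path), "truth": str(truth_path)}
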