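"""Volume, mask, map and table I/O.

The in-memory contract for all image-processing code is :class:`CTVolume`:
a 3D signed-16-bit Hounsfield grid laid out ``[x, y, z]`` with

* x — medial–lateral,
* y — anterior–posterior (index 0 is anterior),
* z — inferior–superior.

NIfTI volumes are reoriented to closest-canonical (RAS) at read time so this
convention holds regardless of how the file was stored; DICOM series are
sorted along the patient z axis and rescaled to HU with the stored
slope/intercept.  Writers are deterministic: no timestamps are embedded in
any data file (gzip members are written with ``mtime=0``).
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

log = logging.getLogger("ctoam")

HU_AIR = -1024  # calibrated CT floor; everything below is clamped

AXIS_CONVENTION = ("x: medial-lateral", "y: anterior-posterior", "z: inferior-superior")


@dataclass
class CTVolume:
    """A 3D CT scalar grid in Hounsfield units.

    ``data`` is stored as int16 (CT semantics; makes HU binning exact).
    Float input is rounded to the nearest integer; values below the air
    floor of -1024 HU are clamped to it.
    """

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"CTVolume requires a 3D grid, got {arr.ndim}D")
        if not np.issubdtype(arr.dtype, np.integer):
            arr = np.rint(arr)
        arr = np.clip(arr, HU_AIR, np.iinfo(np.int16).max).astype(np.int16)
        self.data = arr
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing_mm must be 3 positive values, got {self.spacing_mm}")
        self.origin_mm = tuple(float(o) for o in self.origin_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))


# ---------------------------------------------------------------------------
# volume readers


def read_volume(path: str | Path) -> CTVolume:
    """Read a CT volume from a NIfTI file or a directory holding one DICOM series.

    HU values pass through unmodified apart from the int16/air-floor
    normalisation (DICOM stored values are first rescaled with the series
    slope and intercept).  Axes are reoriented to the package convention and
    the applied permutation is logged.
    """
    path = Path(path)
    if path.is_dir():
        return _read_dicom_series(path)
    if path.suffix in {".nii", ".gz"} or path.name.endswith(".nii.gz"):
        return _read_nifti(path)
    raise ValueError(f"unrecognised volume input: {path} (expected .nii/.nii.gz or a DICOM directory)")


def _read_nifti(path: Path) -> CTVolume:
    img = nib.load(str(path))
    if len(img.shape) != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {img.shape}")
    orig_codes = nib.aff2axcodes(img.affine)
    canon = nib.as_closest_canonical(img)
    if orig_codes != ("R", "A", "S"):
        log.info("reoriented %s from %s to RAS", path.name, "".join(orig_codes))
    zooms = canon.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise ValueError(f"{path}: missing or non-positive voxel spacing {zooms}")
    data = np.asanyarray(canon.dataobj)
    origin = tuple(float(v) for v in canon.affine[:3, 3])
    return CTVolume(data=data, spacing_mm=tuple(float(z) for z in zooms), origin_mm=origin)


def _read_dicom_series(path: Path) -> CTVolume:
    import pydicom

    files = sorted(p for p in path.iterdir() if p.is_file())
    datasets = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue
        if hasattr(ds, "PixelData"):
            datasets.append(ds)
    if len(datasets) < 2:
        raise ValueError(f"{path}: need a DICOM series of >=2 slices, found {len(datasets)}")

    uids = {ds.SeriesInstanceUID for ds in datasets}
    if len(uids) != 1:
        raise ValueError(f"{path}: mixed DICOM series in one directory ({len(uids)} series UIDs)")

    def z_of(ds):
        if hasattr(ds, "ImagePositionPatient"):
            return float(ds.ImagePositionPatient[2])
        return float(ds.InstanceNumber)

    datasets.sort(key=z_of)
    first = datasets[0]
    if not hasattr(first, "PixelSpacing"):
        raise ValueError(f"{path}: DICOM series has no PixelSpacing")
    row_mm, col_mm = (float(v) for v in first.PixelSpacing)

    zs = np.array([z_of(ds) for ds in datasets])
    dz = np.diff(zs)
    if np.any(dz <= 0) or not np.allclose(dz, dz[0], atol=1e-3):
        raise ValueError(f"{path}: slice positions are not uniformly increasing")
    z_mm = float(dz[0])

    slices = []
    for ds in datasets:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(ds.pixel_array.astype(np.float64) * slope + intercept)
    vol_zrc = np.stack(slices, axis=0)  # [z, row, col]
    # rows run anterior->posterior (y), columns left->right (x)
    data = np.transpose(vol_zrc, (2, 1, 0))  # -> [x, y, z]
    log.info("DICOM axes permuted (z,row,col) -> (x,y,z) for %s", path.name)
    origin = tuple(float(v) for v in getattr(first, "ImagePositionPatient", (0.0, 0.0, 0.0)))
    return CTVolume(data=data, spacing_mm=(col_mm, row_mm, z_mm), origin_mm=origin)


# ---------------------------------------------------------------------------
# volume / mask writers


def _affine(vol_spacing: tuple[float, float, float], origin: tuple[float, float, float]) -> np.ndarray:
    aff = np.diag(list(vol_spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def _write_nifti_bytes(img: nib.Nifti1Image, path: Path) -> None:
    raw = img.to_bytes()
    if path.name.endswith(".nii.gz"):
        # fixed mtime and no embedded filename keep output byte-identical
        with open(path, "wb") as fh:
            with gzip.GzipFile(filename="", fileobj=fh, mode="wb", mtime=0) as gz:
                gz.write(raw)
    else:
        path.write_bytes(raw)


def write_volume(vol: CTVolume, path: str | Path) -> Path:
    """Write a volume as NIfTI-1 (int16, spacing in the header)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(vol.data.astype(np.int16), _affine(vol.spacing_mm, vol.origin_mm))
    img.header.set_zooms(vol.spacing_mm)
    _write_nifti_bytes(img, path)
    return path


def write_mask(mask: np.ndarray, spacing_mm: tuple[float, float, float], path: str | Path) -> Path:
    """Write a binary voxel mask as NIfTI-1 (uint8)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), _affine(spacing_mm, (0.0, 0.0, 0.0)))
    img.header.set_zooms(spacing_mm)
    _write_nifti_bytes(img, path)
    return path


def read_mask(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    return data.astype(bool), tuple(float(z) for z in img.header.get_zooms()[:3])


# ---------------------------------------------------------------------------
# table and map writers


def write_btv_profile(profile, path: str | Path) -> Path:
    """Write a 12-row %BTV profile as CSV (one row per HU interval)."""
    from .densitometry import DensityScheme

    scheme = DensityScheme.default()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        {
            "bin": np.arange(1, 13),
            "hu_range": scheme.labels,
            "density_class": scheme.class_of_bin,
            "volume_mm3": np.asarray(profile.volumes_mm3, dtype=float),
            "pct_btv": np.asarray(profile.pct, dtype=float),
        }
    )
    df.to_csv(path, index=False)
    return path


def read_btv_profile(path: str | Path):
    """Read back a profile CSV written by :func:`write_btv_profile`."""
    from .densitometry import BTVProfile

    df = pd.read_csv(path)
    volumes = df["volume_mm3"].to_numpy(dtype=float)
    return BTVProfile(volumes_mm3=volumes, bone="unknown", side="unknown")


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a frequency/pattern/comparison table as CSV (header always present)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def write_density_map(dmap, png_path: str | Path | None = None, csv_path: str | Path | None = None) -> list[Path]:
    """Write a projected density map as a pseudo-colour PNG and/or lossless CSV.

    The CSV holds the raw projected HU values (empty cells outside the
    articular footprint) so a map round-trips exactly; the PNG is the
    pseudo-colour rendering with the 12-interval colour scale.
    """
    from .densitometry import DensityScheme

    written: list[Path] = []
    if csv_path is not None:
        csv_path = Path(csv_path)
        csv_path.parent.mkdir(parents=True, exist_ok=True)
        values = np.where(dmap.footprint, dmap.values, np.nan)
        pd.DataFrame(values).to_csv(csv_path, index=False)
        written.append(csv_path)
    if png_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        from matplotlib import pyplot as plt
        from matplotlib.colors import BoundaryNorm, ListedColormap

        scheme = DensityScheme.default()
        cmap = ListedColormap(scheme.colors)
        cmap.set_bad("black")
        bounds = [lo for lo, _ in scheme.edges] + [1600]
        norm = BoundaryNorm(bounds, cmap.N)
        img = np.ma.masked_invalid(np.where(dmap.footprint, dmap.values, np.nan))
        png_path = Path(png_path)
        png_path.parent.mkdir(parents=True, exist_ok=True)
        # transpose so x (medial-lateral) runs horizontally
        rgba = cmap(norm(img.T))
        plt.imsave(png_path, rgba, origin="lower")
        written.append(png_path)
    return written


def read_density_map_values(csv_path: str | Path) -> np.ndarray:
    """Read back the value grid written by :func:`write_density_map` (NaN outside)."""
    return pd.read_csv(csv_path).to_numpy(dtype=float)
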