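"""Readers, writers, and figure export.

Accepted inputs: a DICOM series directory (geometry from ImagePositionPatient,
PixelSpacing and the slice positions; CT values rescaled by slope/intercept),
a NIfTI file, or an NPZ archive written by :func:`write_npz`.  Grids are
returned indexed (x, y, z) with ascending-z slice order.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .errors import (
    MixedSeries,
    NonUniformSpacing,
    UnsupportedFormat,
)
from .grid_model import ImageGrid3D
from .pipeline import VolumetryReport

logger = logging.getLogger(__name__)


@dataclass
class SeriesGeometry:
    """Geometry of an image series as read from its source."""

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    shape: tuple[int, int, int]
    modality: str
    rescale_slope: float = 1.0
    rescale_intercept: float = 0.0


def _infer_modality(hint: Optional[str], path: Path, default: str = "SPECT") -> str:
    if hint:
        return hint.upper()
    name = path.name.lower()
    if "ct" in name:
        return "CT"
    if "spect" in name or "nm" in name:
        return "SPECT"
    return default


def _read_dicom_dir(path: Path, modality: Optional[str]) -> tuple[ImageGrid3D, SeriesGeometry]:
    import pydicom

    datasets = []
    for f in sorted(path.iterdir()):
        if not f.is_file():
            continue
        try:
            datasets.append(pydicom.dcmread(f))
        except Exception:  # not a DICOM file; skip quietly
            continue
    if not datasets:
        raise UnsupportedFormat(f"no readable DICOM files in {path}")
    uids = {getattr(ds, "SeriesInstanceUID", None) for ds in datasets}
    if len(uids) > 1:
        raise MixedSeries(f"{path} mixes {len(uids)} series")
    datasets.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
    z = np.array([float(ds.ImagePositionPatient[2]) for ds in datasets])
    if len(z) > 1:
        dz_all = np.diff(z)
        dz = float(np.mean(dz_all))
        if dz <= 0 or np.any(np.abs(dz_all - dz) > 0.01 * abs(dz)):
            raise NonUniformSpacing(f"slice spacing varies: {dz_all}")
    else:
        dz = float(getattr(datasets[0], "SliceThickness", 1.0))
    first = datasets[0]
    row_sp, col_sp = (float(v) for v in first.PixelSpacing)  # (dy, dx)
    slope = float(getattr(first, "RescaleSlope", 1.0))
    intercept = float(getattr(first, "RescaleIntercept", 0.0))
    slices = [ds.pixel_array.astype(float) * slope + intercept for ds in datasets]
    vol = np.stack(slices, axis=-1)  # (rows=y, cols=x, z)
    values = np.transpose(vol, (1, 0, 2))  # -> (x, y, z)
    mod = _infer_modality(modality, path, default=getattr(first, "Modality", "SPECT"))
    if mod == "NM":
        mod = "SPECT"
    origin = (
        float(first.ImagePositionPatient[0]),
        float(first.ImagePositionPatient[1]),
        float(z[0]),
    )
    spacing = (col_sp, row_sp, abs(dz))
    grid = ImageGrid3D(values, spacing, origin, mod)
    geom = SeriesGeometry(origin, spacing, grid.shape, mod, slope, intercept)
    return grid, geom


def _read_nifti(path: Path, modality: Optional[str]) -> tuple[ImageGrid3D, SeriesGeometry]:
    import nibabel as nib

    img = nib.load(str(path))
    values = np.asarray(img.get_fdata(), dtype=float)
    if values.ndim != 3:
        raise UnsupportedFormat(f"{path} is not a 3D volume")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in img.affine[:3, 3])
    mod = _infer_modality(modality, path)
    grid = ImageGrid3D(values, zooms, origin, mod)
    return grid, SeriesGeometry(origin, zooms, grid.shape, mod)


def _read_npz(path: Path, modality: Optional[str]) -> tuple[ImageGrid3D, SeriesGeometry]:
    with np.load(path, allow_pickle=False) as npz:
        for key in ("values", "spacing", "origin"):
            if key not in npz:
                raise UnsupportedFormat(f"{path} lacks array {key!r}")
        values = npz["values"]
        spacing = tuple(float(s) for s in npz["spacing"])
        origin = tuple(float(o) for o in npz["origin"])
        mod = str(npz["modality"]) if "modality" in npz else None
    mod = modality.upper() if modality else (mod or _infer_modality(None, path))
    grid = ImageGrid3D(values, spacing, origin, mod)
    return grid, SeriesGeometry(origin, spacing, grid.shape, mod)


def read_series(path, modality: Optional[str] = None) -> tuple[ImageGrid3D, SeriesGeometry]:
    """Read a DICOM series directory, NIfTI file, or NPZ archive.

    Raises
    ------
    MixedSeries, NonUniformSpacing, UnsupportedFormat
    """
    path = Path(path)
    if path.is_dir():
        return _read_dicom_dir(path, modality)
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith((".nii", ".nii.gz")):
        return _read_nifti(path, modality)
    if suffixes.endswith(".npz"):
        return _read_npz(path, modality)
    raise UnsupportedFormat(f"cannot read {path}")


def write_npz(grid: ImageGrid3D, path) -> None:
    """Write a grid as an NPZ archive (round-trips bit-exactly)."""
    np.savez_compressed(
        path,
        values=grid.values,
        spacing=np.asarray(grid.spacing),
        origin=np.asarray(grid.origin),
        modality=np.str_(grid.modality),
    )


def write_report(report: VolumetryReport, path) -> None:
    """Serialize a volumetry report to JSON (stable keys, 3-decimal mL)."""
    path = Path(path)
    path.write_text(json.dumps(report.to_dict(), indent=2) + "\n")


def read_report(path) -> dict:
    return json.loads(Path(path).read_text())


def write_mask(labels: np.ndarray, grid: ImageGrid3D, path) -> None:
    """Write a labeled mask as NIfTI using the grid's geometry."""
    import nibabel as nib

    affine = np.diag([*grid.spacing, 1.0])
    affine[:3, 3] = grid.origin
    nib.save(nib.Nifti1Image(np.asarray(labels, dtype=np.int16), affine), str(path))


def save_overlay_png(
    pair,
    spect_mask: np.ndarray,
    ct_mask: np.ndarray,
    z: int,
    path,
    roi=None,
) -> None:
    """Fused middle slice with V_SPECT and V_SPECT-CT contours."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(pair.ct.values[:, :, z].T, cmap="gray", origin="lower")
    ax.imshow(pair.spect.values[:, :, z].T, cmap="hot", alpha=0.4, origin="lower")
    ax.contour(spect_mask[:, :, z].T.astype(float), levels=[0.5], colors="deepskyblue")
    if ct_mask[:, :, z].any():
        ax.contour(ct_mask[:, :, z].T.astype(float), levels=[0.5], colors="magenta")
    if roi is not None:
        poly = np.vstack([roi.polygon, roi.polygon[:1]])
        ax.plot(poly[:, 0], poly[:, 1], "r--", lw=1)
    ax.set_title(f"slice {z}: V_SPECT (blue) / V_SPECT-CT (magenta)")
    ax.set_axis_off()
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
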