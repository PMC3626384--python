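"""Image-stack containers and medical-format I/O.

The pipeline operates on ordered stacks of coronal 2-D slices with a shared
voxel geometry.  Conventions, used everywhere in the package:

* 0-based ``(row, col)`` pixel indices, row 0 at the top (superior) edge of
  the image;
* slices indexed 0-based, anterior to posterior;
* voxel volume = ``in_plane_mm**2 * (slice_thickness_mm + slice_gap_mm)``.

Default geometry matches the acquisition the pipeline was designed for:
1.8 mm in-plane resolution, 13 mm slice thickness, 0 mm gap.  (One source
section quotes 13.13 mm effective thickness; 13.0 mm is the default and the
discrepancy is documented rather than resolved — override via the geometry
arguments if needed.)
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Literal, Sequence

import numpy as np

DEFAULT_IN_PLANE_MM = 1.8
DEFAULT_SLICE_THICKNESS_MM = 13.0
DEFAULT_SLICE_GAP_MM = 0.0


class GeometryError(ValueError):
    """Raised when slice dimensions or voxel geometry are inconsistent."""


@dataclass(frozen=True)
class ImageStack:
    """Ordered coronal grayscale slices plus voxel geometry.

    Parameters
    ----------
    slices : ndarray, shape (n_slices, n_rows, n_cols)
        Nonnegative, finite intensities.  Row 0 is the image top; slice 0 is
        the most anterior.
    in_plane_mm, slice_thickness_mm, slice_gap_mm : float
        Pixel edge length, slice depth and inter-slice gap in millimetres.
    """

    slices: np.ndarray
    in_plane_mm: float = DEFAULT_IN_PLANE_MM
    slice_thickness_mm: float = DEFAULT_SLICE_THICKNESS_MM
    slice_gap_mm: float = DEFAULT_SLICE_GAP_MM

    def __post_init__(self) -> None:
        arr = np.asarray(self.slices, dtype=float)
        if arr.ndim == 2:
            arr = arr[np.newaxis]
        if arr.ndim != 3:
            raise GeometryError(f"expected 2-D or 3-D array, got ndim={arr.ndim}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("intensities must be finite (no NaN/inf voxels)")
        if np.any(arr < 0):
            raise ValueError("intensities must be >= 0")
        if self.in_plane_mm <= 0 or self.slice_thickness_mm <= 0:
            raise GeometryError("in_plane_mm and slice_thickness_mm must be > 0")
        if self.slice_gap_mm < 0:
            raise GeometryError("slice_gap_mm must be >= 0")
        object.__setattr__(self, "slices", arr)

    @property
    def n_slices(self) -> int:
        return self.slices.shape[0]

    @property
    def n_rows(self) -> int:
        return self.slices.shape[1]

    @property
    def n_cols(self) -> int:
        return self.slices.shape[2]

    @property
    def voxel_volume_mm3(self) -> float:
        return self.in_plane_mm**2 * (self.slice_thickness_mm + self.slice_gap_mm)

    def __iter__(self) -> Iterator[np.ndarray]:
        return iter(self.slices)

    def with_slices(self, slices: np.ndarray) -> "ImageStack":
        return replace(self, slices=slices)


@dataclass(frozen=True)
class MaskStack:
    """Per-slice binary masks sharing :class:`ImageStack` geometry.

    Values are strictly {0, 1} (stored as uint8).
    """

    slices: np.ndarray
    in_plane_mm: float = DEFAULT_IN_PLANE_MM
    slice_thickness_mm: float = DEFAULT_SLICE_THICKNESS_MM
    slice_gap_mm: float = DEFAULT_SLICE_GAP_MM

    def __post_init__(self) -> None:
        arr = np.asarray(self.slices)
        if arr.ndim == 2:
            arr = arr[np.newaxis]
        if arr.ndim != 3:
            raise GeometryError(f"expected 2-D or 3-D array, got ndim={arr.ndim}")
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("mask values must be strictly 0 or 1")
        if self.in_plane_mm <= 0 or self.slice_thickness_mm <= 0:
            raise GeometryError("in_plane_mm and slice_thickness_mm must be > 0")
        if self.slice_gap_mm < 0:
            raise GeometryError("slice_gap_mm must be >= 0")
        object.__setattr__(self, "slices", arr.astype(np.uint8))

    n_slices = ImageStack.n_slices
    n_rows = ImageStack.n_rows
    n_cols = ImageStack.n_cols
    voxel_volume_mm3 = ImageStack.voxel_volume_mm3

    def __iter__(self) -> Iterator[np.ndarray]:
        return iter(self.slices)

    def with_slices(self, slices: np.ndarray) -> "MaskStack":
        return replace(self, slices=slices)

    def pixel_count(self) -> int:
        return int(self.slices.sum())

    @classmethod
    def like(cls, stack: "ImageStack | MaskStack", slices: np.ndarray) -> "MaskStack":
        """Binary mask inheriting ``stack``'s geometry."""
        return cls(
            slices=slices,
            in_plane_mm=stack.in_plane_mm,
            slice_thickness_mm=stack.slice_thickness_mm,
            slice_gap_mm=stack.slice_gap_mm,
        )


def same_geometry(a: ImageStack | MaskStack, b: ImageStack | MaskStack) -> bool:
    return (
        a.slices.shape == b.slices.shape
        and a.in_plane_mm == b.in_plane_mm
        and a.slice_thickness_mm == b.slice_thickness_mm
        and a.slice_gap_mm == b.slice_gap_mm
    )


# --------------------------------------------------------------------------
# Readers / writers
# --------------------------------------------------------------------------

def _nifti_affine(in_plane_mm: float, depth_mm: float) -> np.ndarray:
    aff = np.diag([in_plane_mm, in_plane_mm, depth_mm, 1.0])
    return aff


def read_stack(
    path: str | os.PathLike,
    format: Literal["nifti", "dicom-dir", "raw-array"] = "nifti",
    *,
    in_plane_mm: float | None = None,
    slice_thickness_mm: float | None = None,
    slice_gap_mm: float = DEFAULT_SLICE_GAP_MM,
) -> ImageStack:
    """Read an image stack from disk (or wrap a raw array).

    ``nifti`` expects a .nii/.nii.gz volume stored (col, row, slice); voxel
    geometry is taken from the header zooms unless overridden.  ``dicom-dir``
    ingests every DICOM file in a directory, ordered by ImagePositionPatient
    when present, else InstanceNumber, ties broken by filename.
    ``raw-array`` accepts an in-memory 2-D or 3-D numpy array.
    """
    if format == "raw-array":
        return ImageStack(
            slices=np.asarray(path, dtype=float),
            in_plane_mm=in_plane_mm or DEFAULT_IN_PLANE_MM,
            slice_thickness_mm=slice_thickness_mm or DEFAULT_SLICE_THICKNESS_MM,
            slice_gap_mm=slice_gap_mm,
        )

    p = Path(path)
    if not p.exists():
        raise IOError(f"no such file or directory: {p}")

    if format == "nifti":
        import nibabel as nib

        img = nib.load(str(p))
        data = np.asanyarray(img.dataobj, dtype=float)
        if data.ndim == 2:
            data = data[..., np.newaxis]
        if data.ndim != 3:
            raise GeometryError(f"{p}: expected a 2-D or 3-D NIfTI, got ndim={data.ndim}")
        # header zooms are float32; round off the representation error
        zooms = [round(float(z), 6) for z in img.header.get_zooms()[:3]]
        # stored (col, row, slice) -> (slice, row, col)
        slices = np.transpose(data, (2, 1, 0))
        return ImageStack(
            slices=slices,
            in_plane_mm=in_plane_mm or float(zooms[0]),
            slice_thickness_mm=slice_thickness_mm or float(zooms[2]),
            slice_gap_mm=slice_gap_mm,
        )

    if format == "dicom-dir":
        return _read_dicom_dir(p, in_plane_mm, slice_thickness_mm, slice_gap_mm)

    raise ValueError(f"unknown format: {format!r}")


def _read_dicom_dir(
    p: Path,
    in_plane_mm: float | None,
    slice_thickness_mm: float | None,
    slice_gap_mm: float,
) -> ImageStack:
    import pydicom

    if not p.is_dir():
        raise IOError(f"not a directory: {p}")
    entries = []
    for f in sorted(p.iterdir()):
        if not f.is_file():
            continue
        try:
            ds = pydicom.dcmread(str(f))
        except Exception as exc:  # unreadable file in the directory
            raise IOError(f"failed to read DICOM file {f}: {exc}") from exc
        pos = getattr(ds, "ImagePositionPatient", None)
        # anterior->posterior ordering: position along the normal when present
        sort_key = (
            0 if pos is not None else 1,
            float(pos[1]) if pos is not None else float(getattr(ds, "InstanceNumber", 0)),
            f.name,
        )
        entries.append((sort_key, f, ds))
    if not entries:
        raise IOError(f"no DICOM files found in {p}")
    entries.sort(key=lambda e: e[0])
    arrays = [e[2].pixel_array.astype(float) for e in entries]
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise GeometryError(f"inconsistent slice dimensions in series: {sorted(shapes)}")
    ds0 = entries[0][2]
    spacing = getattr(ds0, "PixelSpacing", None)
    thickness = getattr(ds0, "SliceThickness", None)
    return ImageStack(
        slices=np.stack(arrays),
        in_plane_mm=in_plane_mm or (float(spacing[0]) if spacing else DEFAULT_IN_PLANE_MM),
        slice_thickness_mm=slice_thickness_mm
        or (float(thickness) if thickness else DEFAULT_SLICE_THICKNESS_MM),
        slice_gap_mm=slice_gap_mm,
    )


def write_stack(stack: ImageStack, path: str | os.PathLike) -> None:
    """Write an image stack as NIfTI-1 (lossless within float64)."""
    import nibabel as nib

    data = np.transpose(stack.slices, (2, 1, 0))
    aff = _nifti_affine(stack.in_plane_mm, stack.slice_thickness_mm + stack.slice_gap_mm)
    nib.save(nib.Nifti1Image(data.astype(np.float64), aff), str(path))


def write_mask(
    mask: MaskStack,
    path: str | os.PathLike,
    format: Literal["nifti", "png-per-slice"] = "nifti",
) -> None:
    """Write a binary mask; NIfTI round-trips bit-exactly via read_mask."""
    if format == "nifti":
        import nibabel as nib

        data = np.transpose(mask.slices, (2, 1, 0)).astype(np.uint8)
        aff = _nifti_affine(mask.in_plane_mm, mask.slice_thickness_mm + mask.slice_gap_mm)
        nib.save(nib.Nifti1Image(data, aff), str(path))
        return
    if format == "png-per-slice":
        import imageio.v3 as iio

        outdir = Path(path)
        outdir.mkdir(parents=True, exist_ok=True)
        for i, sl in enumerate(mask.slices):
            iio.imwrite(outdir / f"slice_{i:03d}.png", (sl * 255).astype(np.uint8))
        return
    raise ValueError(f"unknown format: {format!r}")


def read_mask(
    path: str | os.PathLike,
    *,
    in_plane_mm: float | None = None,
    slice_thickness_mm: float | None = None,
    slice_gap_mm: float = DEFAULT_SLICE_GAP_MM,
) -> MaskStack:
    """Read a NIfTI binary mask written by :func:`write_mask`."""
    stack = read_stack(
        path,
        "nifti",
        in_plane_mm=in_plane_mm,
        slice_thickness_mm=slice_thickness_mm,
        slice_gap_mm=slice_gap_mm,
    )
    return MaskStack.like(stack, stack.slices.astype(np.uint8))
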