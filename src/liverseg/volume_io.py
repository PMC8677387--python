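"""Volume, mask, and landmark I/O.

All grids in this package are axis-aligned 3D scalar arrays indexed
``data[x, y, z]`` with 0-based voxel indices.  Physical coordinates are
``origin + index * spacing`` in millimetres; direction cosines are not
supported.  Volumes and masks are read and written as NIfTI
(``.nii``/``.nii.gz``) or MetaImage (``.mhd``/``.mha``) via SimpleITK.
Landmarks are plain CSV with six numeric columns
``mx,my,mz,fx,fy,fz`` (moving point, fixed point, both in mm).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import SimpleITK as sitk

__all__ = [
    "Volume",
    "Mask",
    "LandmarkSet",
    "read_volume",
    "read_mask",
    "write_volume",
    "read_landmarks",
    "write_landmarks",
]

_VOLUME_SUFFIXES = (".nii", ".nii.gz", ".mhd", ".mha")


@dataclass
class Volume:
    """A 3D scalar grid with physical geometry.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Scalar intensities (Hounsfield-like arbitrary units).
    spacing : tuple of float
        Voxel size ``(sx, sy, sz)`` in mm; all components > 0.
    origin : tuple of float
        Physical position of voxel (0, 0, 0) in mm.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValueError(f"degenerate shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 or not np.isfinite(s) for s in self.spacing):
            raise ValueError(f"spacing must be three positive finite numbers, got {self.spacing}")
        if np.issubdtype(self.data.dtype, np.floating) and not np.isfinite(self.data).all():
            raise ValueError("volume data contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def voxel_to_physical(self, index: np.ndarray) -> np.ndarray:
        """Map (continuous) voxel indices to mm: origin + index * spacing."""
        return np.asarray(self.origin) + np.asarray(index, dtype=float) * np.asarray(self.spacing)

    def physical_to_voxel(self, point: np.ndarray) -> np.ndarray:
        """Inverse of :meth:`voxel_to_physical` (continuous indices)."""
        return (np.asarray(point, dtype=float) - np.asarray(self.origin)) / np.asarray(self.spacing)

    def same_grid(self, other: "Volume") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )


@dataclass
class Mask(Volume):
    """A binary grid aligned to a :class:`Volume`; values are exactly {0, 1}."""

    def __post_init__(self) -> None:
        super().__post_init__()
        values = np.unique(self.data)
        if not np.isin(values, (0, 1)).all():
            raise ValueError(f"mask values must be in {{0, 1}}, got {values[:10]}")
        self.data = self.data.astype(np.uint8)

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())


@dataclass
class LandmarkSet:
    """Paired (moving, fixed) anatomical points in physical mm.

    ``moving`` points live in the training image, ``fixed`` points in the
    target image.  At least 4 non-duplicate pairs are required so that a
    spline deformation is solvable.
    """

    moving: np.ndarray  # (count, 3) mm
    fixed: np.ndarray  # (count, 3) mm

    def __post_init__(self) -> None:
        self.moving = np.atleast_2d(np.asarray(self.moving, dtype=float))
        self.fixed = np.atleast_2d(np.asarray(self.fixed, dtype=float))
        if self.moving.shape != self.fixed.shape or self.moving.shape[1] != 3:
            raise ValueError("moving/fixed must both be (count, 3) arrays")
        if not (np.isfinite(self.moving).all() and np.isfinite(self.fixed).all()):
            raise ValueError("landmarks contain non-finite coordinates")
        if self.count < 4:
            raise ValueError(f"need at least 4 landmark pairs, got {self.count}")
        if len(np.unique(self.moving.round(9), axis=0)) != self.count:
            raise ValueError("duplicate moving points in landmark set")

    @property
    def count(self) -> int:
        return self.moving.shape[0]

    @property
    def pairs(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return [(m, f) for m, f in zip(self.moving, self.fixed)]


def _check_suffix(path: Path) -> None:
    name = path.name.lower()
    if not any(name.endswith(s) for s in _VOLUME_SUFFIXES):
        raise ValueError(f"unsupported volume format for {path}; expected one of {_VOLUME_SUFFIXES}")


def read_volume(path: str | Path) -> Volume:
    """Read a NIfTI or MetaImage file into a :class:`Volume`.

    The array is returned in (x, y, z) index order; spacing and origin come
    from the header.  Files carrying NaN voxels or non-positive spacing are
    rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume file: {path}")
    _check_suffix(path)
    try:
        image = sitk.ReadImage(str(path))
    except Exception as exc:  # noqa: BLE001 - normalize ITK errors
        raise ValueError(f"unreadable volume file {path}: {exc}") from exc
    if image.GetDimension() != 3:
        raise ValueError(f"{path}: expected a 3D image, got {image.GetDimension()}D")
    # SimpleITK arrays arrive as (z, y, x); transpose to (x, y, z).
    data = sitk.GetArrayFromImage(image).transpose(2, 1, 0)
    spacing = image.GetSpacing()
    if any((not np.isfinite(s)) or s <= 0 for s in spacing):
        raise ValueError(f"{path}: header spacing {spacing} is missing or invalid")
    return Volume(data=data, spacing=spacing, origin=image.GetOrigin())


def read_mask(path: str | Path) -> Mask:
    """Read a binary mask; any non-{0,1} voxel is an error."""
    v = read_volume(path)
    return Mask(data=v.data, spacing=v.spacing, origin=v.origin)


def write_volume(volume: Volume, path: str | Path) -> None:
    """Write a Volume or Mask; integer data round-trips bit-identically."""
    path = Path(path)
    _check_suffix(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    data = volume.data
    if isinstance(volume, Mask):
        data = data.astype(np.uint8)
    elif np.issubdtype(data.dtype, np.floating):
        data = data.astype(np.float32)
    image = sitk.GetImageFromArray(np.ascontiguousarray(data.transpose(2, 1, 0)))
    image.SetSpacing(volume.spacing)
    image.SetOrigin(volume.origin)
    try:
        sitk.WriteImage(image, str(path))
    except Exception as exc:  # noqa: BLE001
        raise OSError(f"failed to write volume to {path}: {exc}") from exc


def read_landmarks(path: str | Path) -> LandmarkSet:
    """Read paired landmarks from CSV (``mx,my,mz,fx,fy,fz`` per row, mm).

    A single non-numeric header row is tolerated; any other non-numeric
    field is an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such landmark file: {path}")
    rows: list[list[float]] = []
    with open(path, newline="") as fh:
        for i, row in enumerate(csv.reader(fh)):
            row = [c for c in row if c.strip() != ""]
            if not row:
                continue
            try:
                values = [float(c) for c in row]
            except ValueError as exc:
                if i == 0:  # tolerated header line
                    continue
                raise ValueError(f"{path}: non-numeric field on row {i + 1}") from exc
            if len(values) != 6:
                raise ValueError(f"{path}: row {i + 1} has {len(values)} columns, expected 6")
            rows.append(values)
    if len(rows) < 4:
        raise ValueError(f"{path}: {len(rows)} landmark rows, need at least 4")
    arr = np.asarray(rows, dtype=float)
    return LandmarkSet(moving=arr[:, :3], fixed=arr[:, 3:])


def write_landmarks(landmarks: LandmarkSet, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["mx", "my", "mz", "fx", "fy", "fz"])
        for m, f in landmarks.pairs:
            writer.writerow([*(f"{c:.9g}" for c in m), *(f"{c:.9g}" for c in f)])
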