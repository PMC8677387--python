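"""Landmark-driven B-spline registration and prior-boundary extraction.

The deformation between the training image and the target image is built
from a small set of manually (or synthetically) matched point pairs: an
affine transform is fitted to the pairs by least squares, and the residual
displacements are interpolated by a tensor-product cubic B-spline defined
on a uniform control grid.  The resulting field uses the pull-back
(resampling) convention: the displacement stored at a target-grid point
``x`` points into the moving (training) image, i.e. the warped image is
``I_warped(x) = I_moving(x + d(x))``.

Applying the field to the training gold-standard mask yields the prior
liver mask in target space; its 6-neighbour surface voxels form the
initial (prior) liver boundary that seeds patch-based boundary detection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk
from scipy import ndimage
from scipy.interpolate import BSpline

from .volume_io import LandmarkSet, Mask, Volume

__all__ = [
    "DeformationField",
    "BoundaryPointSet",
    "fit_landmark_deformation",
    "apply_deformation",
    "extract_surface_points",
    "write_deformation",
    "read_deformation",
]

_SPLINE_DEGREE = 3


@dataclass
class DeformationField:
    """Dense displacement field on a target grid.

    ``displacement[i, j, k]`` is a 3-vector in mm mapping the target-grid
    point at voxel index (i, j, k) into the moving image (pull-back
    convention).
    """

    displacement: np.ndarray  # (nx, ny, nz, 3) mm
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    control_spacing: float = 0.0

    def __post_init__(self) -> None:
        self.displacement = np.asarray(self.displacement, dtype=float)
        if self.displacement.ndim != 4 or self.displacement.shape[3] != 3:
            raise ValueError("displacement must have shape (nx, ny, nz, 3)")
        if not np.isfinite(self.displacement).all():
            raise ValueError("displacement field contains non-finite values")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.displacement.shape[:3]  # type: ignore[return-value]


@dataclass
class BoundaryPointSet:
    """Integer voxel coordinates of a digital surface on the target grid."""

    points: np.ndarray  # (N, 3) int
    source: str = "prior"  # {"prior", "predicted"}

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=np.int64))
        if self.points.size and self.points.shape[1] != 3:
            raise ValueError("points must be an (N, 3) array")
        if len(np.unique(self.points, axis=0)) != len(self.points):
            raise ValueError("duplicate boundary points")

    def __len__(self) -> int:
        return self.points.shape[0]


def _axis_basis(x: np.ndarray, extent: float, control_spacing: float) -> np.ndarray:
    """Dense cubic B-spline design matrix for 1D coordinates in [0, extent]."""
    h = float(control_spacing)
    n_ctrl = int(np.ceil(max(extent, h) / h)) + _SPLINE_DEGREE
    knots = (np.arange(n_ctrl + _SPLINE_DEGREE + 1) - _SPLINE_DEGREE) * h
    # valid evaluation range is [knots[3], knots[n_ctrl]] ⊇ [0, extent]
    dm = BSpline.design_matrix(np.clip(x, 0.0, extent), knots, _SPLINE_DEGREE)
    return np.asarray(dm.todense())


def _tensor_basis(points: np.ndarray, extents: np.ndarray, h: float) -> np.ndarray:
    """Row-wise Kronecker basis for scattered 3D points, (L, ncx*ncy*ncz)."""
    bx = _axis_basis(points[:, 0], extents[0], h)
    by = _axis_basis(points[:, 1], extents[1], h)
    bz = _axis_basis(points[:, 2], extents[2], h)
    return np.einsum("la,lb,lc->labc", bx, by, bz).reshape(len(points), -1)


def fit_landmark_deformation(
    landmarks: LandmarkSet,
    target_grid: Volume,
    control_spacing: float = 32.0,
    regularization_weight: float = 0.0,
) -> DeformationField:
    """Fit a smooth deformation field from paired landmarks.

    The displacement ``d = moving − fixed`` is modelled at each fixed
    (target-space) landmark as an affine part plus a cubic B-spline
    correction on a uniform control grid with spacing ``control_spacing``
    mm.  With ``regularization_weight = 0`` the spline interpolates the
    landmark residuals exactly (minimum-norm least squares); a positive
    weight ridge-penalizes the spline coefficient magnitudes, trading
    landmark fidelity for a smaller, smoother correction.

    Because the affine part reproduces global translations and linear
    trends exactly, identity pairs yield a zero field and uniformly
    translated pairs yield a constant field at every grid point.
    """
    if control_spacing <= 0:
        raise ValueError("control_spacing must be positive")
    if regularization_weight < 0:
        raise ValueError("regularization_weight must be >= 0")
    fixed = landmarks.fixed - np.asarray(target_grid.origin)
    disp = landmarks.moving - landmarks.fixed  # (L, 3) mm, pull-back

    centered = fixed - fixed.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(centered).max())) < 3:
        warnings.warn(
            "degenerate (coplanar/collinear) landmark configuration; "
            "falling back to least-squares affine + spline fit",
            stacklevel=2,
        )

    # affine part: [fixed | 1] @ M ≈ disp
    A = np.column_stack([fixed, np.ones(len(fixed))])
    M, *_ = np.linalg.lstsq(A, disp, rcond=None)
    residual = disp - A @ M

    extents = np.asarray(target_grid.shape, dtype=float) * np.asarray(target_grid.spacing)
    B = _tensor_basis(fixed, extents, control_spacing)
    if regularization_weight == 0.0:
        coef, *_ = np.linalg.lstsq(B, residual, rcond=None)
    else:
        lam = np.sqrt(regularization_weight)
        B_aug = np.vstack([B, lam * np.eye(B.shape[1])])
        r_aug = np.vstack([residual, np.zeros((B.shape[1], 3))])
        coef, *_ = np.linalg.lstsq(B_aug, r_aug, rcond=None)

    # evaluate on the full grid: separable tensor contraction
    nx, ny, nz = target_grid.shape
    sx, sy, sz = target_grid.spacing
    gx = _axis_basis(np.arange(nx) * sx, extents[0], control_spacing)
    gy = _axis_basis(np.arange(ny) * sy, extents[1], control_spacing)
    gz = _axis_basis(np.arange(nz) * sz, extents[2], control_spacing)
    c = coef.reshape(gx.shape[1], gy.shape[1], gz.shape[1], 3)
    fld = np.tensordot(gx, c, axes=(1, 0))  # (nx, ncy, ncz, 3)
    fld = np.tensordot(gy, fld, axes=(1, 1)).transpose(1, 0, 2, 3)  # (nx, ny, ncz, 3)
    fld = np.tensordot(gz, fld, axes=(1, 2)).transpose(1, 2, 0, 3)  # (nx, ny, nz, 3)

    # add affine part: phys(i,j,k) @ M[:3] + M[3]
    px = (np.arange(nx) * sx)[:, None, None, None]
    py = (np.arange(ny) * sy)[None, :, None, None]
    pz = (np.arange(nz) * sz)[None, None, :, None]
    fld = fld + px * M[0] + py * M[1] + pz * M[2] + M[3]

    return DeformationField(
        displacement=fld,
        spacing=target_grid.spacing,
        origin=target_grid.origin,
        control_spacing=control_spacing,
    )


def apply_deformation(
    field: DeformationField,
    image: Volume,
    interpolation: str = "linear",
) -> Volume:
    """Resample ``image`` through the field: out(x) = image(x + d(x)).

    Masks must use nearest-neighbour interpolation so the output stays
    binary.  Samples falling outside the moving image read as 0.
    """
    if interpolation not in ("linear", "nearest"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    if isinstance(image, Mask) and interpolation == "linear":
        raise ValueError("linear interpolation would break mask binarity; use 'nearest'")
    if field.grid_shape != image.shape:
        raise ValueError(f"field grid {field.grid_shape} does not match image grid {image.shape}")
    nx, ny, nz = image.shape
    idx = np.indices((nx, ny, nz), dtype=float)
    coords = idx + np.moveaxis(field.displacement, 3, 0) / np.asarray(image.spacing).reshape(3, 1, 1, 1)
    order = 1 if interpolation == "linear" else 0
    out = ndimage.map_coordinates(
        image.data.astype(float), coords, order=order, mode="constant", cval=0.0
    )
    if isinstance(image, Mask):
        return Mask(data=out.astype(np.uint8), spacing=image.spacing, origin=image.origin)
    return Volume(data=out, spacing=image.spacing, origin=image.origin)


_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


def extract_surface_points(mask: Mask) -> BoundaryPointSet:
    """Surface voxels of a binary mask under 6-connectivity.

    A foreground voxel is on the surface iff at least one of its six face
    neighbours is background; voxels on the volume border count the
    outside as background.
    """
    data = mask.data.astype(bool)
    if not data.any():
        raise ValueError("cannot extract the surface of an empty mask")
    interior = ndimage.binary_erosion(data, structure=_FACE_STRUCT, border_value=0)
    surface = data & ~interior
    return BoundaryPointSet(points=np.argwhere(surface), source="prior")


def write_deformation(field: DeformationField, path: str) -> None:
    """Persist a field as a 3-component vector NIfTI/MetaImage."""
    arr = np.ascontiguousarray(field.displacement.transpose(2, 1, 0, 3))
    image = sitk.GetImageFromArray(arr, isVector=True)
    image.SetSpacing(field.spacing)
    image.SetOrigin(field.origin)
    sitk.WriteImage(image, str(path))


def read_deformation(path: str) -> DeformationField:
    image = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(image)
    if arr.ndim != 4 or arr.shape[3] != 3:
        raise ValueError(f"{path}: expected a 3-component vector field")
    return DeformationField(
        displacement=arr.transpose(2, 1, 0, 3),
        spacing=image.GetSpacing(),
        origin=image.GetOrigin(),
    )
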