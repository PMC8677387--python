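"""Synthetic abdominal phantoms for exercising every pipeline stage.

A phantom pair consists of a training volume with its gold-standard organ
mask, a target volume produced by warping the training volume with a
known smooth deformation field, the warped gold mask, a set of exactly
corresponding landmark pairs, and the true field itself.

The organ is a superellipsoid whose surface carries a concentric ring
texture (locally an oriented grating tangent to the boundary) so that
Gabor features distinguish boundary patches from interior and exterior
ones; both sides of the boundary are filled with band-limited speckle of
comparable energy but different spatial structure, so flat low-energy
patches cannot fake a low reconstruction error.  The background also
contains a "confuser" blob whose mean intensity matches the organ but
whose texture does not, to exercise false-positive control.

Everything is reproducible from the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .registration import DeformationField
from .volume_io import LandmarkSet, Mask, Volume

__all__ = ["PhantomSpec", "PhantomPair", "make_phantom_pair"]


@dataclass
class PhantomSpec:
    """Generation parameters; defaults give the standard 96³ phantom.

    ``deform_amplitude`` is the peak displacement (mm) of the smooth
    sinusoidal field between training and target; ``contrast`` the
    organ-vs-background intensity gap; ``noise_sigma`` the SD of the
    additive Gaussian noise applied independently to each volume.
    """

    shape: tuple[int, int, int] = (96, 96, 96)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    organ_radii: tuple[float, float, float] = (34.0, 30.0, 26.0)  # voxels
    organ_exponent: float = 2.5  # superellipsoid blockiness
    contrast: float = 100.0
    background_level: float = 40.0
    noise_sigma: float = 2.0
    band_amplitude: float = 50.0
    band_halfwidth: float = 2.0  # voxels
    band_wavelength: float = 4.0  # voxels per ring
    speckle_amplitude: float = 30.0
    speckle_smoothing: float = 1.0  # voxels
    confuser_radius: float = 10.0  # voxels; 0 disables
    deform_amplitude: float = 4.0  # mm
    n_landmarks_per_axis: int = 3
    patch_margin: int = 9  # required organ-to-border margin, voxels
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0 or self.deform_amplitude < 0:
            raise ValueError("noise_sigma and deform_amplitude must be >= 0")
        center = np.asarray(self.shape) / 2.0
        room = center - np.asarray(self.organ_radii)
        if (room < self.patch_margin).any():
            raise ValueError(
                f"organ radii {self.organ_radii} leave less than the required "
                f"{self.patch_margin}-voxel margin inside shape {self.shape}"
            )


@dataclass
class PhantomPair:
    training_volume: Volume
    training_mask: Mask
    target_volume: Volume
    target_mask: Mask
    landmarks: LandmarkSet
    true_field: DeformationField
    spec: PhantomSpec


def _superellipsoid_level(shape, center, radii, exponent) -> np.ndarray:
    """Implicit level function: negative inside, ~signed distance-ish."""
    grids = np.meshgrid(*(np.arange(s, dtype=float) for s in shape), indexing="ij")
    q = sum(
        np.abs((g - c) / r) ** exponent for g, c, r in zip(grids, center, radii)
    )
    return q ** (1.0 / exponent) - 1.0


def _smooth_noise(rng: np.random.Generator, shape, sigma: float, amplitude: float) -> np.ndarray:
    n = rng.standard_normal(shape)
    if sigma > 0:
        n = ndimage.gaussian_filter(n, sigma)
        sd = n.std()
        if sd > 0:
            n = n / sd
    return amplitude * n


def _analytic_field(spec: PhantomSpec, coords_mm: list[np.ndarray]) -> np.ndarray:
    """Smooth low-frequency displacement (mm) at the given mm coordinates."""
    a = spec.deform_amplitude
    extents = np.asarray(spec.shape) * np.asarray(spec.spacing)
    x, y, z = coords_mm
    kx, ky, kz = 2.0 * np.pi / extents
    d = np.stack(
        [
            0.6 * a * np.sin(ky * y + 0.7) * np.cos(kz * z + 0.3) + 0.25 * a,
            0.6 * a * np.sin(kz * z + 1.9) * np.cos(kx * x + 1.1) - 0.2 * a,
            0.6 * a * np.sin(kx * x + 0.4) * np.cos(ky * y + 2.3) + 0.15 * a,
        ],
        axis=-1,
    )
    return d


def make_phantom_pair(spec: PhantomSpec) -> PhantomPair:
    """Generate a training/target phantom pair with known correspondence.

    The target is the training volume resampled through the stored
    pull-back field (target(x) = training(x + d(x))) with independent
    noise; the target gold mask is the nearest-neighbour warp of the
    training gold mask, so the stored field maps one mask exactly onto
    the other.  Landmarks are an ``n³`` grid spanning the organ with
    moving = fixed + d(fixed), i.e. exact correspondences.
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.shape
    center = np.asarray(shape) / 2.0

    level = _superellipsoid_level(shape, center, spec.organ_radii, spec.organ_exponent)
    mask = (level <= 0.0).astype(np.uint8)

    # distance to the organ boundary (positive on both sides)
    d_out = ndimage.distance_transform_edt(mask == 0)
    d_in = ndimage.distance_transform_edt(mask == 1)
    dist = np.where(mask == 1, d_in, d_out)

    clean = np.full(shape, spec.background_level, dtype=float)
    clean += spec.contrast * mask
    # concentric ring band hugging the boundary: locally an oriented grating
    band = (
        spec.band_amplitude
        * np.cos(2.0 * np.pi * dist / spec.band_wavelength)
        * np.exp(-((dist / spec.band_halfwidth) ** 2) / 2.0)
    )
    clean += band
    # speckle with different correlation structure on either side
    speckle_in = _smooth_noise(rng, shape, spec.speckle_smoothing, spec.speckle_amplitude)
    speckle_out = _smooth_noise(rng, shape, 2.0 * spec.speckle_smoothing, spec.speckle_amplitude)
    off_band = 1.0 - np.exp(-((dist / (2.0 * spec.band_halfwidth)) ** 2) / 2.0)
    clean += off_band * np.where(mask == 1, speckle_in, speckle_out)

    if spec.confuser_radius > 0:
        c_center = np.asarray(shape) * np.asarray([0.18, 0.18, 0.5])
        c_level = _superellipsoid_level(shape, c_center, [spec.confuser_radius] * 3, 2.0)
        c_mask = c_level <= 0.0
        c_dist = np.abs(c_level) * spec.confuser_radius
        confuser = spec.contrast + 0.5 * spec.band_amplitude * np.cos(
            2.0 * np.pi * c_dist / (2.5 * spec.band_wavelength)
        )
        clean = np.where(c_mask, spec.background_level + confuser, clean)

    # stored pull-back field on the target grid
    axes_mm = [np.arange(s) * sp for s, sp in zip(shape, spec.spacing)]
    coords_mm = np.meshgrid(*axes_mm, indexing="ij")
    disp = _analytic_field(spec, coords_mm)
    field = DeformationField(
        displacement=disp, spacing=spec.spacing, origin=(0.0, 0.0, 0.0), control_spacing=0.0
    )

    idx = np.indices(shape, dtype=float)
    sample = idx + np.moveaxis(disp, 3, 0) / np.asarray(spec.spacing).reshape(3, 1, 1, 1)
    target_clean = ndimage.map_coordinates(clean, sample, order=1, mode="nearest")
    target_mask = ndimage.map_coordinates(mask, sample, order=0, mode="constant", cval=0)

    train_data = clean + rng.normal(0.0, spec.noise_sigma, shape) if spec.noise_sigma else clean
    target_data = (
        target_clean + rng.normal(0.0, spec.noise_sigma, shape)
        if spec.noise_sigma
        else target_clean
    )

    # landmark grid spanning the organ bounding box (fixed = target space)
    n = spec.n_landmarks_per_axis
    lo = (center - np.asarray(spec.organ_radii)) * np.asarray(spec.spacing)
    hi = (center + np.asarray(spec.organ_radii)) * np.asarray(spec.spacing)
    axes = [np.linspace(l, h, n) for l, h in zip(lo, hi)]
    fixed = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    d_at_fixed = _analytic_field(spec, [fixed[:, 0], fixed[:, 1], fixed[:, 2]])
    moving = fixed + d_at_fixed
    landmarks = LandmarkSet(moving=moving, fixed=fixed)

    return PhantomPair(
        training_volume=Volume(data=train_data, spacing=spec.spacing),
        training_mask=Mask(data=mask, spacing=spec.spacing),
        target_volume=Volume(data=target_data, spacing=spec.spacing),
        target_mask=Mask(data=target_mask.astype(np.uint8), spacing=spec.spacing),
        landmarks=landmarks,
        true_field=field,
        spec=spec,
    )
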