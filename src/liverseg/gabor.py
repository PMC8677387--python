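"""Gabor filter bank and per-patch texture features.

Each image patch is summarized by a fixed-length feature vector: the bank
holds ``n_orientations × n_scales`` real, even-symmetric (cosine-phase)
Gabor kernels, each DC-corrected to zero mean and scaled to unit L2 norm,
and entry ``j`` of a patch's feature is the mean absolute response of
kernel ``j`` over the patch window on the axial (x–y) slice containing
the patch centre.  With the default bank of 6 orientations (every 30° in
[0°, 180°)) and 4 scales the feature is a 24-vector.

Zero-mean kernels make the features invariant to adding a constant to the
image; magnitude pooling makes them insensitive to contrast polarity.
Whole-volume filtering (one 2D convolution per kernel per slice, with
reflect padding at the volume border) followed by window mean-pooling is
mathematically identical to filtering each patch separately away from the
border and is what both the single-patch and batched paths use.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .volume_io import Volume

__all__ = [
    "GaborBankSpec",
    "GaborBank",
    "PatchSet",
    "build_gabor_bank",
    "gabor_energy_stack",
    "patch_feature",
    "patch_matrix",
]


@dataclass
class GaborBankSpec:
    """Parameters of the orientation × scale Gabor bank.

    Wavelengths are mm per cycle (converted to voxels with the in-plane
    spacing); ``sigma_factor`` sets the Gaussian envelope as a fraction of
    the wavelength; ``kernel_radius`` is the kernel half-width in voxels.
    """

    n_orientations: int = 6
    n_scales: int = 4
    wavelengths: tuple[float, ...] = (3.0, 4.0, 6.0, 8.0)
    sigma_factor: float = 0.5
    kernel_radius: int = 8

    def __post_init__(self) -> None:
        if self.n_orientations < 1 or self.n_scales < 1:
            raise ValueError("need at least one orientation and one scale")
        self.wavelengths = tuple(float(w) for w in self.wavelengths)
        if len(self.wavelengths) != self.n_scales:
            raise ValueError("need one wavelength per scale")
        if any(b <= a for a, b in zip(self.wavelengths, self.wavelengths[1:])):
            raise ValueError("wavelengths must be strictly increasing")
        if self.sigma_factor <= 0 or self.kernel_radius < 1:
            raise ValueError("sigma_factor must be > 0 and kernel_radius >= 1")

    @property
    def feature_length(self) -> int:
        return self.n_orientations * self.n_scales

    @property
    def orientations(self) -> np.ndarray:
        """Orientations in radians, evenly spaced over [0, pi)."""
        return np.arange(self.n_orientations) * np.pi / self.n_orientations


@dataclass
class GaborBank:
    """Realized kernels; ``kernels[o * n_scales + s]`` is orientation o, scale s."""

    spec: GaborBankSpec
    kernels: list[np.ndarray]
    in_plane_spacing: tuple[float, float] = (1.0, 1.0)

    def __len__(self) -> int:
        return len(self.kernels)


@dataclass
class PatchSet:
    """Column-wise patch features plus each patch's centre voxel."""

    features: np.ndarray  # (m, N)
    centers: np.ndarray  # (N, 3) int voxel coordinates
    patch_size: tuple[int, int]

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=np.int64))
        if self.features.ndim != 2 or self.features.shape[1] != self.centers.shape[0]:
            raise ValueError("features must be (m, N) with one column per centre")
        if not np.isfinite(self.features).all():
            raise ValueError("patch features contain non-finite values")

    @property
    def n_patches(self) -> int:
        return self.features.shape[1]


def _gabor_kernel(wavelength_vox: float, theta: float, sigma_factor: float, radius: int) -> np.ndarray:
    """Even (cosine) Gabor kernel, zero mean and unit L2 norm."""
    u, v = np.meshgrid(
        np.arange(-radius, radius + 1, dtype=float),
        np.arange(-radius, radius + 1, dtype=float),
        indexing="ij",
    )
    rot = u * np.cos(theta) + v * np.sin(theta)
    perp = -u * np.sin(theta) + v * np.cos(theta)
    sigma = sigma_factor * wavelength_vox
    envelope = np.exp(-(rot**2 + perp**2) / (2.0 * sigma**2))
    k = envelope * np.cos(2.0 * np.pi * rot / wavelength_vox)
    k -= k.mean()
    norm = np.linalg.norm(k)
    if norm == 0:
        raise ValueError("degenerate Gabor kernel (all zero)")
    return k / norm


def build_gabor_bank(
    spec: GaborBankSpec, in_plane_spacing: tuple[float, float] = (1.0, 1.0)
) -> GaborBank:
    """Build the kernel bank for a volume with the given in-plane spacing.

    Raises if the kernel window cannot hold one full cycle of the largest
    wavelength.
    """
    mean_spacing = float(np.mean(in_plane_spacing))
    support_mm = (2 * spec.kernel_radius + 1) * mean_spacing
    if support_mm < max(spec.wavelengths):
        raise ValueError(
            f"kernel_radius {spec.kernel_radius} gives {support_mm:.1f} mm support, "
            f"less than one cycle of the largest wavelength {max(spec.wavelengths):.1f} mm"
        )
    kernels = [
        _gabor_kernel(lam / mean_spacing, theta, spec.sigma_factor, spec.kernel_radius)
        for theta in spec.orientations
        for lam in spec.wavelengths
    ]
    return GaborBank(spec=spec, kernels=kernels, in_plane_spacing=tuple(in_plane_spacing))


def _filter_slices(data: np.ndarray, kernel: np.ndarray, radius: int) -> np.ndarray:
    """Convolve every axial (x–y) slice with a 2D kernel, reflect-padded."""
    padded = np.pad(data.astype(float), ((radius, radius), (radius, radius), (0, 0)), mode="reflect")
    resp = signal.fftconvolve(padded, kernel[:, :, None], mode="same")
    return resp[radius:-radius, radius:-radius, :]


def gabor_energy_stack(
    volume: Volume, bank: GaborBank, patch_size: tuple[int, int]
) -> np.ndarray:
    """Pooled Gabor energy maps, shape (m, nx, ny, nz), float32.

    ``stack[j, x, y, z]`` is the mean of |response of kernel j| over the
    in-plane ``patch_size`` window centred at (x, y) on slice z — i.e. the
    j-th feature entry of the patch centred at that voxel.
    """
    px, py = patch_size
    if px % 2 == 0 or py % 2 == 0:
        raise ValueError("patch_size must be odd in both dimensions")
    radius = bank.spec.kernel_radius
    stack = np.empty((len(bank), *volume.shape), dtype=np.float32)
    for j, kernel in enumerate(bank.kernels):
        resp = np.abs(_filter_slices(volume.data, kernel, radius))
        stack[j] = ndimage.uniform_filter(resp, size=(px, py, 1), mode="nearest")
    return stack


def _check_center(center: np.ndarray, shape: tuple[int, int, int], patch_size: tuple[int, int]) -> None:
    hx, hy = patch_size[0] // 2, patch_size[1] // 2
    cx, cy, cz = (int(c) for c in center)
    if not (hx <= cx < shape[0] - hx and hy <= cy < shape[1] - hy and 0 <= cz < shape[2]):
        raise ValueError(
            f"patch of size {patch_size} centred at {(cx, cy, cz)} crosses the border of volume {shape}"
        )


def patch_feature(
    volume: Volume,
    center: tuple[int, int, int],
    patch_size: tuple[int, int],
    bank: GaborBank,
) -> np.ndarray:
    """Feature vector of one in-plane patch (length = bank feature length)."""
    center = np.asarray(center, dtype=int)
    _check_center(center, volume.shape, patch_size)
    cx, cy, cz = (int(c) for c in center)
    px, py = patch_size
    hx, hy = px // 2, py // 2
    radius = bank.spec.kernel_radius
    # filter only the slice containing the centre (identical to the
    # whole-volume path, which treats slices independently)
    sl = volume.data[:, :, cz : cz + 1]
    feats = np.empty(len(bank))
    for j, kernel in enumerate(bank.kernels):
        resp = np.abs(_filter_slices(sl, kernel, radius))[:, :, 0]
        feats[j] = resp[cx - hx : cx + hx + 1, cy - hy : cy + hy + 1].mean()
    return feats


def patch_matrix(
    volume: Volume,
    centers: np.ndarray,
    patch_size: tuple[int, int],
    bank: GaborBank,
    energy_stack: np.ndarray | None = None,
) -> PatchSet:
    """Feature matrix for many patch centres (columns follow input order).

    A precomputed :func:`gabor_energy_stack` may be passed to amortize the
    filtering cost across calls.
    """
    centers = np.atleast_2d(np.asarray(centers, dtype=int))
    if centers.size == 0:
        raise ValueError("empty centre list")
    for c in centers:
        _check_center(c, volume.shape, patch_size)
    if energy_stack is None:
        energy_stack = gabor_energy_stack(volume, bank, patch_size)
    features = energy_stack[:, centers[:, 0], centers[:, 1], centers[:, 2]].astype(float)
    return PatchSet(features=features, centers=centers, patch_size=tuple(patch_size))
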