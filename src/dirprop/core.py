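"""Volumetric primitives shared by both registration algorithms.

Conventions
-----------
* Arrays are indexed ``[ix, iy, iz]`` with ``z`` the slice (axial) axis.
* Voxel indices are 0-based; ``world = origin + index * spacing`` (mm).
  Volumes are axis-aligned: no orientation matrix.
* Displacement fields store millimetre vectors on the *target* image grid
  (pull-back convention): a warped image is built as
  ``out(x) = source(world(x) + u(x))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "ImageVolume",
    "DisplacementField",
    "GridPoint",
    "trilinear_sample",
    "warp_image",
    "gaussian_smooth_field",
    "downsample",
]

#: truncation radius of every Gaussian kernel, in standard deviations
GAUSS_TRUNCATE = 3.0


@dataclass
class ImageVolume:
    """A 3D scalar grid with spacing and origin in millimetres."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValueError(f"all dims must be >= 1, got {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("spacing and origin must be length-3")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("intensities must all be finite")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def spacing_arr(self) -> np.ndarray:
        return np.asarray(self.spacing, dtype=np.float64)

    @property
    def origin_arr(self) -> np.ndarray:
        return np.asarray(self.origin, dtype=np.float64)

    def index_to_world(self, index: np.ndarray) -> np.ndarray:
        """World mm coordinates of (possibly fractional) voxel indices."""
        return self.origin_arr + np.asarray(index, dtype=np.float64) * self.spacing_arr

    def world_to_index(self, world: np.ndarray) -> np.ndarray:
        """Continuous voxel index of world-mm points."""
        return (np.asarray(world, dtype=np.float64) - self.origin_arr) / self.spacing_arr

    def voxel_centers(self) -> np.ndarray:
        """(nx, ny, nz, 3) array of world coordinates of all voxel centers."""
        idx = np.stack(
            np.meshgrid(*(np.arange(n) for n in self.dims), indexing="ij"), axis=-1
        ).astype(np.float64)
        return self.origin_arr + idx * self.spacing_arr

    def same_grid(self, other: "ImageVolume | DisplacementField") -> bool:
        return (
            self.dims == other.dims
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def copy(self) -> "ImageVolume":
        return ImageVolume(self.data.copy(), self.spacing, self.origin)


@dataclass
class DisplacementField:
    """Per-voxel 3-component displacement in mm, on the target-image grid.

    ``vectors`` has shape ``(nx, ny, nz, 3)``.  The grid (dims, spacing,
    origin) must be identical to the reference (target) volume's grid.
    """

    vectors: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 4 or self.vectors.shape[-1] != 3:
            raise ValueError(
                f"vectors must have shape (nx,ny,nz,3), got {self.vectors.shape}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("displacement components must all be finite")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.vectors.shape[:3]

    @property
    def spacing_arr(self) -> np.ndarray:
        return np.asarray(self.spacing, dtype=np.float64)

    @property
    def origin_arr(self) -> np.ndarray:
        return np.asarray(self.origin, dtype=np.float64)

    @classmethod
    def zeros_like(cls, volume: ImageVolume) -> "DisplacementField":
        return cls(
            np.zeros(volume.dims + (3,), dtype=np.float64),
            volume.spacing,
            volume.origin,
        )

    def magnitude(self) -> np.ndarray:
        return np.sqrt(np.sum(self.vectors**2, axis=-1))

    def copy(self) -> "DisplacementField":
        return DisplacementField(self.vectors.copy(), self.spacing, self.origin)


@dataclass(frozen=True)
class GridPoint:
    """A voxel of a specific grid: 0-based index plus its world position.

    ``world = origin + index * spacing`` with fixed (x, y, z) axis order,
    z being the slice axis.
    """

    index: tuple[int, int, int]
    world: tuple[float, float, float]

    @classmethod
    def from_index(cls, volume: ImageVolume, index) -> "GridPoint":
        idx = tuple(int(i) for i in index)
        world = volume.index_to_world(np.asarray(idx, dtype=np.float64))
        return cls(idx, tuple(float(w) for w in world))

    @classmethod
    def from_world(cls, volume: ImageVolume, world) -> "GridPoint":
        idx = np.round(volume.world_to_index(np.asarray(world, dtype=np.float64)))
        return cls.from_index(volume, idx.astype(int))


def _as_index_coords(volume: ImageVolume, points: np.ndarray) -> np.ndarray:
    pts = np.asarray(points, dtype=np.float64)
    if not np.all(np.isfinite(pts)):
        raise ValueError("sample points must be finite")
    return (pts - volume.origin_arr) / volume.spacing_arr


def trilinear_sample(volume: ImageVolume, points: np.ndarray) -> np.ndarray:
    """Trilinearly interpolate ``volume`` at world-mm ``points``.

    ``points`` is an array of shape ``(..., 3)``.  Points outside the grid
    clamp to the nearest border voxel.  Returns an array of shape ``(...)``
    (a scalar for a single point).
    """
    pts = np.asarray(points, dtype=np.float64)
    scalar = pts.ndim == 1
    idx = _as_index_coords(volume, pts.reshape(-1, 3))
    out = ndimage.map_coordinates(
        volume.data, idx.T, order=1, mode="nearest", prefilter=False
    )
    if scalar:
        return float(out[0])
    return out.reshape(pts.shape[:-1])


def warp_image(source: ImageVolume, dvf: DisplacementField) -> ImageVolume:
    """Pull-back warp: ``out(x) = source(world(x) + u(x))`` per target voxel."""
    grid_world = ImageVolume(
        np.zeros(dvf.dims), dvf.spacing, dvf.origin
    ).voxel_centers()
    sample_points = grid_world + dvf.vectors
    data = trilinear_sample(source, sample_points.reshape(-1, 3)).reshape(dvf.dims)
    return ImageVolume(data, dvf.spacing, dvf.origin)


def gaussian_smooth_field(
    dvf: DisplacementField, sigma: float | tuple[float, float, float]
) -> DisplacementField:
    """Smooth each displacement component with a truncated discrete Gaussian.

    ``sigma`` is in voxels (scalar or per-axis).  The kernel is truncated at
    3 sigma and renormalised, so constants (and interior-supported means) are
    preserved.  ``sigma = 0`` returns the input unchanged.
    """
    sig = np.broadcast_to(np.asarray(sigma, dtype=np.float64), (3,)).copy()
    if np.any(sig < 0):
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    if np.all(sig == 0):
        return dvf.copy()
    out = np.empty_like(dvf.vectors)
    for c in range(3):
        out[..., c] = ndimage.gaussian_filter(
            dvf.vectors[..., c], sigma=sig, mode="nearest", truncate=GAUSS_TRUNCATE
        )
    return DisplacementField(out, dvf.spacing, dvf.origin)


def downsample(volume: ImageVolume, factor: int) -> ImageVolume:
    """Anti-aliased integer-factor downsampling.

    Gaussian prefilter with sigma = 0.5 * factor voxels, then every
    ``factor``-th voxel is kept.  Output spacing is input spacing * factor.
    ``factor = 1`` is the identity.
    """
    if int(factor) != factor or factor < 1:
        raise ValueError(f"factor must be a positive integer, got {factor}")
    factor = int(factor)
    if factor == 1:
        return volume.copy()
    smoothed = ndimage.gaussian_filter(
        volume.data, sigma=0.5 * factor, mode="nearest", truncate=GAUSS_TRUNCATE
    )
    data = smoothed[::factor, ::factor, ::factor]
    spacing = tuple(s * factor for s in volume.spacing)
    return ImageVolume(data, spacing, volume.origin)
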