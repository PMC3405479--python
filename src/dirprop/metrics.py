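"""Contour agreement metrics: Dice, mean slicewise Hausdorff, COM shift.

Boundaries are taken per axial slice as the centers of boundary voxels
(mask voxels with at least one 4-neighbour outside the mask), in world mm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import cdist

from .propagate import BinaryMask

__all__ = [
    "MetricReport",
    "SliceBoundary",
    "dice",
    "slice_hausdorff",
    "mshd",
    "com_displacement",
    "boundary_points_2d",
    "boundary_points_3d",
    "evaluate_roi",
]


@dataclass
class SliceBoundary:
    """In-plane boundary point set for one axial slice (world mm, x/y)."""

    slice_index: int
    points: np.ndarray  # (n, 2) in-plane mm

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=np.float64))
        if self.points.shape[-1] != 2:
            raise ValueError("boundary points must be 2D in-plane")


@dataclass
class MetricReport:
    roi_label: str
    dice: float
    mshd_mm: float
    com_shift_mm: tuple[float, float, float] | None = None
    com_magnitude_mm: float | None = None
    slice_count_used: int = 0

    def to_dict(self) -> dict:
        d = {
            "roi_label": self.roi_label,
            "dice": self.dice,
            "mshd_mm": self.mshd_mm,
            "slice_count_used": self.slice_count_used,
        }
        if self.com_shift_mm is not None:
            d.update(
                com_dx=self.com_shift_mm[0],
                com_dy=self.com_shift_mm[1],
                com_dz=self.com_shift_mm[2],
                com_mag_mm=self.com_magnitude_mm,
            )
        return d


_CROSS_2D = ndimage.generate_binary_structure(2, 1)


def _check_grids(a: BinaryMask, b: BinaryMask) -> None:
    if not a.same_grid(b):
        raise ValueError("masks must share one grid")


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """DS = 2 |A n B| / (|A| + |B|) on voxel counts."""
    _check_grids(a, b)
    na, nb = a.count(), b.count()
    if na + nb == 0:
        raise ValueError("Dice undefined: both masks empty")
    inter = int(np.logical_and(a.data, b.data).sum())
    return 2.0 * inter / (na + nb)


def boundary_points_2d(mask: BinaryMask, k: int) -> np.ndarray:
    """In-plane (x, y) mm centers of boundary voxels on axial slice ``k``."""
    sl = mask.data[:, :, k]
    if not sl.any():
        return np.empty((0, 2))
    interior = ndimage.binary_erosion(sl, structure=_CROSS_2D, border_value=0)
    idx = np.argwhere(sl & ~interior)
    return mask.origin_arr[:2] + idx * mask.spacing_arr[:2]


def boundary_points_3d(mask: BinaryMask) -> np.ndarray:
    """World-mm centers of all 3D boundary voxels (6-connectivity)."""
    structure = ndimage.generate_binary_structure(3, 1)
    interior = ndimage.binary_erosion(mask.data, structure=structure, border_value=0)
    idx = np.argwhere(mask.data & ~interior)
    return mask.origin_arr + idx * mask.spacing_arr


def slice_hausdorff(a: SliceBoundary, b: SliceBoundary) -> float:
    """Symmetric Hausdorff distance between two in-plane point sets (mm)."""
    if len(a.points) == 0 or len(b.points) == 0:
        raise ValueError("slice_hausdorff requires non-empty boundaries")
    d = cdist(a.points, b.points)
    return float(max(d.min(axis=1).max(), d.min(axis=0).max()))


def mshd(propagated: BinaryMask, expert: BinaryMask) -> tuple[float, int]:
    """Mean slicewise Hausdorff distance over all expert-contoured slices.

    On expert slices where the propagated mask is absent the slice value is
    the maximum distance from the expert boundary points on that slice to
    the nearest point of the propagated mask's full 3D boundary, so gross
    under-propagation is penalized rather than skipped.
    """
    _check_grids(propagated, expert)
    if not expert.data.any():
        raise ValueError("expert mask is empty")
    if not propagated.data.any():
        raise ValueError("propagated mask is empty")
    prop_3d = None
    values = []
    for k in range(expert.dims[2]):
        exp_pts = boundary_points_2d(expert, k)
        if len(exp_pts) == 0:
            continue
        prop_pts = boundary_points_2d(propagated, k)
        if len(prop_pts) > 0:
            values.append(
                slice_hausdorff(SliceBoundary(k, exp_pts), SliceBoundary(k, prop_pts))
            )
        else:
            if prop_3d is None:
                prop_3d = boundary_points_3d(propagated)
            z = expert.origin[2] + k * expert.spacing[2]
            exp_3d = np.column_stack([exp_pts, np.full(len(exp_pts), z)])
            d = cdist(exp_3d, prop_3d)
            values.append(float(d.min(axis=1).max()))
    return float(np.mean(values)), len(values)


def com_displacement(a: BinaryMask, b: BinaryMask) -> tuple[np.ndarray, float]:
    """COM(A) - COM(B) in mm (unweighted voxel-center mean) and its norm."""
    for m, name in ((a, "A"), (b, "B")):
        if not m.data.any():
            raise ValueError(f"com_displacement: mask {name} is empty")
    com_a = a.origin_arr + np.argwhere(a.data).mean(axis=0) * a.spacing_arr
    com_b = b.origin_arr + np.argwhere(b.data).mean(axis=0) * b.spacing_arr
    vec = com_a - com_b
    return vec, float(np.linalg.norm(vec))


def evaluate_roi(
    propagated: BinaryMask, expert: BinaryMask, with_com: bool = False
) -> MetricReport:
    """Full per-ROI agreement report (Dice + MSHD, optionally COM shift)."""
    ds = dice(propagated, expert)
    h, n_slices = mshd(propagated, expert)
    report = MetricReport(
        roi_label=expert.label or propagated.label,
        dice=ds,
        mshd_mm=h,
        slice_count_used=n_slices,
    )
    if with_com:
        vec, mag = com_displacement(propagated, expert)
        report.com_shift_mm = tuple(vec)
        report.com_magnitude_mm = mag
    return report
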