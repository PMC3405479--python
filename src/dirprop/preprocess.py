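"""Pre-registration steps: rigid alignment and intensity histogram matching."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .core import ImageVolume, downsample, trilinear_sample

__all__ = [
    "RigidTransform",
    "HistogramMatchParams",
    "rigid_register",
    "apply_rigid",
    "histogram_match",
]


@dataclass
class RigidTransform:
    """6-parameter rigid transform: translation (mm) and rotation (degrees).

    Rotations are about ``center`` (mm), applied in fixed axis order
    x -> y -> z.  The transform maps a point ``p`` in the fixed frame to the
    corresponding point in the moving frame:

        T(p) = R (p - center) + center + translation
    """

    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def matrix(self) -> np.ndarray:
        rx, ry, rz = np.deg2rad(self.rotation_deg)
        cx, sx = np.cos(rx), np.sin(rx)
        cy, sy = np.cos(ry), np.sin(ry)
        cz, sz = np.cos(rz), np.sin(rz)
        Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        return Rz @ Ry @ Rx

    def apply_points(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=np.float64)
        c = np.asarray(self.center)
        t = np.asarray(self.translation)
        return (pts - c) @ self.matrix().T + c + t

    def inverse(self) -> "RigidTransform":
        """Exact inverse, expressed with the same center."""
        R_inv = self.matrix().T
        t_inv = R_inv @ (-np.asarray(self.translation))
        return RigidTransform(tuple(t_inv), _euler_xyz_deg(R_inv), self.center)

    def to_dict(self) -> dict:
        return {
            "convention": "world_mm; T(p) = R(p-center)+center+t; "
            "rotations deg applied x->y->z about center",
            "translation_mm": list(self.translation),
            "rotation_deg": list(self.rotation_deg),
            "center_mm": list(self.center),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(
            tuple(d["translation_mm"]), tuple(d["rotation_deg"]), tuple(d["center_mm"])
        )


def _euler_xyz_deg(R: np.ndarray) -> tuple[float, float, float]:
    """Angles (deg) such that Rz(rz) @ Ry(ry) @ Rx(rx) reproduces ``R``."""
    ry = np.arcsin(np.clip(-R[2, 0], -1.0, 1.0))
    if abs(R[2, 0]) < 1.0 - 1e-12:
        rx = np.arctan2(R[2, 1], R[2, 2])
        rz = np.arctan2(R[1, 0], R[0, 0])
    else:  # gimbal lock: fold everything into rx
        rx = np.arctan2(-R[1, 2], R[1, 1])
        rz = 0.0
    return tuple(np.rad2deg([rx, ry, rz]))


def _volume_center(volume: ImageVolume) -> np.ndarray:
    return volume.origin_arr + (np.asarray(volume.dims) - 1) / 2.0 * volume.spacing_arr


def apply_rigid(
    volume: ImageVolume, t: RigidTransform, reference: ImageVolume
) -> ImageVolume:
    """Resample ``volume`` through ``t`` onto the grid of ``reference``.

    ``out(x) = volume(T(world(x)))`` — the transform pulls fixed-frame voxel
    centers back into the moving volume.
    """
    pts = reference.voxel_centers().reshape(-1, 3)
    data = trilinear_sample(volume, t.apply_points(pts)).reshape(reference.dims)
    return ImageVolume(data, reference.spacing, reference.origin)


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        raise ValueError("NCC undefined: constant image")
    return float((a * b).sum() / denom)


def rigid_register(
    fixed: ImageVolume,
    moving: ImageVolume,
    max_translation_mm: float = 20.0,
    max_rotation_deg: float = 10.0,
) -> RigidTransform:
    """Find the 6-parameter rigid transform maximizing normalized
    cross-correlation between ``fixed`` and the resampled ``moving``.

    Deterministic derivative-free search: a coarse translation grid at 4x
    downsampling seeds Nelder-Mead refinements of all six parameters at 4x,
    2x and 1x resolution.
    """
    if np.ptp(fixed.data) == 0 or np.ptp(moving.data) == 0:
        raise ValueError("rigid_register requires non-constant images")
    center = _volume_center(fixed)

    def objective(params, fx, mv):
        t = RigidTransform(tuple(params[:3]), tuple(params[3:]), tuple(center))
        resampled = apply_rigid(mv, t, fx)
        try:
            return -_ncc(fx.data, resampled.data)
        except ValueError:
            return 0.0

    levels = []
    for f in (4, 2, 1):
        if min(fixed.dims) // f >= 4:
            levels.append((downsample(fixed, f), downsample(moving, f)))
    if not levels:
        levels = [(fixed, moving)]

    # coarse translation-only sweep on the coarsest level
    fx0, mv0 = levels[0]
    step = max(fx0.spacing)
    offsets = np.arange(-max_translation_mm, max_translation_mm + 1e-9, step)
    best = (objective(np.zeros(6), fx0, mv0), np.zeros(6))
    for tx in offsets:
        for ty in offsets:
            for tz in offsets:
                p = np.array([tx, ty, tz, 0.0, 0.0, 0.0])
                v = objective(p, fx0, mv0)
                if v < best[0]:
                    best = (v, p)
    params = best[1]

    for fx, mv in levels:
        res = optimize.minimize(
            objective,
            params,
            args=(fx, mv),
            method="Nelder-Mead",
            options={"xatol": 1e-3, "fatol": 1e-9, "maxiter": 400},
        )
        params = res.x

    result = RigidTransform(tuple(params[:3]), tuple(params[3:]), tuple(center))
    # guarantee the contract: never worse than the identity
    ident = RigidTransform(center=tuple(center))
    if objective(params, fixed, moving) > objective(np.zeros(6), fixed, moving):
        return ident
    return result


@dataclass
class HistogramMatchParams:
    """Quantile-based histogram matching configuration.

    ``exclude_below_mean`` restricts quantile estimation to voxels above
    each image's mean intensity, which keeps a dominant air background from
    swamping the match points (the usual CT practice).
    """

    n_bins: int = 64
    n_match_points: int = 7
    exclude_below_mean: bool = True

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if not 1 <= self.n_match_points <= self.n_bins:
            raise ValueError("n_match_points must be in [1, n_bins]")


def histogram_match(
    source: ImageVolume,
    reference: ImageVolume,
    params: HistogramMatchParams | None = None,
) -> ImageVolume:
    """Map source intensities so their quantiles match the reference's.

    A monotone piecewise-linear map is fitted through the source and
    reference quantiles at ``n_match_points`` equally spaced interior
    quantile levels (the 0 and 1 levels are never pinned).  Outside the
    outermost match points the map extends with the adjacent slope.
    """
    params = params or HistogramMatchParams()
    if np.ptp(source.data) == 0 or np.ptp(reference.data) == 0:
        raise ValueError("histogram_match requires non-constant images")
    src_vals = source.data.ravel()
    ref_vals = reference.data.ravel()
    if params.exclude_below_mean:
        src_sel = src_vals[src_vals > src_vals.mean()]
        ref_sel = ref_vals[ref_vals > ref_vals.mean()]
        if len(src_sel) > 1 and len(ref_sel) > 1:
            src_vals, ref_vals = src_sel, ref_sel
    m = params.n_match_points
    levels = np.arange(1, m + 1) / (m + 1)
    src_q = np.quantile(src_vals, levels)
    ref_q = np.quantile(ref_vals, levels)
    # collapse duplicate source quantiles to keep the map single-valued
    src_knots, keep = np.unique(src_q, return_index=True)
    ref_knots = ref_q[keep]
    flat = source.data.ravel()
    if len(src_knots) == 1:
        data = flat + (ref_knots[0] - src_knots[0])
    else:
        data = np.interp(flat, src_knots, ref_knots)
        # unit-slope extension beyond the outer knots: tails keep their
        # shape and are only shifted, never stretched
        below = flat < src_knots[0]
        above = flat > src_knots[-1]
        data[below] = flat[below] + (ref_knots[0] - src_knots[0])
        data[above] = flat[above] + (ref_knots[-1] - src_knots[-1])
    return ImageVolume(data.reshape(source.dims), source.spacing, source.origin)
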