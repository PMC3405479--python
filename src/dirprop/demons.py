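"""Multi-resolution fast-symmetric-Demons non-rigid registration.

Each iteration warps the moving image with the current field, computes a
symmetric optical-flow force from the fixed and warped-moving intensities,
adds it to the field, and Gaussian-smooths the total field
(diffusion-like regularization).  Iterations stop when the mean relative
change of the intensity mean-square difference over a trailing window drops
below a percentage tolerance.

The resulting displacement field lives on the target (fixed) image grid in
the pull-back convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    DisplacementField,
    ImageVolume,
    downsample,
    gaussian_smooth_field,
    trilinear_sample,
    warp_image,
)

__all__ = [
    "DemonsSchedule",
    "RegistrationResult",
    "mean_square_difference",
    "demons_update",
    "register_level",
    "demons_register",
]

#: guard against division by ~zero in the force denominator
DENOM_EPS = 1e-9


@dataclass
class DemonsSchedule:
    """Per-level (resample_factor, max_iterations, smoothing_sigma_voxels)
    plus the stopping criterion."""

    levels: tuple = ((4, 200, 3.0), (3, 100, 3.0), (2, 100, 0.9), (1, 30, 0.7))
    stop_tolerance_percent: float = 1.5
    stop_window_iterations: int = 5

    def __post_init__(self) -> None:
        factors = [lv[0] for lv in self.levels]
        if factors != sorted(factors, reverse=True) or len(set(factors)) != len(factors):
            raise ValueError(f"level factors must be strictly decreasing: {factors}")
        if factors[-1] != 1:
            raise ValueError("final level must run at full resolution (factor 1)")
        if any(lv[1] < 1 for lv in self.levels):
            raise ValueError("max_iterations must be >= 1 at every level")
        if self.stop_tolerance_percent <= 0:
            raise ValueError("stop_tolerance_percent must be > 0")
        if self.stop_window_iterations < 1:
            raise ValueError("stop_window_iterations must be >= 1")


@dataclass
class RegistrationResult:
    dvf: DisplacementField
    msd_traces: list  # one list of MSD values per level, coarse -> fine
    iterations_used: list  # iterations actually run per level

    def msd_dataframe(self):
        import pandas as pd

        rows = []
        for level_idx, trace in enumerate(self.msd_traces):
            for it, msd in enumerate(trace):
                rows.append({"level": level_idx, "iteration": it, "msd": msd})
        return pd.DataFrame(rows)


def mean_square_difference(fixed: ImageVolume, warped: ImageVolume) -> float:
    """Mean over voxels of the squared intensity difference."""
    if not fixed.same_grid(warped):
        raise ValueError("mean_square_difference requires identical grids")
    diff = fixed.data - warped.data
    return float(np.mean(diff * diff))


def _gradient_mm(volume: ImageVolume) -> np.ndarray:
    """Central-difference gradient, (nx,ny,nz,3) in intensity per mm."""
    gx, gy, gz = np.gradient(volume.data, *volume.spacing)
    return np.stack([gx, gy, gz], axis=-1)


def demons_update(
    fixed: ImageVolume,
    warped_moving: ImageVolume,
    max_step_mm: float | None = 2.0,
) -> DisplacementField:
    """Symmetric optical-flow force field (mm) for one iteration.

    u = 2 (f - m) (grad f + grad m) / (|grad f + grad m|^2 + alpha (f - m)^2)

    with alpha = 1 / mean(spacing)^2.  Voxels whose denominator falls below
    a small epsilon get a zero update.  Following the usual fast-symmetric
    implementation the update magnitude is clipped to ``max_step_mm``
    (pass ``None`` to disable).
    """
    if not fixed.same_grid(warped_moving):
        raise ValueError("demons_update requires identical grids")
    diff = fixed.data - warped_moving.data
    grad_sum = _gradient_mm(fixed) + _gradient_mm(warped_moving)
    alpha = 1.0 / float(np.mean(fixed.spacing)) ** 2
    denom = np.sum(grad_sum**2, axis=-1) + alpha * diff**2
    scale = np.where(denom < DENOM_EPS, 0.0, 2.0 * diff / np.maximum(denom, DENOM_EPS))
    update = grad_sum * scale[..., None]
    if max_step_mm is not None:
        mag = np.sqrt(np.sum(update**2, axis=-1))
        over = mag > max_step_mm
        if np.any(over):
            update[over] *= (max_step_mm / mag[over])[..., None]
    return DisplacementField(update, fixed.spacing, fixed.origin)


def register_level(
    fixed: ImageVolume,
    moving: ImageVolume,
    init: DisplacementField,
    max_iterations: int,
    smoothing_sigma_voxels: float,
    tolerance_percent: float = 1.5,
    window: int = 5,
) -> tuple[DisplacementField, list]:
    """Run Demons iterations at a single resolution level.

    Returns the refined field and the per-iteration MSD trace.  Stops early
    once the mean relative MSD change over the last ``window`` iterations is
    below ``tolerance_percent / 100``.  The returned field is the
    best-scoring (minimum-MSD) state visited — iterations past that point
    are wasted effort and are trimmed from the trace — so the level never
    hands a degraded field to its successor.
    """
    if not (fixed.same_grid(moving) and fixed.same_grid(init)):
        raise ValueError("register_level requires all inputs on one grid")
    dvf = init.copy()
    best_dvf = init.copy()
    best_msd = mean_square_difference(fixed, warp_image(moving, init))
    best_iter = 0
    trace: list[float] = []
    rel_changes: list[float] = []
    for it in range(max_iterations):
        warped = warp_image(moving, dvf)
        update = demons_update(fixed, warped)
        total = dvf.vectors + update.vectors
        dvf = gaussian_smooth_field(
            DisplacementField(total, dvf.spacing, dvf.origin), smoothing_sigma_voxels
        )
        if not np.all(np.isfinite(dvf.vectors)):
            raise FloatingPointError(f"non-finite displacement field at iteration {it}")
        msd = mean_square_difference(fixed, warp_image(moving, dvf))
        if msd < best_msd:
            best_msd = msd
            best_dvf = dvf.copy()
            best_iter = it + 1
        if trace:
            prev = trace[-1]
            rel_changes.append(abs(msd - prev) / max(prev, DENOM_EPS))
        trace.append(msd)
        if len(rel_changes) >= window:
            if np.mean(rel_changes[-window:]) < tolerance_percent / 100.0:
                break
    return best_dvf, trace[: max(best_iter, 1)]


def _resample_field(dvf: DisplacementField, target: ImageVolume) -> DisplacementField:
    """Trilinearly resample each mm component onto ``target``'s grid."""
    pts = target.voxel_centers().reshape(-1, 3)
    comps = []
    for c in range(3):
        vol = ImageVolume(dvf.vectors[..., c], dvf.spacing, dvf.origin)
        comps.append(trilinear_sample(vol, pts).reshape(target.dims))
    return DisplacementField(
        np.stack(comps, axis=-1), target.spacing, target.origin
    )


def demons_register(
    fixed: ImageVolume,
    moving: ImageVolume,
    schedule: DemonsSchedule | None = None,
) -> RegistrationResult:
    """Coarse-to-fine Demons registration.

    Histogram matching is the caller's responsibility (the pipeline applies
    it before calling).  The returned field is on the fixed image's grid.
    """
    schedule = schedule or DemonsSchedule()
    traces: list[list] = []
    iters: list[int] = []
    dvf: DisplacementField | None = None
    for factor, max_it, sigma in schedule.levels:
        fx = downsample(fixed, factor)
        mv = downsample(moving, factor)
        if dvf is None:
            init = DisplacementField.zeros_like(fx)
        else:
            init = _resample_field(dvf, fx)
        dvf, trace = register_level(
            fx,
            mv,
            init,
            max_iterations=max_it,
            smoothing_sigma_voxels=sigma,
            tolerance_percent=schedule.stop_tolerance_percent,
            window=schedule.stop_window_iterations,
        )
        traces.append(trace)
        iters.append(len(trace))
    assert dvf is not None
    if not fixed.same_grid(dvf):
        dvf = _resample_field(dvf, fixed)
    return RegistrationResult(dvf=dvf, msd_traces=traces, iterations_used=iters)
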