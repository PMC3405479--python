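"""Synthetic CT-like phantom pairs with an analytically known deformation.

A planning volume of a neck-like geometry (body ellipse, vertebral bone
ring, spinal cord, brainstem, both parotids, an airway tube and a lobed
tumour next to it) is generated with seeded texture and noise.  A
per-treatment volume is produced by warping the planning volume through a
smooth, invertible, analytically defined displacement field that combines
free-form Gaussian bumps (including a lateral body-recession bump) with a
radial tumour-shrinkage term.  Ground-truth ROIs on the per-treatment frame
and the true displacement field sampled on its grid come along for free.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import DisplacementField, ImageVolume, trilinear_sample
from .propagate import BinaryMask
from .metrics import dice as dice_score

__all__ = [
    "PhantomSpec",
    "DeformationSpec",
    "GaussianBump",
    "generate_planning_phantom",
    "generate_per_treatment",
    "analytic_displacement",
    "body_mask",
    "recovery_report",
    "default_deformation",
]

ROI_LABELS = ("spinal_cord", "brainstem", "parotid_L", "parotid_R", "GTV")


@dataclass
class PhantomSpec:
    """Geometry and intensity model of the planning phantom."""

    dims: tuple[int, int, int] = (96, 96, 48)
    spacing: tuple[float, float, float] = (2.0, 2.0, 3.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    # intensity levels (CT-number-like a.u.)
    air_level: float = -1000.0
    body_level: float = 50.0
    bone_level: float = 700.0
    cord_level: float = 130.0
    brainstem_level: float = 120.0
    parotid_level: float = -30.0
    gtv_level: float = 160.0
    noise_sd: float = 10.0
    # seeded lumpy texture inside the body, needed for feature matching
    n_texture_blobs: int = 200
    texture_amplitude: float = 60.0
    texture_sigma_range_mm: tuple[float, float] = (3.0, 8.0)
    seed: int = 0

    # geometry (world mm)
    body_center_xy: tuple[float, float] = (95.0, 95.0)
    body_radii_xy: tuple[float, float] = (72.0, 62.0)
    cord_center_xy: tuple[float, float] = (95.0, 132.0)
    cord_radius: float = 6.0
    bone_radii: tuple[float, float] = (9.0, 15.0)
    brainstem_center_xy: tuple[float, float] = (95.0, 104.0)
    brainstem_radius: float = 8.0
    brainstem_z_range: tuple[float, float] = (90.0, 135.0)
    parotid_centers: tuple = ((50.0, 98.0, 72.0), (140.0, 98.0, 72.0))
    parotid_radii: tuple[float, float, float] = (11.0, 15.0, 18.0)
    airway_center_xy: tuple[float, float] = (95.0, 76.0)
    airway_radius: float = 7.0
    # axial (z) structure: without it every edge is a z-invariant cylinder
    # and correlation matching is blind along z (aperture problem)
    body_taper: float = 0.07  # mid-neck narrowing fraction
    vertebra_period_mm: float = 24.0
    vertebra_fill: float = 0.7  # bone fraction of each period (rest = disc)
    disc_level: float = 90.0
    airway_wobble: float = 0.25
    airway_wobble_period_mm: float = 60.0
    gtv_center: tuple[float, float, float] = (95.0, 56.0, 40.0)
    gtv_radius: float = 12.0
    gtv_lobe_center: tuple[float, float, float] = (100.0, 61.0, 45.0)
    gtv_lobe_radius: float = 7.0


@dataclass
class GaussianBump:
    """One additive displacement bump: a * exp(-|x-c|^2 / (2 sigma^2))."""

    center: tuple[float, float, float]
    sigma_mm: float
    amplitude_mm: tuple[float, float, float]


@dataclass
class DeformationSpec:
    """Analytic truth field: Gaussian bumps + radial GTV shrinkage.

    The field lives in the target frame (pull-back): the per-treatment
    image at x samples the planning image at ``x + u(x)``.  Shrinkage with
    factor s maps target radii r to source radii r/s inside
    ``shrink_radius_mm`` of the GTV center, fading out with a Gaussian
    window beyond, so the target-frame tumour is an exactly scaled copy.
    """

    bumps: tuple = ()
    gtv_center: tuple[float, float, float] | None = None
    gtv_shrink_factor: float = 0.7
    shrink_radius_mm: float = 16.5
    shrink_window_sigma_mm: float = 9.0
    noise_sd: float = 10.0
    seed: int = 1
    min_jacobian: float = 0.1

    def __post_init__(self) -> None:
        if not 0 < self.gtv_shrink_factor <= 1.5:
            raise ValueError("gtv_shrink_factor out of range")


def default_deformation(spec: PhantomSpec, seed: int = 1) -> DeformationSpec:
    """Default smooth deformation, max magnitude around 8 mm."""
    return DeformationSpec(
        bumps=(
            GaussianBump((60.0, 110.0, 30.0), 30.0, (4.0, 3.0, -2.0)),
            GaussianBump((125.0, 130.0, 110.0), 30.0, (-2.5, 3.0, 2.0)),
            # lateral recession of the body surface on the patient's right
            GaussianBump((165.0, 105.0, 45.0), 22.0, (3.5, 0.0, 0.0)),
        ),
        gtv_center=spec.gtv_center,
        noise_sd=spec.noise_sd,
        seed=seed,
    )


def _grid_world(spec: PhantomSpec) -> np.ndarray:
    idx = np.stack(
        np.meshgrid(*(np.arange(n) for n in spec.dims), indexing="ij"), axis=-1
    ).astype(np.float64)
    return np.asarray(spec.origin) + idx * np.asarray(spec.spacing)


def _organ_masks(spec: PhantomSpec, world: np.ndarray) -> dict[str, np.ndarray]:
    x, y, z = world[..., 0], world[..., 1], world[..., 2]
    masks: dict[str, np.ndarray] = {}
    cx, cy = spec.cord_center_xy
    masks["spinal_cord"] = (x - cx) ** 2 + (y - cy) ** 2 <= spec.cord_radius**2
    bx, by = spec.brainstem_center_xy
    z0, z1 = spec.brainstem_z_range
    masks["brainstem"] = (
        ((x - bx) ** 2 + (y - by) ** 2 <= spec.brainstem_radius**2)
        & (z >= z0)
        & (z <= z1)
    )
    for name, c in zip(("parotid_L", "parotid_R"), spec.parotid_centers):
        rx, ry, rz = spec.parotid_radii
        masks[name] = (
            ((x - c[0]) / rx) ** 2 + ((y - c[1]) / ry) ** 2 + ((z - c[2]) / rz) ** 2
        ) <= 1.0
    g = np.asarray(spec.gtv_center)
    l = np.asarray(spec.gtv_lobe_center)
    masks["GTV"] = (
        ((x - g[0]) ** 2 + (y - g[1]) ** 2 + (z - g[2]) ** 2 <= spec.gtv_radius**2)
        | ((x - l[0]) ** 2 + (y - l[1]) ** 2 + (z - l[2]) ** 2 <= spec.gtv_lobe_radius**2)
    )
    return masks


def _body(spec: PhantomSpec, world: np.ndarray) -> np.ndarray:
    x, y, z = world[..., 0], world[..., 1], world[..., 2]
    bx, by = spec.body_center_xy
    rx, ry = spec.body_radii_xy
    z_extent = spec.dims[2] * spec.spacing[2]
    s = 1.0 - spec.body_taper * np.sin(np.pi * z / z_extent)
    return ((x - bx) / (rx * s)) ** 2 + ((y - by) / (ry * s)) ** 2 <= 1.0


def body_mask(spec: PhantomSpec) -> BinaryMask:
    """Body (patient outline) mask of the planning geometry."""
    world = _grid_world(spec)
    return BinaryMask(_body(spec, world), spec.spacing, spec.origin, "body")


def _texture(spec: PhantomSpec, world: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Sum of seeded Gaussian intensity blobs (analytic, frame-independent)."""
    tex = np.zeros(world.shape[:-1])
    extent = np.asarray(spec.dims) * np.asarray(spec.spacing)
    lo, hi = spec.texture_sigma_range_mm
    centers = rng.uniform(0, 1, size=(spec.n_texture_blobs, 3)) * extent
    sigmas = rng.uniform(lo, hi, size=spec.n_texture_blobs)
    amps = rng.uniform(-1, 1, size=spec.n_texture_blobs) * spec.texture_amplitude
    for c, s, a in zip(centers, sigmas, amps):
        d2 = np.sum((world - c) ** 2, axis=-1)
        tex += a * np.exp(-d2 / (2 * s * s))
    return tex


def _clean_intensities(spec: PhantomSpec, world: np.ndarray) -> np.ndarray:
    """Noise-free phantom intensity at arbitrary world points."""
    data = np.full(world.shape[:-1], spec.air_level)
    body = _body(spec, world)
    data[body] = spec.body_level
    x, y, z = world[..., 0], world[..., 1], world[..., 2]
    cx, cy = spec.cord_center_xy
    r2 = (x - cx) ** 2 + (y - cy) ** 2
    ring = (r2 >= spec.bone_radii[0] ** 2) & (r2 <= spec.bone_radii[1] ** 2) & body
    # vertebral bodies separated by discs: periodic along z
    phase = np.mod(z, spec.vertebra_period_mm) / spec.vertebra_period_mm
    vertebra = phase < spec.vertebra_fill
    data[ring & vertebra] = spec.bone_level
    data[ring & ~vertebra] = spec.disc_level
    organs = _organ_masks(spec, world)
    levels = {
        "spinal_cord": spec.cord_level,
        "brainstem": spec.brainstem_level,
        "parotid_L": spec.parotid_level,
        "parotid_R": spec.parotid_level,
        "GTV": spec.gtv_level,
    }
    for name, m in organs.items():
        data[m & body] = levels[name]
    ax, ay = spec.airway_center_xy
    r_air = spec.airway_radius * (
        1.0 + spec.airway_wobble * np.sin(2 * np.pi * z / spec.airway_wobble_period_mm)
    )
    airway = ((x - ax) ** 2 + (y - ay) ** 2 <= r_air**2) & body
    data[airway] = spec.air_level
    return data


def generate_planning_phantom(
    spec: PhantomSpec | None = None,
) -> tuple[ImageVolume, list[BinaryMask]]:
    """Deterministic (seeded) planning volume plus its five ROI masks."""
    spec = spec or PhantomSpec()
    world = _grid_world(spec)
    organs = _organ_masks(spec, world)
    body = _body(spec, world)
    for name, m in organs.items():
        if not m.any():
            raise ValueError(f"organ {name} is empty for this spec")
        if np.any(m & ~body):
            raise ValueError(f"organ {name} leaves the body outline")
    names = list(organs)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if a == "GTV" or b == "GTV":
                continue  # the lobed GTV is validated against OARs only
            if np.any(organs[a] & organs[b]):
                raise ValueError(f"organs overlap: {a} and {b}")
    for oar in names:
        if oar != "GTV" and np.any(organs[oar] & organs["GTV"]):
            raise ValueError(f"organs overlap: {oar} and GTV")

    data = _clean_intensities(spec, world)
    rng = np.random.default_rng(spec.seed)
    if spec.n_texture_blobs > 0:
        data = data + _texture(spec, world, rng) * body
    if spec.noise_sd > 0:
        data = data + rng.normal(0.0, spec.noise_sd, size=spec.dims)
    volume = ImageVolume(data, spec.spacing, spec.origin)
    masks = [
        BinaryMask(organs[name], spec.spacing, spec.origin, name) for name in ROI_LABELS
    ]
    return volume, masks


def analytic_displacement(points: np.ndarray, d: DeformationSpec) -> np.ndarray:
    """Evaluate the truth field u (mm) at world points of shape (..., 3)."""
    pts = np.asarray(points, dtype=np.float64)
    u = np.zeros_like(pts)
    for b in d.bumps:
        d2 = np.sum((pts - np.asarray(b.center)) ** 2, axis=-1, keepdims=True)
        u = u + np.asarray(b.amplitude_mm) * np.exp(-d2 / (2 * b.sigma_mm**2))
    if d.gtv_center is not None and d.gtv_shrink_factor != 1.0:
        c = np.asarray(d.gtv_center)
        rel = pts - c
        r = np.linalg.norm(rel, axis=-1, keepdims=True)
        excess = np.maximum(r - d.shrink_radius_mm, 0.0)
        w = np.exp(-(excess**2) / (2 * d.shrink_window_sigma_mm**2))
        k = 1.0 / d.gtv_shrink_factor - 1.0
        u = u + k * rel * w
    return u


def _check_jacobian(dvf: DisplacementField, min_det: float) -> float:
    """Min determinant of d(x + u)/dx by central differences on the grid."""
    jac = np.zeros(dvf.dims + (3, 3))
    for c in range(3):
        grads = np.gradient(dvf.vectors[..., c], *dvf.spacing)
        for ax in range(3):
            jac[..., c, ax] = grads[ax]
        jac[..., c, c] += 1.0
    det = np.linalg.det(jac)
    min_found = float(det.min())
    if min_found <= min_det:
        raise ValueError(
            f"deformation not safely invertible: min Jacobian {min_found:.3f}"
        )
    return min_found


def generate_per_treatment(
    planning: ImageVolume,
    masks: list[BinaryMask],
    d: DeformationSpec,
) -> tuple[ImageVolume, list[BinaryMask], DisplacementField]:
    """Warp the planning volume through the analytic field.

    Returns the per-treatment volume (fresh seeded noise added), the
    ground-truth per-treatment ROI masks (nearest-voxel pull-back with the
    same analytic field), and the true displacement field sampled on the
    per-treatment grid.
    """
    world = planning.voxel_centers()
    u = analytic_displacement(world, d)
    true_dvf = DisplacementField(u, planning.spacing, planning.origin)
    _check_jacobian(true_dvf, d.min_jacobian)

    sample_at = (world + u).reshape(-1, 3)
    data = trilinear_sample(planning, sample_at).reshape(planning.dims)
    if d.noise_sd > 0:
        rng = np.random.default_rng(d.seed)
        data = data + rng.normal(0.0, d.noise_sd, size=planning.dims)
    per_treatment = ImageVolume(data, planning.spacing, planning.origin)

    gt_masks = []
    src_idx = np.round(
        (sample_at - planning.origin_arr) / planning.spacing_arr
    ).astype(int)
    ok = np.all((src_idx >= 0) & (src_idx < np.asarray(planning.dims)), axis=1)
    for m in masks:
        vals = np.zeros(len(sample_at), dtype=bool)
        vals[ok] = m.data[src_idx[ok, 0], src_idx[ok, 1], src_idx[ok, 2]]
        gt_masks.append(
            BinaryMask(vals.reshape(planning.dims), m.spacing, m.origin, m.label)
        )
    return per_treatment, gt_masks, true_dvf


def recovery_report(
    true_dvf: DisplacementField,
    estimated_dvf: DisplacementField,
    masks: dict[str, BinaryMask] | list[BinaryMask],
    body: BinaryMask | None = None,
) -> dict:
    """Displacement-error statistics of an estimated field vs. the truth.

    Reports mean and 95th-percentile vector error (mm) over the body (or
    the whole grid when no body mask is given) and over each mask, plus the
    Dice between masks propagated with the estimated field and with the
    true field.
    """
    if true_dvf.dims != estimated_dvf.dims:
        raise ValueError("recovery_report requires matching grids")
    if isinstance(masks, list):
        masks = {m.label: m for m in masks}
    err = np.linalg.norm(true_dvf.vectors - estimated_dvf.vectors, axis=-1)
    region = body.data if body is not None else np.ones(true_dvf.dims, dtype=bool)
    report: dict = {
        "mean_error_mm": float(err[region].mean()),
        "p95_error_mm": float(np.percentile(err[region], 95)),
        "per_roi": {},
    }
    from .propagate import propagate_mask

    for label, m in masks.items():
        entry = {
            "mean_error_mm": float(err[m.data].mean()) if m.data.any() else None,
        }
        truth_prop = propagate_mask(m, true_dvf)
        est_prop = propagate_mask(m, estimated_dvf)
        if truth_prop.data.any() or est_prop.data.any():
            entry["dice_vs_truth"] = dice_score(est_prop, truth_prop)
        report["per_roi"][label] = entry
    return report
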