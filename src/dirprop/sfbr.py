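"""Salient-feature-based registration (SFBR).

Scale-attributed interest points are detected on the planning image as
scale-normalized difference-of-Gaussians extrema, matched one-by-one into
the per-treatment image by maximizing local zero-mean normalized
cross-correlation within a search region, and the retained correspondences
are interpolated with a 3D thin-plate spline (kernel U(r) = r).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.feature import match_template

from .core import ImageVolume

__all__ = [
    "SalientFeature",
    "Correspondence",
    "SFBRParams",
    "ThinPlateSplineTransform",
    "detect_salient_features",
    "match_feature",
    "fit_tps",
    "apply_tps",
    "sfbr_register",
]


@dataclass
class SalientFeature:
    center: tuple[float, float, float]  # world mm
    scale: float  # mm
    response: float

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("feature scale must be > 0")


@dataclass
class Correspondence:
    p_source: tuple[float, float, float]
    p_target: tuple[float, float, float]
    correlation: float


@dataclass
class SFBRParams:
    reliability_threshold: float = 0.80
    search_radius_mm: float = 15.0
    target_anchor_count: int = 1500
    scale_levels_mm: tuple = (2.0, 4.0, 7.0, 12.0)
    min_anchor_count: int = 10
    tps_regularization: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.reliability_threshold < 1:
            raise ValueError("reliability_threshold must be in (0, 1)")
        if self.search_radius_mm <= 0:
            raise ValueError("search_radius_mm must be > 0")
        if len(self.scale_levels_mm) < 2:
            raise ValueError("need at least two scale levels")


def _scale_space(volume: ImageVolume, sigmas_mm) -> list[np.ndarray]:
    out = []
    for s in sigmas_mm:
        sig_vox = s / volume.spacing_arr
        out.append(ndimage.gaussian_filter(volume.data, sigma=sig_vox, mode="nearest"))
    return out


def detect_salient_features(
    volume: ImageVolume, params: SFBRParams | None = None
) -> list[SalientFeature]:
    """Scale-normalized difference-of-Gaussians extrema.

    A voxel/scale sample is kept when it is a strict extremum of its 26
    spatial neighbours at its own scale and not exceeded at the same voxel
    in the adjacent scales.  Features are ordered by |response| descending,
    ties broken lexicographically on the center, and the list is truncated
    to ``target_anchor_count``.
    """
    params = params or SFBRParams()
    if np.ptp(volume.data) == 0:
        return []
    sigmas = np.asarray(params.scale_levels_mm, dtype=np.float64)
    stack = _scale_space(volume, sigmas)
    features: list[SalientFeature] = []
    dogs = []
    for i in range(len(sigmas) - 1):
        # normalize by sigma ratio so responses are comparable across scales
        norm = sigmas[i] / (sigmas[i + 1] - sigmas[i])
        dogs.append((stack[i + 1] - stack[i]) * norm)
    for i, dog in enumerate(dogs):
        foot = np.ones((3, 3, 3), dtype=bool)
        local_max = ndimage.maximum_filter(dog, footprint=foot, mode="nearest")
        local_min = ndimage.minimum_filter(dog, footprint=foot, mode="nearest")
        is_max = dog >= local_max
        is_min = dog <= local_min
        if i > 0:
            is_max &= dog >= dogs[i - 1]
            is_min &= dog <= dogs[i - 1]
        if i < len(dogs) - 1:
            is_max &= dog >= dogs[i + 1]
            is_min &= dog <= dogs[i + 1]
        # flat regions are extrema of themselves; require actual contrast
        contrast = local_max - local_min > 1e-12
        cand = (is_max | is_min) & contrast
        scale_mm = float(np.sqrt(sigmas[i] * sigmas[i + 1]))  # geometric mid-scale
        idx = np.argwhere(cand)
        centers = volume.index_to_world(idx.astype(np.float64))
        responses = dog[cand]
        features.extend(
            SalientFeature(tuple(c), scale_mm, float(r))
            for c, r in zip(centers, responses)
        )
    features.sort(key=lambda f: (-abs(f.response), f.center))
    return features[: params.target_anchor_count]


def _window_halfwidth_voxels(scale_mm: float, spacing: np.ndarray) -> np.ndarray:
    return np.maximum(1, np.round(2.0 * scale_mm / spacing)).astype(int)


def match_feature(
    feature: SalientFeature,
    source: ImageVolume,
    target: ImageVolume,
    params: SFBRParams | None = None,
) -> Correspondence | None:
    """Match one feature into the target image by local NCC.

    The source window (half-width 2 x scale) is correlated against the
    target at every integer-voxel displacement inside the search radius;
    the best displacement is refined per-axis by quadratic interpolation of
    the correlation peak.  Returns ``None`` when the window leaves either
    image or no correlation reaches the reliability threshold.
    """
    params = params or SFBRParams()
    spacing = source.spacing_arr
    ci = np.round(source.world_to_index(np.asarray(feature.center))).astype(int)
    hw = _window_halfwidth_voxels(feature.scale, spacing)
    lo = ci - hw
    hi = ci + hw + 1
    if np.any(lo < 0) or np.any(hi > np.asarray(source.dims)):
        return None
    template = source.data[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    if np.ptp(template) == 0:
        return None

    rad = np.maximum(1, np.round(params.search_radius_mm / spacing)).astype(int)
    tlo = lo - rad
    thi = hi + rad
    if np.any(tlo < 0) or np.any(thi > np.asarray(target.dims)):
        return None
    region = target.data[tlo[0] : thi[0], tlo[1] : thi[1], tlo[2] : thi[2]]

    ncc = match_template(region, template, pad_input=False)
    # ncc[d] corresponds to integer displacement d - rad (voxels)
    best = np.unravel_index(np.argmax(ncc), ncc.shape)
    best_corr = float(ncc[best])
    if not np.isfinite(best_corr) or best_corr < params.reliability_threshold:
        return None

    # quadratic sub-voxel refinement along each axis
    disp = np.asarray(best, dtype=np.float64)
    for ax in range(3):
        b = best[ax]
        if 0 < b < ncc.shape[ax] - 1:
            sl = list(best)
            sl[ax] = slice(b - 1, b + 2)
            y = ncc[tuple(sl)]
            denom = y[0] - 2 * y[1] + y[2]
            if denom < -1e-12:
                delta = 0.5 * (y[0] - y[2]) / denom
                disp[ax] = b + np.clip(delta, -0.5, 0.5)
    disp_vox = disp - rad
    disp_mm = disp_vox * spacing
    p_src = np.asarray(feature.center, dtype=np.float64)
    return Correspondence(tuple(p_src), tuple(p_src + disp_mm), best_corr)


@dataclass
class ThinPlateSplineTransform:
    """3D thin-plate spline with kernel U(r) = r (biharmonic in 3D).

    Maps source points to target points:
    ``T(p) = c + A p + sum_i w_i U(|p - anchor_i|)`` per component.
    """

    anchors: np.ndarray  # (n, 3) source anchor points, mm
    weights: np.ndarray  # (n, 3) kernel weights
    affine: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def to_dict(self) -> dict:
        return {
            "kernel": "U(r)=r",
            "anchors_mm": self.anchors.tolist(),
            "weights": self.weights.tolist(),
            "affine": self.affine.tolist(),
            "translation_mm": self.translation.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ThinPlateSplineTransform":
        return cls(
            np.asarray(d["anchors_mm"], dtype=np.float64),
            np.asarray(d["weights"], dtype=np.float64),
            np.asarray(d["affine"], dtype=np.float64),
            np.asarray(d["translation_mm"], dtype=np.float64),
        )


def fit_tps(
    correspondences: list[Correspondence] | tuple[np.ndarray, np.ndarray],
    regularization: float = 0.0,
) -> ThinPlateSplineTransform:
    """Solve the TPS linear system mapping source anchors to target points.

    With ``regularization`` (lambda) zero the transform interpolates the
    anchors exactly.  Degenerate (coplanar or coincident) anchor sets raise
    a ``ValueError`` naming the rank deficiency.
    """
    if regularization < 0:
        raise ValueError("regularization must be >= 0")
    if isinstance(correspondences, tuple):
        src, dst = (np.asarray(a, dtype=np.float64) for a in correspondences)
    else:
        src = np.asarray([c.p_source for c in correspondences], dtype=np.float64)
        dst = np.asarray([c.p_target for c in correspondences], dtype=np.float64)
    n = len(src)
    if n < 4:
        raise ValueError("fit_tps needs at least 4 correspondences")
    P = np.hstack([np.ones((n, 1)), src])  # (n, 4)
    if np.linalg.matrix_rank(P) < 4:
        raise ValueError(
            "degenerate anchors: points are coplanar or coincident "
            f"(polynomial block rank {np.linalg.matrix_rank(P)} < 4)"
        )
    r = np.linalg.norm(src[:, None, :] - src[None, :, :], axis=-1)
    if np.min(r + np.diag(np.full(n, np.inf))) <= 0:
        raise ValueError("degenerate anchors: duplicate source points")
    K = r + regularization * np.eye(n)
    A = np.zeros((n + 4, n + 4))
    A[:n, :n] = K
    A[:n, n:] = P
    A[n:, :n] = P.T
    b = np.zeros((n + 4, 3))
    b[:n] = dst
    try:
        sol = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"degenerate TPS system: {exc}") from exc
    weights = sol[:n]
    translation = sol[n]
    affine = sol[n + 1 :].T  # rows are output components
    return ThinPlateSplineTransform(src, weights, affine, translation)


def apply_tps(t: ThinPlateSplineTransform, points: np.ndarray) -> np.ndarray:
    """Evaluate the transform at world-mm ``points`` of shape (m, 3)."""
    pts = np.asarray(points, dtype=np.float64)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    out = t.translation + pts @ t.affine.T
    # kernel sum in chunks to bound the distance-matrix size
    chunk = max(1, int(4e7) // max(len(t.anchors), 1))
    for s in range(0, len(pts), chunk):
        block = pts[s : s + chunk]
        r = np.linalg.norm(block[:, None, :] - t.anchors[None, :, :], axis=-1)
        out[s : s + chunk] += r @ t.weights
    return out[0] if single else out


def find_correspondences(
    planning: ImageVolume,
    per_treatment: ImageVolume,
    params: SFBRParams | None = None,
) -> list[Correspondence]:
    """Detect features on planning and match each into per-treatment.

    Only one anchor is kept per source location (the same voxel can fire at
    several scales, and duplicate anchors make the TPS system singular).
    """
    params = params or SFBRParams()
    retained: list[Correspondence] = []
    seen: set = set()
    for f in detect_salient_features(planning, params):
        key = tuple(np.round(np.asarray(f.center), 6))
        if key in seen:
            continue
        c = match_feature(f, planning, per_treatment, params)
        if c is not None:
            seen.add(key)
            retained.append(c)
    return retained


def correspondences_to_frame(correspondences: list[Correspondence]):
    """Correspondences as a pandas table (CSV-exportable)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "src_x": [c.p_source[0] for c in correspondences],
            "src_y": [c.p_source[1] for c in correspondences],
            "src_z": [c.p_source[2] for c in correspondences],
            "dst_x": [c.p_target[0] for c in correspondences],
            "dst_y": [c.p_target[1] for c in correspondences],
            "dst_z": [c.p_target[2] for c in correspondences],
            "correlation": [c.correlation for c in correspondences],
        }
    )


def sfbr_register(
    planning: ImageVolume,
    per_treatment: ImageVolume,
    params: SFBRParams | None = None,
) -> tuple[ThinPlateSplineTransform, int]:
    """Detect on planning, match into per-treatment, fit a TPS.

    Returns the transform (planning -> per-treatment geometry) and the
    number of retained correspondences.  Raises when fewer than
    ``min_anchor_count`` reliable anchors survive.
    """
    params = params or SFBRParams()
    retained = find_correspondences(planning, per_treatment, params)
    if len(retained) < params.min_anchor_count:
        raise ValueError(
            f"insufficient anchors: {len(retained)} reliable correspondences "
            f"(need >= {params.min_anchor_count})"
        )
    transform = fit_tps(retained, params.tps_regularization)
    return transform, len(retained)
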