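"""ROI propagation between image frames.

Two routes, matching the two registration algorithms:

* mask pull-back through a displacement field (Demons route) — each target
  voxel looks up the binary mask value at the nearest source voxel of its
  displaced position;
* mesh forward-warping through a thin-plate spline (SFBR route) — the
  planning mask is converted to a triangulated iso-surface, its vertices are
  mapped by the TPS, and the warped mesh is rasterized back to a mask by a
  voxel-center ray-parity test.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import Counter

import numpy as np
from scipy import ndimage
from skimage import measure

from .core import DisplacementField, ImageVolume
from .sfbr import ThinPlateSplineTransform, apply_tps

__all__ = [
    "BinaryMask",
    "SurfaceMesh",
    "propagate_mask",
    "extract_mesh",
    "warp_mesh",
    "rasterize_mesh",
    "mesh_volume",
]


@dataclass
class BinaryMask:
    """A boolean voxel mask on a reference image grid."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    label: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError("mask must be 3D")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def spacing_arr(self) -> np.ndarray:
        return np.asarray(self.spacing)

    @property
    def origin_arr(self) -> np.ndarray:
        return np.asarray(self.origin)

    def count(self) -> int:
        return int(self.data.sum())

    def volume_mm3(self) -> float:
        return self.count() * float(np.prod(self.spacing))

    def same_grid(self, other) -> bool:
        return (
            self.dims == other.dims
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )


@dataclass
class SurfaceMesh:
    """Triangulated surface; vertices in world mm."""

    vertices: np.ndarray
    triangles: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise ValueError("triangles must be (m, 3)")
        if len(self.triangles) and self.triangles.max() >= len(self.vertices):
            raise ValueError("triangle index out of range")

    def is_closed(self) -> bool:
        edges = Counter()
        for a, b, c in self.triangles:
            for e in ((a, b), (b, c), (c, a)):
                edges[tuple(sorted(e))] += 1
        return all(n == 2 for n in edges.values())


def propagate_mask(mask: BinaryMask, dvf: DisplacementField) -> BinaryMask:
    """Pull a source-frame mask onto the target grid through ``dvf``.

    For each target voxel ``x`` the source mask value at the voxel nearest
    to ``world(x) + u(x)`` is used.  Only a sub-volume around the source
    ROI (dilated by the field's maximum magnitude plus a 2-voxel margin) is
    visited; by construction this equals the full-grid computation.
    """
    out = np.zeros(dvf.dims, dtype=bool)
    if not mask.data.any():
        return BinaryMask(out, dvf.spacing, dvf.origin, mask.label)

    src_idx = np.argwhere(mask.data)
    world_lo = mask.origin_arr + src_idx.min(axis=0) * mask.spacing_arr
    world_hi = mask.origin_arr + src_idx.max(axis=0) * mask.spacing_arr
    max_mag = float(dvf.magnitude().max())
    margin = max_mag + 2.0 * np.asarray(dvf.spacing)
    tlo = np.floor((world_lo - margin - dvf.origin_arr) / dvf.spacing_arr).astype(int)
    thi = np.ceil((world_hi + margin - dvf.origin_arr) / dvf.spacing_arr).astype(int) + 1
    tlo = np.maximum(tlo, 0)
    thi = np.minimum(thi, np.asarray(dvf.dims))
    if np.any(tlo >= thi):
        return BinaryMask(out, dvf.spacing, dvf.origin, mask.label)

    sub_idx = np.stack(
        np.meshgrid(*(np.arange(a, b) for a, b in zip(tlo, thi)), indexing="ij"),
        axis=-1,
    ).reshape(-1, 3)
    world = dvf.origin_arr + sub_idx * dvf.spacing_arr
    disp = dvf.vectors[sub_idx[:, 0], sub_idx[:, 1], sub_idx[:, 2]]
    src = np.round((world + disp - mask.origin_arr) / mask.spacing_arr).astype(int)
    ok = np.all((src >= 0) & (src < np.asarray(mask.dims)), axis=1)
    vals = np.zeros(len(sub_idx), dtype=bool)
    vals[ok] = mask.data[src[ok, 0], src[ok, 1], src[ok, 2]]
    out[sub_idx[:, 0], sub_idx[:, 1], sub_idx[:, 2]] = vals
    return BinaryMask(out, dvf.spacing, dvf.origin, mask.label)


def extract_mesh(mask: BinaryMask, smooth_sigma_voxels: float = 0.5) -> SurfaceMesh:
    """Closed iso-surface (level 0.5) of a binary mask, vertices in mm.

    The mask is zero-padded (guaranteeing closure at the grid border) and
    optionally smoothed by half a voxel before marching cubes.
    """
    if not mask.data.any():
        raise ValueError(f"cannot mesh an empty mask (label={mask.label!r})")
    vol = np.pad(mask.data.astype(np.float64), 1)
    if smooth_sigma_voxels > 0:
        vol = ndimage.gaussian_filter(vol, smooth_sigma_voxels, mode="constant")
    verts, faces, _, _ = measure.marching_cubes(vol, level=0.5, spacing=mask.spacing)
    verts = verts + mask.origin_arr - mask.spacing_arr  # undo the 1-voxel pad
    return SurfaceMesh(verts, faces)


def warp_mesh(mesh: SurfaceMesh, t: ThinPlateSplineTransform) -> SurfaceMesh:
    """Map every vertex through the TPS; triangle topology is unchanged."""
    return SurfaceMesh(apply_tps(t, mesh.vertices), mesh.triangles.copy())


def mesh_volume(mesh: SurfaceMesh) -> float:
    """Enclosed volume (mm^3) by the divergence theorem."""
    v0 = mesh.vertices[mesh.triangles[:, 0]]
    v1 = mesh.vertices[mesh.triangles[:, 1]]
    v2 = mesh.vertices[mesh.triangles[:, 2]]
    return float(abs(np.einsum("ij,ij->i", v0, np.cross(v1, v2)).sum()) / 6.0)


def rasterize_mesh(
    mesh: SurfaceMesh, grid: ImageVolume | BinaryMask, label: str = ""
) -> BinaryMask:
    """Voxel-center point-in-surface test by ray parity along the x axis.

    A voxel is inside iff its center is: rays are cast along +x at each
    (y, z) voxel-center line, triangle crossings are counted, and odd parity
    marks the interior.  Centers lying on the surface count as inside.
    Raises for open meshes (any edge not shared by exactly two triangles).
    """
    if not mesh.is_closed():
        raise ValueError("rasterize_mesh requires a closed mesh")
    dims = grid.dims
    spacing = np.asarray(grid.spacing)
    origin = np.asarray(grid.origin)
    out = np.zeros(dims, dtype=bool)

    tri = mesh.vertices[mesh.triangles]  # (m, 3 verts, 3 xyz)
    ys = origin[1] + np.arange(dims[1]) * spacing[1]
    zs = origin[2] + np.arange(dims[2]) * spacing[2]
    xs = origin[0] + np.arange(dims[0]) * spacing[0]
    # deterministic sub-nanometre jitter keeps rays off edges/vertices
    jitter = 1e-7 * spacing[1:]

    crossings: dict[tuple[int, int], list[float]] = {}
    for v0, v1, v2 in tri:
        py = np.array([v0[1], v1[1], v2[1]])
        pz = np.array([v0[2], v1[2], v2[2]])
        denom = (pz[1] - pz[2]) * (py[0] - py[2]) + (py[2] - py[1]) * (pz[0] - pz[2])
        if abs(denom) < 1e-30:
            continue  # projected triangle is degenerate; neighbours cover it
        jy0 = max(0, int(np.ceil((py.min() - origin[1]) / spacing[1] - 1e-6)))
        jy1 = min(dims[1] - 1, int(np.floor((py.max() - origin[1]) / spacing[1] + 1e-6)))
        jz0 = max(0, int(np.ceil((pz.min() - origin[2]) / spacing[2] - 1e-6)))
        jz1 = min(dims[2] - 1, int(np.floor((pz.max() - origin[2]) / spacing[2] + 1e-6)))
        if jy0 > jy1 or jz0 > jz1:
            continue
        yy = ys[jy0 : jy1 + 1][:, None] + jitter[0]
        zz = zs[jz0 : jz1 + 1][None, :] + jitter[1]
        l0 = ((pz[1] - pz[2]) * (yy - py[2]) + (py[2] - py[1]) * (zz - pz[2])) / denom
        l1 = ((pz[2] - pz[0]) * (yy - py[2]) + (py[0] - py[2]) * (zz - pz[2])) / denom
        l2 = 1.0 - l0 - l1
        inside = (l0 >= 0) & (l1 >= 0) & (l2 >= 0)
        if not inside.any():
            continue
        xhit = l0 * v0[0] + l1 * v1[0] + l2 * v2[0]
        for a, b in zip(*np.nonzero(inside)):
            crossings.setdefault((jy0 + a, jz0 + b), []).append(float(xhit[a, b]))

    for (jy, jz), hits in crossings.items():
        hits = np.sort(np.asarray(hits))
        # merge duplicate hits from shared edges
        keep = np.ones(len(hits), dtype=bool)
        keep[1:] = np.diff(hits) > 1e-9
        hits = hits[keep]
        # inside iff an odd number of crossings lie beyond the center
        counts = len(hits) - np.searchsorted(hits, xs + 1e-9, side="left")
        inside_line = (counts % 2) == 1
        on_surface = np.any(np.abs(xs[:, None] - hits[None, :]) <= 1e-9, axis=1)
        out[:, jy, jz] = inside_line | on_surface
    return BinaryMask(out, grid.spacing, grid.origin, label or getattr(mesh, "label", ""))
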