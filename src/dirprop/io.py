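"""File I/O: NIfTI-1 and MetaImage volumes, vector-field NIfTI, PLY meshes.

NIfTI is handled by nibabel.  MetaImage (.mha single-file and .mhd + .raw)
is written/read directly — only the uncompressed, axis-aligned subset used
by this toolkit is supported.
"""

from __future__ import annotations

import json
import os

import numpy as np
import nibabel as nib

from .core import ImageVolume, DisplacementField

__all__ = [
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_dvf",
    "write_dvf",
    "read_mesh_ply",
    "write_mesh_ply",
]

_MET_TO_DTYPE = {
    "MET_UCHAR": np.uint8,
    "MET_CHAR": np.int8,
    "MET_SHORT": np.int16,
    "MET_USHORT": np.uint16,
    "MET_INT": np.int32,
    "MET_UINT": np.uint32,
    "MET_FLOAT": np.float32,
    "MET_DOUBLE": np.float64,
}
_DTYPE_TO_MET = {np.dtype(v): k for k, v in _MET_TO_DTYPE.items()}


def _nifti_affine(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    aff[:3, 3] = origin
    return aff


def _grid_from_affine(aff: np.ndarray):
    rot = aff[:3, :3]
    if not np.allclose(rot, np.diag(np.diag(rot)), atol=1e-6):
        raise ValueError("only axis-aligned volumes are supported")
    spacing = tuple(float(abs(d)) for d in np.diag(rot))
    origin = tuple(float(o) for o in aff[:3, 3])
    return spacing, origin


def write_volume(volume: ImageVolume, path: str, dtype=np.float32) -> None:
    """Write a volume as NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd)."""
    low = path.lower()
    if low.endswith((".nii", ".nii.gz")):
        img = nib.Nifti1Image(
            volume.data.astype(dtype), _nifti_affine(volume.spacing, volume.origin)
        )
        nib.save(img, path)
    elif low.endswith((".mha", ".mhd")):
        _write_metaimage(volume.data.astype(dtype), volume.spacing, volume.origin, path)
    else:
        raise ValueError(f"unsupported volume extension: {path}")


def read_volume(path: str) -> ImageVolume:
    low = path.lower()
    if low.endswith((".nii", ".nii.gz")):
        img = nib.load(path)
        spacing, origin = _grid_from_affine(img.affine)
        return ImageVolume(np.asarray(img.dataobj, dtype=np.float64), spacing, origin)
    if low.endswith((".mha", ".mhd")):
        data, spacing, origin = _read_metaimage(path)
        return ImageVolume(data.astype(np.float64), spacing, origin)
    raise ValueError(f"unsupported volume extension: {path}")


def write_mask(mask, path: str) -> None:
    """Write a binary mask as a uint8 label volume."""
    write_volume(
        ImageVolume(mask.data.astype(np.float64), mask.spacing, mask.origin),
        path,
        dtype=np.uint8,
    )


def read_mask(path: str, label: str = ""):
    from .propagate import BinaryMask

    vol = read_volume(path)
    return BinaryMask(vol.data > 0.5, vol.spacing, vol.origin, label=label)


def write_dvf(dvf: DisplacementField, path: str) -> None:
    """Write a displacement field as a 4D (x,y,z,3) NIfTI."""
    if not path.lower().endswith((".nii", ".nii.gz")):
        raise ValueError("displacement fields are written as NIfTI only")
    img = nib.Nifti1Image(
        dvf.vectors.astype(np.float32), _nifti_affine(dvf.spacing, dvf.origin)
    )
    nib.save(img, path)


def read_dvf(path: str) -> DisplacementField:
    img = nib.load(path)
    spacing, origin = _grid_from_affine(img.affine)
    vec = np.asarray(img.dataobj, dtype=np.float64)
    if vec.ndim == 5:  # some writers insert a time axis
        vec = vec[:, :, :, 0, :]
    return DisplacementField(vec, spacing, origin)


def _write_metaimage(data: np.ndarray, spacing, origin, path: str) -> None:
    met_type = _DTYPE_TO_MET.get(np.dtype(data.dtype))
    if met_type is None:
        raise ValueError(f"unsupported dtype for MetaImage: {data.dtype}")
    local = path.lower().endswith(".mha")
    header = [
        "ObjectType = Image",
        "NDims = 3",
        "BinaryData = True",
        "BinaryDataByteOrderMSB = False",
        "CompressedData = False",
        "TransformMatrix = 1 0 0 0 1 0 0 0 1",
        f"Offset = {origin[0]} {origin[1]} {origin[2]}",
        f"ElementSpacing = {spacing[0]} {spacing[1]} {spacing[2]}",
        f"DimSize = {data.shape[0]} {data.shape[1]} {data.shape[2]}",
        f"ElementType = {met_type}",
    ]
    # MetaImage raw layout is x-fastest: write in Fortran order of (x,y,z)
    raw = np.asfortranarray(data).tobytes(order="F")
    if local:
        header.append("ElementDataFile = LOCAL")
        with open(path, "wb") as fh:
            fh.write(("\n".join(header) + "\n").encode())
            fh.write(raw)
    else:
        raw_name = os.path.basename(path)[:-4] + ".raw"
        header.append(f"ElementDataFile = {raw_name}")
        with open(path, "w") as fh:
            fh.write("\n".join(header) + "\n")
        with open(os.path.join(os.path.dirname(path) or ".", raw_name), "wb") as fh:
            fh.write(raw)


def _read_metaimage(path: str):
    fields: dict[str, str] = {}
    data_offset = None
    with open(path, "rb") as fh:
        while True:
            line = fh.readline()
            if not line:
                break
            text = line.decode(errors="replace").strip()
            if "=" not in text:
                continue
            key, val = (s.strip() for s in text.split("=", 1))
            fields[key] = val
            if key == "ElementDataFile":
                data_offset = fh.tell()
                break
    if "ElementDataFile" not in fields:
        raise ValueError(f"not a MetaImage header: {path}")
    dims = tuple(int(v) for v in fields["DimSize"].split())
    spacing = tuple(float(v) for v in fields.get("ElementSpacing", "1 1 1").split())
    origin = tuple(float(v) for v in fields.get("Offset", "0 0 0").split())
    dtype = _MET_TO_DTYPE[fields["ElementType"]]
    count = int(np.prod(dims))
    if fields["ElementDataFile"] == "LOCAL":
        with open(path, "rb") as fh:
            fh.seek(data_offset)
            raw = fh.read()
    else:
        raw_path = os.path.join(os.path.dirname(path) or ".", fields["ElementDataFile"])
        with open(raw_path, "rb") as fh:
            raw = fh.read()
    data = np.frombuffer(raw, dtype=dtype, count=count)
    return data.reshape(dims, order="F"), spacing, origin


def write_mesh_ply(mesh, path: str) -> None:
    """Write a triangle mesh as ASCII PLY."""
    verts = np.asarray(mesh.vertices, dtype=np.float64)
    tris = np.asarray(mesh.triangles, dtype=np.int64)
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {len(verts)}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write(f"element face {len(tris)}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        for v in verts:
            fh.write(f"{v[0]:.6f} {v[1]:.6f} {v[2]:.6f}\n")
        for t in tris:
            fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")


def read_mesh_ply(path: str):
    from .propagate import SurfaceMesh

    with open(path) as fh:
        if fh.readline().strip() != "ply":
            raise ValueError(f"not a PLY file: {path}")
        n_vert = n_face = 0
        for line in fh:
            token = line.strip()
            if token.startswith("element vertex"):
                n_vert = int(token.split()[-1])
            elif token.startswith("element face"):
                n_face = int(token.split()[-1])
            elif token == "end_header":
                break
        verts = np.array(
            [[float(x) for x in fh.readline().split()[:3]] for _ in range(n_vert)]
        )
        tris = np.array(
            [[int(x) for x in fh.readline().split()[1:4]] for _ in range(n_face)],
            dtype=np.int64,
        )
    return SurfaceMesh(verts, tris)


def save_json(obj, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)


def load_json(path: str):
    with open(path) as fh:
        return json.load(fh)
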