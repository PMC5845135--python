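"""Mesh input/output and scan pre-processing.

Triangulated surfaces are carried as :class:`trimesh.Trimesh` objects in a
canonical anatomical frame: x mediolateral, y posteroanterior (heel to toe),
z plantodorsal (sole near z = 0), coordinates in millimetres.

Supported formats are OBJ (ASCII), PLY (ASCII and binary little-endian, with
an optional per-vertex float property ``distance`` used for colour-mapped
deviation exports) and STL.  PLY is written with ``double`` precision
coordinates and STL as ASCII so that round trips preserve coordinates far
below scanner accuracy; binary STL (which the format restricts to 32-bit
floats) is still readable.

Pre-processing mirrors the standard foot-scan protocol: left feet are
mirrored into the right-foot frame, scans are cropped just above the ankle,
and foot length/breadth are measured by a principal-component analysis of
the plantar vertex subset.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import trimesh

__all__ = [
    "FootMeasurements",
    "read_mesh",
    "write_mesh",
    "mirror_mesh",
    "crop_above_ankle",
    "measure_foot",
    "validate_mesh",
]

_FORMATS = ("obj", "ply", "stl")


@dataclass(frozen=True)
class FootMeasurements:
    """Foot length and breadth (mm) from plantar-surface principal axes."""

    length: float
    breadth: float

    def __post_init__(self) -> None:
        if not (self.length >= self.breadth > 0):
            raise ValueError(
                f"expected length >= breadth > 0, got {self.length}, {self.breadth}"
            )


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    fmt = fmt.lower()
    if fmt not in _FORMATS:
        raise ValueError(f"unsupported mesh format {fmt!r}; expected one of {_FORMATS}")
    return fmt


def validate_mesh(mesh: trimesh.Trimesh) -> None:
    """Raise ``ValueError`` if the mesh violates basic validity invariants.

    Checks: finite coordinates, face indices in range, no face repeating a
    vertex, non-empty geometry.
    """
    v = np.asarray(mesh.vertices, dtype=float)
    f = np.asarray(mesh.faces, dtype=np.int64)
    if v.size == 0 or f.size == 0:
        raise ValueError("empty geometry")
    if not np.isfinite(v).all():
        raise ValueError("non-finite vertex coordinates")
    if f.min() < 0 or f.max() >= len(v):
        raise ValueError(
            f"face index out of range: max index {f.max()} with {len(v)} vertices"
        )
    if (f[:, 0] == f[:, 1]).any() or (f[:, 1] == f[:, 2]).any() or (f[:, 0] == f[:, 2]).any():
        raise ValueError("degenerate face repeating a vertex")


def read_mesh(path: str | Path, fmt: str | None = None) -> trimesh.Trimesh:
    """Read a triangulated mesh from OBJ, PLY or STL.

    Non-triangular polygons are fan-triangulated by the loader.  A PLY
    per-vertex ``distance`` property, if present, is attached as
    ``mesh.vertex_attributes['distance']``.  STL stores an unindexed
    triangle soup, so shared vertices are merged on load (vertex order is
    not preserved for STL).
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        mesh = trimesh.load(str(path), file_type=fmt, process=False, force="mesh")
    except Exception as exc:  # noqa: BLE001 - normalize loader errors
        raise ValueError(f"could not parse {path} as {fmt}: {exc}") from exc
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.vertices) == 0:
        raise ValueError(f"{path}: empty geometry")
    if fmt == "stl":
        mesh.merge_vertices()
    if fmt == "ply":
        raw = mesh.metadata.get("_ply_raw", {})
        vdata = raw.get("vertex", {}).get("data")
        names: tuple | None = None
        if isinstance(vdata, dict):
            names = tuple(vdata.keys())
        elif vdata is not None and getattr(vdata.dtype, "names", None):
            names = vdata.dtype.names
        if names and "distance" in names:
            scal = np.asarray(vdata["distance"], dtype=float).reshape(-1)
            mesh.vertex_attributes["distance"] = scal
    validate_mesh(mesh)
    return mesh


def _ply_bytes(
    vertices: np.ndarray,
    faces: np.ndarray,
    scalars: np.ndarray | None,
    binary: bool,
) -> bytes:
    """Serialize a PLY with float64 coordinates (and optional 'distance')."""
    nv, nf = len(vertices), len(faces)
    props = ["property double x", "property double y", "property double z"]
    if scalars is not None:
        props.append("property double distance")
    header = "\n".join(
        [
            "ply",
            f"format {'binary_little_endian' if binary else 'ascii'} 1.0",
            f"element vertex {nv}",
            *props,
            f"element face {nf}",
            "property list uchar int vertex_indices",
            "end_header",
        ]
    )
    buf = io.BytesIO()
    buf.write(header.encode("ascii") + b"\n")
    cols = [vertices] if scalars is None else [vertices, scalars.reshape(-1, 1)]
    vdata = np.ascontiguousarray(np.hstack(cols), dtype="<f8")
    if binary:
        buf.write(vdata.tobytes())
        fdata = np.empty(nf, dtype=[("n", "u1"), ("idx", "<i4", (3,))])
        fdata["n"] = 3
        fdata["idx"] = faces
        buf.write(fdata.tobytes())
    else:
        for row in vdata:
            buf.write((" ".join(f"{x:.17g}" for x in row) + "\n").encode("ascii"))
        for tri in faces:
            buf.write(f"3 {tri[0]} {tri[1]} {tri[2]}\n".encode("ascii"))
    return buf.getvalue()


def write_mesh(
    mesh: trimesh.Trimesh,
    path: str | Path,
    fmt: str | None = None,
    vertex_scalars: np.ndarray | None = None,
    binary: bool = True,
) -> None:
    """Write a mesh to OBJ, PLY or STL.

    Parameters
    ----------
    vertex_scalars
        Optional per-vertex scalar field (length V).  Only PLY can carry it
        (as a per-vertex ``distance`` property); passing it with another
        format raises ``ValueError``.
    binary
        For PLY, choose binary little-endian (default) or ASCII encoding.
        Ignored for OBJ/STL (OBJ is text, STL is written as ASCII).
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    validate_mesh(mesh)
    if vertex_scalars is not None:
        vertex_scalars = np.asarray(vertex_scalars, dtype=float).reshape(-1)
        if len(vertex_scalars) != len(mesh.vertices):
            raise ValueError(
                f"vertex_scalars length {len(vertex_scalars)} != V={len(mesh.vertices)}"
            )
        if fmt != "ply":
            raise ValueError("per-vertex scalars are only supported for PLY output")
    v = np.asarray(mesh.vertices, dtype=float)
    f = np.asarray(mesh.faces, dtype=np.int64)
    if fmt == "ply":
        data = _ply_bytes(v, f, vertex_scalars, binary=binary)
    elif fmt == "obj":
        data = trimesh.Trimesh(vertices=v, faces=f, process=False).export(
            file_type="obj", include_normals=False, include_texture=False
        )
        if isinstance(data, str):
            data = data.encode("ascii")
    else:  # stl, ASCII for full precision
        data = trimesh.Trimesh(vertices=v, faces=f, process=False).export(
            file_type="stl_ascii"
        )
        if isinstance(data, str):
            data = data.encode("ascii")
    try:
        path.write_bytes(data)
    except OSError as exc:
        raise OSError(f"cannot write mesh to {path}: {exc}") from exc


def mirror_mesh(mesh: trimesh.Trimesh) -> trimesh.Trimesh:
    """Reflect a mesh through the sagittal plane x = 0.

    Used to map left feet into the right-foot coordinate frame.  Face
    winding is reversed so outward orientation is preserved; the operation
    is an involution.
    """
    v = np.asarray(mesh.vertices, dtype=float).copy()
    v[:, 0] = -v[:, 0]
    f = np.asarray(mesh.faces, dtype=np.int64)[:, ::-1]
    out = trimesh.Trimesh(vertices=v, faces=f, process=False)
    for k, val in mesh.vertex_attributes.items():
        out.vertex_attributes[k] = np.asarray(val).copy()
    return out


def crop_above_ankle(mesh: trimesh.Trimesh, z_cut: float) -> trimesh.Trimesh:
    """Remove the part of the scan above ``z_cut`` (mm, just above the ankle).

    Faces entirely above the plane are removed; straddling faces are clipped
    so boundary vertices land exactly on z = z_cut.  Cropping above the
    mesh's top returns the mesh unchanged; a cut below the sole leaves
    nothing and raises ``ValueError``.
    """
    validate_mesh(mesh)
    z = np.asarray(mesh.vertices, dtype=float)[:, 2]
    if z_cut >= z.max():
        return mesh.copy()
    if z_cut <= z.min():
        raise ValueError(f"z_cut={z_cut} is below the mesh (min z {z.min():.3f})")
    out = trimesh.intersections.slice_mesh_plane(
        mesh, plane_normal=[0.0, 0.0, -1.0], plane_origin=[0.0, 0.0, z_cut]
    )
    if len(out.faces) == 0:
        raise ValueError("cropping removed the whole mesh")
    return trimesh.Trimesh(
        vertices=np.asarray(out.vertices, dtype=float),
        faces=np.asarray(out.faces, dtype=np.int64),
        process=False,
    )


def plantar_vertices(mesh: trimesh.Trimesh, plantar_tol: float = 3.0) -> np.ndarray:
    """Indices of vertices within ``plantar_tol`` mm of the lowest z value."""
    z = np.asarray(mesh.vertices, dtype=float)[:, 2]
    return np.flatnonzero(z <= z.min() + plantar_tol)


def measure_foot(mesh: trimesh.Trimesh, plantar_tol: float = 3.0) -> FootMeasurements:
    """Foot length and breadth from the plantar surface.

    The plantar subset (vertices within ``plantar_tol`` of the lowest z,
    default 3 mm, matching a typical scan-mesh resolution) is analysed with
    PCA; length is the extent along the first principal axis and breadth
    the extent along the second.  The first axis is oriented heel-to-toe
    (+y); extents are invariant to that sign choice.
    """
    validate_mesh(mesh)
    idx = plantar_vertices(mesh, plantar_tol)
    if len(idx) < 10:
        raise ValueError(
            f"only {len(idx)} plantar vertices within {plantar_tol} mm; need >= 10"
        )
    pts = np.asarray(mesh.vertices, dtype=float)[idx]
    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered / max(len(pts) - 1, 1)
    evals, evecs = np.linalg.eigh(cov)
    axes = evecs[:, ::-1]  # descending variance
    # orient first axis heel->toe (+y); tie-break by largest |component| positive
    for j in range(3):
        a = axes[:, j]
        ref = a[1] if abs(a[1]) > 1e-12 and j == 0 else a[np.argmax(np.abs(a))]
        if ref < 0:
            axes[:, j] = -a
    proj = centered @ axes
    length = float(np.ptp(proj[:, 0]))
    breadth = float(np.ptp(proj[:, 1]))
    return FootMeasurements(length=length, breadth=breadth)
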