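"""Triangle-mesh data model and STL/PLY file I/O.

Meshes are plain vertex/face arrays in millimetres with an optional
per-vertex anatomical region label (crown, root, cervical band) and, for
multi-tooth models such as dental casts, an optional per-vertex tooth id.
STL (ASCII and binary) and PLY (ASCII and binary little-endian) are
supported; only PLY carries labels, as an integer per-vertex property
``region`` (0=unlabeled, 1=crown, 2=root, 3=cervical) and optionally
``tooth`` for the tooth id.
"""

from __future__ import annotations

import enum
import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh as _trimesh

__all__ = [
    "Region",
    "TriangleMesh",
    "MeshError",
    "MeshParseError",
    "read_mesh",
    "write_mesh",
    "extract_region",
    "face_areas",
    "weld_vertices",
    "concatenate",
]


class MeshError(ValueError):
    """Invalid mesh content or an operation on an unsuitable mesh."""


class MeshParseError(MeshError):
    """A mesh file could not be parsed."""


class Region(enum.IntEnum):
    """Closed set of per-vertex anatomical region tags."""

    UNLABELED = 0
    CROWN = 1
    ROOT = 2
    CERVICAL = 3


@dataclass
class TriangleMesh:
    """Triangle surface mesh in mm, optionally labeled by anatomical region.

    Parameters
    ----------
    vertices
        ``(n, 3)`` float array of vertex positions in mm.
    faces
        ``(m, 3)`` integer array of vertex indices; faces must reference
        valid vertices and have three distinct corners.
    labels
        Optional ``(n,)`` array of :class:`Region` values, one per vertex.
    tooth_ids
        Optional ``(n,)`` integer array assigning each vertex to a tooth;
        used by multi-tooth models (casts, whole-jaw predictions).
    """

    vertices: np.ndarray
    faces: np.ndarray
    labels: np.ndarray | None = None
    tooth_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshError(f"vertices must be (n, 3), got {self.vertices.shape}")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshError(f"faces must be (m, 3), got {self.faces.shape}")
        if not np.all(np.isfinite(self.vertices)):
            raise MeshError("non-finite vertex coordinates")
        n = len(self.vertices)
        if len(self.faces) and (self.faces.min() < 0 or self.faces.max() >= n):
            raise MeshError("face index out of range")
        if len(self.faces):
            f = self.faces
            if np.any((f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])):
                raise MeshError("degenerate face (repeated vertex index)")
        if self.labels is not None:
            self.labels = np.ascontiguousarray(self.labels, dtype=np.uint8)
            if self.labels.shape != (n,):
                raise MeshError("labels must be one per vertex")
            if self.labels.max(initial=0) > max(Region):
                raise MeshError("unknown region label value")
        if self.tooth_ids is not None:
            self.tooth_ids = np.ascontiguousarray(self.tooth_ids, dtype=np.int32)
            if self.tooth_ids.shape != (n,):
                raise MeshError("tooth_ids must be one per vertex")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(
            self.vertices.copy(),
            self.faces.copy(),
            None if self.labels is None else self.labels.copy(),
            None if self.tooth_ids is None else self.tooth_ids.copy(),
        )

    def triangles(self) -> np.ndarray:
        """``(m, 3, 3)`` array of face corner coordinates."""
        return self.vertices[self.faces]

    def area(self) -> float:
        """Total surface area in mm^2."""
        return float(face_areas(self).sum())

    def bounds(self) -> np.ndarray:
        """``(2, 3)`` min/max corner of the axis-aligned bounding box."""
        return np.vstack([self.vertices.min(axis=0), self.vertices.max(axis=0)])

    def centroid(self) -> np.ndarray:
        """Mean vertex position (not the area centroid)."""
        return self.vertices.mean(axis=0)

    def transformed(self, transform) -> "TriangleMesh":
        """Return a copy with a rigid transform applied to the vertices."""
        out = self.copy()
        out.vertices = transform.apply(out.vertices)
        return out

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted per-vertex unit normals."""
        tm = _trimesh.Trimesh(self.vertices, self.faces, process=False)
        return np.asarray(tm.vertex_normals, dtype=np.float64)

    def submesh_from_vertex_mask(self, mask: np.ndarray) -> "TriangleMesh":
        """Faces whose three corners are all in ``mask``, indices re-packed."""
        mask = np.asarray(mask, dtype=bool)
        keep_faces = mask[self.faces].all(axis=1)
        faces = self.faces[keep_faces]
        used = np.zeros(self.n_vertices, dtype=bool)
        used[faces.ravel()] = True
        remap = np.cumsum(used) - 1
        return TriangleMesh(
            self.vertices[used],
            remap[faces],
            None if self.labels is None else self.labels[used],
            None if self.tooth_ids is None else self.tooth_ids[used],
        )


def face_areas(mesh: TriangleMesh) -> np.ndarray:
    """Per-face areas in mm^2 (half cross-product magnitude)."""
    tri = mesh.triangles()
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    return 0.5 * np.linalg.norm(cross, axis=1)


def extract_region(mesh: TriangleMesh, tag: Region) -> TriangleMesh:
    """Submesh of faces whose three vertices all carry ``tag``.

    Faces with mixed labels sit on region boundaries and belong to
    neither submesh. An empty result is allowed.
    """
    if mesh.labels is None:
        raise MeshError("extract_region requires a labeled mesh")
    return mesh.submesh_from_vertex_mask(mesh.labels == int(tag))


def weld_vertices(mesh: TriangleMesh, tolerance: float = 1e-6) -> TriangleMesh:
    """Merge vertices closer than ``tolerance`` (mm) by snapping to a grid.

    Degenerate faces created by the merge are dropped. Labels and tooth
    ids are taken from the first vertex of each merged group.
    """
    if tolerance <= 0 or mesh.n_vertices == 0:
        return mesh.copy()
    keys = np.round(mesh.vertices / tolerance).astype(np.int64)
    _, first, inverse = np.unique(keys, axis=0, return_index=True, return_inverse=True)
    faces = inverse[mesh.faces]
    ok = (
        (faces[:, 0] != faces[:, 1])
        & (faces[:, 1] != faces[:, 2])
        & (faces[:, 0] != faces[:, 2])
    )
    faces = faces[ok]
    # drop faces that became duplicates of one another (same vertex set)
    _, uniq = np.unique(np.sort(faces, axis=1), axis=0, return_index=True)
    faces = faces[np.sort(uniq)]
    return TriangleMesh(
        mesh.vertices[first],
        faces,
        None if mesh.labels is None else mesh.labels[first],
        None if mesh.tooth_ids is None else mesh.tooth_ids[first],
    )


def concatenate(meshes: list[TriangleMesh]) -> TriangleMesh:
    """Stack meshes into one, offsetting face indices; labels kept if all have them."""
    if not meshes:
        raise MeshError("nothing to concatenate")
    verts, faces, labels, tids = [], [], [], []
    offset = 0
    all_labeled = all(m.labels is not None for m in meshes)
    all_tids = all(m.tooth_ids is not None for m in meshes)
    for m in meshes:
        verts.append(m.vertices)
        faces.append(m.faces + offset)
        offset += m.n_vertices
        if all_labeled:
            labels.append(m.labels)
        if all_tids:
            tids.append(m.tooth_ids)
    return TriangleMesh(
        np.vstack(verts),
        np.vstack(faces),
        np.concatenate(labels) if all_labeled else None,
        np.concatenate(tids) if all_tids else None,
    )


# ---------------------------------------------------------------------------
# file I/O


def _sniff_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".ply":
        return "ply"
    if suffix == ".stl":
        return "stl"
    head = path.open("rb").read(16)
    if head.startswith(b"ply"):
        return "ply"
    return "stl"


def _validate_binary_stl(path: Path) -> None:
    """Check binary-STL header count against the file length."""
    size = path.stat().st_size
    if size < 84:
        raise MeshParseError(f"{path}: binary STL shorter than 84-byte header")
    with path.open("rb") as fh:
        fh.seek(80)
        (count,) = struct.unpack("<I", fh.read(4))
    expected = 84 + 50 * count
    if size != expected:
        raise MeshParseError(
            f"{path}: binary STL declares {count} facets "
            f"(expected {expected} bytes) but file has {size} bytes; "
            f"truncation at byte offset {min(size, expected)}"
        )


def read_mesh(path, format: str = "auto", weld_tolerance: float = 1e-6) -> TriangleMesh:
    """Read an STL or PLY file into a :class:`TriangleMesh`.

    STL stores each facet independently, so coincident vertices are
    welded at ``weld_tolerance`` (mm) to restore connectivity. A PLY
    per-vertex integer property ``region`` maps to labels and ``tooth``
    to tooth ids; PLY vertex order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _sniff_format(path) if format == "auto" else format
    if fmt not in ("stl", "ply"):
        raise MeshParseError(f"unknown mesh format {fmt!r}")

    if fmt == "stl":
        head = path.open("rb").read(512)
        looks_ascii = head.lstrip().startswith(b"solid") and b"facet" in head
        if not looks_ascii:
            _validate_binary_stl(path)
        try:
            tm = _trimesh.load(path, file_type="stl", process=False)
        except Exception as exc:  # trimesh raises assorted types on bad input
            raise MeshParseError(f"{path}: failed to parse STL ({exc})") from exc
        if not isinstance(tm, _trimesh.Trimesh) or len(tm.faces) == 0:
            raise MeshParseError(f"{path}: STL contains no triangles")
        mesh = TriangleMesh(np.asarray(tm.vertices, float), np.asarray(tm.faces))
        return weld_vertices(mesh, weld_tolerance)

    try:
        tm = _trimesh.load(path, file_type="ply", process=False)
    except Exception as exc:
        raise MeshParseError(f"{path}: failed to parse PLY ({exc})") from exc
    if not isinstance(tm, _trimesh.Trimesh) or len(tm.faces) == 0:
        raise MeshParseError(f"{path}: PLY contains no triangles")
    labels = tooth_ids = None
    raw = tm.metadata.get("_ply_raw", {}).get("vertex", {}).get("data")
    # trimesh yields a dict of columns for ASCII PLY, a structured array
    # for binary PLY
    fields = (
        raw.keys() if isinstance(raw, dict) else (raw.dtype.names or ())
    ) if raw is not None else ()
    if "region" in fields:
        labels = np.asarray(raw["region"]).reshape(-1).astype(np.uint8)
    if "tooth" in fields:
        tooth_ids = np.asarray(raw["tooth"]).reshape(-1).astype(np.int32)
    return TriangleMesh(np.asarray(tm.vertices, float), np.asarray(tm.faces), labels, tooth_ids)


def write_mesh(mesh: TriangleMesh, path, format: str = "auto") -> None:
    """Write a mesh as STL (labels dropped, with a warning) or PLY.

    PLY output is ASCII with double-precision coordinates so that a
    write/read round trip preserves geometry to well below 1e-6 mm.
    """
    path = Path(path)
    if mesh.n_faces == 0:
        raise MeshError("refusing to write an empty mesh (0 faces)")
    fmt = format
    if fmt == "auto":
        fmt = "ply" if path.suffix.lower() == ".ply" else "stl"
    if fmt == "stl":
        if mesh.labels is not None:
            warnings.warn("STL cannot store region labels; labels dropped", stacklevel=2)
        tm = _trimesh.Trimesh(mesh.vertices, mesh.faces, process=False)
        tm.export(path, file_type="stl")
        return
    if fmt != "ply":
        raise MeshError(f"unknown mesh format {fmt!r}")
    _write_ply(mesh, path)


def _write_ply(mesh: TriangleMesh, path: Path) -> None:
    # ASCII PLY with float64 coordinates; trimesh's writer is float32,
    # which would limit round-trip precision to ~1e-5 mm at arch scale.
    lines = [
        "ply",
        "format ascii 1.0",
        f"element vertex {mesh.n_vertices}",
        "property double x",
        "property double y",
        "property double z",
    ]
    if mesh.labels is not None:
        lines.append("property uchar region")
    if mesh.tooth_ids is not None:
        lines.append("property int tooth")
    lines += [
        f"element face {mesh.n_faces}",
        "property list uchar int vertex_indices",
        "end_header",
    ]
    with path.open("w") as fh:
        fh.write("\n".join(lines) + "\n")
        for i, v in enumerate(mesh.vertices):
            row = f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}"
            if mesh.labels is not None:
                row += f" {int(mesh.labels[i])}"
            if mesh.tooth_ids is not None:
                row += f" {int(mesh.tooth_ids[i])}"
            fh.write(row + "\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")
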