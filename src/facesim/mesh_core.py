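"""Triangle-mesh data model, standard-format I/O, boundary topology and rigid motion.

Meshes are open triangular shells (facial scans) with vertex coordinates in
millimetres, 0-based vertex indices and right-handed coordinates.  The module
offers only what the registration/measurement pipeline needs: loading and
saving OBJ/PLY/STL, boundary-edge extraction, area-weighted vertex normals and
rigid (optionally uniformly scaled) transformation.
"""

from __future__ import annotations

import io
import logging
import os
import struct
from dataclasses import dataclass, field

import numpy as np
import trimesh as _trimesh

logger = logging.getLogger(__name__)

__all__ = [
    "TriMesh",
    "RigidTransform",
    "MeshError",
    "MeshFormatError",
    "load_mesh",
    "save_mesh",
    "boundary_edges",
    "boundary_vertices",
    "inconsistent_winding_edges",
    "vertex_normals",
    "apply_transform",
]

# area below which a triangle is considered degenerate and dropped at load (mm^2)
_DEGENERATE_AREA = 1e-12


class MeshError(ValueError):
    """Invalid mesh content (empty mesh, bad indices, degenerate geometry)."""


class MeshFormatError(MeshError):
    """A file could not be interpreted as an indexed triangle mesh."""


@dataclass
class TriMesh:
    """Indexed triangle mesh.

    Parameters
    ----------
    vertices : (n, 3) float array
        Vertex coordinates in millimetres.
    triangles : (m, 3) int array
        Vertex-index triples, 0-based, three distinct indices each.
    normals : (n, 3) float array, optional
        Per-vertex unit normals.  Computed lazily by :func:`vertex_normals`
        when absent.
    """

    vertices: np.ndarray
    triangles: np.ndarray
    normals: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.triangles = np.ascontiguousarray(self.triangles, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshError("vertices must be an (n, 3) array")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise MeshError("triangles must be an (m, 3) array")
        if self.n_triangles and (
            self.triangles.min() < 0 or self.triangles.max() >= self.n_vertices
        ):
            raise MeshError("triangle index out of range")
        t = self.triangles
        if self.n_triangles and (
            np.any(t[:, 0] == t[:, 1])
            or np.any(t[:, 1] == t[:, 2])
            or np.any(t[:, 0] == t[:, 2])
        ):
            raise MeshError("triangle with repeated vertex index")
        if self.normals is not None:
            self.normals = np.ascontiguousarray(self.normals, dtype=np.float64)
            if self.normals.shape != self.vertices.shape:
                raise MeshError("normals must be one unit vector per vertex")
            norms = np.linalg.norm(self.normals, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-6):
                raise MeshError("normals must have unit length within 1e-6")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def copy(self) -> "TriMesh":
        return TriMesh(
            self.vertices.copy(),
            self.triangles.copy(),
            None if self.normals is None else self.normals.copy(),
        )

    def triangle_corners(self) -> np.ndarray:
        """Return an (m, 3, 3) array of triangle corner coordinates."""
        return self.vertices[self.triangles]


@dataclass(frozen=True)
class RigidTransform:
    """Rigid motion ``x -> scale * rotation @ x + translation``.

    ``scale`` defaults to 1 (pure rigid motion); a positive uniform scale is
    allowed for similarity transforms.  Composition and inversion are closed.
    """

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    scale: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "rotation", np.ascontiguousarray(self.rotation, dtype=np.float64)
        )
        object.__setattr__(
            self, "translation", np.ascontiguousarray(self.translation, dtype=np.float64)
        )
        r = self.rotation
        if r.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(r.T @ r, np.eye(3), atol=1e-9):
            raise ValueError("rotation must be orthonormal within 1e-9")
        if np.linalg.det(r) < 0:
            raise ValueError("rotation must have determinant +1 (no reflection)")
        if self.translation.shape != (3,):
            raise ValueError("translation must be a 3-vector")
        if not self.scale > 0:
            raise ValueError("scale must be positive")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map an (n, 3) or (3,) array of points."""
        points = np.asarray(points, dtype=np.float64)
        return self.scale * points @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self ∘ other`` (apply ``other`` first, then ``self``)."""
        return RigidTransform(
            rotation=self.rotation @ other.rotation,
            translation=self.scale * self.rotation @ other.translation
            + self.translation,
            scale=self.scale * other.scale,
        )

    def inverse(self) -> "RigidTransform":
        rot_inv = self.rotation.T
        return RigidTransform(
            rotation=rot_inv,
            translation=-(rot_inv @ self.translation) / self.scale,
            scale=1.0 / self.scale,
        )

    def matrix(self) -> np.ndarray:
        """Return the homogeneous 4x4 matrix (row-major)."""
        m = np.eye(4)
        m[:3, :3] = self.scale * self.rotation
        m[:3, 3] = self.translation
        return m

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "RigidTransform":
        m = np.asarray(m, dtype=np.float64)
        if m.shape != (4, 4):
            raise ValueError("expected a 4x4 matrix")
        a = m[:3, :3]
        scale = float(np.cbrt(np.linalg.det(a)))
        return cls(rotation=a / scale, translation=m[:3, 3].copy(), scale=scale)

    def rotation_angle(self) -> float:
        """Rotation angle in radians (0 for the identity)."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.arccos(np.clip(c, -1.0, 1.0)))


def _format_from_path(path: str | os.PathLike, fmt: str) -> str:
    fmt = fmt.lower()
    if fmt != "auto":
        return fmt
    ext = os.path.splitext(os.fspath(path))[1].lstrip(".").lower()
    if ext not in {"obj", "ply", "stl"}:
        raise MeshFormatError(f"cannot infer mesh format from extension {ext!r}")
    return ext


def load_mesh(path: str | os.PathLike, format: str = "auto") -> TriMesh:
    """Load an OBJ, PLY or STL file into a :class:`TriMesh`.

    Vertex order is preserved for the indexed formats (OBJ, PLY); STL is
    de-indexed on load by merging coincident vertices.  Polygonal OBJ faces
    are fan-triangulated.  Zero-area triangles are dropped with a warning.
    """
    fmt = _format_from_path(path, format)
    path = os.fspath(path)
    if not os.path.exists(path):
        raise IOError(f"mesh file not found: {path}")
    try:
        raw = _trimesh.load(path, file_type=fmt, process=False, force="mesh")
    except Exception as exc:  # noqa: BLE001 - trimesh raises heterogeneous types
        raise MeshFormatError(f"could not parse {path} as {fmt}: {exc}") from exc
    if not isinstance(raw, _trimesh.Trimesh) or len(raw.faces) == 0:
        raise MeshFormatError(f"{path} contains no triangles")
    if fmt == "stl":
        raw.merge_vertices()
    vertices = np.asarray(raw.vertices, dtype=np.float64)
    triangles = np.asarray(raw.faces, dtype=np.int64)
    if triangles.shape[1] != 3:
        raise MeshFormatError(f"{path}: non-triangular faces after triangulation")
    # drop repeated-index and zero-area triangles (scanner artifacts)
    distinct = (
        (triangles[:, 0] != triangles[:, 1])
        & (triangles[:, 1] != triangles[:, 2])
        & (triangles[:, 0] != triangles[:, 2])
    )
    corners = vertices[np.clip(triangles, 0, len(vertices) - 1)]
    areas = 0.5 * np.linalg.norm(
        np.cross(corners[:, 1] - corners[:, 0], corners[:, 2] - corners[:, 0]), axis=1
    )
    keep = distinct & (areas > _DEGENERATE_AREA)
    if not np.all(keep):
        logger.warning(
            "%s: dropped %d degenerate triangle(s)", path, int((~keep).sum())
        )
    triangles = triangles[keep]
    if len(triangles) == 0:
        raise MeshFormatError(f"{path}: no non-degenerate triangles")
    return TriMesh(vertices, triangles)


def _export_ply(mesh: TriMesh, path: str, binary: bool = True) -> None:
    # trimesh's PLY writer stores float32; write double precision ourselves.
    n_v, n_t = mesh.n_vertices, mesh.n_triangles
    fmt = "binary_little_endian" if binary else "ascii"
    header = (
        "ply\n"
        f"format {fmt} 1.0\n"
        f"element vertex {n_v}\n"
        "property double x\nproperty double y\nproperty double z\n"
        f"element face {n_t}\n"
        "property list uchar int vertex_indices\n"
        "end_header\n"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        if binary:
            fh.write(np.ascontiguousarray(mesh.vertices, dtype="<f8").tobytes())
            tri = np.asarray(mesh.triangles, dtype="<i4")
            buf = io.BytesIO()
            counts = struct.pack("B", 3)
            for row in tri:
                buf.write(counts)
                buf.write(row.tobytes())
            fh.write(buf.getvalue())
        else:
            lines = ["%.17g %.17g %.17g" % tuple(v) for v in mesh.vertices]
            lines += ["3 %d %d %d" % tuple(t) for t in mesh.triangles]
            fh.write(("\n".join(lines) + "\n").encode("ascii"))


def save_mesh(mesh: TriMesh, path: str | os.PathLike, format: str = "auto") -> None:
    """Write a mesh to OBJ (ASCII), PLY (binary little-endian) or STL (binary).

    The written file round-trips through :func:`load_mesh` with identical
    topology and vertices reproduced within the format's precision.
    """
    if mesh.n_vertices == 0 or mesh.n_triangles == 0:
        raise MeshError("refusing to write an empty mesh")
    fmt = _format_from_path(path, format)
    path = os.fspath(path)
    if fmt == "ply":
        _export_ply(mesh, path, binary=True)
        return
    tm = _trimesh.Trimesh(mesh.vertices, mesh.triangles, process=False)
    try:
        tm.export(path, file_type=fmt)
    except OSError as exc:
        raise IOError(f"cannot write {path}: {exc}") from exc


def _edge_counts(triangles: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return (unique undirected edges, incidence counts)."""
    e = np.concatenate(
        [triangles[:, [0, 1]], triangles[:, [1, 2]], triangles[:, [2, 0]]], axis=0
    )
    e = np.sort(e, axis=1)
    return np.unique(e, axis=0, return_counts=True)


def boundary_edges(mesh: TriMesh) -> set[tuple[int, int]]:
    """Edges incident to exactly one triangle (the open border and hole rims)."""
    if mesh.n_triangles == 0:
        return set()
    edges, counts = _edge_counts(mesh.triangles)
    return {tuple(int(i) for i in e) for e in edges[counts == 1]}


def boundary_vertices(mesh: TriMesh) -> np.ndarray:
    """Sorted array of vertex indices lying on some boundary edge."""
    be = boundary_edges(mesh)
    if not be:
        return np.empty(0, dtype=np.int64)
    return np.unique(np.asarray(sorted(be), dtype=np.int64).ravel())


def inconsistent_winding_edges(mesh: TriMesh) -> int:
    """Count interior edges whose two incident triangles disagree in winding.

    Consistently wound neighbors traverse a shared edge in opposite
    directions.  Scanner pipelines normally deliver consistent winding; this
    check only reports (no repair).
    """
    directed = np.concatenate(
        [mesh.triangles[:, [0, 1]], mesh.triangles[:, [1, 2]],
         mesh.triangles[:, [2, 0]]], axis=0
    )
    _, counts = np.unique(directed, axis=0, return_counts=True)
    # a directed edge occurring twice means both triangles run it the same way
    n_bad = int((counts >= 2).sum())
    if n_bad:
        logger.warning("%d edge(s) with inconsistent triangle winding", n_bad)
    return n_bad


def vertex_normals(mesh: TriMesh) -> np.ndarray:
    """Area-weighted per-vertex unit normals following triangle winding.

    Isolated vertices (no incident non-degenerate triangle) get a NaN normal;
    callers using signed distances must exclude them.
    """
    corners = mesh.triangle_corners()
    # cross product length = 2*area, so summing raw cross products is
    # exactly the area weighting
    face_n = np.cross(corners[:, 1] - corners[:, 0], corners[:, 2] - corners[:, 0])
    acc = np.zeros_like(mesh.vertices)
    for k in range(3):
        np.add.at(acc, mesh.triangles[:, k], face_n)
    lengths = np.linalg.norm(acc, axis=1)
    ok = lengths > 0
    normals = np.full_like(acc, np.nan)
    normals[ok] = acc[ok] / lengths[ok, None]
    if not np.all(ok):
        logger.warning("%d vertex normal(s) undefined (isolated vertices)",
                       int((~ok).sum()))
    return normals


def apply_transform(mesh: TriMesh, t: RigidTransform) -> TriMesh:
    """Return a new mesh with vertices mapped by ``t``; topology unchanged.

    Normals, if present, are rotated (scale and translation do not affect
    unit normals).
    """
    normals = None
    if mesh.normals is not None:
        normals = mesh.normals @ t.rotation.T
    return TriMesh(t.apply(mesh.vertices), mesh.triangles.copy(), normals)
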