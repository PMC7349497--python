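"""Triangle-mesh container, Wavefront OBJ I/O, and topology inspection.

The whole pipeline operates on :class:`TriangleMesh`: an indexed triangle
surface with vertex coordinates in centimeters and faces wound
counter-clockwise when viewed from outside the enclosed solid.  Scanner
exports routinely duplicate vertices along seams, so :func:`clean` welds
coincident vertices and drops degenerate faces before any topological
analysis (hole detection requires welded connectivity).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "TriangleMesh",
    "MeshReport",
    "MeshParseError",
    "read_obj",
    "write_obj",
    "clean",
    "inspect_mesh",
]


class MeshParseError(ValueError):
    """Raised for malformed OBJ content; message names the offending line."""


@dataclass
class TriangleMesh:
    """Indexed triangle surface.

    Parameters
    ----------
    vertices : (n, 3) float array
        Vertex positions in centimeters.
    faces : (m, 3) int array
        Vertex indices per triangle, counter-clockwise from outside.
    label : str, optional
        Free-form tag (e.g. the food item a segment belongs to).
    """

    vertices: np.ndarray
    faces: np.ndarray
    label: str | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if len(self.faces):
            if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
                raise ValueError("face index out of range")
            same = (
                (self.faces[:, 0] == self.faces[:, 1])
                | (self.faces[:, 1] == self.faces[:, 2])
                | (self.faces[:, 2] == self.faces[:, 0])
            )
            if same.any():
                raise ValueError(
                    f"face {int(np.flatnonzero(same)[0])} repeats a vertex"
                )

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(self.vertices.copy(), self.faces.copy(), self.label)

    def face_normals(self) -> np.ndarray:
        """Unnormalized face normals (cross product of edge vectors)."""
        v = self.vertices
        f = self.faces
        return np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])

    def face_areas(self) -> np.ndarray:
        return 0.5 * np.linalg.norm(self.face_normals(), axis=1)


@dataclass
class MeshReport:
    """Topological health summary of a mesh."""

    n_vertices: int
    n_faces: int
    n_boundary_edges: int
    n_connected_components: int
    is_edge_manifold: bool
    is_watertight: bool
    is_consistently_oriented: bool


def read_obj(path) -> TriangleMesh:
    """Read an ASCII Wavefront OBJ file into a :class:`TriangleMesh`.

    Only ``v`` and ``f`` records are interpreted; normals, texture
    coordinates and materials are ignored.  Polygonal faces are
    fan-triangulated from their first vertex.  OBJ 1-based indices are
    converted to 0-based (negative relative indices are resolved against
    the vertices read so far).

    Raises
    ------
    FileNotFoundError
        If *path* does not exist.
    MeshParseError
        For a non-numeric vertex coordinate or an out-of-range face
        index; the message carries the 1-based line number.
    """
    vertices: list[tuple[float, float, float]] = []
    faces: list[tuple[int, int, int]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            tag = parts[0]
            if tag == "v":
                if len(parts) < 4:
                    raise MeshParseError(f"line {lineno}: vertex needs 3 coordinates")
                try:
                    xyz = tuple(float(p) for p in parts[1:4])
                except ValueError as exc:
                    raise MeshParseError(
                        f"line {lineno}: non-numeric vertex coordinate"
                    ) from exc
                vertices.append(xyz)
            elif tag == "f":
                idx: list[int] = []
                for token in parts[1:]:
                    head = token.split("/", 1)[0]
                    try:
                        i = int(head)
                    except ValueError as exc:
                        raise MeshParseError(
                            f"line {lineno}: non-integer face index {head!r}"
                        ) from exc
                    if i < 0:
                        i = len(vertices) + i  # OBJ relative index
                    else:
                        i = i - 1
                    if i < 0 or i >= len(vertices):
                        raise MeshParseError(
                            f"line {lineno}: face index {head} out of range"
                        )
                    idx.append(i)
                if len(idx) < 3:
                    raise MeshParseError(f"line {lineno}: face needs >=3 vertices")
                for k in range(1, len(idx) - 1):  # fan triangulation
                    faces.append((idx[0], idx[k], idx[k + 1]))
            # silently skip vn/vt/usemtl/o/g/s/...
    verts = np.array(vertices, dtype=np.float64).reshape(-1, 3)
    tris = np.array(faces, dtype=np.int64).reshape(-1, 3)
    return TriangleMesh(verts, tris)


def write_obj(mesh: TriangleMesh, path) -> None:
    """Write *mesh* as ASCII OBJ with full float precision (repr, >=9 s.d.)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# mealscan triangle mesh\n")
        for x, y, z in mesh.vertices:
            fh.write(f"v {float(x)!r} {float(y)!r} {float(z)!r}\n")
        for a, b, c in mesh.faces:
            fh.write(f"f {int(a) + 1} {int(b) + 1} {int(c) + 1}\n")


def clean(
    mesh: TriangleMesh,
    weld_tolerance: float = 1e-6,
    area_tolerance: float = 1e-10,
) -> TriangleMesh:
    """Weld coincident vertices and drop degenerate faces.

    Vertices closer than *weld_tolerance* (cm) are merged (grid rounding);
    faces that repeat a vertex after welding or whose area falls below
    *area_tolerance* (cm^2) are removed.  Unreferenced vertices are kept
    out of the output.
    """
    if mesh.n_vertices == 0:
        return mesh.copy()
    key = np.round(mesh.vertices / weld_tolerance).astype(np.int64)
    _, first, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
    # keep first-occurrence order so cleaning an already-clean mesh is identity
    order = np.argsort(first)
    rank = np.empty(len(first), dtype=np.int64)
    rank[order] = np.arange(len(first))
    verts = mesh.vertices[first[order]]
    faces = rank[inverse][mesh.faces] if len(mesh.faces) else mesh.faces.copy()
    if len(faces):
        ok = (
            (faces[:, 0] != faces[:, 1])
            & (faces[:, 1] != faces[:, 2])
            & (faces[:, 2] != faces[:, 0])
        )
        faces = faces[ok]
        m = TriangleMesh(verts, faces, mesh.label)
        faces = faces[m.face_areas() > area_tolerance]
    # drop unreferenced vertices
    used = np.zeros(len(verts), dtype=bool)
    if len(faces):
        used[faces.ravel()] = True
    remap = np.cumsum(used) - 1
    return TriangleMesh(verts[used], remap[faces] if len(faces) else faces, mesh.label)


def _edge_incidence(faces: np.ndarray):
    """Undirected edges with per-edge face counts.

    Returns (unique_edges (e,2) sorted pairs, counts (e,)).
    """
    if len(faces) == 0:
        return np.empty((0, 2), dtype=np.int64), np.empty(0, dtype=np.int64)
    e = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    e = np.sort(e, axis=1)
    uniq, counts = np.unique(e, axis=0, return_counts=True)
    return uniq, counts


def inspect_mesh(mesh: TriangleMesh) -> MeshReport:
    """Compute a :class:`MeshReport` from edge incidence.

    A boundary edge is used by exactly one face; an edge used by more
    than two faces breaks edge-manifoldness.  Watertight means zero
    boundary edges on an edge-manifold mesh.  Orientation is consistent
    when no directed half-edge occurs twice.
    """
    edges, counts = _edge_incidence(mesh.faces)
    n_boundary = int((counts == 1).sum())
    manifold = bool((counts <= 2).all()) if len(counts) else True
    watertight = manifold and n_boundary == 0 and mesh.n_faces > 0

    # connected components over referenced vertices
    if len(edges):
        n = mesh.n_vertices
        ones = np.ones(len(edges))
        adj = coo_matrix((ones, (edges[:, 0], edges[:, 1])), shape=(n, n))
        n_comp_all, labels = connected_components(adj, directed=False)
        used = np.zeros(n, dtype=bool)
        used[mesh.faces.ravel()] = True
        n_components = len(np.unique(labels[used]))
    else:
        n_components = 0

    # orientation: each directed half-edge must be unique
    if len(mesh.faces):
        d = np.concatenate(
            [mesh.faces[:, [0, 1]], mesh.faces[:, [1, 2]], mesh.faces[:, [2, 0]]]
        )
        _, dcounts = np.unique(d, axis=0, return_counts=True)
        oriented = bool((dcounts == 1).all())
    else:
        oriented = True

    return MeshReport(
        n_vertices=mesh.n_vertices,
        n_faces=mesh.n_faces,
        n_boundary_edges=n_boundary,
        n_connected_components=n_components,
        is_edge_manifold=manifold,
        is_watertight=watertight,
        is_consistently_oriented=oriented,
    )
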