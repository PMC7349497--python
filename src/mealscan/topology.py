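"""Hole-boundary detection and scan segmentation.

Holes in a scan show up as cycles of boundary edges (edges used by
exactly one face).  :func:`find_holes` traces each cycle, oriented so
that the existing surface lies to the left of the traversal, and
annotates every boundary vertex with its front angle theta — the
interior angle (on the hole side) between the two boundary edges meeting
there.  Theta drives the advancing-front filling rules.

Segmentation replaces the interactive steps a scan operator would
otherwise perform in a mesh editor: :func:`segment_plate` removes the
support plate with a RANSAC plane fit, and :func:`split_items` divides
the remaining food surface between user-supplied seed points by geodesic
flood fill, cutting at sharp concave creases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components, dijkstra

from .mesh import TriangleMesh, _edge_incidence

__all__ = [
    "BoundaryLoop",
    "PlateConfig",
    "SegmentationResult",
    "NonManifoldError",
    "NoPlateError",
    "find_holes",
    "segment_plate",
    "split_items",
    "submesh",
]


class NonManifoldError(ValueError):
    """An edge is shared by more than two faces."""


class NoPlateError(ValueError):
    """No plane supported by enough vertices was found."""


@dataclass
class BoundaryLoop:
    """One closed cycle of hole-boundary vertices.

    ``vertices[i]`` is preceded by ``vertices[i-1]`` and followed by
    ``vertices[(i+1) % k]``; every consecutive pair is a boundary edge.
    ``angles[i]`` is the front angle theta_i in degrees, measured on the
    hole side, in (0, 360).  ``normal`` is the loop's Newell normal —
    the traversal is counter-clockwise around it — used as the reference
    axis when classifying reflex angles on non-planar boundaries.
    """

    vertices: np.ndarray  # (k,) int
    angles: np.ndarray  # (k,) float degrees
    normal: np.ndarray  # (3,) unit vector

    def __len__(self) -> int:
        return len(self.vertices)


def _newell_normal(points: np.ndarray) -> np.ndarray:
    """Area-weighted polygon normal; traversal is CCW around it."""
    shifted = np.roll(points, -1, axis=0)
    n = np.cross(points, shifted).sum(axis=0)
    norm = np.linalg.norm(n)
    if norm < 1e-15:
        return np.array([0.0, 0.0, 1.0])
    return n / norm


def loop_angles(points: np.ndarray, normal: np.ndarray) -> np.ndarray:
    """Front angles (degrees) at every vertex of a cycle.

    The base angle between the two boundary edge vectors at each vertex
    is measured in 3D; a vertex is reflex (theta > 180) when the cross
    product of the forward and backward edge vectors points against
    *normal*.
    """
    k = len(points)
    fwd = np.roll(points, -1, axis=0) - points
    bwd = np.roll(points, 1, axis=0) - points
    out = np.empty(k)
    for i in range(k):
        a, b = fwd[i], bwd[i]
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        if na < 1e-15 or nb < 1e-15:
            out[i] = 180.0
            continue
        cosang = np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0)
        base = np.degrees(np.arccos(cosang))
        if np.dot(np.cross(a, b), normal) < 0:
            base = 360.0 - base
        out[i] = base
    return out


def find_holes(mesh: TriangleMesh) -> list[BoundaryLoop]:
    """Trace every hole boundary cycle of an edge-manifold mesh.

    Each boundary edge appears in exactly one face as a directed
    half-edge; traversing the *reversed* direction puts the hole on the
    left of the traversal (counter-clockwise around the loop's Newell
    normal), so triangles filling the hole can be wound in traversal
    order and match the mesh orientation.

    Raises
    ------
    NonManifoldError
        If any edge is used by more than two faces.
    """
    edges, counts = _edge_incidence(mesh.faces)
    bad = counts > 2
    if bad.any():
        u, v = edges[np.flatnonzero(bad)[0]]
        raise NonManifoldError(f"edge ({u}, {v}) is used by more than 2 faces")
    if not (counts == 1).any():
        return []

    boundary = {tuple(e) for e in edges[counts == 1]}
    # boundary half-edges, reversed so the hole sits on the left of the
    # traversal; a pinch vertex may start several of them
    succ: dict[int, list[int]] = {}
    for f in mesh.faces:
        for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            if (min(a, b), max(a, b)) in boundary:
                succ.setdefault(int(b), []).append(int(a))
    for targets in succ.values():
        targets.sort()

    n_halfedges = sum(len(t) for t in succ.values())
    loops: list[BoundaryLoop] = []
    remaining = {v: list(t) for v, t in succ.items()}
    for start in sorted(succ):
        while remaining.get(start):
            cycle = [start]
            cur = remaining[start].pop(0)
            steps = 0
            while cur != start:
                cycle.append(cur)
                nxt_list = remaining.get(cur)
                if not nxt_list:
                    raise NonManifoldError(
                        f"boundary traversal stuck at vertex {cur}"
                    )
                cur = nxt_list.pop(0)
                steps += 1
                if steps > n_halfedges:
                    raise NonManifoldError("boundary traversal does not close")
            if len(cycle) < 3:
                continue
            verts = np.asarray(cycle, dtype=np.int64)
            pts = mesh.vertices[verts]
            normal = _newell_normal(pts)
            loops.append(BoundaryLoop(verts, loop_angles(pts, normal), normal))
    return loops


@dataclass
class PlateConfig:
    """RANSAC plane-fit settings for plate removal.

    plane_tolerance : inlier distance to the fitted plane (cm).
    min_inlier_fraction : minimum fraction of vertices supporting the
        plane before it is accepted as the plate.
    n_iterations : RANSAC draws.
    seed : RNG seed, fixed for reproducibility.
    crease_angle : dihedral angle (degrees) above which an edge blocks
        the flood fill in :func:`split_items`.
    """

    plane_tolerance: float = 0.3
    min_inlier_fraction: float = 0.2
    n_iterations: int = 200
    seed: int = 0
    crease_angle: float = 50.0


@dataclass
class SegmentationResult:
    plate: TriangleMesh | None
    items: list[TriangleMesh]
    seeds: list[np.ndarray] = field(default_factory=list)


def submesh(mesh: TriangleMesh, face_mask: np.ndarray, label=None) -> TriangleMesh:
    """Extract the faces selected by *face_mask* with compacted vertices."""
    faces = mesh.faces[face_mask]
    used = np.unique(faces)
    remap = np.full(mesh.n_vertices, -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return TriangleMesh(mesh.vertices[used], remap[faces], label)


def _fit_plane(points: np.ndarray):
    """Least-squares plane through *points*: returns (origin, unit normal)."""
    c = points.mean(axis=0)
    _, _, vt = np.linalg.svd(points - c, full_matrices=False)
    return c, vt[-1]


def segment_plate(mesh: TriangleMesh, cfg: PlateConfig | None = None) -> SegmentationResult:
    """Split a scan into the support plate and the food resting on it.

    A RANSAC plane fit finds the dominant near-planar surface; faces
    whose three vertices all lie within ``cfg.plane_tolerance`` of the
    refined plane become the plate, everything else the food.  Removing
    the plate opens a boundary on the food mesh that is then closed by
    hole filling.

    Raises
    ------
    NoPlateError
        When no candidate plane reaches ``cfg.min_inlier_fraction``.
    """
    cfg = cfg or PlateConfig()
    v = mesh.vertices
    n = len(v)
    rng = np.random.default_rng(cfg.seed)
    best_inliers = None
    best_count = -1
    for _ in range(cfg.n_iterations):
        i, j, k = rng.choice(n, size=3, replace=False)
        nrm = np.cross(v[j] - v[i], v[k] - v[i])
        norm = np.linalg.norm(nrm)
        if norm < 1e-12:
            continue
        nrm = nrm / norm
        dist = np.abs((v - v[i]) @ nrm)
        inl = dist < cfg.plane_tolerance
        cnt = int(inl.sum())
        if cnt > best_count:
            best_count = cnt
            best_inliers = inl
    if best_inliers is None or best_count < cfg.min_inlier_fraction * n:
        raise NoPlateError(
            f"no plate found: best plane supports {max(best_count, 0)}/{n} vertices"
        )
    origin, normal = _fit_plane(v[best_inliers])
    dist = np.abs((v - origin) @ normal)
    on_plane = dist < cfg.plane_tolerance
    plate_faces = on_plane[mesh.faces].all(axis=1)
    if plate_faces.all():
        return SegmentationResult(
            plate=submesh(mesh, plate_faces, "plate"), items=[]
        )
    plate = submesh(mesh, plate_faces, "plate")
    food = submesh(mesh, ~plate_faces, "food")
    return SegmentationResult(plate=plate, items=[food])


def _face_adjacency(mesh: TriangleMesh):
    """Pairs of faces sharing an edge: returns (pairs (p,2), shared edge ids)."""
    faces = mesh.faces
    e = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    e = np.sort(e, axis=1)
    fid = np.tile(np.arange(len(faces)), 3)
    order = np.lexsort((e[:, 1], e[:, 0]))
    e, fid = e[order], fid[order]
    same = (e[:-1] == e[1:]).all(axis=1)
    pairs = np.stack([fid[:-1][same], fid[1:][same]], axis=1)
    return pairs


def split_items(
    mesh: TriangleMesh,
    seeds,
    crease_angle: float = 50.0,
) -> list[TriangleMesh]:
    """Partition a food mesh into one sub-mesh per seed point.

    Each face is assigned to the seed with the smallest geodesic
    distance over the face-adjacency graph (edge weight: centroid
    distance), with adjacency cut wherever the dihedral angle between
    neighbouring faces exceeds *crease_angle* degrees — the junction
    between two touching food items is such a crease.  Faces unreachable
    from every seed fall back to the Euclidean-nearest seed.
    """
    seeds = [np.asarray(s, dtype=float).reshape(3) for s in seeds]
    if not seeds:
        raise ValueError("at least one seed point is required")
    for i in range(len(seeds)):
        for j in range(i + 1, len(seeds)):
            if np.allclose(seeds[i], seeds[j]):
                raise ValueError("seed points must be distinct")

    centroids = mesh.vertices[mesh.faces].mean(axis=1)
    normals = mesh.face_normals()
    nlen = np.linalg.norm(normals, axis=1, keepdims=True)
    normals = normals / np.maximum(nlen, 1e-15)

    pairs = _face_adjacency(mesh)
    if len(pairs):
        cosd = np.einsum("ij,ij->i", normals[pairs[:, 0]], normals[pairs[:, 1]])
        dihedral = np.degrees(np.arccos(np.clip(cosd, -1.0, 1.0)))
        keep = dihedral <= crease_angle
        pairs = pairs[keep]

    nf = mesh.n_faces
    if len(pairs):
        w = np.linalg.norm(centroids[pairs[:, 0]] - centroids[pairs[:, 1]], axis=1)
        graph = coo_matrix((w, (pairs[:, 0], pairs[:, 1])), shape=(nf, nf))
    else:
        graph = coo_matrix((nf, nf))

    seed_faces = [
        int(np.argmin(np.linalg.norm(centroids - s, axis=1))) for s in seeds
    ]
    dist = dijkstra(graph, directed=False, indices=seed_faces)
    assign = np.argmin(dist, axis=0)
    unreachable = ~np.isfinite(dist.min(axis=0))
    if unreachable.any():
        d_euclid = np.stack(
            [np.linalg.norm(centroids - s, axis=1) for s in seeds]
        )
        assign[unreachable] = np.argmin(d_euclid[:, unreachable], axis=0)

    return [
        submesh(mesh, assign == i, label=f"item_{i}")
        for i in range(len(seeds))
    ]
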