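"""Advancing-front hole filling with harmonic patch refinement.

A hole is closed by growing triangles inward from its boundary (the
"front").  Each iteration selects the front vertex with the smallest
front angle theta and applies one of three rules:

* theta <= 75 deg   — connect the two neighbouring front vertices
  directly into one triangle (no new vertex);
* 75 < theta <= 135 — add one new vertex on the bisector of the two
  boundary edges, in their plane, at the average of the two edge
  lengths, forming two triangles;
* theta > 135       — add two new vertices on the trisectors, same
  plane and length, forming three triangles.

A candidate vertex that lands within ``epsilon`` of an existing front
vertex is replaced by that vertex (the merge keeps the patch from
self-overlapping and from accumulating clutter); among several vertices
inside the radius the one yielding the triangle closest to equilateral
wins.  When a merge reconnects the front to a non-adjacent vertex the
front splits into two loops, each filled in turn.

Once a patch is topologically closed its interior vertices are
repositioned by solving the discrete Laplace equation with cotangent
weights — for every free vertex v_i with 1-ring N_i,

    sum_{v_j in N_i}  w_ij (f(v_j) - f(v_i)) = 0,
    w_ij = cot(alpha_ij) + cot(beta_ij),

once per coordinate, with the hole boundary (and the rest of the mesh)
held fixed.  This minimizes the discrete Dirichlet energy of the patch;
planar hole boundaries therefore stay exactly planar.  On strongly
curved holes the harmonic patch sags toward the boundary plane — a
known bias of membrane-style fills that is reported, not corrected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix, csc_matrix
from scipy.sparse.linalg import spsolve

from .mesh import TriangleMesh, clean
from .topology import BoundaryLoop, find_holes

__all__ = [
    "FillConfig",
    "PatchFill",
    "FillError",
    "afm_fill",
    "harmonic_refine",
    "fill_all_holes",
]


class FillError(RuntimeError):
    """The advancing front failed to close a hole."""


@dataclass
class FillConfig:
    """Hole-filling parameters.

    epsilon_factor : merge radius as a fraction of the loop's mean
        boundary-edge length (the merge radius itself has units of cm).
    max_iter_factor : iteration budget per hole, times the loop size.
    cot_clamp : cotangent weights are clamped to [-cot_clamp, cot_clamp]
        so skinny triangles cannot blow up the linear system.
    min_angle : angles below this (radians) are treated as min_angle
        when taking cotangents.
    """

    epsilon_factor: float = 0.5
    max_iter_factor: int = 10
    cot_clamp: float = 1e6
    min_angle: float = 1e-4


@dataclass
class PatchFill:
    """Triangles and vertices created while closing one hole.

    ``mesh`` is the input mesh with the patch appended (original
    vertices and faces untouched, in their original order).  Vertices in
    ``new_vertices`` are interior to the patch and free to move during
    refinement; ``fixed`` holds the hole's boundary vertices.
    """

    mesh: TriangleMesh
    new_vertices: np.ndarray  # (p,) indices into mesh.vertices
    new_faces: np.ndarray  # (q,) indices into mesh.faces
    fixed: np.ndarray  # (k,) boundary vertex indices


def _rotate(vec: np.ndarray, axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation of *vec* about unit *axis*."""
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return (
        vec * c
        + np.cross(axis, vec) * s
        + axis * np.dot(axis, vec) * (1.0 - c)
    )


def _triangle_quality(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray) -> float:
    """1 for equilateral, -> 0 for degenerate: 4*sqrt(3)*A / sum(l^2)."""
    l2 = (
        np.dot(p1 - p0, p1 - p0)
        + np.dot(p2 - p1, p2 - p1)
        + np.dot(p0 - p2, p0 - p2)
    )
    if l2 < 1e-30:
        return 0.0
    area = 0.5 * np.linalg.norm(np.cross(p1 - p0, p2 - p0))
    return 4.0 * np.sqrt(3.0) * area / l2


def _simplify_cycles(cyc: list[int]) -> list[list[int]]:
    """Collapse consecutive duplicates, split at repeated vertices.

    Merging a candidate vertex into an existing front vertex makes the
    front cycle non-simple; splitting at the repeat yields the two
    simple sub-loops.  Cycles shorter than 3 are fully closed already.
    """
    out: list[int] = []
    for v in cyc:
        if out and v == out[-1]:
            continue
        out.append(v)
    while len(out) > 1 and out[0] == out[-1]:
        out.pop()
    pos: dict[int, int] = {}
    for i, v in enumerate(out):
        if v in pos:
            a = out[pos[v] : i]
            b = out[: pos[v]] + out[i:]
            return _simplify_cycles(a) + _simplify_cycles(b)
        pos[v] = i
    return [out] if len(out) >= 3 else []


def _candidate_positions(
    p_i: np.ndarray,
    a_hat: np.ndarray,
    mean_len: float,
    theta_deg: float,
    axis: np.ndarray,
    n_new: int,
) -> list[np.ndarray]:
    """Bisector/trisector vertices at a front vertex.

    New vertices sit in the plane spanned by the two boundary edges
    (the rotation plane of *axis*), at distances equal to the mean edge
    length, on the rays dividing theta into ``n_new + 1`` equal parts.
    """
    theta = np.radians(theta_deg)
    return [
        p_i + mean_len * _rotate(a_hat, axis, theta * k / (n_new + 1))
        for k in range(1, n_new + 1)
    ]


class _Front:
    """Mutable advancing-front state for one original hole.

    Tracks, besides the active loops, two local quantities that keep
    the fill on the hole side of curved boundaries:

    * per-vertex surface wedge — the summed corner angles of the faces
      currently incident to a vertex; the hole wedge complements it, so
      a small 3D angle whose complement fits 360 deg far better is
      recognized as reflex even where the loop-plane side test fails
      (e.g. around the apex of a cone);
    * per-edge usage counts — an edge already shared by two faces must
      not receive a third, so direct connections that would duplicate
      an existing triangle are demoted to vertex-adding rules.
    """

    def __init__(self, mesh: TriangleMesh, loop: BoundaryLoop):
        self.verts: list[np.ndarray] = [v for v in mesh.vertices]
        self.normal = np.asarray(loop.normal, dtype=float)
        self.loops: list[list[int]] = [list(int(v) for v in loop.vertices)]
        self.new_faces: list[tuple[int, int, int]] = []
        self.new_vertices: list[int] = []

        self.wedge = np.zeros(mesh.n_vertices)  # degrees, grown on add_vertex
        v = mesh.vertices
        for f in mesh.faces:
            p = v[f]
            for c in range(3):
                u1 = p[(c + 1) % 3] - p[c]
                u2 = p[(c + 2) % 3] - p[c]
                l1, l2 = np.linalg.norm(u1), np.linalg.norm(u2)
                if l1 < 1e-15 or l2 < 1e-15:
                    continue
                self.wedge[f[c]] += np.degrees(
                    np.arccos(np.clip(np.dot(u1, u2) / (l1 * l2), -1, 1))
                )
        self.edge_use: dict[tuple[int, int], int] = {}
        for f in mesh.faces:
            for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
                key = (min(a, b), max(a, b))
                self.edge_use[key] = self.edge_use.get(key, 0) + 1

    def positions(self, ids) -> np.ndarray:
        return np.array([self.verts[i] for i in ids])

    def edge_count(self, a: int, b: int) -> int:
        return self.edge_use.get((min(a, b), max(a, b)), 0)

    def add_vertex(self, p: np.ndarray) -> int:
        self.verts.append(np.asarray(p, dtype=float))
        self.wedge = np.append(self.wedge, 0.0)
        idx = len(self.verts) - 1
        self.new_vertices.append(idx)
        return idx

    def add_face(self, a: int, b: int, c: int) -> None:
        if a == b or b == c or c == a:
            return  # merge produced a degenerate fan triangle; skip
        self.new_faces.append((a, b, c))
        pa, pb, pc = self.verts[a], self.verts[b], self.verts[c]
        for i, (p, q, r) in (
            (a, (pa, pb, pc)),
            (b, (pb, pc, pa)),
            (c, (pc, pa, pb)),
        ):
            u1, u2 = q - p, r - p
            l1, l2 = np.linalg.norm(u1), np.linalg.norm(u2)
            if l1 > 1e-15 and l2 > 1e-15:
                self.wedge[i] += np.degrees(
                    np.arccos(np.clip(np.dot(u1, u2) / (l1 * l2), -1, 1))
                )
        for u, w in ((a, b), (b, c), (c, a)):
            key = (min(u, w), max(u, w))
            self.edge_use[key] = self.edge_use.get(key, 0) + 1

    def theta_and_axis(self, l: list[int], i: int):
        """Front angle (deg) and rotation axis at position *i* of loop *l*.

        The base angle between the boundary edge vectors is measured in
        3D.  Reflex classification: the hole wedge plus the surface
        wedge at the vertex should total a full turn; when base and
        360-base differ clearly on that score the better fit wins,
        otherwise the side test against the loop normal decides.  The
        returned axis is oriented so rotating the forward edge by theta
        reaches the backward edge through the hole.
        """
        k = len(l)
        p_i = self.verts[l[i]]
        a = self.verts[l[(i + 1) % k]] - p_i  # forward edge
        b = self.verts[l[(i - 1) % k]] - p_i  # backward edge
        la, lb = np.linalg.norm(a), np.linalg.norm(b)
        if la < 1e-15 or lb < 1e-15:
            return 180.0, self.normal
        base = np.degrees(np.arccos(np.clip(np.dot(a, b) / (la * lb), -1, 1)))
        cross = np.cross(a, b)
        ncross = np.linalg.norm(cross)

        s = self.wedge[l[i]]
        fit_plain = abs(base + s - 360.0)
        fit_reflex = abs((360.0 - base) + s - 360.0)
        if abs(fit_plain - fit_reflex) > 45.0:
            reflex = fit_reflex < fit_plain
        else:
            reflex = np.dot(cross, self.normal) < 0.0

        theta = 360.0 - base if reflex else base
        if ncross < 1e-8 * la * lb:
            axis = self.normal / max(np.linalg.norm(self.normal), 1e-15)
        else:
            axis = cross / ncross
            if reflex:
                axis = -axis
        return theta, axis


def afm_fill(mesh: TriangleMesh, loop: BoundaryLoop, epsilon: float) -> PatchFill:
    """Close one boundary loop with an advancing-front patch.

    Parameters
    ----------
    mesh : TriangleMesh
        Mesh containing the hole; returned augmented, never mutated.
    loop : BoundaryLoop
        Boundary cycle from :func:`~mealscan.topology.find_holes`.
    epsilon : float
        Merge radius in cm; candidate vertices closer than this to an
        existing front vertex are replaced by it.

    Raises
    ------
    FillError
        If the loop has fewer than 3 vertices or the front fails to
        close within ``10 * len(loop)`` iterations.
    """
    if len(loop) < 3:
        raise FillError(f"boundary loop has {len(loop)} vertices; need >= 3")
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")

    front = _Front(mesh, loop)
    k0 = len(loop)
    max_iter_afm = max(10 * k0, 100)
    grow_limit = 2 * k0 + 16
    iterations = 0
    ear_mode = False  # fallback: zip remaining loops by smallest-angle ears

    while front.loops:
        # close any triangle-sized loop outright
        tri = next((l for l in front.loops if len(l) == 3), None)
        if tri is not None:
            front.add_face(tri[0], tri[1], tri[2])
            front.loops.remove(tri)
            continue

        iterations += 1
        front_size = sum(len(l) for l in front.loops)
        if not ear_mode and (iterations > max_iter_afm or front_size > grow_limit):
            # the front stopped converging (strongly reflex or badly
            # classified regions can make it oscillate or grow): close
            # what remains with plain ears, which always terminates
            ear_mode = True
        if iterations > max_iter_afm + front_size + 100:
            raise FillError(
                f"hole did not close within {iterations} iterations "
                f"(epsilon={epsilon:.4g} may be too large)"
            )

        # candidate front vertices, most acute first
        cands_all = []
        for l in front.loops:
            for pos_in_loop, vid in enumerate(l):
                th, ax = front.theta_and_axis(l, pos_in_loop)
                cands_all.append((th, vid, ax, l, pos_in_loop))
        cands_all.sort(key=lambda t: (t[0], t[1]))

        if ear_mode:
            # smallest angle whose ear edge is not already saturated
            pick = next(
                (
                    c
                    for c in cands_all
                    if front.edge_count(
                        c[3][(c[4] - 1) % len(c[3])], c[3][(c[4] + 1) % len(c[3])]
                    )
                    < 2
                ),
                cands_all[0],
            )
            theta, vid, axis, l, i = pick
            k = len(l)
            v_prev, v_next = l[(i - 1) % k], l[(i + 1) % k]
            front.add_face(v_prev, vid, v_next)
            new_cycle = l[:i] + l[i + 1 :]
            front.loops.remove(l)
            front.loops.extend(_simplify_cycles(new_cycle))
            continue

        # advancing front: skip direct connections that would put a
        # third face on an existing edge (the surface closes across)
        pick = None
        for th, vid, ax, l, i in cands_all:
            if th <= 75.0 and front.edge_count(
                l[(i - 1) % len(l)], l[(i + 1) % len(l)]
            ) >= 2:
                continue
            pick = (th, vid, ax, l, i)
            break
        if pick is None:
            ear_mode = True
            continue
        theta, vid, axis, l, i = pick
        k = len(l)
        p_i = front.verts[vid]
        v_prev, v_next = l[(i - 1) % k], l[(i + 1) % k]
        p_prev, p_next = front.verts[v_prev], front.verts[v_next]

        n_new = 0 if theta <= 75.0 else (1 if theta <= 135.0 else 2)
        la = np.linalg.norm(p_next - p_i)
        lb = np.linalg.norm(p_prev - p_i)
        cands = _candidate_positions(
            p_i, (p_next - p_i) / la, 0.5 * (la + lb), theta, axis, n_new
        )

        # epsilon-merge each candidate against the current loop's vertices
        chain: list[int] = []
        for p_c in cands:
            merged = None
            best_q = -1.0
            for w in l:
                if w == vid:
                    continue
                if (
                    front.edge_count(w, vid) >= 2
                    or front.edge_count(w, v_prev) >= 2
                    or front.edge_count(w, v_next) >= 2
                ):
                    continue  # merging would over-use an existing edge
                if np.linalg.norm(front.verts[w] - p_c) < epsilon:
                    q = min(
                        _triangle_quality(p_prev, p_i, front.verts[w]),
                        _triangle_quality(front.verts[w], p_i, p_next),
                    )
                    if q > best_q:
                        best_q, merged = q, w
            chain.append(merged if merged is not None else front.add_vertex(p_c))

        # fan of triangles around v_i, wound with the loop traversal
        seq = [v_prev] + chain + [v_next]
        for a, b in zip(seq[:-1], seq[1:]):
            front.add_face(a, vid, b)

        # rebuild the front: v_i replaced by the (possibly merged) chain
        new_cycle = l[:i] + chain + l[i + 1 :]
        front.loops.remove(l)
        front.loops.extend(_simplify_cycles(new_cycle))

    verts = np.array(front.verts).reshape(-1, 3)
    faces = (
        np.vstack([mesh.faces, np.array(front.new_faces, dtype=np.int64)])
        if front.new_faces
        else mesh.faces.copy()
    )
    out = TriangleMesh(verts, faces, mesh.label)
    n0 = mesh.n_faces
    return PatchFill(
        mesh=out,
        new_vertices=np.array(front.new_vertices, dtype=np.int64),
        new_faces=np.arange(n0, out.n_faces, dtype=np.int64),
        fixed=loop.vertices.copy(),
    )


def _clamped_cot(angle: float, cfg: FillConfig) -> float:
    a = max(angle, cfg.min_angle)
    return float(np.clip(1.0 / np.tan(a), -cfg.cot_clamp, cfg.cot_clamp))


def harmonic_refine(
    mesh: TriangleMesh, patch: PatchFill, cfg: FillConfig | None = None
) -> TriangleMesh:
    """Reposition interior patch vertices harmonically.

    Solves ``sum_j w_ij (f_j - f_i) = 0`` with cotangent weights
    ``w_ij = cot(alpha_ij) + cot(beta_ij)`` for every free (newly
    created) vertex, once per coordinate, boundary held fixed.  The
    topology is unchanged; only the free vertices move.

    Raises
    ------
    FillError
        If the system is singular (a free vertex with an all-degenerate
        1-ring), naming the vertex.
    """
    cfg = cfg or FillConfig()
    free = np.asarray(patch.new_vertices, dtype=np.int64)
    if len(free) == 0:
        return mesh.copy()

    verts = mesh.vertices
    col = {int(v): c for c, v in enumerate(free)}
    is_free = np.zeros(mesh.n_vertices, dtype=bool)
    is_free[free] = True

    # accumulate cotangent weights from the patch triangles (every
    # triangle incident to a free vertex is a patch triangle)
    weights: dict[tuple[int, int], float] = {}
    for fi in patch.new_faces:
        tri = mesh.faces[fi]
        p = verts[tri]
        for c in range(3):
            j, k_, o = tri[(c + 1) % 3], tri[(c + 2) % 3], tri[c]
            u = p[(c + 1) % 3] - p[c]
            w_ = p[(c + 2) % 3] - p[c]
            lu, lw = np.linalg.norm(u), np.linalg.norm(w_)
            if lu < 1e-15 or lw < 1e-15:
                continue
            ang = np.arccos(np.clip(np.dot(u, w_) / (lu * lw), -1.0, 1.0))
            key = (min(j, k_), max(j, k_))
            weights[key] = weights.get(key, 0.0) + _clamped_cot(ang, cfg)

    rows, cols, vals = [], [], []
    rhs = np.zeros((len(free), 3))
    diag = np.zeros(len(free))
    for (a, b), w in weights.items():
        for i, j in ((a, b), (b, a)):
            if not is_free[i]:
                continue
            r = col[i]
            diag[r] += w
            if is_free[j]:
                rows.append(r)
                cols.append(col[j])
                vals.append(-w)
            else:
                rhs[r] += w * verts[j]
    rows.extend(range(len(free)))
    cols.extend(range(len(free)))
    vals.extend(diag)

    if np.any(diag == 0.0):
        bad = int(free[np.argmax(diag == 0.0)])
        raise FillError(f"singular harmonic system at vertex {bad}")

    A = csc_matrix(
        coo_matrix((vals, (rows, cols)), shape=(len(free), len(free)))
    )
    sol = spsolve(A, rhs)
    sol = np.asarray(sol).reshape(len(free), 3)
    if not np.isfinite(sol).all():
        bad = int(free[np.argmax(~np.isfinite(sol).any(axis=1))])
        raise FillError(f"singular harmonic system at vertex {bad}")

    out = mesh.copy()
    out.vertices[free] = sol
    return out


def fill_all_holes(
    mesh: TriangleMesh, cfg: FillConfig | None = None
) -> TriangleMesh:
    """Detect and close every hole: AFM patch then harmonic refinement.

    The mesh is welded first (scanner exports duplicate seam vertices);
    holes are processed largest boundary first.  The merge radius for
    each hole is ``cfg.epsilon_factor`` times that loop's mean
    boundary-edge length.  A closed mesh passes through unchanged.

    Raises
    ------
    FillError
        Propagated from the per-hole steps, tagged with the hole index.
    """
    cfg = cfg or FillConfig()
    m = clean(mesh)
    loops = find_holes(m)
    if not loops:
        return m
    order = sorted(
        range(len(loops)),
        key=lambda i: (-len(loops[i]), int(loops[i].vertices.min())),
    )
    for rank, li in enumerate(order):
        loop = loops[li]
        pts = m.vertices[loop.vertices]
        edge_len = np.linalg.norm(pts - np.roll(pts, -1, axis=0), axis=1).mean()
        eps = cfg.epsilon_factor * edge_len
        try:
            patch = afm_fill(m, loop, eps)
            m = harmonic_refine(patch.mesh, patch, cfg)
        except FillError as exc:
            raise FillError(f"hole {rank} (of {len(loops)}): {exc}") from exc
    return m
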