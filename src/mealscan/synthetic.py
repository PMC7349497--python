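"""Deterministic synthetic scan fixtures.

Depth-sensor food scans are partial surfaces: blind spots during
capture and the contact seam between food, neighbouring items and the
plate leave holes, and the bottom of an item resting on the plate is
never seen.  This module builds closed ground-truth solids (cubes,
cones, food-like blobs), then degrades them the way a scan is degraded:
Gaussian displacement of vertices along their normals (sensor noise)
and punched-out face neighbourhoods (blind spots, missing bottoms).
Every operation is reproducible from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from .mesh import TriangleMesh, inspect_mesh
from .volumetry import signed_volume

__all__ = [
    "ScanScenario",
    "make_cube",
    "make_cone",
    "make_blob",
    "puncture",
    "subdivide",
    "simulate_scan",
    "scan_suite",
]


@dataclass
class ScanScenario:
    """A ground-truth solid paired with its degraded partial scan."""

    truth: TriangleMesh
    true_volume: float  # cm^3, signed volume of the ground truth
    degraded: TriangleMesh
    holes: list  # dicts: center, radius, n_faces_removed
    noise: float  # cm, sigma of the normal-direction displacement
    seed: int


def make_cube(edge: float) -> TriangleMesh:
    """Closed axis-aligned cube of the given edge length: 8 vertices, 12
    outward-wound triangles, one corner at the origin."""
    if edge <= 0:
        raise ValueError("edge must be > 0")
    v = edge * np.array(
        [
            [0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
            [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1],
        ],
        dtype=float,
    )
    f = np.array(
        [
            [0, 2, 1], [0, 3, 2],  # bottom (z=0), normal -z
            [4, 5, 6], [4, 6, 7],  # top (z=edge), normal +z
            [0, 1, 5], [0, 5, 4],  # y=0
            [1, 2, 6], [1, 6, 5],  # x=edge
            [2, 3, 7], [2, 7, 6],  # y=edge
            [3, 0, 4], [3, 4, 7],  # x=0
        ],
        dtype=np.int64,
    )
    return TriangleMesh(v, f, label="cube")


def make_cone(radius: float, height: float, n_segments: int) -> TriangleMesh:
    """Closed cone: polygonal fan to the apex plus a fanned base disk.

    The rim polygon is inscribed in the circle, so the discrete volume
    approaches pi r^2 h / 3 from below as ``n_segments`` grows.
    """
    if n_segments < 8:
        raise ValueError("n_segments must be >= 8")
    if radius <= 0 or height <= 0:
        raise ValueError("radius and height must be > 0")
    ang = 2 * np.pi * np.arange(n_segments) / n_segments
    rim = np.stack(
        [radius * np.cos(ang), radius * np.sin(ang), np.zeros(n_segments)], axis=1
    )
    apex = np.array([[0.0, 0.0, height]])
    base_c = np.array([[0.0, 0.0, 0.0]])
    v = np.vstack([rim, apex, base_c])
    ia, ic = n_segments, n_segments + 1
    faces = []
    for i in range(n_segments):
        j = (i + 1) % n_segments
        faces.append([i, j, ia])  # lateral, outward
        faces.append([ic, j, i])  # base, normal -z
    return TriangleMesh(v, np.array(faces, dtype=np.int64), label="cone")


def _smooth_radial_field(directions: np.ndarray, rng, amplitude: float, n_lobes: int = 4):
    """Low-frequency random radial modulation in [1-a, 1+a]-ish."""
    field_ = np.zeros(len(directions))
    for _ in range(n_lobes):
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        phase = rng.uniform(0, 2 * np.pi)
        freq = rng.uniform(1.0, 2.5)
        field_ += rng.uniform(0.3, 1.0) * np.cos(freq * directions @ u * np.pi + phase)
    field_ /= n_lobes
    return 1.0 + amplitude * field_


def make_blob(kind: str, scale: float, seed: int) -> TriangleMesh:
    """Food-like closed blob of overall size *scale* (cm).

    ``apple``: sphere with polar dimples; ``croissant``: bent flattened
    ellipsoid; ``mound``: squashed dome (a serving heaped on a plate).
    All get a seeded low-frequency radial perturbation so no two seeds
    produce the same shape.
    """
    if scale <= 0:
        raise ValueError("scale must be > 0")
    if kind not in ("apple", "croissant", "mound"):
        raise ValueError(f"unknown blob kind {kind!r}")
    rng = np.random.default_rng(seed)
    base = trimesh.creation.icosphere(subdivisions=3, radius=1.0)
    d = np.asarray(base.vertices)  # unit directions
    r = _smooth_radial_field(d, rng, amplitude=0.06)
    v = d * r[:, None]
    if kind == "apple":
        # dimple both poles, as an apple's stem and calyx basins
        polar = np.abs(v[:, 2]) / np.linalg.norm(v, axis=1)
        v *= (1.0 - 0.18 * np.exp(-((1.0 - polar) / 0.12) ** 2))[:, None]
        v *= scale / 2.0
    elif kind == "croissant":
        v = v * np.array([1.25, 0.55, 0.45])
        v[:, 1] += 0.45 * v[:, 0] ** 2  # parabolic bend
        v *= scale / 2.0
    else:  # mound
        v = v * np.array([1.0, 1.0, 0.55]) * scale / 2.0
    v[:, 2] -= v[:, 2].min()  # rest on z=0
    return TriangleMesh(v, np.asarray(base.faces, dtype=np.int64), label=kind)


def subdivide(mesh: TriangleMesh, n: int = 1) -> TriangleMesh:
    """Midpoint 1-to-4 subdivision, *n* times; geometry is unchanged."""
    v = mesh.vertices
    f = mesh.faces
    for _ in range(n):
        verts = [p for p in v]
        mid_cache: dict[tuple[int, int], int] = {}

        def midpoint(a: int, b: int) -> int:
            key = (min(a, b), max(a, b))
            if key not in mid_cache:
                verts.append(0.5 * (verts[a] + verts[b]))
                mid_cache[key] = len(verts) - 1
            return mid_cache[key]

        new_faces = []
        for a, b, c in f:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [[a, ab, ca], [ab, b, bc], [ca, bc, c], [ab, bc, ca]]
        v = np.array(verts)
        f = np.array(new_faces, dtype=np.int64)
    return TriangleMesh(v, f, mesh.label)


def puncture(mesh: TriangleMesh, center, radius: float) -> TriangleMesh:
    """Remove every face whose centroid lies within *radius* of *center*.

    Nothing else changes; vertices stranded by the removal stay in the
    vertex array so indices remain stable.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    center = np.asarray(center, dtype=float).reshape(3)
    centroids = mesh.vertices[mesh.faces].mean(axis=1)
    keep = np.linalg.norm(centroids - center, axis=1) > radius
    return TriangleMesh(mesh.vertices.copy(), mesh.faces[keep], mesh.label)


def _vertex_normals(mesh: TriangleMesh) -> np.ndarray:
    fn = mesh.face_normals()  # area-weighted
    vn = np.zeros_like(mesh.vertices)
    for c in range(3):
        np.add.at(vn, mesh.faces[:, c], fn)
    nrm = np.linalg.norm(vn, axis=1, keepdims=True)
    return vn / np.maximum(nrm, 1e-15)


def simulate_scan(
    shape: str = "cube",
    *,
    seed: int = 0,
    noise: float = 0.0,
    n_punctures: int = 1,
    puncture_area_fraction: float = 0.08,
    subdivisions: int = 2,
    edge: float = 7.0,
    radius: float = 3.0,
    height: float = 6.0,
    n_segments: int = 48,
    kind: str = "apple",
    scale: float = 8.0,
) -> ScanScenario:
    """Build a ground-truth solid and its degraded partial scan.

    The degraded mesh is a face-subset of a noised copy of the ground
    truth: vertices are displaced along their normals by Gaussian noise
    of sigma *noise* (cm), then ``n_punctures`` face neighbourhoods are
    punched out at seeded random locations, each sized so the removed
    disk covers about ``puncture_area_fraction`` of the total surface
    area.  The true volume is that of the noise-free ground truth.
    """
    if shape == "cube":
        truth = subdivide(make_cube(edge), subdivisions)
    elif shape == "cone":
        truth = subdivide(make_cone(radius, height, n_segments), max(subdivisions - 1, 0))
    elif shape == "blob":
        truth = make_blob(kind, scale, seed=seed)
    else:
        raise ValueError(f"unknown shape {shape!r}")

    true_volume = signed_volume(truth).volume
    rng = np.random.default_rng(seed)

    degraded_v = truth.vertices.copy()
    if noise > 0:
        vn = _vertex_normals(truth)
        degraded_v += vn * rng.normal(0.0, noise, size=len(degraded_v))[:, None]
    degraded = TriangleMesh(degraded_v, truth.faces.copy(), truth.label)

    total_area = degraded.face_areas().sum()
    hole_radius = float(np.sqrt(puncture_area_fraction * total_area / np.pi))
    holes = []
    for _ in range(n_punctures):
        fi = int(rng.integers(degraded.n_faces))
        center = degraded.vertices[degraded.faces[fi]].mean(axis=0)
        before = degraded.n_faces
        degraded = puncture(degraded, center, hole_radius)
        holes.append(
            {
                "center": [float(x) for x in center],
                "radius": hole_radius,
                "n_faces_removed": int(before - degraded.n_faces),
            }
        )
    return ScanScenario(
        truth=truth,
        true_volume=true_volume,
        degraded=degraded,
        holes=holes,
        noise=noise,
        seed=seed,
    )


#: Geometric-shape evaluation suite: cubes with edges 5-10 cm and cones
#: with radii 2-4 cm / heights 4-8 cm, each degraded by one puncture
#: covering 10% of the surface and 0.03 cm surface noise.
SUITE_SPECS = tuple(
    [("cube", {"edge": float(e)}) for e in (5, 6, 7, 8, 9, 10)]
    + [
        ("cone", {"radius": r, "height": h})
        for r, h in ((2.0, 4.0), (2.5, 5.0), (3.0, 6.0), (3.5, 7.0), (4.0, 8.0), (3.0, 5.0))
    ]
)


def scan_suite(seed: int = 1) -> list[ScanScenario]:
    """The fixed cube-and-cone evaluation suite as scan scenarios.

    Twelve scenarios (see :data:`SUITE_SPECS`), each with a single
    puncture covering 10% of the surface area and Gaussian surface
    noise of 0.03 cm; per-scenario seeds derive deterministically from
    *seed*.
    """
    out = []
    for i, (shape, kw) in enumerate(SUITE_SPECS):
        out.append(
            simulate_scan(
                shape,
                seed=(seed * 1009 + i) % (2**31),
                noise=0.03,
                n_punctures=1,
                puncture_area_fraction=0.10,
                **kw,
            )
        )
    return out
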