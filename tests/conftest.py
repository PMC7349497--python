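"""Shared mesh fixtures, generated programmatically."""

import numpy as np
import pytest

from mealscan import TriangleMesh, make_blob, make_cube
from mealscan.synthetic import subdivide


@pytest.fixture
def cube7():
    return make_cube(7.0)


@pytest.fixture
def open_cube7(cube7):
    """7 cm cube with the two triangles of the top face removed."""
    return TriangleMesh(cube7.vertices.copy(), np.delete(cube7.faces, [2, 3], axis=0))


def fan_disk(radius=10.0, n=48, z=0.0):
    """Flat disk in the z-plane, triangulated as a fan (CCW from +z)."""
    ang = 2 * np.pi * np.arange(n) / n
    rim = np.stack(
        [radius * np.cos(ang), radius * np.sin(ang), np.full(n, z)], axis=1
    )
    v = np.vstack([rim, [[0.0, 0.0, z]]])
    f = [[i, (i + 1) % n, n] for i in range(n)]
    return TriangleMesh(v, np.array(f, dtype=np.int64))


def hemisphere(r=3.0, n_rings=8, n_seg=24, center=(0.0, 0.0, 0.0)):
    """Open hemisphere shell (no bottom cap), pole up, resting at z=center_z."""
    cx, cy, cz = center
    verts = [[cx, cy, cz + r]]
    faces = []
    for j in range(1, n_rings + 1):
        phi = np.pi / 2 * j / n_rings
        zz = r * np.cos(phi)
        rr = r * np.sin(phi)
        for s in range(n_seg):
            th = 2 * np.pi * s / n_seg
            verts.append([cx + rr * np.cos(th), cy + rr * np.sin(th), cz + zz])

    def vid(j, s):
        return 1 + (j - 1) * n_seg + s % n_seg

    for s in range(n_seg):
        faces.append([0, vid(1, s), vid(1, s + 1)])
    for j in range(1, n_rings):
        for s in range(n_seg):
            faces.append([vid(j, s), vid(j + 1, s), vid(j + 1, s + 1)])
            faces.append([vid(j, s), vid(j + 1, s + 1), vid(j, s + 1)])
    return TriangleMesh(np.array(verts, dtype=float), np.array(faces, dtype=np.int64))


def annulus_with_polygon_hole(n=36, r_in=3.0, r_out=6.0):
    """Flat annulus whose inner boundary is a regular n-gon hole.

    Interior angle of the hole polygon at every vertex: (n-2)*180/n.
    """
    ang = 2 * np.pi * np.arange(n) / n
    inner = np.stack([r_in * np.cos(ang), r_in * np.sin(ang), np.zeros(n)], axis=1)
    outer = np.stack([r_out * np.cos(ang), r_out * np.sin(ang), np.zeros(n)], axis=1)
    v = np.vstack([inner, outer])
    f = []
    for i in range(n):
        j = (i + 1) % n
        f.append([i, n + j, n + i])
        f.append([i, j, n + j])
    return TriangleMesh(v, np.array(f, dtype=np.int64))


def cube_top_square_hole(edge=8.0):
    """Subdivided cube with a centred square hole in its top face.

    Returns (mesh, hole_area, z_plane): a planar convex square hole of
    side edge/2 in the z = edge plane, with no other boundary.
    """
    m = subdivide(make_cube(edge), 2)
    cent = m.vertices[m.faces].mean(axis=1)
    lo, hi = edge / 4, 3 * edge / 4
    in_hole = (
        (np.abs(cent[:, 2] - edge) < 1e-9)
        & (cent[:, 0] > lo)
        & (cent[:, 0] < hi)
        & (cent[:, 1] > lo)
        & (cent[:, 1] < hi)
    )
    holed = TriangleMesh(m.vertices.copy(), m.faces[~in_hole])
    return holed, (edge / 2) ** 2, edge


def two_bump_sheet(nx=48, ny=24):
    """Open height-field sheet with two cone bumps meeting at a sharp
    valley crease at x=0; face labels split at the crease."""
    xs = np.linspace(-2, 2, nx)
    ys = np.linspace(-1, 1, ny)
    X, Y = np.meshgrid(xs, ys, indexing="ij")

    def bump(cx):
        return np.maximum(0.0, 0.9 - 1.5 * np.sqrt((X - cx) ** 2 + Y**2))

    Z = np.maximum(bump(-1.0), bump(1.0))
    V = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    F = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            a = i * ny + j
            b = (i + 1) * ny + j
            c = (i + 1) * ny + j + 1
            d = i * ny + j + 1
            F += [[a, b, c], [a, c, d]]
    mesh = TriangleMesh(V, np.array(F, dtype=np.int64))
    labels = (mesh.vertices[mesh.faces].mean(axis=1)[:, 0] >= 0).astype(int)
    return mesh, labels


@pytest.fixture
def punched_fixtures():
    """Small battery of punctured closed solids for fill properties."""
    from mealscan import puncture

    cube = subdivide(make_cube(6.0), 2)
    c1 = puncture(cube, [3.0, 3.0, 6.0], 1.2)  # top-face disk
    c2 = puncture(cube, [6.0, 6.0, 6.0], 1.0)  # corner
    blob = make_blob("apple", 8.0, seed=3)
    lo = blob.vertices[:, 2].min()
    b1 = puncture(
        blob, [blob.vertices[:, 0].mean(), blob.vertices[:, 1].mean(), lo], 1.5
    )
    return {"cube_face": c1, "cube_corner": c2, "blob_bottom": b1}
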