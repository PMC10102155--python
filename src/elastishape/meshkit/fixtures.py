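"""Synthetic mesh generation: the package's test-bed surfaces.

Real anatomical scans (bones, skulls, body surfaces) are large, irregularly
meshed, and frequently incomplete.  The generators here emulate those regimes
with analytically controlled shapes — planes, spheres with two different mesh
combinatorics, tori, tubes, ellipsoids — plus deterministic deformation
helpers (translate / rotate / scale / bend / noise) and component deletion to
mimic partially observed data.  Everything is deterministic given ``seed``.
"""

from __future__ import annotations

import numpy as np
import trimesh

from .core import MeshError, TriMesh

__all__ = [
    "make_fixture", "plane_grid", "icosphere", "uv_sphere", "torus", "tube",
    "ellipsoid", "translated", "rotated", "scaled", "bent", "noisy",
    "rotation_matrix", "delete_component", "connected_face_components",
    "two_triangle_square", "hex_fan", "single_triangle",
]


# ---------------------------------------------------------------------------
# primitive shapes


def plane_grid(nx: int = 8, ny: int = 8, width: float = 1.0, height: float = 1.0) -> TriMesh:
    """Triangulated rectangle in the z=0 plane with (nx+1)*(ny+1) vertices."""
    if nx < 1 or ny < 1:
        raise MeshError("plane_grid needs nx, ny >= 1")
    xs = np.linspace(0.0, width, nx + 1)
    ys = np.linspace(0.0, height, ny + 1)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    verts = np.column_stack([X.ravel(), Y.ravel(), np.zeros(X.size)])
    faces = []
    for i in range(nx):
        for j in range(ny):
            a = i * (ny + 1) + j
            b = (i + 1) * (ny + 1) + j
            faces.append([a, b, b + 1])
            faces.append([a, b + 1, a + 1])
    return TriMesh(verts, np.asarray(faces, dtype=np.int64))


def icosphere(subdiv: int = 2, radius: float = 1.0) -> TriMesh:
    """Icosahedron-based sphere: 12 vertices / 20 faces at subdiv=0, x4 faces per level."""
    if subdiv < 0:
        raise MeshError("subdiv must be >= 0")
    m = trimesh.creation.icosphere(subdivisions=subdiv, radius=radius)
    return TriMesh(np.asarray(m.vertices), np.asarray(m.faces))


def uv_sphere(n_lon: int = 24, n_lat: int = 12, radius: float = 1.0) -> TriMesh:
    """Latitude/longitude sphere — same geometry as an icosphere, different mesh."""
    if n_lon < 3 or n_lat < 2:
        raise MeshError("uv_sphere needs n_lon >= 3 and n_lat >= 2")
    m = trimesh.creation.uv_sphere(radius=radius, count=(n_lat + 1, n_lon))
    tri = TriMesh(np.asarray(m.vertices), np.asarray(m.faces))
    return _drop_unused_and_degenerate(tri)


def torus(R: float = 2.0, r: float = 0.5, n_major: int = 32, n_minor: int = 16) -> TriMesh:
    """Genus-1 torus with major radius R and tube radius r."""
    if R <= r or r <= 0:
        raise MeshError("torus needs R > r > 0")
    m = trimesh.creation.torus(
        major_radius=R, minor_radius=r, major_sections=n_major, minor_sections=n_minor
    )
    return TriMesh(np.asarray(m.vertices), np.asarray(m.faces))


def tube(radius: float = 0.5, length: float = 3.0, n_circ: int = 16, n_len: int = 8) -> TriMesh:
    """Open cylinder (pipe) along z, without caps — a surface with boundary."""
    if n_circ < 3 or n_len < 1:
        raise MeshError("tube needs n_circ >= 3 and n_len >= 1")
    theta = np.linspace(0, 2 * np.pi, n_circ, endpoint=False)
    zs = np.linspace(0.0, length, n_len + 1)
    verts = []
    for z in zs:
        for t in theta:
            verts.append([radius * np.cos(t), radius * np.sin(t), z])
    faces = []
    for i in range(n_len):
        for j in range(n_circ):
            a = i * n_circ + j
            b = i * n_circ + (j + 1) % n_circ
            c = a + n_circ
            d = b + n_circ
            faces.append([a, b, d])
            faces.append([a, d, c])
    return TriMesh(np.asarray(verts), np.asarray(faces, dtype=np.int64))


def ellipsoid(radii=(1.0, 1.0, 1.5), subdiv: int = 2) -> TriMesh:
    """Axis-aligned ellipsoid: an icosphere scaled anisotropically."""
    radii = np.asarray(radii, dtype=np.float64)
    if np.any(radii <= 0):
        raise MeshError("ellipsoid radii must be positive")
    m = icosphere(subdiv=subdiv, radius=1.0)
    return m.with_vertices(m.vertices * radii[None, :])


def _drop_unused_and_degenerate(mesh: TriMesh) -> TriMesh:
    """Remove exactly-degenerate faces (pole fans) and unreferenced vertices."""
    v, f = mesh.vertices, mesh.faces
    e1 = v[f[:, 1]] - v[f[:, 0]]
    e2 = v[f[:, 2]] - v[f[:, 0]]
    area2 = np.linalg.norm(np.cross(e1, e2), axis=1)
    f = f[area2 > 1e-14 * max(mesh.bbox_diagonal() ** 2, 1e-300)]
    used = np.unique(f)
    remap = -np.ones(len(v), dtype=np.int64)
    remap[used] = np.arange(len(used))
    return TriMesh(v[used], remap[f])


# ---------------------------------------------------------------------------
# deterministic transforms


def rotation_matrix(seed: int) -> np.ndarray:
    """Seeded random rotation: QR of a Gaussian matrix, determinant forced to +1."""
    rng = np.random.default_rng(seed)
    Q, R = np.linalg.qr(rng.standard_normal((3, 3)))
    Q = Q * np.sign(np.diag(R))[None, :]
    if np.linalg.det(Q) < 0:
        Q[:, [0, 1]] = Q[:, [1, 0]]
    return Q


def translated(mesh: TriMesh, tau) -> TriMesh:
    return mesh.with_vertices(mesh.vertices + np.asarray(tau, dtype=np.float64)[None, :])


def rotated(mesh: TriMesh, R) -> TriMesh:
    R = np.asarray(R, dtype=np.float64)
    return mesh.with_vertices(mesh.vertices @ R.T)


def scaled(mesh: TriMesh, s) -> TriMesh:
    return mesh.with_vertices(mesh.vertices * np.asarray(s, dtype=np.float64))


def bent(mesh: TriMesh, amplitude: float = 0.3, axis: int = 0) -> TriMesh:
    """Smooth sinusoidal bend: displaces along z by amplitude*sin(pi * x_axis / extent)."""
    v = mesh.vertices.copy()
    coord = v[:, axis]
    lo, hi = coord.min(), coord.max()
    ext = max(hi - lo, 1e-12)
    v[:, 2] += amplitude * np.sin(np.pi * (coord - lo) / ext)
    return mesh.with_vertices(v)


def noisy(mesh: TriMesh, level: float, seed: int) -> TriMesh:
    """Gaussian vertex jitter with standard deviation level * bbox diagonal."""
    rng = np.random.default_rng(seed)
    sigma = level * mesh.bbox_diagonal()
    return mesh.with_vertices(mesh.vertices + sigma * rng.standard_normal(mesh.vertices.shape))


# ---------------------------------------------------------------------------
# component surgery


def connected_face_components(mesh: TriMesh) -> list[np.ndarray]:
    """Face index sets of the vertex-connected components, largest first."""
    adj = trimesh.graph.connected_component_labels(
        trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False).face_adjacency,
        node_count=mesh.n_faces,
    )
    comps = [np.flatnonzero(adj == k) for k in np.unique(adj)]
    comps.sort(key=len, reverse=True)
    return comps


def delete_component(mesh: TriMesh, keep: int = 0) -> TriMesh:
    """Keep only the ``keep``-th largest connected component (drops its complement)."""
    comps = connected_face_components(mesh)
    if keep < 0 or keep >= len(comps):
        raise MeshError(f"component index {keep} out of range (mesh has {len(comps)})")
    f = mesh.faces[comps[keep]]
    used = np.unique(f)
    remap = -np.ones(mesh.n_vertices, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return TriMesh(mesh.vertices[used], remap[f])


def merge(a: TriMesh, b: TriMesh) -> TriMesh:
    """Disjoint union of two meshes (vertex indices of b shifted)."""
    return TriMesh(
        np.vstack([a.vertices, b.vertices]),
        np.vstack([a.faces, b.faces + a.n_vertices]),
    )


# ---------------------------------------------------------------------------
# tiny hand-checkable meshes


def single_triangle() -> TriMesh:
    """Unit right triangle (0,0,0), (1,0,0), (0,1,0): area 1/2, normal +z."""
    return TriMesh(
        np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]),
        np.array([[0, 1, 2]]),
    )


def two_triangle_square() -> TriMesh:
    """Unit square split along the diagonal: total area 1."""
    verts = np.array(
        [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [1.0, 1.0, 0.0], [0.0, 1.0, 0.0]]
    )
    faces = np.array([[0, 1, 2], [0, 2, 3]])
    return TriMesh(verts, faces)


def hex_fan() -> TriMesh:
    """Six equilateral unit triangles around a central vertex (vertex 0)."""
    center = np.zeros((1, 3))
    theta = np.arange(6) * np.pi / 3
    ring = np.column_stack([np.cos(theta), np.sin(theta), np.zeros(6)])
    verts = np.vstack([center, ring])
    faces = np.array([[0, 1 + i, 1 + (i + 1) % 6] for i in range(6)])
    return TriMesh(verts, faces)


# ---------------------------------------------------------------------------
# dispatcher


_KINDS = {
    "plane_grid": plane_grid,
    "icosphere": icosphere,
    "uv_sphere": uv_sphere,
    "torus": torus,
    "tube": tube,
    "ellipsoid": ellipsoid,
}


def make_fixture(kind: str, params: dict | None = None, seed: int = 0) -> TriMesh:
    """Generate a synthetic mesh by name.

    ``kind`` is one of plane_grid, icosphere, uv_sphere, torus, tube,
    ellipsoid.  ``params`` are forwarded to the generator, with the optional
    extras ``noise`` (jitter level relative to the bbox diagonal, applied with
    ``seed``), ``translate``, ``rotate_seed`` and ``scale`` applied afterwards
    in that order.
    """
    if kind not in _KINDS:
        raise MeshError(f"unknown fixture kind {kind!r}; choose from {sorted(_KINDS)}")
    params = dict(params or {})
    noise = params.pop("noise", 0.0)
    translate = params.pop("translate", None)
    rotate_seed = params.pop("rotate_seed", None)
    scale = params.pop("scale", None)
    mesh = _KINDS[kind](**params)
    if noise:
        mesh = noisy(mesh, float(noise), seed)
    if scale is not None:
        mesh = scaled(mesh, scale)
    if rotate_seed is not None:
        mesh = rotated(mesh, rotation_matrix(int(rotate_seed)))
    if translate is not None:
        mesh = translated(mesh, translate)
    return mesh
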