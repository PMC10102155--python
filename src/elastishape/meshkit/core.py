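"""Mesh data model and discrete differential-geometry kernels.

A surface is represented by a :class:`TriMesh`: vertex positions plus a fixed
list of consistently oriented triangles.  All Riemannian computations in the
package treat the face list as the combinatorial structure of a solution
space, with the vertex positions as the only degrees of freedom.

The per-face quantities (edge matrix, induced 2x2 metric, area, unit normal,
barycenter) and the per-vertex quantities (one-third area weights, integrated
cotangent Laplacian) follow the standard discrete-differential-geometry
conventions: edge rows ``e01 = v1 - v0``, ``e02 = v2 - v0`` stacked as a 2x3
matrix ``dq_f``, the pullback metric ``g_f = dq_f dq_f^T`` and the trace
pairing ``tr(g_f^{-1} A B^T)`` (so that ``tr(g^{-1} dq dq^T) = 2`` on every
non-degenerate face).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .. import _ad as ad

log = logging.getLogger("elastishape")

#: |cot| values are capped here so degenerate corners cannot blow up the
#: Laplacian term on noisy meshes.
COT_CLAMP = 1.0e4

#: faces with area below DEGENERATE_REL * (bbox diagonal)^2 are flagged.
DEGENERATE_REL = 1.0e-12


class MeshError(ValueError):
    """Raised for invalid mesh structure or incompatible inputs."""


def canonical_faces(faces):
    """Rotate each face cyclically so its smallest vertex index comes first.

    Cyclic rotation preserves orientation; this yields the canonical
    representative (i, j, k) with i < j, k of each oriented triangle.
    """
    faces = np.asarray(faces, dtype=np.int64)
    if faces.ndim != 2 or faces.shape[1] != 3:
        raise MeshError(f"faces must be (m, 3), got {faces.shape}")
    shift = np.argmin(faces, axis=1)
    cols = (np.arange(3)[None, :] + shift[:, None]) % 3
    return np.take_along_axis(faces, cols, axis=1)


@dataclass
class TriMesh:
    """Oriented triangular mesh: the discrete immersion.

    Parameters
    ----------
    vertices : (n, 3) float array
        Vertex coordinates, arbitrary length units.
    faces : (m, 3) int array
        Vertex indices, oriented so that ``(v_j - v_i) x (v_k - v_i)`` is the
        outward/consistent normal.  Stored canonically (smallest index first).
    """

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self):
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshError(f"vertices must be (n, 3), got {self.vertices.shape}")
        self.faces = canonical_faces(self.faces)
        n = len(self.vertices)
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= n):
            raise MeshError("face index out of range")
        degen = (
            (self.faces[:, 0] == self.faces[:, 1])
            | (self.faces[:, 1] == self.faces[:, 2])
            | (self.faces[:, 0] == self.faces[:, 2])
        )
        if degen.any():
            raise MeshError(f"face {int(np.flatnonzero(degen)[0])} repeats a vertex index")

    # -- basic derived structure ----------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def edges(self) -> np.ndarray:
        """Undirected edge set as sorted (i, j) pairs, each once."""
        e = np.concatenate([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]])
        e = np.sort(e, axis=1)
        return np.unique(e, axis=0)

    def euler_characteristic(self) -> int:
        return self.n_vertices - len(self.edges) + self.n_faces

    def bbox_diagonal(self) -> float:
        if self.n_vertices == 0:
            return 0.0
        ext = self.vertices.max(axis=0) - self.vertices.min(axis=0)
        return float(np.linalg.norm(ext))

    def diameter(self) -> float:
        """Bounding-box diagonal; the length scale used for tolerances."""
        return self.bbox_diagonal()

    def with_vertices(self, vertices) -> "TriMesh":
        """Same combinatorics, new vertex positions."""
        return TriMesh(np.asarray(vertices, dtype=np.float64), self.faces)

    def copy(self) -> "TriMesh":
        return TriMesh(self.vertices.copy(), self.faces.copy())

    def is_oriented(self) -> bool:
        """True if every interior edge is traversed once in each direction."""
        directed = np.concatenate(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        seen = set(map(tuple, directed))
        if len(seen) != len(directed):
            return False  # duplicated directed edge => inconsistent orientation
        return True


@dataclass
class TangentField:
    """One 3-vector per vertex: a discrete tangent vector h at a mesh."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.ascontiguousarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[1] != 3:
            raise MeshError(f"tangent field must be (n, 3), got {self.values.shape}")

    @classmethod
    def zeros(cls, mesh: TriMesh) -> "TangentField":
        return cls(np.zeros_like(mesh.vertices))

    def check(self, mesh: TriMesh) -> "TangentField":
        if len(self.values) != mesh.n_vertices:
            raise MeshError(
                f"tangent field length {len(self.values)} != vertex count {mesh.n_vertices}"
            )
        return self

    def __add__(self, other):
        return TangentField(self.values + other.values)

    def __sub__(self, other):
        return TangentField(self.values - other.values)

    def __mul__(self, s):
        return TangentField(self.values * float(s))

    __rmul__ = __mul__

    def __neg__(self):
        return TangentField(-self.values)


@dataclass
class FaceGeometry:
    """Per-face discrete first-order quantities.

    Attributes
    ----------
    dq : (m, 2, 3)
        Row-stacked edge matrices [e01; e02].
    g : (m, 2, 2)
        Pullback metric g_f = dq_f dq_f^T.
    vol : (m,)
        Face areas, 0.5 |e01 x e02|.
    normal : (m, 3)
        Unit normals (unit whenever vol > 0; zero rows on degenerate faces).
    center : (m, 3)
        Barycenters.
    degenerate : (m,) bool
        Faces with vol below the degeneracy tolerance.
    """

    dq: np.ndarray
    g: np.ndarray
    vol: np.ndarray
    normal: np.ndarray
    center: np.ndarray
    degenerate: np.ndarray


def face_frames(verts, faces):
    """Differentiable per-face frame quantities.

    Works on plain arrays or autodiff variables; returns a dict with edge rows
    ``e1, e2``, metric entries ``g11, g12, g22``, inverse-metric entries,
    ``vol``, ``normal``, ``center`` and the constant boolean ``degenerate``
    mask (evaluated on primal values).
    """
    v0 = ad.take(verts, faces[:, 0])
    v1 = ad.take(verts, faces[:, 1])
    v2 = ad.take(verts, faces[:, 2])
    e1 = ad.sub(v1, v0)
    e2 = ad.sub(v2, v0)
    cr = ad.cross3(e1, e2)
    cross_norm2 = ad.rowdot(cr, cr)
    g11 = ad.rowdot(e1, e1)
    g12 = ad.rowdot(e1, e2)
    g22 = ad.rowdot(e2, e2)

    vvals = ad.value(verts)
    ext = vvals.max(axis=0) - vvals.min(axis=0) if len(vvals) else np.zeros(3)
    bbox2 = float(np.dot(ext, ext))
    tol_area = DEGENERATE_REL * max(bbox2, np.finfo(float).tiny)
    vol_primal = 0.5 * np.sqrt(np.maximum(ad.value(cross_norm2), 0.0))
    det_primal = ad.value(g11) * ad.value(g22) - ad.value(g12) ** 2
    degenerate = (vol_primal <= tol_area) | (det_primal <= (2.0 * tol_area) ** 2)

    cross_norm = ad.sqrt(ad.maximum(cross_norm2, np.finfo(float).tiny))
    vol = ad.mul(0.5, cross_norm)
    normal = ad.div(cr, ad.reshape(cross_norm, (-1, 1)))
    if degenerate.any():
        normal = ad.where(degenerate[:, None], 0.0, normal)
    center = ad.div(ad.add(ad.add(v0, v1), v2), 3.0)

    det = ad.sub(ad.mul(g11, g22), ad.mul(g12, g12))
    det_safe = ad.where(degenerate, 1.0, det) if degenerate.any() else det
    gi11 = ad.div(g22, det_safe)
    gi12 = ad.div(ad.neg(g12), det_safe)
    gi22 = ad.div(g11, det_safe)

    return {
        "e1": e1, "e2": e2,
        "g11": g11, "g12": g12, "g22": g22,
        "gi11": gi11, "gi12": gi12, "gi22": gi22,
        "vol": vol, "normal": normal, "center": center,
        "degenerate": degenerate,
    }


def face_geometry(mesh: TriMesh) -> FaceGeometry:
    """Per-face edge matrices, pullback metrics, areas, normals, barycenters.

    Degenerate faces (area below ``DEGENERATE_REL * bbox_diag^2``) are flagged
    rather than raising; downstream metric terms skip them.
    """
    fr = face_frames(mesh.vertices, mesh.faces)
    m = mesh.n_faces
    dq = np.stack([ad.value(fr["e1"]), ad.value(fr["e2"])], axis=1)
    g = np.empty((m, 2, 2))
    g[:, 0, 0] = ad.value(fr["g11"])
    g[:, 0, 1] = g[:, 1, 0] = ad.value(fr["g12"])
    g[:, 1, 1] = ad.value(fr["g22"])
    return FaceGeometry(
        dq=dq,
        g=g,
        vol=ad.value(fr["vol"]) * ~fr["degenerate"] ,
        normal=ad.value(fr["normal"]),
        center=ad.value(fr["center"]),
        degenerate=fr["degenerate"],
    )


def vertex_areas_of(verts, faces):
    """Differentiable per-vertex areas: one third of each incident face area."""
    fr = face_frames(verts, faces)
    vol = fr["vol"]
    if fr["degenerate"].any():
        vol = ad.where(fr["degenerate"], 0.0, vol)
    third = ad.div(vol, 3.0)
    n = len(ad.value(verts))
    va = ad.scatter_add(third, faces[:, 0], n)
    va = ad.add(va, ad.scatter_add(third, faces[:, 1], n))
    va = ad.add(va, ad.scatter_add(third, faces[:, 2], n))
    return va


def vertex_areas(mesh: TriMesh) -> np.ndarray:
    """Per-vertex areas vol_v = (1/3) sum of incident face areas.

    Sums to the total surface area; isolated vertices get 0.
    """
    return ad.value(vertex_areas_of(mesh.vertices, mesh.faces))


def cotan_laplacian_of(verts, faces, field, clamp: float = COT_CLAMP):
    """Differentiable integrated cotangent Laplacian applied to ``field``.

    (L h)_v = sum over neighbours w of (cot a_vw + cot b_vw)(h_v - h_w),
    accumulated from face corners: the corner opposite each edge contributes
    its cotangent to that edge's weight.  Boundary edges see only their single
    opposite angle.  Cotangents are clamped to ``+-clamp`` and degenerate
    faces contribute nothing.
    """
    n = len(ad.value(verts))
    fr = face_frames(verts, faces)
    vol = fr["vol"]
    two_area = ad.mul(2.0, vol)
    v0 = ad.take(verts, faces[:, 0])
    v1 = ad.take(verts, faces[:, 1])
    v2 = ad.take(verts, faces[:, 2])
    # cot at corner c opposite edge (a, b): ((a-c).(b-c)) / (2 * area)
    cot0 = ad.div(ad.rowdot(ad.sub(v1, v0), ad.sub(v2, v0)), two_area)  # opp edge (1,2)
    cot1 = ad.div(ad.rowdot(ad.sub(v0, v1), ad.sub(v2, v1)), two_area)  # opp edge (2,0)
    cot2 = ad.div(ad.rowdot(ad.sub(v0, v2), ad.sub(v1, v2)), two_area)  # opp edge (0,1)

    deg = fr["degenerate"]
    clamped = False
    cots, pairs = [], [(1, 2), (2, 0), (0, 1)]
    for c in (cot0, cot1, cot2):
        cv = ad.value(c)
        if np.any(np.abs(cv) > clamp):
            clamped = True
        c = ad.clip(c, -clamp, clamp)
        if deg.any():
            c = ad.where(deg, 0.0, c)
        cots.append(c)
    if clamped:
        log.warning("cotan_laplacian: clamped cotangents on near-degenerate corners")

    h = field
    out = None
    for c, (ia, ib) in zip(cots, pairs):
        a_idx, b_idx = faces[:, ia], faces[:, ib]
        ha = ad.take(h, a_idx)
        hb = ad.take(h, b_idx)
        w = ad.reshape(c, (-1, 1))
        contrib_a = ad.mul(w, ad.sub(ha, hb))
        part = ad.scatter_add(contrib_a, a_idx, n)
        part = ad.add(part, ad.scatter_add(ad.neg(contrib_a), b_idx, n))
        out = part if out is None else ad.add(out, part)
    return out


def cotan_laplacian(
    mesh: TriMesh, field: TangentField, mass_normalized: bool = False
) -> TangentField:
    """Apply the cotangent Laplacian to a tangent field, componentwise.

    By default returns the integrated operator (the plain cotan sum).  With
    ``mass_normalized=True`` each row is divided by twice the vertex area,
    giving the pointwise operator many mesh-processing codes use.
    """
    field.check(mesh)
    out = ad.value(cotan_laplacian_of(mesh.vertices, mesh.faces, field.values))
    if mass_normalized:
        va = vertex_areas(mesh)
        mass = np.where(va > 0, 2.0 * va, 1.0)
        out = out / mass[:, None]
    return TangentField(out)
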