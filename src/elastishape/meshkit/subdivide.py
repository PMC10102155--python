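"""Spatial and temporal refinement used by the multiresolution solvers.

Spatial refinement is plain 1-to-4 midpoint (Loop-connectivity, no smoothing)
subdivision: new vertices sit at edge midpoints, so planar regions keep their
area exactly and the subdivision map depends only on the face list — a path
of meshes sharing one face list can be refined breakpoint-by-breakpoint with
a single shared operator.
"""

from __future__ import annotations

import numpy as np

from .core import TriMesh

__all__ = ["midpoint_subdivision_operator", "refine_mesh", "upsample_time"]


def midpoint_subdivision_operator(faces: np.ndarray, n_vertices: int):
    """Build the 1->4 subdivision of a face list.

    Returns ``(new_faces, edge_pairs)`` where ``edge_pairs`` is a (n_edges, 2)
    array: new vertex ``n_vertices + e`` is the midpoint of that vertex pair.
    Applying the operator to any vertex array of matching length gives the
    subdivided positions, so paths of meshes refine consistently.
    """
    faces = np.asarray(faces, dtype=np.int64)
    raw = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    key = np.sort(raw, axis=1)
    edge_pairs, inverse = np.unique(key, axis=0, return_inverse=True)
    mid = n_vertices + inverse.reshape(3, -1)  # rows: edge 01, 12, 20 per face
    m01, m12, m20 = mid[0], mid[1], mid[2]
    v0, v1, v2 = faces[:, 0], faces[:, 1], faces[:, 2]
    new_faces = np.concatenate(
        [
            np.column_stack([v0, m01, m20]),
            np.column_stack([m01, v1, m12]),
            np.column_stack([m20, m12, v2]),
            np.column_stack([m01, m12, m20]),
        ]
    )
    return new_faces, edge_pairs


def subdivide_vertices(vertices: np.ndarray, edge_pairs: np.ndarray) -> np.ndarray:
    mids = 0.5 * (vertices[edge_pairs[:, 0]] + vertices[edge_pairs[:, 1]])
    return np.vstack([vertices, mids])


def refine_mesh(mesh: TriMesh, level: int = 1) -> TriMesh:
    """Midpoint-subdivide ``level`` times (4^level as many faces)."""
    if level < 0:
        raise ValueError("level must be >= 0")
    out = mesh
    for _ in range(level):
        new_faces, edge_pairs = midpoint_subdivision_operator(out.faces, out.n_vertices)
        out = TriMesh(subdivide_vertices(out.vertices, edge_pairs), new_faces)
    return out


def upsample_time(breakpoints: np.ndarray) -> np.ndarray:
    """Insert linear midpoints between consecutive breakpoints of a PL path.

    (N+1, n, 3) -> (2N+1, n, 3); existing breakpoints are preserved.
    """
    bp = np.asarray(breakpoints, dtype=np.float64)
    if bp.ndim != 3 or len(bp) < 2:
        raise ValueError("breakpoints must be (N+1, n, 3) with N >= 1")
    mids = 0.5 * (bp[:-1] + bp[1:])
    out = np.empty((2 * len(bp) - 1,) + bp.shape[1:], dtype=np.float64)
    out[0::2] = bp
    out[1::2] = mids
    return out
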