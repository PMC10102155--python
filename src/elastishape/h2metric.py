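"""The discrete second-order Sobolev (H²) metric on triangle meshes.

For a mesh ``q`` with vertex positions V and a pair of tangent fields h, k
(one 3-vector per vertex) the metric is the six-coefficient family

    G_q(h,k) = a0 * sum_v <h_v, k_v> vol_v
             + sum_f [ a1 tr(g^-1 dh_m dk_m^T) + b1 tr(g^-1 dh_+ dk_+^T)
                     + c1 tr(g^-1 dh_perp dk_perp^T) + d1 tr(g^-1 dh_0 dk_0^T) ] vol_f
             + a2 * sum_v <(L h)_v, (L k)_v> vol_v,

where the first-order differential dh (per face, a 2x3 matrix of edge
differences) is split into four mutually G-orthogonal parts:

* ``dh_m``    — change of the pullback metric at fixed volume (shearing),
* ``dh_+``    — change of the volume density (scaling),
* ``dh_perp`` — change of the unit normal (bending),
* ``dh_0``    — in-plane rotation of the parametrization,

and L is the integrated cotangent Laplacian.  All trace pairings use the
convention ``tr(g_f^{-1} A B^T)`` with A, B stored as 2x3 row-stacked edge
matrices, under which ``tr(g^{-1} dq dq^T) = 2`` on every non-degenerate
face.  The metric is invariant under simultaneous rotation/translation of the
mesh and the tangent fields, and under relabelling of the parametrization.

Degenerate faces contribute zero to the first-order terms (they are flagged
by the mesh kernels); this keeps the energy finite on noisy meshes.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from . import _ad as ad
from .meshkit.core import (
    TangentField,
    TriMesh,
    cotan_laplacian_of,
    face_frames,
    vertex_areas_of,
)

__all__ = [
    "MetricCoefficients",
    "SplitDifferential",
    "split_differential",
    "inner_product",
    "rigid_invariance_check",
    "metric_inner_of",
]


@dataclass(frozen=True)
class MetricCoefficients:
    """Non-negative weights (a0, a1, b1, c1, d1, a2) of the H² metric.

    a0 weights the L² term, (a1, b1, c1, d1) the shearing / scaling /
    bending / parameter-rotation first-order terms, a2 the Laplacian term.
    The shipped default is the all-ones configuration.
    """

    a0: float = 1.0
    a1: float = 1.0
    b1: float = 1.0
    c1: float = 1.0
    d1: float = 1.0
    a2: float = 1.0

    def __post_init__(self):
        vals = (self.a0, self.a1, self.b1, self.c1, self.d1, self.a2)
        if any(v < 0 for v in vals):
            raise ValueError("metric coefficients must be non-negative")
        if all(v == 0 for v in vals):
            raise ValueError("at least one metric coefficient must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d) -> "MetricCoefficients":
        return cls(**{k: float(v) for k, v in d.items()})

    @classmethod
    def from_sequence(cls, seq) -> "MetricCoefficients":
        a0, a1, b1, c1, d1, a2 = (float(v) for v in seq)
        return cls(a0, a1, b1, c1, d1, a2)

    def as_tuple(self):
        return (self.a0, self.a1, self.b1, self.c1, self.d1, self.a2)


@dataclass
class SplitDifferential:
    """Per-face four-way split of a tangent field's differential.

    Each part is an (m, 2, 3) array in the same row-stacked edge convention
    as ``dq_f``; the parts sum to dh and are pairwise orthogonal under
    ``tr(g^{-1} A B^T) vol_f``.
    """

    dh_m: np.ndarray
    dh_plus: np.ndarray
    dh_perp: np.ndarray
    dh_0: np.ndarray

    def total(self) -> np.ndarray:
        return self.dh_m + self.dh_plus + self.dh_perp + self.dh_0


def _split_rows(fr, h, faces):
    """Differentiable four-way split; returns rows (part -> (row1, row2))."""
    h0 = ad.take(h, faces[:, 0])
    h1 = ad.take(h, faces[:, 1])
    h2 = ad.take(h, faces[:, 2])
    b1 = ad.sub(h1, h0)  # dh row 1
    b2 = ad.sub(h2, h0)  # dh row 2
    e1, e2 = fr["e1"], fr["e2"]
    gi11, gi12, gi22 = fr["gi11"], fr["gi12"], fr["gi22"]

    # M1 = dq dh^T entries (paper convention: dq^T dh in the transposed layout)
    m11 = ad.rowdot(e1, b1)
    m12 = ad.rowdot(e1, b2)
    m21 = ad.rowdot(e2, b1)
    m22 = ad.rowdot(e2, b2)

    def col(s):  # (m,) -> (m,1) for row scaling
        return ad.reshape(s, (-1, 1))

    trace = ad.add(ad.add(ad.mul(gi11, m11), ad.mul(gi12, ad.add(m12, m21))), ad.mul(gi22, m22))
    half_tr = ad.mul(0.5, trace)
    plus1 = ad.mul(col(half_tr), e1)
    plus2 = ad.mul(col(half_tr), e2)

    # T = (M1 + M1^T) g^-1
    s11 = ad.mul(2.0, m11)
    s12 = ad.add(m12, m21)
    s22 = ad.mul(2.0, m22)
    T11 = ad.add(ad.mul(s11, gi11), ad.mul(s12, gi12))
    T12 = ad.add(ad.mul(s11, gi12), ad.mul(s12, gi22))
    T21 = ad.add(ad.mul(s12, gi11), ad.mul(s22, gi12))
    T22 = ad.add(ad.mul(s12, gi12), ad.mul(s22, gi22))
    mrow1 = ad.sub(ad.mul(0.5, ad.add(ad.mul(col(T11), e1), ad.mul(col(T12), e2))), plus1)
    mrow2 = ad.sub(ad.mul(0.5, ad.add(ad.mul(col(T21), e1), ad.mul(col(T22), e2))), plus2)

    # U = M1^T g^-1  (tangential projector coefficients)
    u11 = ad.add(ad.mul(m11, gi11), ad.mul(m21, gi12))
    u12 = ad.add(ad.mul(m11, gi12), ad.mul(m21, gi22))
    u21 = ad.add(ad.mul(m12, gi11), ad.mul(m22, gi12))
    u22 = ad.add(ad.mul(m12, gi12), ad.mul(m22, gi22))
    perp1 = ad.sub(b1, ad.add(ad.mul(col(u11), e1), ad.mul(col(u12), e2)))
    perp2 = ad.sub(b2, ad.add(ad.mul(col(u21), e1), ad.mul(col(u22), e2)))

    # W = (M1^T - M1) g^-1, antisymmetric part
    a12 = ad.sub(m21, m12)
    w11 = ad.mul(a12, gi12)
    w12 = ad.mul(a12, gi22)
    w21 = ad.neg(ad.mul(a12, gi11))
    w22 = ad.neg(ad.mul(a12, gi12))
    z1 = ad.mul(0.5, ad.add(ad.mul(col(w11), e1), ad.mul(col(w12), e2)))
    z2 = ad.mul(0.5, ad.add(ad.mul(col(w21), e1), ad.mul(col(w22), e2)))

    deg = fr["degenerate"]
    rows = {
        "m": (mrow1, mrow2),
        "plus": (plus1, plus2),
        "perp": (perp1, perp2),
        "zero": (z1, z2),
    }
    if deg.any():
        mask = deg[:, None]
        rows = {k: (ad.where(mask, 0.0, r1), ad.where(mask, 0.0, r2)) for k, (r1, r2) in rows.items()}
    return rows


def trace_pairing(fr, arows, brows):
    """tr(g^{-1} A B^T) per face for row pairs A=(a1,a2), B=(b1,b2)."""
    a1, a2 = arows
    b1, b2 = brows
    gi11, gi12, gi22 = fr["gi11"], fr["gi12"], fr["gi22"]
    t = ad.mul(gi11, ad.rowdot(a1, b1))
    t = ad.add(t, ad.mul(gi12, ad.add(ad.rowdot(a1, b2), ad.rowdot(a2, b1))))
    t = ad.add(t, ad.mul(gi22, ad.rowdot(a2, b2)))
    return t


def split_differential(mesh: TriMesh, field: TangentField) -> SplitDifferential:
    """Four-way split of dh on every face (zeros on degenerate faces)."""
    field.check(mesh)
    fr = face_frames(mesh.vertices, mesh.faces)
    rows = _split_rows(fr, field.values, mesh.faces)

    def pack(r):
        return np.stack([ad.value(r[0]), ad.value(r[1])], axis=1)

    return SplitDifferential(
        dh_m=pack(rows["m"]),
        dh_plus=pack(rows["plus"]),
        dh_perp=pack(rows["perp"]),
        dh_0=pack(rows["zero"]),
    )


def metric_inner_of(verts, faces, h, k, coeffs: MetricCoefficients,
                    a2_weighting: str = "vertex_area", fr=None):
    """Differentiable G_q(h, k); operands may be arrays or autodiff variables.

    ``a2_weighting`` selects whether the Laplacian term is weighted by the
    vertex areas (default, consistent with the zeroth-order term) or summed
    raw (``"none"``).
    """
    if a2_weighting not in ("vertex_area", "none"):
        raise ValueError("a2_weighting must be 'vertex_area' or 'none'")
    c = coeffs
    need_first = any(v != 0 for v in (c.a1, c.b1, c.c1, c.d1))
    need_vertex_area = c.a0 != 0 or (c.a2 != 0 and a2_weighting == "vertex_area")
    if fr is None and (need_first or True):
        fr = face_frames(verts, faces)
    total = None

    def acc(term):
        nonlocal total
        total = term if total is None else ad.add(total, term)

    va = vertex_areas_of(verts, faces) if need_vertex_area else None
    if c.a0 != 0:
        acc(ad.mul(c.a0, ad.sum_(ad.mul(ad.rowdot(h, k), va))))
    if need_first:
        vol = fr["vol"]
        if fr["degenerate"].any():
            vol = ad.where(fr["degenerate"], 0.0, vol)
        hrows = _split_rows(fr, h, faces)
        same = k is h
        krows = hrows if same else _split_rows(fr, k, faces)
        per_face = None
        for w, key in ((c.a1, "m"), (c.b1, "plus"), (c.c1, "perp"), (c.d1, "zero")):
            if w == 0:
                continue
            t = ad.mul(w, trace_pairing(fr, hrows[key], krows[key]))
            per_face = t if per_face is None else ad.add(per_face, t)
        if per_face is not None:
            acc(ad.sum_(ad.mul(per_face, vol)))
    if c.a2 != 0:
        lh = cotan_laplacian_of(verts, faces, h)
        lk = lh if k is h else cotan_laplacian_of(verts, faces, k)
        sq = ad.rowdot(lh, lk)
        if a2_weighting == "vertex_area":
            sq = ad.mul(sq, va)
        acc(ad.mul(c.a2, ad.sum_(sq)))
    return total


def inner_product(
    mesh: TriMesh,
    h: TangentField,
    k: TangentField,
    coeffs: MetricCoefficients | None = None,
    a2_weighting: str = "vertex_area",
) -> float:
    """Evaluate G_q(h, k); symmetric, bilinear, >= 0 for h = k."""
    coeffs = coeffs or MetricCoefficients()
    h.check(mesh)
    k.check(mesh)
    return float(
        ad.value(
            metric_inner_of(
                mesh.vertices, mesh.faces, h.values, k.values, coeffs, a2_weighting
            )
        )
    )


def rigid_invariance_check(
    mesh: TriMesh,
    h: TangentField,
    k: TangentField,
    coeffs: MetricCoefficients,
    R,
    tau,
) -> float:
    """|G_{Rq+tau}(Rh, Rk) - G_q(h, k)| for a rotation R and translation tau.

    Refuses improper orthogonal inputs (det < 0): the metric's invariance
    statement covers rotations, not reflections.
    """
    R = np.asarray(R, dtype=np.float64)
    if np.linalg.det(R) <= 0:
        raise ValueError("R must be a proper rotation (det > 0)")
    if not np.allclose(R @ R.T, np.eye(3), atol=1e-10):
        raise ValueError("R must be orthogonal")
    tau = np.asarray(tau, dtype=np.float64)
    moved = mesh.with_vertices(mesh.vertices @ R.T + tau[None, :])
    gh = TangentField(h.values @ R.T)
    gk = TangentField(k.values @ R.T)
    a = inner_product(moved, gh, gk, coeffs)
    b = inner_product(mesh, h, k, coeffs)
    return abs(a - b)
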