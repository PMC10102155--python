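"""Matching of weighted surfaces: joint deformation + per-face weight estimation.

When a target surface is missing parts present in the source (partial scans,
different topology), forcing a full-surface match produces singular geodesics
that shrink the unmatched parts to slivers.  Augmenting the transformed
source with a per-face weight function rho in [0, 1]^m — carried into its
varifold representation as a density — lets the optimizer *erase* such parts
instead: the matching objective

    E(path) + lambda0 ||mu_{V(0), rho} - mu_{source, rho0}||^2
            + lambda1 ||mu_{V(1), rho} - mu_{target, rho1}||^2

is minimized jointly over all breakpoints and over rho, with the box
constraint handled by L-BFGS-B.  Only the transformed source carries free
weights; estimating target-side or both-side weights is deliberately not
offered (the trivial all-zero solution makes the dual problem ill-posed
without extra regularization).

Optional penalties (off by default, weights are user inputs): a double-well
term pushing rho towards {0, 1}, and total variation of rho - rho0 across
interior edges to promote piecewise-constant weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import _ad as ad
from .geodesics import (
    GeodesicResult,
    MatchConfig,
    PLPath,
    _lbfgs,
    path_energy,
    path_energy_of,
    _auto_lambdas,
)
from .meshkit.core import MeshError, TriMesh, face_geometry
from .varifold import (
    VarifoldKernel,
    default_sigma,
    to_varifold,
    varifold_terms_of,
    vf_sqdist,
)

log = logging.getLogger("elastishape")

__all__ = [
    "WeightedMesh",
    "solve_bvp_weighted",
    "interpolate_weights",
    "regularizers",
]


@dataclass
class WeightedMesh:
    """A mesh together with a per-face weight function rho in [0, 1]."""

    mesh: TriMesh
    rho: np.ndarray | None = None

    def __post_init__(self):
        if self.rho is None:
            self.rho = np.ones(self.mesh.n_faces)
        self.rho = np.asarray(self.rho, dtype=np.float64)
        if self.rho.shape != (self.mesh.n_faces,):
            raise MeshError(
                f"rho must have one value per face ({self.mesh.n_faces}), got {self.rho.shape}"
            )
        if np.any(self.rho < 0) or np.any(self.rho > 1):
            raise MeshError("rho values must lie in [0, 1]")


def interpolate_weights(rho0, rho, t: float):
    """Convex combination (1 - t) rho0 + t rho for displaying weights along a path."""
    if not 0.0 <= t <= 1.0:
        raise ValueError("t must lie in [0, 1]")
    rho0 = np.asarray(rho0, dtype=np.float64)
    rho = np.asarray(rho, dtype=np.float64)
    return (1.0 - t) * rho0 + t * rho


def regularizers(rho, rho0, mesh: TriMesh, kind: str) -> float:
    """Optional weight penalties.

    ``double_well``: sum_f (rho_f (rho_f - 1))^2 vol_f — zero exactly on
    binary weights.  ``tv``: total variation of rho - rho0 across interior
    edges, weighted by edge length.  ``none``: 0.
    """
    if kind == "none":
        return 0.0
    rho = np.asarray(rho, dtype=np.float64)
    fg = face_geometry(mesh)
    if kind == "double_well":
        return float(np.sum((rho * (rho - 1.0)) ** 2 * fg.vol))
    if kind == "tv":
        rho0 = np.asarray(rho0, dtype=np.float64)
        d = rho - rho0
        faces = mesh.faces
        # interior edges: shared by exactly two faces
        edges = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
        key = np.sort(edges, axis=1)
        face_of = np.tile(np.arange(mesh.n_faces), 3)
        uniq, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
        tv = 0.0
        order = np.argsort(inv, kind="stable")
        inv_sorted = inv[order]
        faces_sorted = face_of[order]
        starts = np.searchsorted(inv_sorted, np.arange(len(uniq)))
        for e in np.flatnonzero(counts == 2):
            fa, fb = faces_sorted[starts[e]], faces_sorted[starts[e] + 1]
            va, vb = uniq[e]
            elen = np.linalg.norm(mesh.vertices[va] - mesh.vertices[vb])
            tv += abs(d[fa] - d[fb]) * elen
        return float(tv)
    raise ValueError("kind must be one of {'double_well', 'tv', 'none'}")


def solve_bvp_weighted(
    source: WeightedMesh,
    target: WeightedMesh,
    config: MatchConfig | None = None,
    template: TriMesh | None = None,
    weight_mode: str = "source",
) -> tuple[GeodesicResult, np.ndarray]:
    """Symmetric relaxed matching with joint estimation of source-side weights.

    Returns ``(result, rho)`` where ``rho`` holds the estimated per-face
    weights on the transformed source (initialized at the source's weights).
    ``template`` sets the path's combinatorics (default: the source mesh).
    """
    if weight_mode != "source":
        raise NotImplementedError(
            "only source-side weight estimation is implemented; target/dual weight "
            "modes risk the trivial all-zero solution and are not offered"
        )
    config = config or MatchConfig()
    kernel = config.kernel or VarifoldKernel(sigma=default_sigma(target.mesh))
    src_vf = to_varifold(source.mesh, source.rho)
    tgt_vf = to_varifold(target.mesh, target.rho)
    lam0, lam1 = _auto_lambdas(src_vf, kernel, config)

    base = template if template is not None else source.mesh
    faces = base.faces
    m = len(faces)
    n = base.n_vertices
    if template is None:
        rho_init = source.rho.copy()
    else:
        rho_init = np.ones(m)
    # the start fidelity compares the path start, carrying the *fixed* source
    # weights, against the source datum: erasure is paid for only at the
    # target end, which is what lets rho vanish on parts missing there.
    rho_start = rho_init.copy()

    tsched = config.time_schedule()
    path = PLPath(np.repeat(base.vertices[None], tsched[0] + 1, axis=0), faces)
    rho = rho_init
    total_iters = 0
    converged = True

    for N in tsched:
        from .geodesics import _resample_time

        path = _resample_time(path, N)
        nvert_vars = (N + 1) * n * 3

        def fun_grad(x, N=N):
            xv = ad.var(x[:nvert_vars].reshape(N + 1, n, 3))
            rv = ad.var(x[nvert_vars:])
            bps = [ad.getitem(xv, (i,)) for i in range(N + 1)]
            obj = path_energy_of(bps, faces, config.coeffs, config.a2_weighting)
            obj = ad.add(
                obj, ad.mul(lam0, varifold_terms_of(bps[0], faces, src_vf, kernel,
                                                    weights=rho_start))
            )
            obj = ad.add(
                obj, ad.mul(lam1, varifold_terms_of(bps[-1], faces, tgt_vf, kernel, weights=rv))
            )
            val = float(ad.value(obj))
            if not np.isfinite(val):
                raise FloatingPointError(
                    "weighted matching objective is non-finite; check the kernel width sigma"
                )
            gx, gr = ad.grad(obj, [xv, rv])
            return val, np.concatenate([gx.ravel(), gr.ravel()])

        x0 = np.concatenate([path.breakpoints.ravel(), rho])
        bounds = [(None, None)] * nvert_vars + [(0.0, 1.0)] * m
        x, res, trace = _lbfgs(fun_grad, x0, config, bounds=bounds)
        total_iters += res.nit
        converged = converged and (res.status == 0 or np.max(np.abs(res.jac)) <= config.tolerance * 10)
        path = PLPath(x[:nvert_vars].reshape(N + 1, n, 3), faces)
        rho = np.clip(x[nvert_vars:], 0.0, 1.0)

    energy = path_energy(path, config.coeffs, config.a2_weighting)
    res0 = vf_sqdist(to_varifold(path.mesh_at(0), rho_start), src_vf, kernel)
    res1 = vf_sqdist(to_varifold(path.mesh_at(path.N), rho), tgt_vf, kernel)
    total = energy + lam0 * res0 + lam1 * res1
    result = GeodesicResult(
        path=path,
        energy=energy,
        varifold_residuals=(res0, res1),
        total_objective=total,
        converged=bool(converged),
        iterations=total_iters,
    )
    return result, rho
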