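"""Population statistics on the space of surfaces.

All tools are built on the geodesic solvers: a Karcher mean estimated by the
stochastic iterative-geodesic-centroid scheme, principal component analysis
in the tangent space at a reference shape (under the Riemannian inner
product), stress-minimizing multidimensional scaling of a geodesic distance
matrix, and first-order parallel transport by Schild's ladder.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.manifold import smacof

from .geodesics import (
    GeodesicResult,
    MatchConfig,
    PLPath,
    initial_velocity,
    solve_bvp_param,
    solve_bvp_relaxed,
    solve_ivp,
)
from .h2metric import MetricCoefficients, inner_product
from .meshkit.core import MeshError, TangentField, TriMesh

log = logging.getLogger("elastishape")

__all__ = [
    "karcher_mean",
    "tangent_pca",
    "PCABasis",
    "principal_geodesic",
    "mds_embed",
    "pairwise_distances",
    "schilds_ladder",
]


def _same_structure(a: TriMesh, b: TriMesh) -> bool:
    return a.n_vertices == b.n_vertices and np.array_equal(a.faces, b.faces)


def _solve_geodesic(src: TriMesh, dst: TriMesh, config: MatchConfig, mode: str) -> GeodesicResult:
    if mode == "param":
        return solve_bvp_param(src, dst, config)
    return solve_bvp_relaxed(src, dst, config, symmetric=False)


def _resolve_mode(meshes, mode: str) -> str:
    if mode != "auto":
        return mode
    first = meshes[0]
    return "param" if all(_same_structure(first, m) for m in meshes[1:]) else "relaxed"


# ---------------------------------------------------------------------------
# Karcher mean


def karcher_mean(
    data: list[TriMesh],
    config: MatchConfig | None = None,
    init: TriMesh | None = None,
    mode: str = "auto",
    n_iter: int | None = None,
    return_info: bool = False,
):
    """Iterative geodesic centroid estimate of the Karcher mean.

    Starting from ``init`` (default: the Euclidean vertex mean, available when
    all data share one mesh structure), each iteration i picks a datum
    uniformly at random (with replacement, seeded by ``config.seed``), solves
    the geodesic from the current estimate to it, and moves the estimate to
    the path point at time 1/(i+1).  ``n_iter`` defaults to 3 K.  For
    inconsistently meshed data, ``init`` is required and fixes the mean's
    combinatorics; the relaxed solver is then used.
    """
    if not data:
        raise ValueError("karcher_mean needs at least one mesh")
    config = config or MatchConfig()
    K = len(data)
    mode = _resolve_mode(([init] if init is not None else []) + list(data), mode)
    if init is None:
        if mode == "relaxed":
            raise MeshError("inconsistently meshed data: an init mesh is required")
        init = data[0].with_vertices(np.mean([m.vertices for m in data], axis=0))
    n_iter = 3 * K if n_iter is None else int(n_iter)
    rng = np.random.default_rng(config.seed)

    estimate = init.copy()
    failures = 0
    for i in range(1, n_iter + 1):
        k = int(rng.integers(K))
        try:
            result = _solve_geodesic(estimate, data[k], config, mode)
        except FloatingPointError as e:  # pragma: no cover - diagnostic path
            log.warning("karcher_mean: iteration %d matching failed (%s); skipped", i, e)
            failures += 1
            continue
        estimate = result.path.at_time(1.0 / (i + 1))
    if return_info:
        return estimate, {"failures": failures, "n_iter": n_iter, "mode": mode}
    return estimate


def karcher_objective(estimate: TriMesh, data, config: MatchConfig, mode: str = "auto") -> float:
    """Sum of squared geodesic distance estimates from ``estimate`` to the data."""
    mode = _resolve_mode([estimate] + list(data), mode)
    return float(
        sum(_solve_geodesic(estimate, m, config, mode).distance_estimate ** 2 for m in data)
    )


# ---------------------------------------------------------------------------
# tangent PCA


@dataclass
class PCABasis:
    """Tangent-space PCA result at a reference shape.

    ``eigenvalues`` are the (non-increasing, clamped-at-0) eigenvalues of the
    K x K Gram matrix of centered tangents under G_ref; ``components[l]`` is
    the principal tangent field w_l = sum_k v_{l,k} (h_k - hbar), which makes
    the components G_ref-orthogonal with squared norms equal to the
    eigenvalues.  ``coords[k, l] = G_ref(h_k - hbar, w_l)`` are the data
    coordinates.
    """

    reference: TriMesh
    eigenvalues: np.ndarray
    components: list
    mean_tangent: TangentField
    coords: np.ndarray
    tangents: list = field(default_factory=list)
    coeffs: MetricCoefficients = field(default_factory=MetricCoefficients)


def tangent_pca(
    data: list[TriMesh],
    reference: TriMesh,
    config: MatchConfig | None = None,
    mode: str = "auto",
    n_components: int | None = None,
) -> PCABasis:
    """PCA of log-map tangents at ``reference`` under the H² inner product.

    One geodesic BVP is solved per datum (parametrized when structures match,
    relaxed otherwise); tangents are the finite-difference initial velocities
    of those paths.  The eigendecomposition of the centered Gram matrix under
    G_ref yields the principal tangent directions.
    """
    config = config or MatchConfig()
    K = len(data)
    if K < 2:
        raise ValueError("tangent_pca needs at least 2 data meshes")
    mode = _resolve_mode([reference] + list(data), mode)
    tangents = []
    for m in data:
        res = _solve_geodesic(reference, m, config, mode)
        tangents.append(initial_velocity(res.path))
    hbar = TangentField(np.mean([t.values for t in tangents], axis=0))
    centered = [t - hbar for t in tangents]

    gram = np.empty((K, K))
    for i in range(K):
        for j in range(i, K):
            gram[i, j] = gram[j, i] = inner_product(
                reference, centered[i], centered[j], config.coeffs, config.a2_weighting
            )
    evals, evecs = np.linalg.eigh(gram)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    evals = np.where(evals > 0, evals, 0.0)

    L = K if n_components is None else min(n_components, K)
    components = []
    for l in range(L):
        w = np.zeros_like(hbar.values)
        for k in range(K):
            w += evecs[k, l] * centered[k].values
        components.append(TangentField(w))
    coords = gram @ evecs[:, :L]  # coords[k, l] = G(h_k - hbar, w_l) = lambda_l v_{l,k}
    return PCABasis(
        reference=reference,
        eigenvalues=evals[:L],
        components=components,
        mean_tangent=hbar,
        coords=coords,
        tangents=tangents,
        coeffs=config.coeffs,
    )


def principal_geodesic(
    basis: PCABasis,
    component: int,
    N: int = 4,
    sign: int = +1,
    pc_scale: str = "lambda",
    config: MatchConfig | None = None,
) -> PLPath:
    """Shoot the principal geodesic along +-scale * w_l from the reference.

    ``pc_scale`` is ``"lambda"`` (the eigenvalue, matching the construction
    of the basis) or ``"sqrt_lambda"`` (the conventional standard deviation).
    """
    if pc_scale not in ("lambda", "sqrt_lambda"):
        raise ValueError("pc_scale must be 'lambda' or 'sqrt_lambda'")
    lam = basis.eigenvalues[component]
    scale = lam if pc_scale == "lambda" else np.sqrt(lam)
    h = TangentField(float(sign) * scale * basis.components[component].values)
    return solve_ivp(basis.reference, h, N, basis.coeffs, config)


# ---------------------------------------------------------------------------
# multidimensional scaling


def pairwise_distances(data: list[TriMesh], config: MatchConfig | None = None) -> np.ndarray:
    """Symmetric geodesic distance matrix via the symmetric relaxed solver.

    Distances are computed for i < j and symmetrized by averaging the two
    orientations of each pair when the solver's left-endpoint time rule makes
    them differ (they agree to O(1/N)); here each pair is solved once and
    mirrored, which is exact under the symmetric formulation up to that
    discretization asymmetry.
    """
    config = config or MatchConfig()
    K = len(data)
    D = np.zeros((K, K))
    for i in range(K):
        for j in range(i + 1, K):
            dij = solve_bvp_relaxed(data[i], data[j], config, symmetric=True).distance_estimate
            dji = solve_bvp_relaxed(data[j], data[i], config, symmetric=True).distance_estimate
            D[i, j] = D[j, i] = 0.5 * (dij + dji)
    return D


def _classical_scaling(D: np.ndarray, dim: int) -> np.ndarray:
    K = len(D)
    J = np.eye(K) - np.ones((K, K)) / K
    B = -0.5 * J @ (D**2) @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1][:dim]
    lam = np.clip(evals[order], 0.0, None)
    return evecs[:, order] * np.sqrt(lam)[None, :]


def _stress(D: np.ndarray, Y: np.ndarray) -> float:
    delta = np.linalg.norm(Y[:, None, :] - Y[None, :, :], axis=-1)
    off = ~np.eye(len(D), dtype=bool)
    return float(np.sqrt(np.sum((D[off] - delta[off]) ** 2)))


def mds_embed(dist_matrix: np.ndarray, dim: int, max_iter: int = 300):
    """Metric MDS: minimize the root-sum-of-squares distance mismatch.

    Classical scaling provides the start (exact for Euclidean-realizable
    matrices); SMACOF majorization iterations then minimize the stress.
    Returns ``(coords, stress)``; the embedding is determined only up to
    rigid motion, so only its pairwise distances are meaningful.
    """
    D = np.asarray(dist_matrix, dtype=np.float64)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("dist_matrix must be square")
    if not np.allclose(D, D.T, atol=1e-12 * max(1.0, np.abs(D).max())):
        raise ValueError("dist_matrix must be symmetric")
    if np.any(D < 0) or np.any(np.abs(np.diag(D)) > 0):
        raise ValueError("dist_matrix must be non-negative with zero diagonal")
    init = _classical_scaling(D, dim)
    Y, _ = smacof(
        D,
        metric=True,
        n_components=dim,
        init=init,
        n_init=1,
        max_iter=max_iter,
        eps=1e-12,
        random_state=0,
        normalized_stress=False,
    )
    if _stress(D, Y) > _stress(D, init):  # majorization should not regress
        Y = init
    return Y, _stress(D, Y)


# ---------------------------------------------------------------------------
# Schild's ladder


def schilds_ladder(
    x0: TriMesh,
    x1: TriMesh,
    h: TangentField,
    config: MatchConfig | None = None,
    n_rungs: int = 3,
) -> TangentField:
    """First-order parallel transport of ``h`` from x0 to x1 along their geodesic.

    The base geodesic is split into ``n_rungs`` uniform segments; each rung
    builds one geodesic parallelogram: with P_i the segment ends and A_i the
    endpoint of the transported vector (A_0 = Exp_{x0} h), the midpoint M of
    A_i and P_{i+1} is computed by a BVP, the diagonal geodesic from P_i
    through M is extended to twice its length by an IVP to give A_{i+1}, and
    the transported vector at x1 is the log map Log_{x1} A_n.  All
    sub-geodesics use the parametrized solver (x0 and x1 must share their
    mesh structure).
    """
    h.check(x0)
    config = config or MatchConfig()
    if not _same_structure(x0, x1):
        raise MeshError("schilds_ladder requires meshes with shared structure")
    if np.allclose(x0.vertices, x1.vertices):
        return TangentField(h.values.copy())
    if not np.any(h.values):
        return TangentField.zeros(x1)
    if n_rungs < 1:
        raise ValueError("n_rungs must be >= 1")

    sub = MatchConfig(
        coeffs=config.coeffs,
        N=max(2, config.N // 2),
        max_iter=config.max_iter,
        tolerance=config.tolerance,
        a2_weighting=config.a2_weighting,
    )
    base = solve_bvp_param(x0, x1, MatchConfig(
        coeffs=config.coeffs, N=n_rungs, max_iter=config.max_iter,
        tolerance=config.tolerance, a2_weighting=config.a2_weighting,
    ))
    # resample the base geodesic at the rung points
    P = [base.path.at_time(i / n_rungs) for i in range(n_rungs + 1)]

    def exp_map(q: TriMesh, vec: TangentField) -> TriMesh:
        path = solve_ivp(q, vec, sub.N, sub.coeffs, sub)
        return path.mesh_at(path.N)

    def log_map(q: TriMesh, p: TriMesh) -> TangentField:
        res = solve_bvp_param(q, p, sub)
        return initial_velocity(res.path)

    A = exp_map(x0, h)
    for i in range(n_rungs):
        mid_res = solve_bvp_param(A, P[i + 1], sub)
        M = mid_res.path.at_time(0.5)
        v = log_map(P[i], M)
        A = exp_map(P[i], TangentField(2.0 * v.values))
    return log_map(x1, A)
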