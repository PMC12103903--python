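"""Unified-graph learning with a constrained Laplacian rank.

The fused objective couples per-view adaptive-neighbor graphs S^v, the
unified graph U and a spectral embedding F:

    min  sum_v sum_ij ||x_i^v - x_j^v||^2 s_ij^v
       + sum_v sum_i gamma_i^v ||s_i^v||^2
       + sum_v w_v ||U - S^v||_F^2
       + 2 lambda Tr(F^T L_U F)

subject to every row of every S^v and of U lying on the probability
simplex (zero diagonal for S^v) and F^T F = I, where
L_U = D_U - (U^T + U) / 2.  When lambda is large enough the c smallest
eigenvalues of L_U vanish, rank(L_U) = n - c, and the connected components
of U are the c clusters — no downstream clustering step is needed.
lambda is not tuned by hand: it doubles while fewer than c eigenvalues are
(numerically) zero and halves when too many are.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse
import scipy.sparse.csgraph

from .graphs import (
    SimilarityGraph,
    ViewWeights,
    init_similarity_graph,
    init_weights,
    pairwise_sq_dist,
    update_similarity_graph,
    update_view_weights,
)
from .views import ViewSet

__all__ = [
    "UnifiedGraph",
    "Embedding",
    "FusionState",
    "laplacian",
    "update_embedding",
    "simplex_project",
    "update_unified",
    "count_components",
    "adapt_lambda",
    "objective",
    "coordinate_sweep",
    "run_scmcgf",
]


@dataclass
class UnifiedGraph:
    """Nonnegative row-stochastic fused affinity matrix."""

    U: np.ndarray

    def validate(self, tol: float = 1e-8) -> None:
        if np.any(self.U < -tol):
            raise ValueError("negative entries in U")
        if np.any(np.abs(self.U.sum(axis=1) - 1.0) > tol):
            raise ValueError("rows of U do not sum to 1")


@dataclass
class Embedding:
    """Orthonormal spectral embedding F (n x c) and the c smallest eigenvalues."""

    F: np.ndarray
    eigenvalues: np.ndarray

    def validate(self, tol: float = 1e-8) -> None:
        c = self.F.shape[1]
        if np.linalg.norm(self.F.T @ self.F - np.eye(c)) > tol:
            raise ValueError("F columns are not orthonormal")


@dataclass
class FusionState:
    """All optimizer variables for one run."""

    graphs: list[SimilarityGraph]
    weights: ViewWeights
    unified: UnifiedGraph
    embedding: Embedding
    lam: float
    iteration: int = 0
    converged: bool = False
    fallback_used: bool = False
    history: list[dict] = field(default_factory=list)


def laplacian(U: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Symmetrized graph Laplacian L_U = D_U - (U^T + U)/2 and degree matrix."""
    A = (U + U.T) / 2.0
    D = np.diag(A.sum(axis=1))
    return D - A, D


def update_embedding(L: np.ndarray, c: int) -> Embedding:
    """Eigenvectors of the c smallest eigenvalues of symmetric L (Ky Fan).

    Deterministic sign convention: each column's largest-magnitude entry is
    made positive.
    """
    n = L.shape[0]
    if not (1 <= c <= n):
        raise ValueError(f"need 1 <= c <= n, got c={c}")
    evals, evecs = scipy.linalg.eigh(L, subset_by_index=[0, c - 1])
    for j in range(c):
        i = int(np.argmax(np.abs(evecs[:, j])))
        if evecs[i, j] < 0:
            evecs[:, j] = -evecs[:, j]
    return Embedding(evecs, evals)


def simplex_project(p: np.ndarray, tol: float = 1e-12, max_iter: int = 100) -> np.ndarray:
    """Euclidean projection of p onto {u : u >= 0, 1^T u = 1}.

    The projection is invariant to shifts along the all-ones direction, so p
    is first shifted to sum to 1; the threshold phi* then solves
    f(phi) = (1/n) sum_j (phi - p_j)_+ - phi = 0, found by safeguarded
    Newton iteration (f is piecewise linear and strictly decreasing), and
    u_j = (p_j - phi*)_+.
    """
    p = np.asarray(p, dtype=float)
    if not np.all(np.isfinite(p)):
        raise ValueError("non-finite input to simplex projection")
    n = p.size
    q = p - (p.sum() - 1.0) / n

    lo, hi = float(q.min()) - 1.0, float(q.max())  # f(lo) > 0 >= f(hi)
    phi = 0.0 if lo <= 0.0 <= hi else (lo + hi) / 2.0
    for _ in range(max_iter):
        diff = phi - q
        pos = diff > 0
        fval = diff[pos].sum() / n - phi
        if abs(fval) < tol:
            break
        if fval > 0:
            lo = phi
        else:
            hi = phi
        fprime = pos.sum() / n - 1.0
        if fprime < 0:
            step = phi - fval / fprime
        else:
            step = (lo + hi) / 2.0
        phi = step if lo < step < hi else (lo + hi) / 2.0
    u = np.maximum(q - phi, 0.0)
    total = u.sum()
    if not np.isfinite(total) or total <= 0:
        raise RuntimeError("simplex projection failed to converge")
    return u / total


def update_unified(
    graphs: list[SimilarityGraph],
    weights: ViewWeights,
    F: np.ndarray,
    lam: float,
) -> UnifiedGraph:
    """Row-wise closed-form U-update.

    With d_ij = ||f_i - f_j||^2 and q^v = s_i^v - lambda/(2 m w_v) d_i, the
    minimizer of each row subproblem is the simplex projection of the mean
    of the q^v.
    """
    if lam <= 0:
        raise ValueError("lam must be positive")
    m = len(graphs)
    n = graphs[0].S.shape[0]
    D_f = pairwise_sq_dist(F.T)
    S_mean = sum(g.S for g in graphs) / m
    coef = lam / (2.0 * m * m) * float(np.sum(1.0 / weights.w))
    P = S_mean - coef * D_f
    U = np.empty((n, n))
    for i in range(n):
        U[i] = simplex_project(P[i])
    return UnifiedGraph(U)


def count_components(
    U: np.ndarray,
    edge_tol: float = 1e-8,
    eig_tol: float | None = None,
    check_eigen: bool = True,
) -> tuple[int, np.ndarray]:
    """Connected components of the symmetrized graph, cross-checked against
    the multiplicity of (near-)zero eigenvalues of L_U.

    A disagreement between the two counts (possible while the optimizer is
    mid-flight and edges hover at the thresholds) emits a diagnostic
    warning; the traversal count is returned.
    """
    n = U.shape[0]
    A = (U + U.T) / 2.0
    adj = A > edge_tol
    np.fill_diagonal(adj, False)
    count, labels = scipy.sparse.csgraph.connected_components(
        scipy.sparse.csr_matrix(adj), directed=False
    )
    if check_eigen:
        L, _ = laplacian(U)
        tol = eig_tol if eig_tol is not None else 1e-10 * n
        z = int(np.sum(scipy.linalg.eigvalsh(L) < tol))
        if z != count:
            warnings.warn(
                f"component count mismatch: {z} near-zero eigenvalues vs "
                f"{count} graph components"
            )
    return count, labels


def zero_eigenvalue_count(L: np.ndarray, eig_tol: float | None = None) -> int:
    """Multiplicity of the (numerically) zero eigenvalue of L."""
    n = L.shape[0]
    tol = eig_tol if eig_tol is not None else 1e-10 * n
    return int(np.sum(scipy.linalg.eigvalsh(L) < tol))


def adapt_lambda(state: FusionState, c: int, eig_tol: float | None = None) -> float:
    """Steer lambda by the zero-eigenvalue count z of L_U: double while
    z < c, halve when z > c, flag convergence at z = c."""
    L, _ = laplacian(state.unified.U)
    z = zero_eigenvalue_count(L, eig_tol)
    if z == c:
        state.converged = True
    elif z < c:
        state.lam *= 2.0
    else:
        state.lam /= 2.0
    return state.lam


def objective(
    distances: list[np.ndarray],
    graphs: list[SimilarityGraph],
    weights: ViewWeights,
    U: np.ndarray,
    F: np.ndarray,
    lam: float,
    gamma_rows: list[np.ndarray] | None = None,
) -> float:
    """Value of the fused objective at the given state.

    ``gamma_rows`` (one vector per view) overrides the per-row regularizers
    recorded in the graphs, so the objective can be evaluated with frozen
    parameters during a coordinate-descent sweep.
    """
    total = 0.0
    for v, (D_v, g) in enumerate(zip(distances, graphs)):
        gam = gamma_rows[v] if gamma_rows is not None else g.gamma_rows
        total += float(np.sum(D_v * g.S))
        total += float(np.sum(gam * np.sum(g.S**2, axis=1)))
        total += weights.w[v] * float(np.linalg.norm(U - g.S, "fro") ** 2)
    L, _ = laplacian(U)
    total += 2.0 * lam * float(np.trace(F.T @ L @ F))
    return total


def coordinate_sweep(
    distances: list[np.ndarray],
    graphs: list[SimilarityGraph],
    weights: ViewWeights,
    U: np.ndarray,
    F: np.ndarray,
    lam: float,
    c: int,
) -> tuple[list[SimilarityGraph], np.ndarray, np.ndarray]:
    """One exact block-coordinate sweep S -> U -> F at fixed gamma, w, lambda.

    Each block update is the exact minimizer of its subproblem, so the
    objective evaluated at the frozen parameters cannot increase.
    """
    new_graphs = [
        update_similarity_graph(D_v, U, weights.w[v], k=g.k, gamma_rows=g.gamma_rows)
        for v, (D_v, g) in enumerate(zip(distances, graphs))
    ]
    new_U = update_unified(new_graphs, weights, F, lam).U
    L, _ = laplacian(new_U)
    new_F = update_embedding(L, c).F
    return new_graphs, new_U, new_F


def run_scmcgf(
    views: ViewSet,
    c: int,
    k: int | None = None,
    max_iter: int = 50,
    *,
    lambda_init: float | None = None,
    eig_tol: float | None = None,
    edge_tol: float = 1e-8,
    order_by: str = "combined",
    fallback: str = "kmeans_F",
    seed: int = 0,
    callback=None,
) -> tuple[FusionState, np.ndarray]:
    """Alternating optimization of the fused objective; clusters are the
    connected components of the final unified graph.

    Per iteration: update every S^v against U, refresh the view weights,
    update U row-wise, recompute the embedding F, then adapt lambda by the
    zero-eigenvalue count (a halving recomputes the U-update with the
    smaller lambda).  Stops when L_U has exactly c zero eigenvalues or
    after ``max_iter`` sweeps.  If the final graph does not split into c
    components, labels fall back to seeded k-means on the rows of F and the
    state is flagged; ``fallback="error"`` raises instead.
    """
    n = views.n
    m = views.m
    if c < 2:
        raise ValueError("c must be >= 2")
    if c > n:
        raise ValueError("more clusters than cells")
    if k is None:
        k = 5 if n < 3000 else 15
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")

    distances = [pairwise_sq_dist(X) for X in views.views]
    graphs = [init_similarity_graph(D, k) for D in distances]
    weights = init_weights(m)

    # U starts at the simplex-projected weighted mean of the initial graphs
    # (the lambda -> 0 fixed point); F from its Laplacian.
    S_w = sum(w * g.S for w, g in zip(weights.w, graphs))
    U = np.empty((n, n))
    for i in range(n):
        U[i] = simplex_project(S_w[i])
    unified = UnifiedGraph(U)
    L, _ = laplacian(U)
    embedding = update_embedding(L, c)

    if lambda_init is None:
        lambda_init = float(np.mean([g.gamma_rows.mean() for g in graphs]))
        lambda_init = max(lambda_init, 1e-8)
    state = FusionState(graphs, weights, unified, embedding, lambda_init)

    for it in range(1, max_iter + 1):
        state.iteration = it
        state.graphs = [
            update_similarity_graph(
                distances[v], state.unified.U, state.weights.w[v], k, order_by=order_by
            )
            for v in range(m)
        ]
        state.weights = update_view_weights(state.unified.U, state.graphs)
        state.unified = update_unified(
            state.graphs, state.weights, state.embedding.F, state.lam
        )
        L, _ = laplacian(state.unified.U)
        state.embedding = update_embedding(L, c)
        z = zero_eigenvalue_count(L, eig_tol)
        if z > c:
            # overshoot: halve lambda and redo the U-update at the smaller value
            state.lam /= 2.0
            state.unified = update_unified(
                state.graphs, state.weights, state.embedding.F, state.lam
            )
            L, _ = laplacian(state.unified.U)
            state.embedding = update_embedding(L, c)
            z = zero_eigenvalue_count(L, eig_tol)
        if not np.all(np.isfinite(state.unified.U)):
            raise RuntimeError(
                f"non-finite unified graph at iteration {it}; "
                f"lambda={state.lam:.3e}, weights={state.weights.w}"
            )
        obj = objective(
            distances, state.graphs, state.weights, state.unified.U,
            state.embedding.F, state.lam,
        )
        state.history.append(
            dict(
                iteration=it,
                objective=obj,
                zero_eigenvalues=int(z),
                lam=state.lam,
                weights=state.weights.w.tolist(),
            )
        )
        if callback is not None:
            callback(state)
        if z == c:
            state.converged = True
            break
        elif z < c:
            state.lam *= 2.0

    count, comp_labels = count_components(
        state.unified.U, edge_tol, eig_tol, check_eigen=False
    )
    if count == c:
        labels = comp_labels
    else:
        if fallback == "error":
            raise RuntimeError(
                f"rank constraint not met: {count} components, wanted {c}"
            )
        from sklearn.cluster import KMeans

        state.fallback_used = True
        labels = KMeans(n_clusters=c, random_state=seed, n_init=10).fit_predict(
            state.embedding.F
        )
    return state, np.asarray(labels, dtype=int)
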