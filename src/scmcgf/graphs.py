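"""Per-view similarity graphs with adaptive neighbors, and the view weights.

Each view v gets an n x n row-stochastic, zero-diagonal, k-sparse
similarity matrix S^v.  A row is the minimizer over the probability simplex
of

    sum_j cost_ij * s_ij + (gamma_i + w_v) * ||s_i||^2,

where the cost is the squared Euclidean distance b_ij at initialization
(w_v = 0) and the combined cost e_ij - 2 * w_v * u_ij once a unified graph
U exists.  Choosing gamma_i per row as half of (k * c_(k+1) - sum of the k
smallest costs) makes the solution exactly k-sparse and yields the closed
form

    s_ij = (c_(k+1) - c_ij) / (k * c_(k+1) - sum_{h<=k} c_ih)

over the k smallest-cost neighbors.  View weights follow the auto-weighting
rule w_v = 1 / (2 ||U - S^v||_F).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SimilarityGraph",
    "ViewWeights",
    "pairwise_sq_dist",
    "init_similarity_graph",
    "update_similarity_graph",
    "update_view_weights",
    "init_weights",
]

_DEGENERATE_TOL = 1e-12


@dataclass
class SimilarityGraph:
    """Row-stochastic, zero-diagonal, k-sparse similarity matrix.

    ``gamma_rows[i]`` is the per-row regularizer that makes row i the exact
    simplex-QP minimizer (see module docstring); recorded so the fused
    objective can be evaluated and so oracle checks can reproduce the row.
    """

    S: np.ndarray
    k: int
    gamma_rows: np.ndarray

    def validate(self, tol: float = 1e-8) -> None:
        n = self.S.shape[0]
        if self.S.shape != (n, n):
            raise ValueError("S must be square")
        if np.any(self.S < -tol):
            raise ValueError("negative similarity entries")
        if np.any(np.abs(np.diag(self.S)) > tol):
            raise ValueError("nonzero diagonal")
        if np.any(np.abs(self.S.sum(axis=1) - 1.0) > tol):
            raise ValueError("row sums differ from 1")
        if np.any((self.S > tol).sum(axis=1) > self.k):
            raise ValueError(f"a row has more than k={self.k} nonzeros")


@dataclass
class ViewWeights:
    w: np.ndarray

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if np.any(self.w <= 0) or not np.all(np.isfinite(self.w)):
            raise ValueError("view weights must be positive and finite")

    @property
    def m(self) -> int:
        return self.w.size


def pairwise_sq_dist(X: np.ndarray) -> np.ndarray:
    """Squared Euclidean distances between the columns of X (d_v x n).

    Symmetric, zero diagonal; negative round-off clamped to 0.
    """
    X = np.asarray(X, dtype=float)
    G = X.T @ X
    sq = np.diag(G)
    D = sq[:, None] + sq[None, :] - 2.0 * G
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    return np.maximum(D, 0.0)


def _closed_form_rows(costs: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise adaptive-neighbor closed form on an arbitrary cost matrix.

    ``costs`` has the diagonal set to +inf by the caller.  Returns (S, eta)
    where eta_i = (k * c_(k+1) - sum_{h<=k} c_ih) / 2 is the effective
    quadratic regularizer of row i.  Ties at the k/(k+1) boundary break by
    ascending column index (stable argsort).  A degenerate row (k nearest
    all equal to the (k+1)-th) falls back to uniform 1/k with a warning.
    """
    n = costs.shape[0]
    S = np.zeros((n, n))
    eta = np.zeros(n)
    order = np.argsort(costs, axis=1, kind="stable")
    degenerate = 0
    for i in range(n):
        nn = order[i, :k]
        c_nn = costs[i, nn]
        c_k1 = costs[i, order[i, k]]
        denom = k * c_k1 - c_nn.sum()
        eta[i] = denom / 2.0
        if not np.isfinite(denom) or denom <= _DEGENERATE_TOL:
            S[i, nn] = 1.0 / k
            degenerate += 1
        else:
            S[i, nn] = (c_k1 - c_nn) / denom
    if degenerate:
        warnings.warn(
            f"{degenerate} row(s) had a degenerate denominator; used uniform 1/k"
        )
    return S, eta


def init_similarity_graph(D: np.ndarray, k: int) -> SimilarityGraph:
    """Initial graph from squared distances alone (the w_v = 0 case).

    Row i spreads mass over its k nearest neighbors:
    s_ij = (b_(k+1) - b_ij) / (k * b_(k+1) - sum_{h<=k} b_ih), and
    gamma_i = (k/2) * b_(k+1) - (1/2) * sum_{h<=k} b_ih.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if not (1 <= k <= n - 2):
        raise ValueError(f"need 1 <= k <= n-2 (the (k+1)-th neighbor), got k={k}, n={n}")
    costs = D.copy()
    np.fill_diagonal(costs, np.inf)
    S, eta = _closed_form_rows(costs, k)
    return SimilarityGraph(S, k, eta)


def update_similarity_graph(
    D_v: np.ndarray,
    U: np.ndarray,
    w_v: float,
    k: int,
    *,
    order_by: str = "combined",
    gamma_rows: np.ndarray | None = None,
) -> SimilarityGraph:
    """Refresh one view's graph against the current unified graph U.

    Default (``order_by="combined"``): neighbors are ranked by the combined
    cost e_ij - 2 * w_v * u_ij — the quantity the row subproblem actually
    penalizes — and the k-sparse closed form is applied to it; the recorded
    gamma is the implied row regularizer minus w_v.

    ``order_by="expression"`` ranks by e_ij alone and evaluates the printed
    update on that ordering; entries the formula drives negative are clamped
    to 0 and the row renormalized.

    ``gamma_rows`` switches to the exact fixed-regularizer mode: each row is
    the simplex projection of -(e_i - 2 w_v u_i) / (2 (gamma_i + w_v)),
    i.e. the exact minimizer of the row subproblem at that gamma (used by
    the monotone coordinate-descent sweep; not k-sparse in general).
    """
    D_v = np.asarray(D_v, dtype=float)
    U = np.asarray(U, dtype=float)
    n = D_v.shape[0]
    if w_v <= 0:
        raise ValueError("w_v must be positive")
    if gamma_rows is None and not (1 <= k <= n - 2):
        raise ValueError(f"need 1 <= k <= n-2, got k={k}, n={n}")

    combined = D_v - 2.0 * w_v * U
    np.fill_diagonal(combined, np.inf)

    if gamma_rows is not None:
        S = np.zeros((n, n))
        mask = ~np.eye(n, dtype=bool)
        for i in range(n):
            eta = gamma_rows[i] + w_v
            if eta <= 0:
                raise ValueError(f"gamma_rows[{i}] + w_v must be positive")
            p = -combined[i, mask[i]] / (2.0 * eta)
            S[i, mask[i]] = _project_simplex_sorted(p)
        return SimilarityGraph(S, n - 1, np.asarray(gamma_rows, dtype=float))

    if order_by == "combined":
        S, eta = _closed_form_rows(combined, k)
        return SimilarityGraph(S, k, eta - w_v)
    if order_by != "expression":
        raise ValueError(f"unknown order_by {order_by!r}")

    # printed form on the plain-distance ordering; may need clamping
    e = D_v.copy()
    np.fill_diagonal(e, np.inf)
    order = np.argsort(e, axis=1, kind="stable")
    S = np.zeros((n, n))
    eta = np.zeros(n)
    for i in range(n):
        nn = order[i, :k]
        j_k1 = order[i, k]
        e_nn, e_k1 = e[i, nn], e[i, j_k1]
        u_nn, u_k1 = U[i, nn], U[i, j_k1]
        denom = (
            k * e_k1 - e_nn.sum() - 2.0 * k * w_v * u_k1 + 2.0 * w_v * u_nn.sum()
        )
        eta[i] = denom / 2.0 - w_v
        if not np.isfinite(denom) or abs(denom) <= _DEGENERATE_TOL:
            warnings.warn(f"row {i}: zero denominator; used uniform 1/k")
            S[i, nn] = 1.0 / k
            continue
        row = (e_k1 - e_nn + 2.0 * w_v * u_nn - 2.0 * w_v * u_k1) / denom
        row = np.maximum(row, 0.0)
        total = row.sum()
        if total <= 0:
            warnings.warn(f"row {i}: clamping removed all mass; used uniform 1/k")
            S[i, nn] = 1.0 / k
        else:
            S[i, nn] = row / total
    return SimilarityGraph(S, k, eta)


def _project_simplex_sorted(p: np.ndarray) -> np.ndarray:
    """Euclidean projection onto the probability simplex (sorting form)."""
    u = np.sort(p)[::-1]
    css = np.cumsum(u)
    rho = np.nonzero(u + (1.0 - css) / np.arange(1, p.size + 1) > 0)[0][-1]
    tau = (css[rho] - 1.0) / (rho + 1)
    return np.maximum(p - tau, 0.0)


def update_view_weights(U: np.ndarray, graphs: list[SimilarityGraph]) -> ViewWeights:
    """Auto-weighting: w_v = 1 / (2 ||U - S^v||_F), residual floored at 1e-10."""
    w = np.array(
        [1.0 / (2.0 * max(np.linalg.norm(U - g.S, "fro"), 1e-10)) for g in graphs]
    )
    return ViewWeights(w)


def init_weights(m: int) -> ViewWeights:
    """Uniform 1/m initialization."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return ViewWeights(np.full(m, 1.0 / m))
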