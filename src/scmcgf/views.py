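"""Construction of the four data views.

View 1 is the pre-processed expression matrix itself.  View 2 scores every
pathway gene set in every cell by the area under its recovery curve within
the top fraction of that cell's expression ranking (AUCell-style).  Views 3
and 4 are linear (PCA) and non-linear (diffusion-map) embeddings of the
pre-processed data, with the target dimensionality chosen by the
Levina–Bickel maximum-likelihood intrinsic-dimension estimator unless
overridden.

All view matrices are features x cells and share one cell order.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .graphs import pairwise_sq_dist
from .io import ExpressionMatrix, PathwayGeneSets

__all__ = [
    "ViewSet",
    "VIEW_ORDER",
    "estimate_intrinsic_dim",
    "pca_view",
    "diffusion_map_view",
    "aucell_view",
    "build_views",
]

VIEW_ORDER = ("expression", "pathway", "pca", "dm")


@dataclass
class ViewSet:
    """Ordered collection of feature matrices X^v (d_v x n) over one cell set."""

    views: list[np.ndarray]
    names: list[str]

    def __post_init__(self) -> None:
        if len(self.views) == 0:
            raise ValueError("a ViewSet needs at least one view")
        if len(self.views) != len(self.names):
            raise ValueError("views and names differ in length")
        self.views = [np.asarray(v, dtype=float) for v in self.views]
        n = self.views[0].shape[1]
        for name, v in zip(self.names, self.views):
            if v.ndim != 2 or v.shape[1] != n:
                raise ValueError(f"view {name!r} does not share the cell count {n}")
            if not np.all(np.isfinite(v)):
                raise ValueError(f"view {name!r} contains non-finite entries")

    @property
    def n(self) -> int:
        return self.views[0].shape[1]

    @property
    def m(self) -> int:
        return len(self.views)


def _fix_signs(components: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: the largest-|entry| of each row/axis
    is made positive.  ``components`` is (d, n) or (d, g); flips rows."""
    out = components.copy()
    for i in range(out.shape[0]):
        j = int(np.argmax(np.abs(out[i])))
        if out[i, j] < 0:
            out[i] = -out[i]
    return out


def estimate_intrinsic_dim(X: np.ndarray, k_min: int = 6, k_max: int = 12) -> int:
    """Levina–Bickel maximum-likelihood intrinsic dimension.

    For each point x and neighbor count k, with T_j(x) the Euclidean
    distance to the j-th nearest neighbor,

        m_hat_k(x) = [ (1/(k-1)) * sum_{j=1}^{k-1} log(T_k(x)/T_j(x)) ]^{-1}

    averaged over points and over k in [k_min, k_max], rounded to the
    nearest integer and clipped to [1, min(d, n-1)].  ``X`` is features x
    cells.
    """
    X = np.asarray(X, dtype=float)
    d, n = X.shape
    if not (2 <= k_min <= k_max):
        raise ValueError("need 2 <= k_min <= k_max")
    if n < k_max + 1:
        raise ValueError(f"need at least k_max+1={k_max + 1} points, got {n}")
    D2 = pairwise_sq_dist(X)
    np.fill_diagonal(D2, np.inf)
    T = np.sqrt(np.sort(D2, axis=1)[:, :k_max])  # T[:, j-1] = j-th NN distance
    floor = max(np.finfo(float).tiny, 1e-15 * float(T[np.isfinite(T)].max(initial=1.0)))
    if np.any(T <= 0):
        warnings.warn("duplicate points: nearest-neighbor distances floored")
        T = np.maximum(T, floor)
    logT = np.log(T)
    estimates = []
    for k in range(k_min, k_max + 1):
        inv = np.mean(logT[:, k - 1 : k] - logT[:, : k - 1], axis=1)  # (n,)
        inv = np.maximum(inv, 1e-12)
        estimates.append(np.mean(1.0 / inv))
    est = float(np.mean(estimates))
    return int(np.clip(int(round(est)), 1, min(d, n - 1)))


def pca_view(X: np.ndarray, d: int) -> np.ndarray:
    """Project cells onto the top-d principal axes.  X is genes x cells.

    Gene means are subtracted, the axes come from an SVD of the centered
    matrix, and each axis is sign-fixed so its largest-magnitude loading is
    positive.  If ``d`` exceeds the matrix rank the projection is truncated
    with a warning.
    """
    X = np.asarray(X, dtype=float)
    g, n = X.shape
    if d > min(g, n):
        raise ValueError(f"d={d} exceeds min(genes, cells)={min(g, n)}")
    Xc = X - X.mean(axis=1, keepdims=True)
    U, s, Vt = scipy.linalg.svd(Xc, full_matrices=False)
    tol = max(g, n) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    rank = int(np.sum(s > tol))
    if d > rank:
        warnings.warn(f"requested {d} components but rank is {rank}; truncating")
        d = max(rank, 1)
    axes = U[:, :d].T  # (d, g) loadings
    flip = np.array(
        [-1.0 if axes[i, np.argmax(np.abs(axes[i]))] < 0 else 1.0 for i in range(d)]
    )
    return (flip[:, None] * axes) @ Xc  # (d, n)


def diffusion_map_view(
    X: np.ndarray, d: int, sigma: float | str = "median", t: int = 1
) -> np.ndarray:
    """Diffusion-map embedding of the cells (columns of X).

    Gaussian kernel K_ij = exp(-||x_i - x_j||^2 / (2 sigma^2)), Markov
    normalization P = D^-1 K, and coordinates lambda_l^t * psi_l for the
    top-d non-trivial right eigenvectors of P (the constant eigenvector at
    eigenvalue 1 is skipped).  ``sigma="median"`` uses the median pairwise
    distance, a self-tuning bandwidth that keeps the kernel informative for
    high-dimensional expression data.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[1]
    if not (1 <= d <= n - 1):
        raise ValueError(f"need 1 <= d <= n-1, got d={d}, n={n}")
    if t < 1:
        raise ValueError("t must be >= 1")
    D2 = pairwise_sq_dist(X)
    off = D2[~np.eye(n, dtype=bool)]
    if np.all(off <= 0):
        raise ValueError("degenerate kernel: all cells are identical")
    if sigma == "median":
        sigma = float(np.median(np.sqrt(off)))
    sigma = float(sigma)
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    K = np.exp(-D2 / (2.0 * sigma**2))
    deg = K.sum(axis=1)
    if np.any(deg <= 0):
        raise ValueError("degenerate kernel: a cell has zero total affinity")
    # symmetric conjugate of P = D^-1 K shares its spectrum; right
    # eigenvectors recovered as D^-1/2 phi
    dinv_sqrt = 1.0 / np.sqrt(deg)
    A = K * np.outer(dinv_sqrt, dinv_sqrt)
    evals, phi = scipy.linalg.eigh(A)
    order = np.argsort(-evals)
    evals, phi = evals[order], phi[:, order]
    psi = (dinv_sqrt[:, None] * phi).T  # rows = right eigenvectors of P
    psi /= np.linalg.norm(psi, axis=1, keepdims=True)
    psi = _fix_signs(psi)
    coords = (evals[1 : d + 1] ** t)[:, None] * psi[1 : d + 1]
    return coords


def aucell_view(
    X: ExpressionMatrix, gene_sets: PathwayGeneSets, top_frac: float = 0.05
) -> np.ndarray:
    """Per-cell gene-set activity scores (n_sets x n_cells), each in [0, 1].

    For each cell, genes are ranked by expression descending (ties keep the
    original gene order); the score of a set is the area under its recovery
    curve over the top ``ceil(top_frac * G)`` ranks, normalized by the
    maximum achievable area.  Set members absent from the matrix are
    dropped; a set with no overlap scores 0 with a warning.
    """
    if not (0 < top_frac < 1):
        raise ValueError("top_frac must be in (0, 1)")
    G, n = X.values.shape
    L = math.ceil(top_frac * G)
    gene_index = {g: i for i, g in enumerate(X.gene_ids)}

    # rank[g, c] = 1-based position of gene g in cell c's descending ordering
    order = np.argsort(-X.values, axis=0, kind="stable")
    rank = np.empty_like(order)
    cols = np.arange(n)[None, :]
    rank[order, np.broadcast_to(cols, order.shape)] = np.arange(1, G + 1)[:, None]

    scores = np.zeros((len(gene_sets), n))
    for s, (name, genes) in enumerate(gene_sets.sets.items()):
        members = [gene_index[g] for g in genes if g in gene_index]
        if not members:
            warnings.warn(f"gene set {name!r} has no overlap with the matrix genes")
            continue
        gs = len(members)
        # member at rank r contributes (L - r + 1) to the discrete area
        contrib = np.maximum(L - rank[members, :] + 1, 0)
        area = contrib.sum(axis=0)
        r = np.arange(1, L + 1)
        max_area = float(np.minimum(r, gs).sum())
        scores[s] = area / max_area
    return scores


def build_views(
    X_pre: ExpressionMatrix,
    gene_sets: PathwayGeneSets | None = None,
    include: tuple[str, ...] = VIEW_ORDER,
    *,
    X_pathway: ExpressionMatrix | None = None,
    pca_dim: int | None = None,
    dm_dim: int | None = None,
    dm_sigma: float | str = "median",
    dm_t: int = 1,
    aucell_top_frac: float = 0.05,
    id_kmin: int = 6,
    id_kmax: int = 12,
) -> ViewSet:
    """Assemble the requested views, in the fixed order expression ->
    pathway -> pca -> dm.

    ``X_pre`` is the pre-processed (HVG) expression matrix; pathway scoring
    uses ``X_pathway`` when given (typically the normalized pre-HVG matrix,
    so gene-set coverage is not destroyed by HVG filtering), else ``X_pre``.
    PCA/DM dimensionality defaults to the maximum-likelihood intrinsic
    dimension of ``X_pre``.
    """
    include_set = set(include)
    unknown = include_set - set(VIEW_ORDER)
    if unknown:
        raise ValueError(f"unknown view(s): {sorted(unknown)}")
    if not include_set:
        raise ValueError("at least one view must be included")
    n = X_pre.n_cells

    intrinsic = None
    if ("pca" in include_set and pca_dim is None) or (
        "dm" in include_set and dm_dim is None
    ):
        intrinsic = estimate_intrinsic_dim(X_pre.values, id_kmin, id_kmax)

    views: list[np.ndarray] = []
    names: list[str] = []
    for name in VIEW_ORDER:
        if name not in include_set:
            continue
        if name == "expression":
            views.append(X_pre.values)
        elif name == "pathway":
            if gene_sets is None:
                raise ValueError("pathway view requested but no gene sets supplied")
            Xp = X_pathway if X_pathway is not None else X_pre
            if Xp.cell_ids != X_pre.cell_ids:
                raise ValueError("cell order mismatch between pathway and expression matrices")
            views.append(aucell_view(Xp, gene_sets, aucell_top_frac))
        elif name == "pca":
            d = pca_dim if pca_dim is not None else min(intrinsic, X_pre.n_genes, n)
            views.append(pca_view(X_pre.values, d))
        elif name == "dm":
            d = dm_dim if dm_dim is not None else min(intrinsic, n - 1)
            views.append(diffusion_map_view(X_pre.values, d, dm_sigma, dm_t))
        names.append(name)
    return ViewSet(views, names)
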