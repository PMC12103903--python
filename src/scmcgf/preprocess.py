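"""Expression pre-processing: the four steps that produce View 1.

Order: conditional log2 transform -> sparse-gene filter -> size-factor
normalization -> highly-variable-gene selection.  Library sizes for the
size factors are column sums of the (possibly log-transformed) matrix, and
each cell is divided by ``s_i / s_m`` where ``s_m`` is the median library
size — so after normalization every cell's library size equals ``s_m``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import ExpressionMatrix

__all__ = [
    "PreprocessReport",
    "conditional_log2",
    "filter_sparse_genes",
    "size_factor_normalize",
    "select_hvg",
    "preprocess_pipeline",
]


@dataclass
class PreprocessReport:
    applied_log: bool = False
    genes_removed_sparse: int = 0
    size_factors: np.ndarray | None = None
    hvg_indices: np.ndarray | None = None
    #: normalized matrix before HVG selection (used for pathway scoring,
    #: where restricting to 2000 HVGs would empty most gene sets)
    normalized_pre_hvg: ExpressionMatrix | None = None


def conditional_log2(X: ExpressionMatrix) -> tuple[ExpressionMatrix, bool]:
    """log2(x + 1) if the value range (max - min) exceeds 100, else identity."""
    rng = float(X.values.max() - X.values.min()) if X.values.size else 0.0
    if rng > 100:
        return ExpressionMatrix(np.log2(X.values + 1.0), X.gene_ids, X.cell_ids), True
    return X, False


def filter_sparse_genes(
    X: ExpressionMatrix, max_zero_frac: float = 0.95
) -> tuple[ExpressionMatrix, np.ndarray]:
    """Drop genes whose zero fraction is strictly greater than ``max_zero_frac``.

    A gene at exactly the threshold (e.g. zero in 95 of 100 cells with the
    default) is kept.
    """
    if not (0 < max_zero_frac <= 1):
        raise ValueError("max_zero_frac must be in (0, 1]")
    zero_frac = np.mean(X.values == 0, axis=1)
    keep = zero_frac <= max_zero_frac
    removed = np.flatnonzero(~keep)
    if not keep.any():
        raise ValueError(
            f"all {X.n_genes} genes exceed the {max_zero_frac:.0%} zero-fraction "
            "threshold; nothing left to cluster"
        )
    return X.subset_genes(np.flatnonzero(keep)), removed


def size_factor_normalize(X: ExpressionMatrix) -> tuple[ExpressionMatrix, np.ndarray]:
    """Divide each cell by its size factor s_i / s_m (s_m = median library size)."""
    lib = X.values.sum(axis=0)
    zero = np.flatnonzero(lib <= 0)
    if zero.size:
        raise ValueError(
            f"cell(s) with zero library size: {[X.cell_ids[i] for i in zero[:5]]}"
        )
    s_m = float(np.median(lib))
    factors = lib / s_m
    return (
        ExpressionMatrix(X.values / factors[None, :], X.gene_ids, X.cell_ids),
        factors,
    )


def _variability_score(values: np.ndarray, method: str) -> np.ndarray:
    if method == "variance":
        return values.var(axis=1)
    if method == "dispersion":
        mean = values.mean(axis=1)
        return values.var(axis=1) / np.maximum(mean, 1e-12)
    raise ValueError(f"unknown hvg method {method!r}")


def select_hvg(
    X: ExpressionMatrix, n_top: int = 2000, method: str = "variance"
) -> tuple[ExpressionMatrix, np.ndarray]:
    """Keep the ``n_top`` most variable genes, in original gene order.

    Ties in the variability score are broken by ascending gene index
    (stable sort on the negated score).
    """
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    score = _variability_score(X.values, method)
    order = np.argsort(-score, kind="stable")
    chosen = np.sort(order[: min(n_top, X.n_genes)])
    return X.subset_genes(chosen), chosen


def preprocess_pipeline(
    X: ExpressionMatrix,
    max_zero_frac: float = 0.95,
    n_hvg: int = 2000,
    log_range_threshold: float = 100,
    hvg_method: str = "variance",
) -> tuple[ExpressionMatrix, PreprocessReport]:
    """Run log -> sparse filter -> size factors -> HVG and report each step."""
    report = PreprocessReport()
    rng = float(X.values.max() - X.values.min()) if X.values.size else 0.0
    if rng > log_range_threshold:
        X = ExpressionMatrix(np.log2(X.values + 1.0), X.gene_ids, X.cell_ids)
        report.applied_log = True
    X, removed = filter_sparse_genes(X, max_zero_frac)
    report.genes_removed_sparse = int(removed.size)
    X, factors = size_factor_normalize(X)
    report.size_factors = factors
    report.normalized_pre_hvg = X
    X, hvg_idx = select_hvg(X, n_hvg, hvg_method)
    report.hvg_indices = hvg_idx
    return X, report
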