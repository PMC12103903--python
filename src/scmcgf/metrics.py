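"""Clustering agreement metrics: CA, NMI and ARI.

CA (clustering accuracy) is the largest fraction of cells on which the two
partitions agree under an optimal one-to-one matching of cluster labels,
found by the Hungarian algorithm on the contingency table.  NMI normalizes
the mutual information of the partitions by the arithmetic mean of their
entropies (sqrt and max normalizations available); degenerate
single-cluster cases return 0.  ARI is the pair-counting Rand index with
expected-value correction, delegated to scikit-learn.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.optimize
from sklearn.metrics import adjusted_rand_score

__all__ = ["ClusterLabels", "clustering_accuracy", "nmi", "ari", "all_metrics"]


@dataclass
class ClusterLabels:
    labels: np.ndarray
    n_clusters: int
    fallback_used: bool = False

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        uniq = np.unique(self.labels)
        if uniq.min() < 0 or uniq.max() >= self.n_clusters:
            raise ValueError("labels not dense in [0, n_clusters)")


def _contingency(pred: np.ndarray, truth: np.ndarray) -> np.ndarray:
    pu, pi = np.unique(pred, return_inverse=True)
    tu, ti = np.unique(truth, return_inverse=True)
    table = np.zeros((pu.size, tu.size), dtype=int)
    np.add.at(table, (pi, ti), 1)
    return table


def _as_labels(pred, truth) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape or pred.ndim != 1:
        raise ValueError("pred and truth must be 1-D and the same length")
    if pred.size == 0:
        raise ValueError("empty label vectors")
    return pred, truth


def clustering_accuracy(pred, truth) -> float:
    """Accuracy under the best one-to-one cluster matching (Hungarian).

    Unequal cluster counts are handled by padding the contingency table
    with empty clusters.
    """
    pred, truth = _as_labels(pred, truth)
    table = _contingency(pred, truth)
    size = max(table.shape)
    padded = np.zeros((size, size), dtype=int)
    padded[: table.shape[0], : table.shape[1]] = table
    rows, cols = scipy.optimize.linear_sum_assignment(padded, maximize=True)
    return float(padded[rows, cols].sum() / pred.size)


def _entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-np.sum(p * np.log(p)))


def nmi(pred, truth, normalization: str = "arithmetic") -> float:
    """Normalized mutual information of two partitions.

    ``normalization`` is the mean of the two partition entropies used as
    denominator: "arithmetic" (default), "sqrt" (geometric) or "max".
    If either partition has a single cluster the score is 0 by convention.
    """
    pred, truth = _as_labels(pred, truth)
    table = _contingency(pred, truth).astype(float)
    n = table.sum()
    h_pred = _entropy(table.sum(axis=1))
    h_truth = _entropy(table.sum(axis=0))
    if h_pred == 0.0 or h_truth == 0.0:
        return 0.0
    outer = np.outer(table.sum(axis=1), table.sum(axis=0))
    nz = table > 0
    mi = float(np.sum(table[nz] / n * np.log(n * table[nz] / outer[nz])))
    if normalization == "arithmetic":
        denom = (h_pred + h_truth) / 2.0
    elif normalization == "sqrt":
        denom = float(np.sqrt(h_pred * h_truth))
    elif normalization == "max":
        denom = max(h_pred, h_truth)
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    return float(np.clip(mi / denom, 0.0, 1.0))


def ari(pred, truth) -> float:
    """Adjusted Rand index in [-1, 1]."""
    pred, truth = _as_labels(pred, truth)
    return float(adjusted_rand_score(truth, pred))


def all_metrics(pred, truth) -> dict[str, float]:
    return {
        "CA": clustering_accuracy(pred, truth),
        "NMI": nmi(pred, truth),
        "ARI": ari(pred, truth),
    }
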