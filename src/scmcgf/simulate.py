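"""Synthetic clustered count matrices with matching pathway gene sets.

The generator emulates the structure the clustering method exploits in real
scRNA-seq data: a small panel of cluster-specific marker genes whose mean
expression is amplified by a multiplicative effect size, a shared baseline
for all other genes, count noise (Poisson by default, negative binomial
optionally), and zero-inflation ("dropout") applied entrywise.  A fraction
of the generated pathways is enriched for one cluster's markers so the
pathway-score view carries cluster signal, as curated pathway databases do
for real cell types.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import ExpressionMatrix, PathwayGeneSets

__all__ = ["SyntheticTruth", "generate_synthetic"]


@dataclass
class SyntheticTruth:
    """Ground-truth labels plus the generator settings that produced them."""

    labels: np.ndarray
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        c = self.params.get("n_clusters")
        if c is not None:
            if self.labels.min() < 0 or self.labels.max() >= c:
                raise ValueError("labels outside [0, n_clusters)")
            if len(np.unique(self.labels)) != c:
                raise ValueError("some cluster is empty")


def _cluster_sizes(n_cells: int, n_clusters: int, proportions, rng) -> np.ndarray:
    if proportions is None:
        base = n_cells // n_clusters
        sizes = np.full(n_clusters, base, dtype=int)
        sizes[: n_cells - base * n_clusters] += 1
        return sizes
    if isinstance(proportions, str) and proportions == "dirichlet":
        p = rng.dirichlet(np.full(n_clusters, 5.0))
    else:
        p = np.asarray(proportions, dtype=float)
        p = p / p.sum()
    sizes = np.floor(p * n_cells).astype(int)
    sizes[np.argsort(-(p * n_cells - sizes))[: n_cells - sizes.sum()]] += 1
    if np.any(sizes == 0):
        raise ValueError("requested proportions leave an empty cluster")
    return sizes


def generate_synthetic(
    n_cells: int = 300,
    n_genes: int = 1000,
    n_clusters: int = 3,
    effect: float = 8.0,
    dropout: float = 0.3,
    n_pathways: int = 50,
    seed: int = 0,
    *,
    counts_model: str = "poisson",
    nb_dispersion: float = 0.5,
    proportions=None,
    markers_per_cluster: int | None = None,
    genes_per_set: int = 30,
    enriched_frac: float = 0.4,
    marker_frac_in_set: float = 0.7,
) -> tuple[ExpressionMatrix, PathwayGeneSets, SyntheticTruth]:
    """Generate a clustered count matrix, a GMT-style gene-set collection and
    the ground-truth labels.

    Marker genes are disjoint random panels of ``markers_per_cluster`` genes
    (default ``max(10, n_genes // 20)``), whose baseline mean is multiplied
    by ``effect`` in their cluster.  Baseline means are log-normal with a
    floor of 0.2, so at moderate dropout essentially no gene is zero in more
    than 95% of cells.  ``effect=1`` yields clusters with identical means.

    Fully deterministic given ``seed``.
    """
    if n_clusters < 2:
        raise ValueError("n_clusters must be >= 2")
    if not (0 <= dropout < 1):
        raise ValueError("dropout must be in [0, 1)")
    if effect <= 0:
        raise ValueError("effect must be positive")
    if counts_model not in ("poisson", "nb"):
        raise ValueError(f"unknown counts_model {counts_model!r}")
    if markers_per_cluster is None:
        markers_per_cluster = max(10, n_genes // 20)
    if markers_per_cluster * n_clusters > n_genes:
        raise ValueError(
            f"{markers_per_cluster} markers x {n_clusters} clusters exceed "
            f"{n_genes} genes"
        )

    rng = np.random.default_rng(seed)
    sizes = _cluster_sizes(n_cells, n_clusters, proportions, rng)
    labels = np.repeat(np.arange(n_clusters), sizes)

    baseline = np.clip(rng.lognormal(mean=np.log(1.5), sigma=0.8, size=n_genes), 0.2, 50.0)
    marker_pool = rng.permutation(n_genes)[: markers_per_cluster * n_clusters]
    markers = marker_pool.reshape(n_clusters, markers_per_cluster)

    means = np.tile(baseline[:, None], (1, n_clusters))
    for c in range(n_clusters):
        means[markers[c], c] *= effect

    mu = means[:, labels]  # genes x cells
    if counts_model == "poisson":
        counts = rng.poisson(mu).astype(float)
    else:
        # gamma-Poisson mixture: Var = mu + dispersion * mu^2
        shape = 1.0 / nb_dispersion
        lam = rng.gamma(shape, mu / shape)
        counts = rng.poisson(lam).astype(float)
    if dropout > 0:
        counts *= rng.random(counts.shape) >= dropout

    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    cell_ids = [f"C{i:05d}" for i in range(n_cells)]
    em = ExpressionMatrix(counts, gene_ids, cell_ids)

    n_enriched = int(round(enriched_frac * n_pathways))
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    for p in range(n_pathways):
        name = f"PW{p:04d}"
        if p < n_enriched:
            c = p % n_clusters
            n_mark = min(int(round(marker_frac_in_set * genes_per_set)), markers_per_cluster)
            picked = list(rng.choice(markers[c], size=n_mark, replace=False))
            rest = rng.choice(n_genes, size=genes_per_set - n_mark, replace=False)
            picked.extend(g for g in rest if g not in picked)
            descriptions[name] = f"synthetic; enriched for cluster {c} markers"
        else:
            picked = list(rng.choice(n_genes, size=genes_per_set, replace=False))
            descriptions[name] = "synthetic; background"
        sets[name] = [gene_ids[g] for g in picked]
    gs = PathwayGeneSets(sets, descriptions)

    truth = SyntheticTruth(
        labels,
        params=dict(
            n_cells=n_cells,
            n_genes=n_genes,
            n_clusters=n_clusters,
            effect=effect,
            dropout=dropout,
            n_pathways=n_pathways,
            seed=seed,
            counts_model=counts_model,
        ),
    )
    return em, gs, truth
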