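"""Marker-set evaluation: cluster cells on selected genes, score vs truth.

Cells are clustered on the gene-restricted log-scale submatrix (k-means or
agglomerative hierarchical clustering) and agreement with known labels is
quantified by the adjusted Rand index (ARI), the chance-corrected
Hubert-Arabie statistic on the partition contingency table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import AgglomerativeClustering, KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import adjusted_rand_score

from .io import ExpressionMatrix

CLUSTER_METHODS = ("kmeans", "hierarchical")


@dataclass
class CellLabeling:
    """Integer cluster/type assignment for an ordered list of cells."""

    cell_ids: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.cell_ids) != self.labels.size:
            raise ValueError("cell_ids and labels must have the same length")


def cluster_cells(
    m: ExpressionMatrix,
    genes: list[str],
    n_clusters: int,
    seed: int = 0,
    method: str = "kmeans",
    pca_components: int | None = None,
) -> CellLabeling:
    """Cluster cells on the submatrix restricted to ``genes``.

    Deterministic given ``seed``. ``pca_components`` optionally reduces the
    gene space before clustering; the default clusters on the genes directly
    so the comparison stays about gene selection.
    """
    if len(genes) == 0:
        raise ValueError("empty gene list")
    if n_clusters < 2:
        raise ValueError("n_clusters must be >= 2")
    sub = m.restrict_genes(genes)
    data = sub.dense().T  # cells x genes
    if pca_components is not None:
        n_comp = min(pca_components, *data.shape)
        data = PCA(n_components=n_comp, random_state=seed).fit_transform(data)
    if method == "kmeans":
        model = KMeans(n_clusters=n_clusters, random_state=seed, n_init=10)
        labels = model.fit_predict(data)
    elif method == "hierarchical":
        model = AgglomerativeClustering(n_clusters=n_clusters, linkage="ward")
        labels = model.fit_predict(data)
    else:
        raise ValueError(f"unknown clustering method {method!r}")
    return CellLabeling(cell_ids=list(m.cell_ids), labels=labels)


def adjusted_rand_index(a: CellLabeling, b: CellLabeling) -> float:
    """Hubert-Arabie adjusted Rand index between two labelings, in [-1, 1]."""
    if len(a.cell_ids) != len(b.cell_ids):
        raise ValueError("labelings cover different numbers of cells")
    if a.cell_ids != b.cell_ids:
        raise ValueError("labelings cover different cells or orders")
    return float(adjusted_rand_score(a.labels, b.labels))


def score_gene_sets(
    m: ExpressionMatrix,
    gene_sets: dict[str, list[str]],
    truth: CellLabeling,
    n_clusters: int,
    seed: int = 0,
    methods: tuple[str, ...] = ("kmeans",),
) -> pd.DataFrame:
    """ARI vs truth for each named gene set and clustering method.

    Returns a tidy frame: selector, n_genes, clustering_method, seed, ari.
    """
    rows = []
    for name, genes in gene_sets.items():
        for method in methods:
            labeling = cluster_cells(m, genes, n_clusters, seed=seed, method=method)
            rows.append(
                {
                    "selector": name,
                    "n_genes": len(genes),
                    "clustering_method": method,
                    "seed": seed,
                    "ari": adjusted_rand_index(labeling, truth),
                }
            )
    return pd.DataFrame(rows)
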