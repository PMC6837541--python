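"""Canonical comparison selectors: highest-expressed and highest-variable genes.

These are the two standard pre-clustering gene filters the graph-based
selector is benchmarked against, always at equal marker-set sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse as sp

from .io import ExpressionMatrix


@dataclass
class RankedGeneList:
    """Genes ordered by a per-gene score, best first."""

    gene_ids: list[str]
    scores: np.ndarray
    criterion: str  # "mean_expression" | "dispersion"


def _gene_means(m: ExpressionMatrix) -> np.ndarray:
    if sp.issparse(m.values):
        return np.asarray(m.values.mean(axis=1)).ravel()
    return m.values.mean(axis=1)


def _gene_variances(m: ExpressionMatrix) -> np.ndarray:
    """Per-gene sample variance (L-1 denominator), sparse-aware."""
    L = m.n_cells
    if L < 2:
        return np.zeros(m.n_genes)
    if sp.issparse(m.values):
        mean = np.asarray(m.values.mean(axis=1)).ravel()
        sq = np.asarray(m.values.multiply(m.values).mean(axis=1)).ravel()
        return (sq - mean**2) * L / (L - 1)
    return m.values.var(axis=1, ddof=1)


def _take_top(scores: np.ndarray, count: int) -> np.ndarray:
    # stable sort on index, then descending score: ties resolve by gene index
    order = np.argsort(-scores, kind="stable")
    return order[:count]


def top_expressed(m: ExpressionMatrix, count: int) -> RankedGeneList:
    """The ``count`` genes with the highest mean expression across cells."""
    if not 1 <= count <= m.n_genes:
        raise ValueError(f"count must be in [1, {m.n_genes}]")
    scores = _gene_means(m)
    idx = _take_top(scores, count)
    return RankedGeneList(
        gene_ids=[m.gene_ids[i] for i in idx],
        scores=scores[idx],
        criterion="mean_expression",
    )


def dispersion_scores(m: ExpressionMatrix, n_bins: int = 20) -> np.ndarray:
    """Mean-binned standardized dispersion (variance / mean), z-scored
    within ``n_bins`` equal-frequency bins of gene mean expression.

    The binning removes the mean-dispersion trend so highly variable genes
    are ranked relative to genes of similar abundance. Genes with zero mean
    get dispersion 0; bins with zero spread get z-score 0.
    """
    means = _gene_means(m)
    variances = _gene_variances(m)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(means > 0, variances / means, 0.0)
    # keep >= ~10 genes per bin so the within-bin z-score is meaningful
    n_bins = max(1, min(n_bins, m.n_genes // 10, m.n_genes))
    # equal-frequency bins over gene means
    quantiles = np.quantile(means, np.linspace(0, 1, n_bins + 1))
    bins = np.clip(np.searchsorted(quantiles, means, side="right") - 1, 0, n_bins - 1)
    z = np.zeros_like(disp)
    for b in range(n_bins):
        in_bin = bins == b
        if not in_bin.any():
            continue
        mu, sd = disp[in_bin].mean(), disp[in_bin].std()
        z[in_bin] = (disp[in_bin] - mu) / sd if sd > 0 else 0.0
    return z


def top_variable(
    m: ExpressionMatrix, count: int, method: str = "variance"
) -> RankedGeneList:
    """The ``count`` most variable genes.

    ``method="variance"`` ranks by plain per-gene sample variance;
    ``method="dispersion_binned"`` by mean-binned standardized dispersion.
    """
    if not 1 <= count <= m.n_genes:
        raise ValueError(f"count must be in [1, {m.n_genes}]")
    if method == "variance":
        scores = _gene_variances(m)
    elif method == "dispersion_binned":
        scores = dispersion_scores(m)
    else:
        raise ValueError(f"unknown method {method!r}")
    idx = _take_top(scores, count)
    return RankedGeneList(
        gene_ids=[m.gene_ids[i] for i in idx],
        scores=scores[idx],
        criterion="dispersion",
    )


def write_ranked_list(ranked: RankedGeneList, path) -> None:
    """Marker-list text output with the criterion in a header comment."""
    with open(path, "w") as fh:
        fh.write(f"# criterion: {ranked.criterion}\n")
        for g in ranked.gene_ids:
            fh.write(f"{g}\n")
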