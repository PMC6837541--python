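"""Scikit-learn style feature selectors over the marker-selection pipeline.

These estimators follow the sklearn transformer protocol (``fit`` on a
cells x genes array, ``transform`` keeps the selected gene columns,
``get_support`` exposes the mask) so they compose with pipelines and model
selection. They are thin shells over the library functions in
:mod:`multimark.graph` and :mod:`multimark.baselines`, which operate on the
genes x cells :class:`~multimark.io.ExpressionMatrix`.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse as sp
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_array, check_is_fitted

from . import baselines, graph
from .io import ExpressionMatrix


def _as_expression_matrix(X, feature_names=None) -> ExpressionMatrix:
    if feature_names is None:
        width = max(4, len(str(X.shape[1] - 1)))
        feature_names = [f"g{i:0{width}d}" for i in range(X.shape[1])]
    values = X.T if sp.issparse(X) else np.asarray(X, dtype=float).T
    return ExpressionMatrix(
        values=values,
        gene_ids=list(feature_names),
        cell_ids=[f"cell{j}" for j in range(X.shape[0])],
        scale="log",
        platform="unknown",
    )


class _BaseGeneSelector(SelectorMixin, BaseEstimator):
    """Shared fit plumbing: validate cells x genes input, capture names."""

    def _validate(self, X):
        if hasattr(X, "columns"):  # DataFrame: keep gene names
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        X = check_array(X, accept_sparse="csr", ensure_min_samples=2, ensure_min_features=1)
        self.n_features_in_ = X.shape[1]
        return X

    def _feature_names(self, X):
        return list(getattr(self, "feature_names_in_", [])) or None

    def fit(self, X, y=None):  # pragma: no cover - overridden
        raise NotImplementedError

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_

    def selected_genes(self) -> list[str]:
        """IDs of the selected genes, in gene-index order."""
        check_is_fitted(self, "support_")
        return [self.gene_ids_[i] for i in np.flatnonzero(self.support_)]


class MarkerSelector(_BaseGeneSelector):
    """Annotation-free marker-gene selector for log-scale expression.

    Keeps genes whose expression density across cells is multimodal
    (Gaussian KDE, 2h-window peak rule, >= 2 peaks) and that are reciprocally
    connected to another gene in the k-nearest co-occurrence (KNCON) or
    mutual-exclusivity (KNMEN) graph built from the mean-binarized
    multimodal submatrix.

    Parameters
    ----------
    bandwidth : float or "silverman", default 0.3
        Fixed KDE bandwidth on the log scale (0.3 suits full-transcript
        plate data, 0.05 droplet 3' data), or "silverman" for the per-gene
        rule-of-thumb value.
    k : int, default 300
        Neighbour-list size per gene in both graphs.
    n : int, default 30
        Minimum supporting cells for a graph edge.

    Attributes
    ----------
    support_ : bool array of shape (n_genes,)
        Mask of selected marker genes.
    peak_counts_ : int array of shape (n_genes,)
        Density peak count per gene (0 for degenerate/unexamined genes).
    marker_set_ : :class:`multimark.graph.MarkerSet`
        Selected genes with CMEGP partner provenance.
    """

    def __init__(self, bandwidth: float | str = 0.3, k: int = 300, n: int = 30):
        self.bandwidth = bandwidth
        self.k = k
        self.n = n

    def fit(self, X, y=None):
        if self.k < 1 or self.n < 1:
            raise ValueError("k and n must be >= 1")
        X = self._validate(X)
        m = _as_expression_matrix(X, self._feature_names(X))
        self.gene_ids_ = list(m.gene_ids)
        if self.bandwidth == "silverman":
            h_mode, h_fixed = "per_gene", None
        else:
            h_mode, h_fixed = "fixed", float(self.bandwidth)
        self.marker_set_ = graph.select_markers(
            m, h_mode=h_mode, h_fixed=h_fixed, k=self.k, n=self.n
        )
        index = {g: i for i, g in enumerate(self.gene_ids_)}
        self.support_ = np.zeros(self.n_features_in_, dtype=bool)
        self.peak_counts_ = np.zeros(self.n_features_in_, dtype=int)
        for g, info in self.marker_set_.provenance.items():
            self.support_[index[g]] = True
            if info["peak_count"] is not None:
                self.peak_counts_[index[g]] = info["peak_count"]
        return self


class TopMeanSelector(_BaseGeneSelector):
    """Baseline selector: the ``n_genes`` highest-mean-expression genes."""

    def __init__(self, n_genes: int = 500):
        self.n_genes = n_genes

    def fit(self, X, y=None):
        X = self._validate(X)
        m = _as_expression_matrix(X, self._feature_names(X))
        self.gene_ids_ = list(m.gene_ids)
        count = min(self.n_genes, self.n_features_in_)
        self.ranking_ = baselines.top_expressed(m, count)
        index = {g: i for i, g in enumerate(self.gene_ids_)}
        self.support_ = np.zeros(self.n_features_in_, dtype=bool)
        self.support_[[index[g] for g in self.ranking_.gene_ids]] = True
        return self


class TopVarianceSelector(_BaseGeneSelector):
    """Baseline selector: the ``n_genes`` most variable genes.

    ``method="variance"`` ranks by sample variance; ``"dispersion_binned"``
    by mean-binned standardized dispersion (the classic highly-variable-gene
    ranking).
    """

    def __init__(self, n_genes: int = 500, method: str = "variance"):
        self.n_genes = n_genes
        self.method = method

    def fit(self, X, y=None):
        X = self._validate(X)
        m = _as_expression_matrix(X, self._feature_names(X))
        self.gene_ids_ = list(m.gene_ids)
        count = min(self.n_genes, self.n_features_in_)
        self.ranking_ = baselines.top_variable(m, count, method=self.method)
        index = {g: i for i, g in enumerate(self.gene_ids_)}
        self.support_ = np.zeros(self.n_features_in_, dtype=bool)
        self.support_[[index[g] for g in self.ranking_.gene_ids]] = True
        return self
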