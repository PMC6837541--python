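"""Gene co-occurrence / mutual-exclusivity graphs and marker selection.

The multimodal-gene submatrix is binarized at each gene's own mean
(x_ij = 1 iff expression strictly above the gene mean). From the binary
matrix X two pair-count matrices are formed:

* co-occurrence  S = X X'         (cells where both genes are on)
* mutual exclusivity  M = (1-X) X'  (cells where the source is off and the
  target is on; asymmetric)

Each count matrix induces a directed k-nearest-neighbour gene graph: an edge
A -> B requires at least n supporting cells, and B must be among A's k
largest counts (threshold first, then top-k; ties at the cut broken by
ascending gene index). A co-/mutually-exclusively expressing gene pair
(CMEGP) is a pair reciprocally connected in the co-occurrence graph (KNCON)
or in the mutual-exclusivity graph (KNMEN). Markers are the genes belonging
to at least one CMEGP.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse as sp

from .io import ExpressionMatrix
from .modality import multimodal_genes

logger = logging.getLogger(__name__)


@dataclass
class BinaryMatrix:
    """{0,1} matrix over the multimodal gene subset (genes x cells)."""

    x: np.ndarray | sp.spmatrix
    gene_ids: list[str]
    gene_means: np.ndarray

    @property
    def n_genes(self) -> int:
        return self.x.shape[0]

    @property
    def n_cells(self) -> int:
        return self.x.shape[1]

    def dense(self) -> np.ndarray:
        if sp.issparse(self.x):
            return np.asarray(self.x.todense(), dtype=np.int64)
        return np.asarray(self.x, dtype=np.int64)


@dataclass
class PairCountMatrix:
    """Gene x gene supporting-cell counts, co-occurrence or mutual-exclusive."""

    counts: np.ndarray
    kind: str  # "cooccurrence" | "mutual_exclusive"
    gene_ids: list[str] = field(default_factory=list)


@dataclass
class NeighborGraph:
    """Directed gene graph; ``edges[a][b]`` is the supporting cell count."""

    kind: str  # "kncon" | "knmen"
    k: int
    n: int
    gene_ids: list[str]
    edges: dict[int, dict[int, int]]

    def has_edge(self, a: int, b: int) -> bool:
        return b in self.edges.get(a, {})

    def edge_list(self) -> list[tuple[int, int, int]]:
        return sorted(
            (a, b, w) for a, nbrs in self.edges.items() for b, w in nbrs.items()
        )


@dataclass
class MarkerSet:
    """Selected marker genes with per-gene provenance.

    ``provenance[gene_id]`` holds the gene's density peak count and its
    reciprocal-pair partners with the supporting graph kind.
    """

    gene_ids: list[str]
    provenance: dict[str, dict]

    def __len__(self) -> int:
        return len(self.gene_ids)


def binarize(m: ExpressionMatrix) -> BinaryMatrix:
    """Threshold each gene at its own mean: 1 iff strictly above the mean.

    Requires non-constant rows (constant rows binarize to all zeros and
    should have been removed by the multimodality filter).
    """
    if m.scale != "log":
        raise ValueError("binarization expects log-scale expression")
    if sp.issparse(m.values):
        v = sp.csr_matrix(m.values)
        means = np.asarray(v.mean(axis=1)).ravel()
        if (means < 0).any():
            # negative means would flip implicit zeros to 1; handle densely
            dense = np.asarray(v.todense())
            x = (dense > means[:, None]).astype(np.int8)
        else:
            # nonneg means: implicit zeros stay 0, compare stored entries only
            row_of = np.repeat(np.arange(v.shape[0]), np.diff(v.indptr))
            mask = (v.data > means[row_of]).astype(np.int8)
            x = sp.csr_matrix((mask, v.indices.copy(), v.indptr.copy()), shape=v.shape)
            x.eliminate_zeros()
    else:
        means = m.values.mean(axis=1)
        x = (m.values > means[:, None]).astype(np.int8)
    row_sums = np.asarray(x.sum(axis=1)).ravel()
    bad = np.flatnonzero((row_sums == 0) | (row_sums == m.n_cells))
    if bad.size:
        names = [m.gene_ids[i] for i in bad[:5]]
        raise ValueError(
            f"gene(s) with zero variance cannot be binarized: {names} "
            "(filter to multimodal genes first)"
        )
    if sp.issparse(x):
        x = sp.csr_matrix(x, dtype=np.int8)
    return BinaryMatrix(x=x, gene_ids=list(m.gene_ids), gene_means=means)


def cooccurrence(x: BinaryMatrix) -> PairCountMatrix:
    """S = X X': counts[i][j] = number of cells with gene i on and gene j on."""
    if sp.issparse(x.x):
        s = np.asarray((x.x @ x.x.T).todense(), dtype=np.int64)
    else:
        xd = np.asarray(x.x, dtype=np.float64)
        s = np.rint(xd @ xd.T).astype(np.int64)
    return PairCountMatrix(counts=s, kind="cooccurrence", gene_ids=list(x.gene_ids))


def mutual_exclusive(x: BinaryMatrix) -> PairCountMatrix:
    """M = (1 - X) X': counts[i][j] = cells with gene i off and gene j on."""
    xd = x.dense().astype(np.float64)
    m = np.rint((1.0 - xd) @ xd.T).astype(np.int64)
    return PairCountMatrix(counts=m, kind="mutual_exclusive", gene_ids=list(x.gene_ids))


_GRAPH_KIND = {"cooccurrence": "kncon", "mutual_exclusive": "knmen"}


def build_graph(counts: PairCountMatrix, k: int, n: int) -> NeighborGraph:
    """k-nearest-neighbour graph from a pair-count matrix.

    For each gene A: keep candidates B != A with counts[A][B] >= n, then the
    k candidates with largest counts (ties at the cut by ascending gene
    index). Fewer than k surviving candidates are all kept.
    """
    if k < 1 or n < 1:
        raise ValueError("k and n must be >= 1")
    c = counts.counts
    n_genes = c.shape[0]
    edges: dict[int, dict[int, int]] = {}
    for a in range(n_genes):
        row = c[a]
        candidates = np.flatnonzero(row >= n)
        candidates = candidates[candidates != a]
        if candidates.size == 0:
            continue
        # stable sort on index then counts descending => deterministic ties
        order = candidates[np.argsort(-row[candidates], kind="stable")]
        top = order[:k]
        edges[a] = {int(b): int(row[b]) for b in sorted(top)}
    return NeighborGraph(
        kind=_GRAPH_KIND[counts.kind], k=k, n=n, gene_ids=list(counts.gene_ids), edges=edges
    )


def find_cmegps(
    g_con: NeighborGraph | None, g_mex: NeighborGraph | None
) -> list[tuple[int, int, str]]:
    """Reciprocally connected gene pairs in either graph.

    Returns sorted (i, j, kind) with i < j; ``kind`` is "cooccurrence",
    "mutual_exclusive" or "both".
    """
    support: dict[tuple[int, int], set[str]] = {}
    for graph, label in ((g_con, "cooccurrence"), (g_mex, "mutual_exclusive")):
        if graph is None:
            continue
        for a, nbrs in graph.edges.items():
            for b in nbrs:
                if a < b and graph.has_edge(b, a):
                    support.setdefault((a, b), set()).add(label)
    out = []
    for (i, j), kinds in sorted(support.items()):
        kind = "both" if len(kinds) == 2 else next(iter(kinds))
        out.append((i, j, kind))
    return out


def markers_from_binary(
    x: BinaryMatrix,
    k: int = 300,
    n: int = 30,
    peak_counts: dict[str, int] | None = None,
) -> MarkerSet:
    """Graph stage: binary matrix -> S, M -> KNCON/KNMEN -> CMEGP markers."""
    s = cooccurrence(x)
    m = mutual_exclusive(x)
    g_con = build_graph(s, k, n)
    g_mex = build_graph(m, k, n)
    pairs = find_cmegps(g_con, g_mex)
    partners: dict[int, list[tuple[str, str]]] = {}
    for i, j, kind in pairs:
        partners.setdefault(i, []).append((x.gene_ids[j], kind))
        partners.setdefault(j, []).append((x.gene_ids[i], kind))
    selected = sorted(partners)
    peak_counts = peak_counts or {}
    provenance = {
        x.gene_ids[i]: {
            "peak_count": peak_counts.get(x.gene_ids[i]),
            "partners": partners[i],
        }
        for i in selected
    }
    return MarkerSet(gene_ids=[x.gene_ids[i] for i in selected], provenance=provenance)


def select_markers(
    m: ExpressionMatrix,
    h_mode: str = "fixed",
    h_fixed: float | None = None,
    k: int = 300,
    n: int = 30,
) -> MarkerSet:
    """End-to-end marker selection on a log-scale expression matrix.

    Pipeline: multimodality filter -> mean binarization -> pair counts ->
    KNCON and KNMEN graphs -> reciprocal pairs -> union of paired genes.
    Fewer than two multimodal genes yields an empty set with a warning.
    """
    profiles = multimodal_genes(m, h_mode=h_mode, h_fixed=h_fixed)
    logger.info("%d / %d genes multimodal", len(profiles), m.n_genes)
    if len(profiles) < 2:
        warnings.warn(
            "fewer than 2 multimodal genes; no marker pairs possible", stacklevel=2
        )
        return MarkerSet(gene_ids=[], provenance={})
    sub = m.restrict_genes([p.gene_id for p in profiles])
    x = binarize(sub)
    peak_counts = {p.gene_id: int(p.peak_count) for p in profiles}
    markers = markers_from_binary(x, k=k, n=n, peak_counts=peak_counts)
    logger.info("%d markers in >= 1 CMEGP", len(markers))
    return markers


def parameter_sweep(
    m: ExpressionMatrix,
    k_values: list[int],
    n_values: list[int],
    h_mode: str = "fixed",
    h_fixed: float | None = None,
) -> list[dict]:
    """Marker sets over a (k, n) grid, sharing the expensive stages.

    The multimodality filter, binarization and pair-count matrices are
    computed once; only the graph/CMEGP stage is rebuilt per grid cell.
    Returns one dict per (k, n) with the marker count and gene list,
    identical to what a single :func:`select_markers` run would give.
    """
    profiles = multimodal_genes(m, h_mode=h_mode, h_fixed=h_fixed)
    rows = []
    if len(profiles) < 2:
        for k in k_values:
            for n in n_values:
                rows.append({"k": k, "n": n, "n_markers": 0, "markers": []})
        return rows
    sub = m.restrict_genes([p.gene_id for p in profiles])
    x = binarize(sub)
    s = cooccurrence(x)
    mx = mutual_exclusive(x)
    for k in k_values:
        for n in n_values:
            pairs = find_cmegps(build_graph(s, k, n), build_graph(mx, k, n))
            selected = sorted({i for i, j, _ in pairs} | {j for i, j, _ in pairs})
            rows.append(
                {
                    "k": k,
                    "n": n,
                    "n_markers": len(selected),
                    "markers": [x.gene_ids[i] for i in selected],
                }
            )
    return rows


def write_marker_list(markers: MarkerSet, path) -> None:
    with open(path, "w") as fh:
        for g in markers.gene_ids:
            fh.write(f"{g}\n")


def write_provenance(markers: MarkerSet, path) -> None:
    """TSV: gene_id, peak count, number of partners, partner ids, pair kinds."""
    with open(path, "w") as fh:
        fh.write("gene_id\tT\tn_cmegp_partners\tpartner_ids\tpair_kinds\n")
        for g in markers.gene_ids:
            info = markers.provenance[g]
            ids = ",".join(p for p, _ in info["partners"])
            kinds = ",".join(kind for _, kind in info["partners"])
            t = info["peak_count"] if info["peak_count"] is not None else "NA"
            fh.write(f"{g}\t{t}\t{len(info['partners'])}\t{ids}\t{kinds}\n")


def write_edges(graphs: list[NeighborGraph], path) -> None:
    """Edge-list TSV (source, target, weight, graph_kind) for graph tools."""
    with open(path, "w") as fh:
        fh.write("source\ttarget\tweight\tgraph_kind\n")
        for g in graphs:
            for a, b, w in g.edge_list():
                fh.write(f"{g.gene_ids[a]}\t{g.gene_ids[b]}\t{w}\t{g.kind}\n")
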