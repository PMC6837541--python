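import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy import sparse as sp

from multimark import (
    BinaryMatrix,
    ExpressionMatrix,
    PairCountMatrix,
    binarize,
    build_graph,
    cooccurrence,
    find_cmegps,
    mutual_exclusive,
    parameter_sweep,
    select_markers,
)


def make_binary(x):
    x = np.asarray(x, dtype=np.int8)
    return BinaryMatrix(
        x=x,
        gene_ids=[f"g{i}" for i in range(x.shape[0])],
        gene_means=np.full(x.shape[0], 0.5),
    )


def and_count_brute_force(x):
    n = x.shape[0]
    s = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(n):
            s[i, j] = int(np.sum((x[i] == 1) & (x[j] == 1)))
    return s


def notand_count_brute_force(x):
    n = x.shape[0]
    m = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(n):
            m[i, j] = int(np.sum((x[i] == 0) & (x[j] == 1)))
    return m


binary_matrices = hnp.arrays(
    dtype=np.int8,
    shape=st.tuples(st.integers(2, 12), st.integers(2, 30)),
    elements=st.integers(0, 1),
)


class TestBinarize:
    def _matrix(self, values):
        values = np.asarray(values, dtype=float)
        n, l = values.shape
        return ExpressionMatrix(
            values, [f"g{i}" for i in range(n)], [f"c{j}" for j in range(l)], scale="log"
        )

    def test_strictly_above_mean(self):
        x = binarize(self._matrix([[1.0, 3.0], [0.0, 2.0]]))
        np.testing.assert_array_equal(x.dense(), [[0, 1], [0, 1]])
        np.testing.assert_allclose(x.gene_means, [2.0, 1.0])

    def test_value_at_mean_maps_to_zero(self):
        x = binarize(self._matrix([[2.0, 2.0, 8.0], [0.0, 1.0, 2.0]]))
        np.testing.assert_array_equal(x.dense()[0], [0, 0, 1])  # mean 4, strict >
        np.testing.assert_array_equal(x.dense()[1], [0, 0, 1])  # mean 1: tie -> 0

    def test_row_sums_strictly_interior(self):
        rng = np.random.default_rng(0)
        values = rng.random((30, 50)) * 5
        x = binarize(self._matrix(values))
        sums = x.dense().sum(axis=1)
        assert (sums > 0).all() and (sums < 50).all()

    def test_constant_row_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            binarize(self._matrix([[1.0, 1.0, 1.0], [0.0, 1.0, 2.0]]))

    def test_sparse_matches_dense(self):
        rng = np.random.default_rng(1)
        values = np.clip(rng.normal(1, 1, size=(20, 40)), 0, None)
        dense = binarize(self._matrix(values))
        m = self._matrix(values)
        sparse = binarize(
            ExpressionMatrix(sp.csr_matrix(values), m.gene_ids, m.cell_ids, scale="log")
        )
        np.testing.assert_array_equal(sparse.dense(), dense.dense())
        np.testing.assert_allclose(sparse.gene_means, dense.gene_means)


class TestPairCounts:
    def test_hand_example(self):
        x = make_binary([[1, 1, 0], [1, 0, 1]])
        s = cooccurrence(x)
        np.testing.assert_array_equal(s.counts, [[2, 1], [1, 2]])
        m = mutual_exclusive(x)
        assert m.counts[0, 1] == 1 and m.counts[1, 0] == 1
        np.testing.assert_array_equal(np.diag(m.counts), 0)

    def test_disjoint_rows_have_zero_cooccurrence(self):
        s = cooccurrence(make_binary([[1, 0], [0, 1]]))
        assert s.counts[0, 1] == 0 and s.counts[1, 0] == 0

    def test_identical_rows_have_zero_mutual_exclusivity(self):
        m = mutual_exclusive(make_binary([[1, 0, 1], [1, 0, 1]]))
        np.testing.assert_array_equal(m.counts, 0)

    @given(binary_matrices)
    @settings(max_examples=60, deadline=None)
    def test_matches_brute_force_and_conservation_identity(self, x):
        b = make_binary(x)
        s = cooccurrence(b).counts
        m = mutual_exclusive(b).counts
        np.testing.assert_array_equal(s, and_count_brute_force(x))
        np.testing.assert_array_equal(m, notand_count_brute_force(x))
        # (1 - x_i) x_j + x_i x_j = x_j summed over cells
        np.testing.assert_array_equal(m + s, np.broadcast_to(np.diag(s), s.shape))
        assert (s == s.T).all()
        np.testing.assert_array_equal(np.diag(s), x.sum(axis=1))

    def test_sparse_cooccurrence_matches_dense(self):
        rng = np.random.default_rng(2)
        x = (rng.random((15, 40)) < 0.4).astype(np.int8)
        dense = make_binary(x)
        sparse = BinaryMatrix(sp.csr_matrix(x), dense.gene_ids, dense.gene_means)
        np.testing.assert_array_equal(cooccurrence(sparse).counts, cooccurrence(dense).counts)


class TestBuildGraph:
    def _counts(self, c):
        c = np.asarray(c)
        return PairCountMatrix(
            counts=c, kind="cooccurrence", gene_ids=[f"g{i}" for i in range(c.shape[0])]
        )

    def test_threshold_then_top_k(self):
        # A's counts: B=5, C=3, D=1; k=2, n=2 -> edges A->B, A->C only
        c = np.array(
            [[9, 5, 3, 1], [5, 9, 0, 0], [3, 0, 9, 0], [1, 0, 0, 9]]
        )
        g = build_graph(self._counts(c), k=2, n=2)
        assert set(g.edges[0]) == {1, 2}
        assert g.edges[0][1] == 5

    def test_no_truncation_when_k_large(self):
        c = np.array([[5, 1, 2], [1, 5, 3], [2, 3, 5]])
        g = build_graph(self._counts(c), k=10, n=1)
        assert all(len(nbrs) == 2 for nbrs in g.edges.values())

    def test_all_below_threshold_gives_empty_graph(self):
        c = np.array([[9, 1], [1, 9]])
        g = build_graph(self._counts(c), k=3, n=2)
        assert g.edges == {}

    def test_tie_at_cut_broken_by_ascending_index(self):
        c = np.array([[9, 4, 4, 4], [4, 9, 0, 0], [4, 0, 9, 0], [4, 0, 0, 9]])
        g = build_graph(self._counts(c), k=2, n=1)
        assert set(g.edges[0]) == {1, 2}

    def test_no_self_edges_and_degree_bound(self):
        rng = np.random.default_rng(3)
        c = rng.integers(0, 20, size=(10, 10))
        np.fill_diagonal(c, 50)
        g = build_graph(PairCountMatrix(c, "cooccurrence", [f"g{i}" for i in range(10)]), k=3, n=2)
        for a, nbrs in g.edges.items():
            assert a not in nbrs
            assert len(nbrs) <= 3
            assert all(w >= 2 for w in nbrs.values())


class TestFindCmegps:
    def test_reciprocal_in_one_graph(self):
        g_con = graph_from_edges([(0, 1), (1, 0)], "kncon")
        g_mex = graph_from_edges([], "knmen")
        assert find_cmegps(g_con, g_mex) == [(0, 1, "cooccurrence")]

    def test_one_way_edge_is_not_a_pair(self):
        g_con = graph_from_edges([(0, 1)], "kncon")
        g_mex = graph_from_edges([], "knmen")
        assert find_cmegps(g_con, g_mex) == []

    def test_reciprocal_in_both_graphs_tagged_both(self):
        g_con = graph_from_edges([(0, 1), (1, 0)], "kncon")
        g_mex = graph_from_edges([(0, 1), (1, 0)], "knmen")
        assert find_cmegps(g_con, g_mex) == [(0, 1, "both")]


def graph_from_edges(edges, kind):
    from multimark.graph import NeighborGraph

    e = {}
    for a, b in edges:
        e.setdefault(a, {})[b] = 10
    return NeighborGraph(kind=kind, k=5, n=1, gene_ids=[f"g{i}" for i in range(5)], edges=e)


class TestSelectMarkers:
    def test_two_module_schematic_yields_expected_markers(self, fig1_matrix):
        ms = select_markers(fig1_matrix, h_fixed=0.3, k=2, n=3)
        assert ms.gene_ids == ["g1", "g2", "g3", "g6", "g7"]
        con_pairs = {
            frozenset((g, p))
            for g in ms.gene_ids
            for p, kind in ms.provenance[g]["partners"]
            if kind == "cooccurrence"
        }
        mex_pairs = {
            frozenset((g, p))
            for g in ms.gene_ids
            for p, kind in ms.provenance[g]["partners"]
            if kind == "mutual_exclusive"
        }
        assert con_pairs == {
            frozenset(p) for p in [("g1", "g2"), ("g1", "g3"), ("g2", "g3"), ("g6", "g7")]
        }
        assert mex_pairs == {
            frozenset(p)
            for p in [("g1", "g6"), ("g1", "g7"), ("g2", "g6"), ("g2", "g7")]
        }

    def test_pure_noise_selects_nothing(self):
        rng = np.random.default_rng(4)
        values = np.clip(rng.normal(1.0, 0.5, size=(60, 120)), 0, None)
        m = ExpressionMatrix(
            values, [f"g{i}" for i in range(60)], [f"c{j}" for j in range(120)], scale="log"
        )
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)  # may find < 2 multimodal genes
            ms = select_markers(m, h_fixed=0.3, k=300, n=30)
        assert len(ms) <= 3

    def test_fewer_than_two_multimodal_genes_warns_empty(self):
        m = ExpressionMatrix(
            np.ones((3, 10)), ["a", "b", "c"], [f"c{j}" for j in range(10)], scale="log"
        )
        with pytest.warns(UserWarning, match="fewer than 2 multimodal"):
            ms = select_markers(m, h_fixed=0.3)
        assert len(ms) == 0

    def test_cell_permutation_invariance(self, fig1_matrix):
        rng = np.random.default_rng(5)
        perm = rng.permutation(fig1_matrix.n_cells)
        permuted = ExpressionMatrix(
            fig1_matrix.values[:, perm],
            fig1_matrix.gene_ids,
            [fig1_matrix.cell_ids[j] for j in perm],
            scale="log",
        )
        a = select_markers(fig1_matrix, h_fixed=0.3, k=2, n=3)
        b = select_markers(permuted, h_fixed=0.3, k=2, n=3)
        assert a.gene_ids == b.gene_ids

    def test_gene_permutation_equivariance(self, fig1_matrix):
        rng = np.random.default_rng(6)
        perm = rng.permutation(fig1_matrix.n_genes)
        permuted = ExpressionMatrix(
            fig1_matrix.values[perm],
            [fig1_matrix.gene_ids[i] for i in perm],
            fig1_matrix.cell_ids,
            scale="log",
        )
        a = select_markers(fig1_matrix, h_fixed=0.3, k=2, n=3)
        b = select_markers(permuted, h_fixed=0.3, k=2, n=3)
        assert sorted(a.gene_ids) == sorted(b.gene_ids)

    def test_marker_set_nested_in_multimodal_set(self, reference_sim):
        from multimark import multimodal_genes

        matrix, _, _ = reference_sim
        ms = select_markers(matrix, h_fixed=0.3, k=300, n=30)
        multimodal = {p.gene_id for p in multimodal_genes(matrix, h_fixed=0.3)}
        assert set(ms.gene_ids) <= multimodal <= set(matrix.gene_ids)

    def test_monotonicity_in_n(self, reference_sim):
        matrix, _, _ = reference_sim
        loose = select_markers(matrix, h_fixed=0.3, k=300, n=10)
        tight = select_markers(matrix, h_fixed=0.3, k=300, n=60)
        assert set(tight.gene_ids) <= set(loose.gene_ids)


class TestParameterSweep:
    def test_matches_single_runs(self, fig1_matrix):
        rows = parameter_sweep(fig1_matrix, k_values=[2, 3], n_values=[2, 3], h_fixed=0.3)
        assert len(rows) == 4
        for row in rows:
            single = select_markers(fig1_matrix, h_fixed=0.3, k=row["k"], n=row["n"])
            assert row["markers"] == single.gene_ids
            assert row["n_markers"] == len(single)

    def test_marker_count_non_increasing_in_n(self, reference_sim):
        matrix, _, _ = reference_sim
        rows = parameter_sweep(matrix, k_values=[300], n_values=[10, 30, 60], h_fixed=0.3)
        counts = [r["n_markers"] for r in rows]
        assert counts == sorted(counts, reverse=True)
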