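"""Soft assignment layers and graph coarsening."""

import numpy as np
import pytest

from hierpool.autodiff import Tensor
from hierpool.message_passing import NodeEmbeddings, gnn_forward, init_gnn_params
from hierpool.model import count_parameters, init_diffpool_layer_params, init_fpool_layer_params
from hierpool.pooling import (
    AssignmentMatrix,
    FPoolAssignParams,
    coarsen,
    diffpool_layer,
    fpool_layer,
    row_softmax,
)

import straightline_oracle as oracle
from conftest import random_graph


class TestRowSoftmax:
    def test_zero_logits_give_uniform_rows(self):
        S = row_softmax(np.zeros((4, 3)))
        assert S.values == pytest.approx(np.full((4, 3), 1 / 3))

    def test_closed_form_two_way(self):
        S = row_softmax(np.array([[10.0, 0.0]]))
        expected = np.array([np.exp(10), 1.0]) / (np.exp(10) + 1)
        assert S.values[0] == pytest.approx(expected, abs=1e-9)

    def test_shift_invariance(self):
        rng = np.random.default_rng(0)
        logits = rng.standard_normal((5, 4))
        shifted = row_softmax(logits + 123.0).values
        assert shifted == pytest.approx(row_softmax(logits).values, abs=1e-12)

    def test_rows_sum_to_one_even_for_extreme_logits(self):
        S = row_softmax(np.array([[1e4, -1e4, 0.0]]))
        assert np.isfinite(S.values).all()
        assert S.values.sum(axis=1) == pytest.approx([1.0])


class TestFPoolLayer:
    def test_zero_assignment_map_gives_uniform_clusters(self):
        rng = np.random.default_rng(1)
        g = random_graph(rng, n=6, d=3)
        gnn = init_gnn_params(rng, [3, 4])
        assign = FPoolAssignParams(W=Tensor(np.zeros((4, 3))), B=Tensor(np.zeros(3)))
        _, S = fpool_layer(g.adjacency, g.features, gnn, assign)
        assert S.values == pytest.approx(np.full((6, 3), 1 / 3))

    def test_bias_only_assignment_is_embedding_independent(self):
        rng = np.random.default_rng(2)
        g = random_graph(rng, n=5, d=3)
        gnn = init_gnn_params(rng, [3, 4])
        assign = FPoolAssignParams(
            W=Tensor(np.zeros((4, 2))), B=Tensor(np.array([10.0, 0.0]))
        )
        _, S = fpool_layer(g.adjacency, g.features, gnn, assign)
        expected = np.array([np.exp(10), 1.0]) / (np.exp(10) + 1)
        assert S.values == pytest.approx(np.tile(expected, (5, 1)), abs=1e-9)

    def test_dimension_mismatch_rejected(self):
        rng = np.random.default_rng(3)
        gnn = init_gnn_params(rng, [3, 4])
        assign = FPoolAssignParams(W=Tensor(np.zeros((5, 2))), B=Tensor(np.zeros(2)))
        with pytest.raises(ValueError, match="assignment weight rows"):
            fpool_layer(np.zeros((2, 2)), np.ones((2, 3)), gnn, assign)


class TestDiffPoolLayer:
    def test_single_cluster_assignment_is_all_ones_column(self):
        rng = np.random.default_rng(4)
        g = random_graph(rng, n=6, d=3)
        embed = init_gnn_params(rng, [3, 4])
        pool = init_gnn_params(rng, [3, 4])
        assign = FPoolAssignParams(
            W=Tensor(rng.standard_normal((4, 1))), B=Tensor(np.zeros(1))
        )
        _, S = diffpool_layer(g.adjacency, g.features, embed, pool, assign)
        assert np.array_equal(S.values, np.ones((6, 1)))

    def test_rows_are_stochastic_and_embeddings_compose(self):
        rng = np.random.default_rng(5)
        g = random_graph(rng, n=7, d=3)
        embed = init_gnn_params(rng, [3, 4])
        pool = init_gnn_params(rng, [3, 4])
        assign = FPoolAssignParams(
            W=Tensor(rng.standard_normal((4, 3))), B=Tensor(np.zeros(3))
        )
        Z, S = diffpool_layer(g.adjacency, g.features, embed, pool, assign)
        assert S.values.sum(axis=1) == pytest.approx(np.ones(7), abs=1e-6)
        standalone = gnn_forward(g.adjacency, g.features, embed)
        assert np.array_equal(Z.values, standalone.values)  # bitwise

    def test_gnn_entry_count_is_double_fpool_at_identical_config(self):
        rng = np.random.default_rng(6)
        fp = init_fpool_layer_params(rng, input_dim=10, hidden=64, k=3, n_clusters=25)
        dp = init_diffpool_layer_params(rng, input_dim=10, hidden=64, k=3, n_clusters=25)
        assert count_parameters(dp, "gnn_only") == 2 * count_parameters(fp, "gnn_only")


class TestCoarsen:
    def _assignment(self, values):
        return AssignmentMatrix(tensor=Tensor(np.asarray(values, dtype=float)))

    def _embeddings(self, values):
        return NodeEmbeddings(tensor=Tensor(np.asarray(values, dtype=float)))

    def test_identity_assignment_is_a_no_op(self):
        rng = np.random.default_rng(7)
        g = random_graph(rng, n=5, d=3)
        Z = rng.standard_normal((5, 3))
        out = coarsen(self._assignment(np.eye(5)), self._embeddings(Z), g.adjacency)
        assert np.array_equal(out.features, Z)
        assert np.array_equal(out.adjacency, g.adjacency)

    def test_single_cluster_sums_everything(self):
        A = np.array([[0.0, 1.0], [1.0, 0.0]])
        Z = np.array([[1.0, 2.0], [3.0, 4.0]])
        out = coarsen(self._assignment([[1.0], [1.0]]), self._embeddings(Z), A)
        assert np.array_equal(out.features, [[4.0, 6.0]])
        assert np.array_equal(out.adjacency, [[2.0]])

    def test_symmetry_and_mass_conservation(self):
        rng = np.random.default_rng(8)
        g = random_graph(rng, n=6, d=2)
        Z = rng.standard_normal((6, 2))
        S = row_softmax(rng.standard_normal((6, 3)))
        out = coarsen(S, self._embeddings(Z), g.adjacency)
        assert out.adjacency == pytest.approx(out.adjacency.T, abs=1e-9)
        assert out.adjacency.sum() == pytest.approx(g.adjacency.sum(), abs=1e-6)
        assert out.features.sum(axis=0) == pytest.approx(Z.sum(axis=0), abs=1e-6)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(9)
        g = random_graph(rng, n=6, d=2)
        Z = rng.standard_normal((6, 2))
        S = row_softmax(rng.standard_normal((6, 3)))
        out = coarsen(S, self._embeddings(Z), g.adjacency)
        X1, A1 = oracle.coarsen_loops(S.values, Z, g.adjacency)
        assert out.features == pytest.approx(X1, abs=1e-9)
        assert out.adjacency == pytest.approx(A1, abs=1e-9)

    def test_permutation_of_nodes_cancels(self):
        rng = np.random.default_rng(10)
        g = random_graph(rng, n=6, d=2)
        Z = rng.standard_normal((6, 2))
        S = row_softmax(rng.standard_normal((6, 3)))
        P = np.eye(6)[rng.permutation(6)]
        base = coarsen(S, self._embeddings(Z), g.adjacency)
        permuted = coarsen(
            self._assignment(P @ S.values),
            self._embeddings(P @ Z),
            P @ g.adjacency @ P.T,
        )
        assert permuted.features == pytest.approx(base.features, abs=1e-9)
        assert permuted.adjacency == pytest.approx(base.adjacency, abs=1e-9)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="assignment rows"):
            coarsen(
                self._assignment(np.ones((3, 1)) / 1.0),
                self._embeddings(np.ones((4, 2))),
                np.zeros((4, 4)),
            )
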