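"""Assembled classifiers: readout, parameter counting, full forward."""

import numpy as np
import pytest

from hierpool.autodiff import Tensor
from hierpool.graph_io import Graph
from hierpool.message_passing import NodeEmbeddings
from hierpool.model import (
    ModelConfig,
    argmax_assignment,
    count_parameters,
    forward,
    init_parameters,
    load_checkpoint,
    readout,
    save_checkpoint,
)

import straightline_oracle as oracle
from conftest import random_graph


def small_config(arch="fpool", **kw):
    base = dict(
        architecture=arch,
        input_dim=3,
        n_classes=2,
        n_stages=3,
        k=2,
        hidden=6,
        clusters=(4, 3),
        head_hidden=5,
        seed=0,
    )
    base.update(kw)
    return ModelConfig(**base)


class TestReadout:
    def _emb(self, values):
        return NodeEmbeddings(tensor=Tensor(np.asarray(values, dtype=float)))

    def test_single_row_is_direction_cosines(self):
        hG = readout([self._emb([[3.0, 4.0]])])
        assert hG.data == pytest.approx([0.6, 0.8])

    def test_length_is_sum_of_widths(self):
        rng = np.random.default_rng(0)
        embs = [self._emb(rng.standard_normal((5, d))) for d in (2, 3, 4)]
        assert readout(embs).data.shape == (9,)

    def test_all_zero_matrix_maps_to_zero_segment(self):
        hG = readout([self._emb(np.zeros((4, 3)))])
        assert np.array_equal(hG.data, np.zeros(3))

    def test_normalised_matrices_have_unit_frobenius_norm(self):
        rng = np.random.default_rng(1)
        Z = rng.standard_normal((6, 4))
        norm = np.linalg.norm(Z)
        hG = readout([self._emb(Z)])
        assert hG.data == pytest.approx((Z / norm).mean(axis=0), abs=1e-9)

    def test_row_normalised_variant_handles_zero_rows(self):
        Z = np.array([[3.0, 4.0], [0.0, 0.0]])
        hG = readout([self._emb(Z)], row_normalize=True)
        assert hG.data == pytest.approx([0.3, 0.4])


class TestCountParameters:
    def test_single_linear_map_with_bias(self):
        params = {
            "stage1.gnn.w1": Tensor(np.zeros((2, 3)), requires_grad=True),
            "stage1.gnn.b1": Tensor(np.zeros(3), requires_grad=True),
        }
        assert count_parameters(params, "all") == 9
        assert count_parameters(params, "gnn_only") == 9

    def test_fpool_model_is_smaller_than_diffpool(self):
        for kw in ({}, {"hidden": 12, "clusters": (6, 2)}):
            fp = init_parameters(small_config("fpool", **kw))
            dp = init_parameters(small_config("diffpool", **kw))
            assert count_parameters(fp, "all") < count_parameters(dp, "all")

    def test_all_scope_matches_independent_tally(self):
        params = init_parameters(small_config())
        tally = sum(int(np.prod(p.data.shape)) for p in params.values())
        assert count_parameters(params, "all") == tally

    def test_unknown_scope_rejected(self):
        with pytest.raises(ValueError, match="scope"):
            count_parameters({}, "everything")


class TestArgmaxAssignment:
    def test_one_hot_rows_return_hot_index(self):
        assert np.array_equal(argmax_assignment(np.eye(3)[[2, 0, 1]]), [2, 0, 1])

    def test_ties_break_to_lowest_index(self):
        assert argmax_assignment(np.full((1, 3), 1 / 3))[0] == 0

    def test_plain_argmax(self):
        assert argmax_assignment(np.array([[0.2, 0.5, 0.3]]))[0] == 1


class TestForward:
    def test_log_probabilities_normalise(self):
        rng = np.random.default_rng(2)
        g = random_graph(rng, n=9, d=3)
        for arch in ("fpool", "diffpool", "mean_baseline"):
            cfg = small_config(arch)
            logp, _ = forward(g, init_parameters(cfg), cfg)
            assert np.exp(logp).sum() == pytest.approx(1.0, abs=1e-6)

    def test_permutation_invariance_of_log_probabilities(self):
        rng = np.random.default_rng(3)
        cfg = small_config()
        params = init_parameters(cfg)
        for _ in range(5):
            g = random_graph(rng, n=8, d=3)
            base, _ = forward(g, params, cfg)
            perm = rng.permutation(8)
            P = np.eye(8)[perm]
            permuted_graph = Graph(
                adjacency=P @ g.adjacency @ P.T,
                features=P @ g.features,
                label=g.label,
                graph_id=0,
            )
            permuted, _ = forward(permuted_graph, params, cfg)
            assert np.abs(permuted - base).max() < 1e-5

    def test_trace_shapes_follow_the_hierarchy(self):
        rng = np.random.default_rng(4)
        g = random_graph(rng, n=10, d=3)
        cfg = small_config()
        _, trace = forward(g, init_parameters(cfg), cfg)
        assert [s.values.shape for s in trace.assignments] == [(10, 4), (4, 3)]
        assert [c.adjacency.shape for c in trace.coarsened] == [(4, 4), (3, 3)]
        assert trace.graph_embedding.shape == (3 * cfg.hidden,)

    def test_single_stage_architectures_coincide(self):
        # with one stage there is no pooling layer, so FPool and DiffPool
        # degenerate to the same GNN + normalised mean readout + head
        rng = np.random.default_rng(5)
        g = random_graph(rng, n=7, d=3)
        fp_cfg = small_config("fpool", n_stages=1, clusters=())
        dp_cfg = small_config("diffpool", n_stages=1, clusters=())
        fp_logp, _ = forward(g, init_parameters(fp_cfg), fp_cfg)
        dp_logp, _ = forward(g, init_parameters(dp_cfg), dp_cfg)
        assert np.array_equal(fp_logp, dp_logp)

    def test_full_forward_matches_straightline_script(self):
        rng = np.random.default_rng(6)
        g = random_graph(rng, n=6, d=2)
        cfg = ModelConfig(
            architecture="fpool",
            input_dim=2,
            n_classes=2,
            n_stages=3,
            k=1,
            hidden=2,
            clusters=(3, 2),
            head_hidden=2,
            seed=7,
        )
        params = init_parameters(cfg)
        logp, trace = forward(g, params, cfg)
        ref = oracle.full_fpool_forward(
            g.adjacency,
            g.features,
            {k: p.data for k, p in params.items()},
            n_stages=3,
            k=1,
        )
        for ours, theirs in zip(trace.embeddings, ref["embeddings"]):
            assert ours.values == pytest.approx(theirs, abs=1e-9)
        for ours, theirs in zip(trace.assignments, ref["assignments"]):
            assert ours.values == pytest.approx(theirs, abs=1e-9)
        assert trace.graph_embedding == pytest.approx(ref["hG"], abs=1e-9)
        assert logp == pytest.approx(ref["log_probs"], abs=1e-9)

    def test_feature_width_mismatch_rejected(self):
        rng = np.random.default_rng(8)
        g = random_graph(rng, n=5, d=4)
        cfg = small_config()
        with pytest.raises(ValueError, match="input_dim"):
            forward(g, init_parameters(cfg), cfg)


def test_checkpoint_round_trip(tmp_path):
    cfg = small_config()
    params = init_parameters(cfg)
    path = tmp_path / "model.npz"
    save_checkpoint(path, params, cfg)
    loaded, loaded_cfg = load_checkpoint(path)
    assert loaded_cfg == cfg
    assert set(loaded) == set(params)
    for name in params:
        assert np.array_equal(loaded[name].data, params[name].data)
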