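"""Transformer forward pass: projections, attention, updates, heads."""

import numpy as np
import pytest
import scipy.sparse as sp

from raregraph import autodiff as ad
from raregraph.autodiff import Parameter, Tensor, no_grad
from raregraph.hgt_core import (BatchGraph, HGTConfig, cell_assignment,
                                encode, full_graph, hgt_layer, init_embed,
                                init_params, link_assignment,
                                load_checkpoint, save_checkpoint)

RNG = np.random.default_rng(0)


def make_bg(nc=2, ng=2, npk=1, cf=3, gf=2, pf=2, edges=None, feats=None):
    if feats is None:
        feats = (RNG.random((nc, cf)), RNG.random((ng, gf)),
                 RNG.random((npk, pf)))
    fc, fg, fp = (sp.csr_matrix(f) for f in feats)
    if edges is None:
        edges = [(np.array([], dtype=int),) * 2] * 4
    return BatchGraph(fc, fg, fp, list(edges), nc, ng, npk)


def default_params(cf=3, gf=2, pf=2, config=None):
    return init_params(np.random.default_rng(1), cf, gf, pf,
                       config or HGTConfig(dim=8, heads=2, layers=1,
                                           n_init=None))


class TestInitEmbed:
    def test_default_width_is_256(self):
        params = init_params(np.random.default_rng(0), 5, 4, 3)
        bg = make_bg(cf=5, gf=4, pf=3)
        H = init_embed(params, bg)
        assert H.shape == (5, 256)

    def test_zero_features_zero_bias_give_zero_embedding(self):
        params = default_params()
        bg = make_bg(feats=(np.zeros((2, 3)), np.zeros((2, 2)),
                            np.zeros((1, 2))))
        H = init_embed(params, bg)
        assert np.allclose(H.data, 0.0)

    def test_projection_additivity_on_log_scale(self):
        # projection itself is linear; features pass through log1p first
        params = default_params()
        f1 = np.array([[np.e - 1, 0.0, 0.0]])
        f2 = np.array([[0.0, np.e - 1, 0.0]])
        f12_log = np.log1p(f1) + np.log1p(f2)
        bg1 = make_bg(nc=1, feats=(f1, np.zeros((2, 2)), np.zeros((1, 2))))
        bg2 = make_bg(nc=1, feats=(f2, np.zeros((2, 2)), np.zeros((1, 2))))
        h1 = init_embed(params, bg1).data[0]
        h2 = init_embed(params, bg2).data[0]
        direct = f12_log @ params["W_C"].data + params["b_C"].data
        assert np.allclose(h1 + h2 - params["b_C"].data, direct[0])

    def test_dim_mismatch_raises(self):
        params = default_params(cf=7)
        bg = make_bg(cf=3)
        with pytest.raises(ValueError, match="feature dim"):
            init_embed(params, bg)


class TestAttention:
    def test_softmax_of_hand_scores(self):
        # scores (0, ln2, ln4) -> weights (1/7, 2/7, 4/7)
        scores = Tensor(np.log(np.array([1.0, 2.0, 4.0])))
        out = ad.segment_softmax(scores, np.zeros(3, dtype=int), 1)
        assert out.data == pytest.approx([1 / 7, 2 / 7, 4 / 7])

    def test_single_neighbor_gets_weight_one(self):
        out = ad.segment_softmax(Tensor(np.array([13.7])),
                                 np.array([0]), 1)
        assert out.data == pytest.approx([1.0])

    def test_identical_neighbors_split_evenly_through_layer(self):
        # two gene neighbors with identical features and edge type must
        # contribute symmetrically: the cell update equals the update
        # with either gene's message at full weight
        cfg = HGTConfig(dim=8, heads=2, layers=1, n_init=None)
        params = default_params(config=cfg)
        gf = np.tile(RNG.random(2), (2, 1))
        edges = [(np.array([1, 2]), np.array([0, 0])),
                 (np.array([], dtype=int), np.array([], dtype=int)),
                 (np.array([], dtype=int), np.array([], dtype=int)),
                 (np.array([], dtype=int), np.array([], dtype=int))]
        bg = make_bg(nc=1, ng=2, npk=1, edges=edges,
                     feats=(RNG.random((1, 3)), gf, np.zeros((1, 2))))
        H0 = init_embed(params, bg)
        H1 = hgt_layer(params, 0, H0, bg)
        single = [(np.array([1]), np.array([0]))] + edges[1:]
        bg_single = make_bg(nc=1, ng=2, npk=1, edges=single,
                            feats=(bg.feat_c.toarray(), gf,
                                   np.zeros((1, 2))))
        H1s = hgt_layer(params, 0, init_embed(params, bg_single),
                        bg_single)
        assert np.allclose(H1.data[0], H1s.data[0])


class TestUpdate:
    def test_alpha_zero_keeps_previous_embedding(self):
        params = default_params()
        params.tensors["alpha0"].data = np.array(0.0)
        bg = make_bg()
        H0 = init_embed(params, bg)
        H1 = hgt_layer(params, 0, H0, bg)
        assert np.allclose(H1.data, H0.data)

    def test_isolated_node_halves_with_alpha_half(self):
        params = default_params()
        params.tensors["alpha0"].data = np.array(0.5)
        bg = make_bg()  # no edges at all
        H0 = init_embed(params, bg)
        H1 = hgt_layer(params, 0, H0, bg)
        assert np.allclose(H1.data, 0.5 * H0.data)

    def test_alpha_clamped_into_unit_interval(self):
        params = default_params()
        params.tensors["alpha0"].data = np.array(7.3)  # clamps to 1
        bg = make_bg()
        H0 = init_embed(params, bg)
        H1 = hgt_layer(params, 0, H0, bg)
        assert np.allclose(H1.data, np.maximum(0, np.zeros_like(H0.data)))


class TestHeads:
    def test_cell_assignment_rows_are_distributions(self):
        params = default_params()
        P, labels = cell_assignment(params, Tensor(RNG.normal(size=(5,
                                                                    8))))
        assert np.allclose(P.data.sum(axis=1), 1.0)
        assert np.all(P.data >= 0)
        assert labels.shape == (5,)

    def test_tied_scores_pick_lowest_index(self):
        params = default_params()
        P, labels = cell_assignment(params, Tensor(np.zeros((2, 8))))
        assert np.allclose(P.data, 1 / 8)
        assert labels.tolist() == [0, 0]

    def test_hand_softmax_row(self):
        params = default_params()
        h = np.log(np.array([[1.0, 2.0, 7.0] + [1e-9] * 5]))
        P, labels = cell_assignment(params, Tensor(h))
        assert P.data[0, :3] == pytest.approx([0.1, 0.2, 0.7])
        assert labels[0] == 2

    def test_linear_head_changes_width(self):
        cfg = HGTConfig(dim=8, heads=2, layers=1, n_init=5)
        params = default_params(config=cfg)
        P, _ = cell_assignment(params, Tensor(RNG.normal(size=(4, 8))))
        assert P.shape == (4, 5)

    def test_link_rows_are_distributions(self):
        params = default_params()
        o = link_assignment(params, Tensor(RNG.normal(size=(3, 8))),
                            Tensor(RNG.normal(size=(2, 8))),
                            np.array([0, 1, 2]), np.array([0, 1, 0]))
        assert o.shape == (3, 8)
        assert np.allclose(o.data.sum(axis=1), 1.0)

    def test_link_scores_all_zero_fall_back_to_uniform(self):
        params = default_params()
        params.tensors["W_link"].data[:] = 0.0
        o = link_assignment(params, Tensor(np.ones((1, 8))),
                            Tensor(np.ones((1, 8))), np.array([0]),
                            np.array([0]))
        assert o.data[0] == pytest.approx([1 / 8] * 8)


class TestForward:
    def test_deterministic(self, small_graph):
        cfg = HGTConfig(dim=16, heads=2, layers=2, n_init=None)
        params = init_params(np.random.default_rng(5), small_graph.n_genes,
                             small_graph.n_cells, small_graph.n_cells, cfg)
        bg = full_graph(small_graph)
        with no_grad():
            a = encode(params, bg)[0].data
            b = encode(params, bg)[0].data
        assert np.array_equal(a, b)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        nc, ng, npk = 4, 3, 2
        xr = (rng.random((ng, nc)) < 0.7) * rng.integers(1, 5, (ng, nc))
        xa = (rng.random((npk, nc)) < 0.7) * 1
        from conftest import make_count_matrix
        from raregraph.hetgraph import build_graph
        g = build_graph(make_count_matrix(xr, "rna"),
                        make_count_matrix(xa, "atac"))
        cfg = HGTConfig(dim=8, heads=2, layers=2, n_init=None)
        params = init_params(np.random.default_rng(0), ng, nc, nc, cfg)
        with no_grad():
            Hc = encode(params, full_graph(g))[0].data
        perm = np.array([2, 0, 3, 1])
        g2 = build_graph(
            make_count_matrix(xr[:, perm], "rna"),
            make_count_matrix(xa[:, perm], "atac"))
        # permuting cells also permutes the gene/peak feature columns, so
        # project with permuted fan-in weights to match
        params2 = init_params(np.random.default_rng(0), ng, nc, nc, cfg)
        params2.tensors["W_G"].data = params.tensors["W_G"].data[perm]
        params2.tensors["W_E"].data = params.tensors["W_E"].data[perm]
        with no_grad():
            Hc2 = encode(params2, full_graph(g2))[0].data
        assert np.allclose(Hc2, Hc[perm], atol=1e-10)


def test_checkpoint_roundtrip(tmp_path):
    params = default_params()
    save_checkpoint(params, tmp_path / "model")
    back = load_checkpoint(tmp_path / "model")
    assert back.config == params.config
    for k, t in params.tensors.items():
        assert np.array_equal(back.tensors[k].data, t.data)
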