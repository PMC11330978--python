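import numpy as np
import pytest

from stcomm.autodiff import Tensor
from stcomm.data_model import (CellTypeAnnotation, ExpressionMatrix,
                               Resolution, SpatialDataset)
from stcomm.integration import (AttentionLayerParams, IntegrationNet,
                                MappingMatrix, TrainConfig,
                                attention_message, attention_weights,
                                celltype_probability_map, encode_nodes,
                                fit_mapping, gnn_forward,
                                similarity_and_loss)
from stcomm.preprocessing import normalize_counts


def make_net(n_genes=6, dim=8, heads=2, layers=2, seed=0):
    cfg = TrainConfig(n_layers=layers, dim=dim, heads=heads, epochs=1,
                      seed=seed)
    return IntegrationNet(n_genes, cfg, np.random.default_rng(seed)), cfg


class TestTrainConfig:
    def test_odd_layers_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(n_layers=3)

    def test_dim_head_divisibility(self):
        with pytest.raises(ValueError):
            TrainConfig(dim=10, heads=4)


class TestEncodeNodes:
    def test_zero_position_mlp_gives_pure_expression(self, rng):
        net, _ = make_net()
        expr = rng.normal(size=(5, 6))
        pos = rng.normal(size=(5, 2))
        state = encode_nodes(expr, pos, net, "st")
        # position MLP output layer is zero-initialized
        lifted = expr @ net.W_lift.data + net.b_lift.data
        assert np.allclose(state.x.data, lifted)

    def test_identical_units_identical_states(self, rng):
        net, _ = make_net()
        row = rng.normal(size=6)
        expr = np.vstack([row, row])
        pos = np.zeros((2, 2))
        state = encode_nodes(expr, pos, net, "sc")
        assert np.allclose(state.x.data[0], state.x.data[1])

    def test_position_change_only_moves_position_term(self, rng):
        net, _ = make_net()
        net.pos_enc.W2.data = rng.normal(size=net.pos_enc.W2.shape)
        expr = rng.normal(size=(4, 6))
        p1 = rng.normal(size=(4, 2))
        s1 = encode_nodes(expr, p1, net, "st")
        s2 = encode_nodes(expr, 2 * p1, net, "st")
        enc = net.pos_enc
        term1 = np.maximum(p1 @ enc.W1.data + enc.b1.data, 0) @ enc.W2.data
        term2 = np.maximum(2 * p1 @ enc.W1.data + enc.b1.data, 0) @ enc.W2.data
        assert np.allclose(s2.x.data - s1.x.data, term2 - term1 + 0.0)

    def test_width_mismatch_rejected(self, rng):
        net, _ = make_net(n_genes=6)
        with pytest.raises(ValueError):
            encode_nodes(rng.normal(size=(3, 7)), np.zeros((3, 2)), net, "sc")


class TestAttentionMessage:
    def test_single_source_returns_its_value(self, rng):
        layer = AttentionLayerParams(8, 2, "cross", rng)
        xq = Tensor(rng.normal(size=(3, 8)))
        xs = Tensor(rng.normal(size=(1, 8)))
        m = attention_message(xq, xs, layer)
        v = np.concatenate([xs.data @ layer.W3[h].data + layer.b3[h].data
                            for h in range(2)], axis=1)
        assert np.allclose(m.data, np.repeat(v, 3, axis=0))

    def test_equal_logits_give_uniform_weights(self, rng):
        layer = AttentionLayerParams(8, 2, "self", rng)
        for h in range(2):
            layer.W1[h].data[:] = 0.0  # all queries identical -> logits equal
        xq = Tensor(rng.normal(size=(2, 8)))
        xs = Tensor(rng.normal(size=(5, 8)))
        for a in attention_weights(xq, xs, layer):
            assert np.allclose(a, 1.0 / 5.0)

    def test_matches_brute_force_oracle(self, rng):
        layer = AttentionLayerParams(8, 2, "self", rng)
        xq = Tensor(rng.normal(size=(4, 8)))
        xs = Tensor(rng.normal(size=(4, 8)))
        m = attention_message(xq, xs, layer)
        dh = 4
        expected = []
        for h in range(2):
            q = xq.data @ layer.W1[h].data + layer.b1[h].data
            k = xs.data @ layer.W2[h].data + layer.b2[h].data
            v = xs.data @ layer.W3[h].data + layer.b3[h].data
            out = np.zeros((4, dh))
            for i in range(4):
                logits = np.array([q[i] @ k[j] / np.sqrt(dh)
                                   for j in range(4)])
                w = np.exp(logits - logits.max())
                w /= w.sum()
                out[i] = sum(w[j] * v[j] for j in range(4))
            expected.append(out)
        assert np.allclose(m.data, np.concatenate(expected, axis=1),
                           atol=1e-6)

    def test_empty_source_rejected(self, rng):
        layer = AttentionLayerParams(8, 2, "self", rng)
        with pytest.raises(ValueError):
            attention_message(Tensor(np.zeros((2, 8))),
                              Tensor(np.zeros((0, 8))), layer)

    def test_weights_sum_to_one(self, rng):
        layer = AttentionLayerParams(8, 4, "cross", rng)
        xq = Tensor(rng.normal(size=(6, 8)))
        xs = Tensor(rng.normal(size=(9, 8)))
        for a in attention_weights(xq, xs, layer):
            assert np.allclose(a.sum(axis=1), 1.0, atol=1e-9)


class TestGNNForward:
    def test_zero_mlps_reduce_to_linear_projection(self, rng):
        net, _ = make_net(layers=4)
        sc = encode_nodes(rng.normal(size=(3, 6)), np.zeros((3, 2)), net, "sc")
        st = encode_nodes(rng.normal(size=(5, 6)), rng.normal(size=(5, 2)),
                          net, "st")
        fA, fB = gnn_forward(sc, st, net)  # residual MLPs zero-initialized
        assert np.allclose(fA.data, sc.x.data @ net.W_out.data + net.b_out.data)
        assert np.allclose(fB.data, st.x.data @ net.W_out.data + net.b_out.data)

    def test_permutation_equivariance(self, rng):
        net, _ = make_net(layers=2)
        for layer in net.layers:  # make MLPs active
            layer.Wm2.data = rng.normal(size=layer.Wm2.shape) * 0.1
        sc_e = rng.normal(size=(4, 6))
        st_e = rng.normal(size=(5, 6))
        st_p = rng.normal(size=(5, 2))
        perm = rng.permutation(5)
        f1 = gnn_forward(encode_nodes(sc_e, np.zeros((4, 2)), net, "sc"),
                         encode_nodes(st_e, st_p, net, "st"), net)[1]
        f2 = gnn_forward(encode_nodes(sc_e, np.zeros((4, 2)), net, "sc"),
                         encode_nodes(st_e[perm], st_p[perm], net, "st"),
                         net)[1]
        assert np.allclose(f1.data[perm], f2.data, atol=1e-10)

    def test_two_layer_hand_oracle(self, rng):
        """L=2, 2 cells x 2 spots, D=4: replicate the forward pass step by
        step with plain numpy."""
        net, _ = make_net(n_genes=3, dim=4, heads=1, layers=2, seed=5)
        for layer in net.layers:
            layer.Wm2.data = rng.normal(size=layer.Wm2.shape) * 0.2
        sc_e, st_e = rng.normal(size=(2, 3)), rng.normal(size=(2, 3))
        st_p = rng.normal(size=(2, 2))
        sc0 = encode_nodes(sc_e, np.zeros((2, 2)), net, "sc")
        st0 = encode_nodes(st_e, st_p, net, "st")
        fA, fB = gnn_forward(sc0, st0, net)

        def attn(xq, xs, layer):
            q = xq @ layer.W1[0].data + layer.b1[0].data
            k = xs @ layer.W2[0].data + layer.b2[0].data
            v = xs @ layer.W3[0].data + layer.b3[0].data
            logits = q @ k.T / 2.0  # sqrt(d_h) = 2
            w = np.exp(logits - logits.max(axis=1, keepdims=True))
            w /= w.sum(axis=1, keepdims=True)
            return w @ v

        def upd(x, m, layer):
            h = np.maximum(np.concatenate([x, m], axis=1)
                           @ layer.Wm1.data + layer.bm1.data, 0)
            return x + h @ layer.Wm2.data + layer.bm2.data

        xa, xb = sc0.x.data, st0.x.data
        l1, l2 = net.layers
        xa, xb = upd(xa, attn(xa, xa, l1), l1), upd(xb, attn(xb, xb, l1), l1)
        xa2 = upd(xa, attn(xa, xb, l2), l2)
        xb2 = upd(xb, attn(xb, xa, l2), l2)
        assert np.allclose(fA.data, xa2 @ net.W_out.data + net.b_out.data,
                           atol=1e-10)
        assert np.allclose(fB.data, xb2 @ net.W_out.data + net.b_out.data,
                           atol=1e-10)


class TestSimilarityAndLoss:
    def test_perfect_reconstruction_loss(self):
        # each cell maps fully onto the spot holding its exact duplicate
        n, g = 4, 3
        rng = np.random.default_rng(1)
        A = rng.uniform(1, 5, size=(n, g))
        big = 50.0
        fA = Tensor(np.eye(n) * big)
        fB = Tensor(np.eye(n))
        M, loss, info = similarity_and_loss(fA, fB, A, A)
        assert np.allclose(loss.item(), -(g + n), atol=1e-6)
        assert info["n_skipped_terms"] == 0

    def test_orthogonal_descriptors_give_zero_matrix(self):
        fA = Tensor(np.array([[1.0, 0.0]]))
        fB = Tensor(np.array([[0.0, 1.0], [0.0, 2.0]]))
        A = np.ones((1, 2))
        B = np.ones((2, 2))
        M, _, _ = similarity_and_loss(fA, fB, A, B)
        assert np.allclose(M.data, 0.0)

    def test_matches_cosine_sum_oracle(self, rng):
        fA = Tensor(rng.normal(size=(5, 4)))
        fB = Tensor(rng.normal(size=(3, 4)))
        A = rng.uniform(0.5, 2, size=(5, 6))
        B = rng.uniform(0.5, 2, size=(3, 6))
        _, loss, _ = similarity_and_loss(fA, fB, A, B)
        M = fA.data @ fB.data.T
        P = np.exp(M - M.max(axis=1, keepdims=True))
        P /= P.sum(axis=1, keepdims=True)
        pred = P.T @ A

        def cos(a, b):
            return a @ b / (np.linalg.norm(a) * np.linalg.norm(b))

        score = sum(cos(pred[:, k], B[:, k]) for k in range(6)) + \
            sum(cos(pred[j], B[j]) for j in range(3))
        assert np.allclose(-loss.item(), score, atol=1e-6)


class TestFitMapping:
    def make_self_pair(self, rng, n_cells=30, n_genes=20):
        counts = rng.poisson(
            rng.lognormal(1.0, 1.0, size=(n_genes, 1))
            * rng.lognormal(0, 0.8, size=(n_genes, n_cells)))
        sc = ExpressionMatrix(counts.astype(float),
                              [f"g{i}" for i in range(n_genes)],
                              [f"c{i}" for i in range(n_cells)])
        scn = normalize_counts(sc)
        stn = ExpressionMatrix(scn.values.copy(), scn.gene_names,
                               [f"s{i}" for i in range(n_cells)],
                               "normalized")
        st = SpatialDataset(stn, rng.uniform(0, 1000, size=(n_cells, 2)),
                            Resolution.single_cell)
        return scn, st

    def test_self_mapping_recovery(self, rng):
        scn, st = self.make_self_pair(rng)
        cfg = TrainConfig(n_layers=2, dim=16, heads=2, epochs=80,
                          learning_rate=5e-3, seed=0)
        mapping = fit_mapping(scn, st, scn.gene_names, cfg)
        P = mapping.softmax_rows()
        acc = (P.argmax(axis=1) == np.arange(len(scn.unit_names))).mean()
        assert acc > 0.9
        assert P[np.arange(P.shape[0]), P.argmax(axis=1)].mean() > 0.5

    def test_same_seed_identical_trajectory(self, rng):
        scn, st = self.make_self_pair(rng, n_cells=12, n_genes=10)
        cfg = TrainConfig(n_layers=2, dim=8, heads=2, epochs=10, seed=3)
        m1 = fit_mapping(scn, st, scn.gene_names, cfg)
        m2 = fit_mapping(scn, st, scn.gene_names, cfg)
        assert m1.loss_history == m2.loss_history  # bitwise identical
        assert np.array_equal(m1.M, m2.M)

    def test_loss_trend_non_increasing(self, rng):
        scn, st = self.make_self_pair(rng, n_cells=15, n_genes=12)
        cfg = TrainConfig(n_layers=2, dim=8, heads=2, epochs=60, seed=1)
        m = fit_mapping(scn, st, scn.gene_names, cfg)
        head = np.mean(m.loss_history[:10])
        tail = np.mean(m.loss_history[-10:])
        assert tail < head

    def test_too_few_genes_rejected(self, rng):
        scn, st = self.make_self_pair(rng, n_cells=5, n_genes=4)
        with pytest.raises(ValueError):
            fit_mapping(scn, st, ["g0"], TrainConfig(epochs=1))


class TestCellTypeProbabilityMap:
    def test_single_type_gives_probability_one(self):
        m = MappingMatrix(np.random.default_rng(0).normal(size=(3, 4)),
                          ["c0", "c1", "c2"], ["s0", "s1", "s2", "s3"])
        ann = CellTypeAnnotation({f"c{i}": "A" for i in range(3)})
        p = celltype_probability_map(m, ann)
        assert np.allclose(p.to_numpy(), 1.0)

    def test_uniform_mapping_gives_global_frequencies(self):
        m = MappingMatrix(np.zeros((4, 3)), [f"c{i}" for i in range(4)],
                          [f"s{j}" for j in range(3)])
        ann = CellTypeAnnotation({"c0": "A", "c1": "A", "c2": "A", "c3": "B"},
                                 type_order=["A", "B"])
        p = celltype_probability_map(m, ann)
        assert np.allclose(p["A"], 0.75)
        assert np.allclose(p["B"], 0.25)

    def test_missing_annotation_errors(self):
        m = MappingMatrix(np.zeros((2, 2)), ["c0", "c1"], ["s0", "s1"])
        ann = CellTypeAnnotation({"c0": "A"})
        with pytest.raises(KeyError):
            celltype_probability_map(m, ann)
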