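import numpy as np
import pandas as pd
import pytest

from stcomm.ccc_scoring import (build_cell_graph, ccc_scores,
                                count_lr_pairs, embed_ccc_events,
                                permutation_pvalue, rwr_scores,
                                tf_activity_filter)
from stcomm.data_model import (CellTypeAnnotation, ExpressionMatrix,
                               LRDatabase, ReceptorTFNetwork, Resolution,
                               SpatialDataset)


def make_map(coords, expr_vals, genes, labels=None):
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    cells = [f"c{i}" for i in range(n)]
    expr = ExpressionMatrix(np.asarray(expr_vals, float), genes, cells,
                            "normalized")
    ds = SpatialDataset(expr, coords, Resolution.single_cell)
    ann = None
    if labels is not None:
        ann = CellTypeAnnotation(dict(zip(cells, labels)))
    return ds, ann


class TestBuildCellGraph:
    def test_two_cells_within_cutoff(self):
        ds, _ = make_map([[0, 0], [150, 0]], [[1, 1]], ["g"])
        g = build_cell_graph(ds, k=3, cutoff_um=200)
        assert g.adjacency.sum() == 2  # one undirected edge, both directions

    def test_two_cells_beyond_cutoff(self):
        ds, _ = make_map([[0, 0], [250, 0]], [[1, 1]], ["g"])
        g = build_cell_graph(ds, k=3, cutoff_um=200)
        assert g.adjacency.sum() == 0

    def test_matches_brute_force_oracle(self, rng):
        coords = rng.uniform(0, 500, size=(20, 2))
        ds, _ = make_map(coords, rng.uniform(1, 2, size=(3, 20)),
                         ["g0", "g1", "g2"])
        k, cutoff = 4, 200.0
        g = build_cell_graph(ds, k=k, cutoff_um=cutoff)
        expected = np.zeros((20, 20), dtype=bool)
        for i in range(20):
            d = np.linalg.norm(coords - coords[i], axis=1)
            order = [j for j in np.argsort(d, kind="stable")
                     if j != i and d[j] <= cutoff][:k]
            expected[i, order] = True
        expected |= expected.T
        assert np.array_equal(g.adjacency, expected)

    def test_single_cell_rejected(self):
        ds, _ = make_map([[0, 0]], [[1]], ["g"])
        with pytest.raises(ValueError):
            build_cell_graph(ds)

    def test_every_edge_within_cutoff(self, rng):
        coords = rng.uniform(0, 600, size=(30, 2))
        ds, _ = make_map(coords, rng.uniform(1, 2, size=(2, 30)),
                         ["g0", "g1"])
        g = build_cell_graph(ds, k=5, cutoff_um=150)
        si, ri = g.edge_index
        assert (g.distances[si, ri] <= 150).all()


class TestRWR:
    def chain_network(self):
        edges = [("R", "M", 1.0), ("M", "TF1", 1.0), ("M", "TF2", 0.5)]
        return ReceptorTFNetwork(edges, {"TF1", "TF2"})

    def test_closed_form_solution(self):
        # 5-node toy: compare against iterative fixed-point evaluation
        edges = [("R", "a", 1.0), ("a", "b", 2.0), ("a", "c", 1.0),
                 ("b", "d", 1.0), ("c", "d", 1.0)]
        net = ReceptorTFNetwork(edges, {"d"})
        r = 0.5
        scores = rwr_scores(net, "R", r)
        nodes = net.nodes
        idx = {n: i for i, n in enumerate(nodes)}
        W = np.zeros((5, 5))
        for s, d, w in edges:
            W[idx[s], idx[d]] += w
        W = W / np.maximum(W.sum(axis=1, keepdims=True), 1e-300)
        e = np.zeros(5)
        e[idx["R"]] = 1.0
        s_vec = e.copy()
        for _ in range(10_000):
            s_vec = r * e + (1 - r) * W.T @ s_vec
        for n in nodes:
            assert np.isclose(scores[n], s_vec[idx[n]], atol=1e-8)

    def test_missing_seed_rejected(self):
        with pytest.raises(KeyError):
            rwr_scores(self.chain_network(), "nope")


class TestTFActivityFilter:
    def test_chain_receptor_tf_eligible(self):
        ds, _ = make_map([[0, 0], [10, 0]],
                         [[2, 0], [3, 0]], ["R", "TF1"])
        net = ReceptorTFNetwork([("R", "TF1", 1.0)], {"TF1"})
        eligible = tf_activity_filter(ds.expr, net, "R")
        assert eligible == {"c0"}

    def test_receptor_without_tf_ineligible(self):
        ds, _ = make_map([[0, 0], [10, 0]],
                         [[2, 2], [3, 0]], ["R", "TF1"])
        net = ReceptorTFNetwork([("R", "TF1", 1.0)], {"TF1"})
        # c1 expresses R but not TF1 -> ineligible
        assert tf_activity_filter(ds.expr, net, "R") == {"c0"}

    def test_receptor_absent_from_network_warns(self):
        ds, _ = make_map([[0, 0], [10, 0]], [[2, 0]], ["R2"])
        net = ReceptorTFNetwork([("R", "TF1", 1.0)], {"TF1"})
        with pytest.warns(RuntimeWarning):
            eligible = tf_activity_filter(ds.expr, net, "R2")
        assert eligible == {"c0"}


class FullyConnectedToy:
    """2 A-cells + 2 B-cells, all within cutoff, everyone expressing."""

    def build(self, lig_vals=(4, 4, 0, 0), rec_vals=(0, 0, 9, 9)):
        coords = [[0, 0], [10, 0], [0, 10], [10, 10]]
        expr = np.array([lig_vals, rec_vals], dtype=float)
        ds, ann = make_map(coords, expr, ["L", "R"], ["A", "A", "B", "B"])
        graph = build_cell_graph(ds, k=3, cutoff_um=200)
        return ds, ann, graph


class TestCountLRPairs(FullyConnectedToy):
    def test_no_edges_gives_zero(self):
        ds, ann, _ = self.build()
        far, _ = make_map([[0, 0], [500, 0]], [[1, 1], [1, 1]], ["L", "R"])
        g = build_cell_graph(far, cutoff_um=200)
        assert count_lr_pairs(g, far.expr, "L", "R", "A", "B",
                              labels=np.array(["A", "B"], object)) == 0

    def test_fully_connected_enumeration(self):
        ds, ann, graph = self.build()
        c = count_lr_pairs(graph, ds.expr, "L", "R", "A", "B",
                           annotation=ann)
        assert c == 4  # 2 senders x 2 receivers, all adjacent

    def test_same_type_excludes_self_pairs(self, rng):
        coords = rng.uniform(0, 50, size=(6, 2))
        expr = rng.uniform(1, 2, size=(2, 6))
        ds, ann = make_map(coords, expr, ["L", "R"], ["A"] * 6)
        graph = build_cell_graph(ds, k=5, cutoff_um=200)
        c = count_lr_pairs(graph, ds.expr, "L", "R", "A", "A",
                           annotation=ann)
        si, ri = graph.edge_index
        expected = sum(1 for i, j in zip(si, ri)
                       if expr[0, i] > 0 and expr[1, j] > 0)
        assert c == expected
        assert not any(i == j for i, j in zip(si, ri))

    def test_monotone_in_coexpression(self):
        ds, ann, graph = self.build(lig_vals=(4, 0, 0, 0))
        c1 = count_lr_pairs(graph, ds.expr, "L", "R", "A", "B",
                            annotation=ann)
        ds2, _, graph2 = self.build(lig_vals=(4, 4, 0, 0))
        c2 = count_lr_pairs(graph2, ds2.expr, "L", "R", "A", "B",
                            annotation=ann)
        assert c2 >= c1


class TestPermutationPvalue(FullyConnectedToy):
    def test_observed_above_all_gives_zero(self):
        # L only in A cells, R only in B cells, A/B separated spatially
        coords = [[0, 0], [10, 0], [0, 10], [10, 10]]
        expr = np.array([[5, 5, 0, 0], [0, 0, 7, 7]], dtype=float)
        ds, ann = make_map(coords, expr, ["L", "R"], ["A", "A", "B", "B"])
        graph = build_cell_graph(ds, k=3, cutoff_um=200)
        null = permutation_pvalue(graph, ds.expr, "L", "R", "A", "B", ann,
                                  z=200, seed=0)
        assert null.observed == 4
        # fully connected graph: permutations cannot beat the maximum
        assert (null.background <= 4).all()

    def test_tie_everywhere_gives_one(self):
        ds, ann, graph = self.build(lig_vals=(1, 1, 1, 1),
                                    rec_vals=(1, 1, 1, 1))
        null = permutation_pvalue(graph, ds.expr, "L", "R", "A", "B", ann,
                                  z=50, seed=1)
        # every cell expresses both: any labeling gives the same count
        assert null.p_value == 1.0

    def test_zero_permutations_rejected(self):
        ds, ann, graph = self.build()
        with pytest.raises(ValueError):
            permutation_pvalue(graph, ds.expr, "L", "R", "A", "B", ann, z=0)

    def test_plus_one_correction(self):
        ds, ann, graph = self.build(lig_vals=(1, 1, 1, 1),
                                    rec_vals=(1, 1, 1, 1))
        null = permutation_pvalue(graph, ds.expr, "L", "R", "A", "B", ann,
                                  z=50, seed=1, plus_one_correction=True)
        assert null.p_value == (50 + 1) / (50 + 1)

    def test_seeded_determinism(self):
        ds, ann, graph = self.build()
        n1 = permutation_pvalue(graph, ds.expr, "L", "R", "A", "B", ann,
                                z=100, seed=4)
        n2 = permutation_pvalue(graph, ds.expr, "L", "R", "A", "B", ann,
                                z=100, seed=4)
        assert np.array_equal(n1.background, n2.background)


class TestCCCScores(FullyConnectedToy):
    def test_score_is_geometric_mean(self):
        ds, ann, graph = self.build(lig_vals=(4, 4, 0, 0),
                                    rec_vals=(0, 0, 9, 9))
        db = LRDatabase([("L", "R")])
        table = ccc_scores(graph, ds.expr, db, ann, alpha=1.1, z=20, seed=0)
        ab = table[(table.sender_type == "A") & (table.receiver_type == "B")]
        assert len(ab) == 4
        assert np.allclose(ab["score"], 6.0)  # sqrt(4 * 9)

    def test_score_squared_equals_product(self, rng):
        lig = rng.uniform(0.5, 5, 4)
        rec = rng.uniform(0.5, 5, 4)
        ds, ann, graph = self.build(lig_vals=tuple(lig), rec_vals=tuple(rec))
        db = LRDatabase([("L", "R")])
        table = ccc_scores(graph, ds.expr, db, ann, alpha=1.1, z=20, seed=0)
        lut_l = dict(zip(ds.expr.unit_names, lig))
        lut_r = dict(zip(ds.expr.unit_names, rec))
        for _, row in table.iterrows():
            assert np.isclose(row.score ** 2,
                              lut_l[row.sender] * lut_r[row.receiver])

    def test_zero_ligand_pair_not_emitted(self):
        ds, ann, graph = self.build(lig_vals=(0, 0, 0, 0))
        db = LRDatabase([("L", "R")])
        table = ccc_scores(graph, ds.expr, db, ann, alpha=1.1, z=20, seed=0)
        assert len(table) == 0

    def test_emitted_pairs_are_graph_edges(self):
        ds, ann, graph = self.build()
        db = LRDatabase([("L", "R")])
        table = ccc_scores(graph, ds.expr, db, ann, alpha=1.1, z=20, seed=0)
        idx = {c: i for i, c in enumerate(graph.cell_names)}
        for _, row in table.iterrows():
            assert graph.adjacency[idx[row.sender], idx[row.receiver]]

    def test_empty_database_rejected(self):
        ds, ann, graph = self.build()
        with pytest.raises(ValueError):
            ccc_scores(graph, ds.expr, LRDatabase([]), ann)


class TestEmbedEvents:
    def make_table(self, rng, n_events=12, block=True):
        rows = []
        for i in range(n_events):
            grp = i % 2
            lr = (f"L{grp}", f"R{grp}") if block else ("L0", "R0")
            rows.append([f"s{i}", f"r{i}", "A", "B", lr[0], lr[1],
                         float(rng.uniform(1, 5)), 0.01])
        return pd.DataFrame(rows, columns=["sender", "receiver",
                                           "sender_type", "receiver_type",
                                           "ligand", "receptor", "score",
                                           "pvalue"])

    def test_too_few_events_rejected(self, rng):
        with pytest.raises(ValueError):
            embed_ccc_events(self.make_table(rng).head(2))

    def test_seeded_determinism(self, rng):
        tab = self.make_table(rng)
        e1 = embed_ccc_events(tab, seed=0)
        e2 = embed_ccc_events(tab, seed=0)
        assert np.array_equal(e1[["x", "y"]].to_numpy(),
                              e2[["x", "y"]].to_numpy())

    def test_block_structure_separates(self, rng):
        tab = self.make_table(rng, n_events=20, block=True)
        emb = embed_ccc_events(tab, seed=0)
        grp = np.array([int(e[1:]) % 2 for e in
                        emb["event"].str.split("->").str[0]])
        xy = emb[["x", "y"]].to_numpy()
        from sklearn.metrics import silhouette_score
        assert silhouette_score(xy, grp) > 0
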