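"""Spatially constrained ligand-receptor communication scoring.

Builds a KNN cell graph under a 200 µm cutoff, restricts receiver cells to
those with random-walk-activated downstream TFs, counts 1-hop
ligand-receptor co-expressing sender→receiver pairs, and assigns
permutation-test p-values by re-drawing cell-type labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

from .data_model import (CellTypeAnnotation, ExpressionMatrix, LRDatabase,
                         ReceptorTFNetwork, Resolution, SpatialDataset)

__all__ = [
    "CellGraph",
    "PermutationNull",
    "build_cell_graph",
    "rwr_scores",
    "tf_activity_filter",
    "count_lr_pairs",
    "permutation_pvalue",
    "ccc_scores",
    "embed_ccc_events",
]

DEFAULT_CUTOFF_UM = 200.0
DEFAULT_K = 6
DEFAULT_Z = 1000
DEFAULT_RESTART = 0.5
DEFAULT_TF_PERCENTILE = 90.0


@dataclass
class CellGraph:
    """Symmetric KNN-with-cutoff adjacency over single cells."""

    cell_names: list[str]
    distances: np.ndarray
    adjacency: np.ndarray   # boolean, symmetric, zero diagonal
    k: int
    cutoff_um: float

    def __post_init__(self):
        n = len(self.cell_names)
        if self.distances.shape != (n, n) or self.adjacency.shape != (n, n):
            raise ValueError("graph matrix shape mismatch")
        if not np.allclose(self.distances, self.distances.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.adjacency)):
            raise ValueError("adjacency has self-loops")

    @property
    def edge_index(self) -> tuple[np.ndarray, np.ndarray]:
        """Ordered (sender, receiver) index arrays, both directions."""
        return np.nonzero(self.adjacency)


@dataclass
class PermutationNull:
    observed: int
    background: np.ndarray
    p_value: float

    def __post_init__(self):
        if len(self.background) < 1:
            raise ValueError("background needs Z >= 1 permutations")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value out of [0, 1]")


def build_cell_graph(single_cell_map: SpatialDataset, k: int = DEFAULT_K,
                     cutoff_um: float = DEFAULT_CUTOFF_UM) -> CellGraph:
    """Per cell, connect its K nearest neighbors within the distance
    cutoff (fewer if not enough qualify); edges are symmetrized by union."""
    if single_cell_map.resolution is not Resolution.single_cell:
        raise ValueError("cell graph requires single-cell resolution")
    n = single_cell_map.expr.n_units
    if n < 2:
        raise ValueError("cell graph needs at least 2 cells")
    D = squareform(pdist(single_cell_map.coords))
    adj = np.zeros((n, n), dtype=bool)
    for i in range(n):
        order = np.argsort(D[i], kind="stable")
        picked = 0
        for j in order:
            if j == i:
                continue
            if D[i, j] > cutoff_um:
                break
            adj[i, j] = True
            picked += 1
            if picked == k:
                break
    adj |= adj.T
    return CellGraph(list(single_cell_map.unit_names), D, adj, k, cutoff_um)


def rwr_scores(network: ReceptorTFNetwork, seed_gene: str,
               restart_prob: float = DEFAULT_RESTART) -> dict[str, float]:
    """Random walk with restart from `seed_gene`: solves
    s = r (I - (1-r) Wᵀ)⁻¹ e with W the row-normalized weighted adjacency."""
    nodes = network.nodes
    if seed_gene not in nodes:
        raise KeyError(f"seed gene {seed_gene!r} not in network")
    idx = {n: i for i, n in enumerate(nodes)}
    W = np.zeros((len(nodes), len(nodes)))
    for s, d, w in network.edges:
        W[idx[s], idx[d]] += w
    row = W.sum(axis=1, keepdims=True)
    W = np.divide(W, row, out=np.zeros_like(W), where=row > 0)
    e = np.zeros(len(nodes))
    e[idx[seed_gene]] = 1.0
    r = restart_prob
    s = r * np.linalg.solve(np.eye(len(nodes)) - (1 - r) * W.T, e)
    return dict(zip(nodes, s))


def tf_activity_filter(expression: ExpressionMatrix,
                       network: ReceptorTFNetwork, receptor: str,
                       restart_prob: float = DEFAULT_RESTART,
                       score_percentile: float = DEFAULT_TF_PERCENTILE,
                       ) -> set[str]:
    """Eligible receiver cells for a receptor.

    A cell qualifies iff it expresses the receptor (> 0) and at least one
    downstream-activated TF — a TF whose random-walk-with-restart score
    from the receptor exceeds the given percentile over TF nodes. A
    receptor absent from the network admits all receptor-expressing cells
    (with a warning).
    """
    gene_lut = {g: i for i, g in enumerate(expression.gene_names)}
    if receptor not in gene_lut:
        return set()
    expressed = expression.values[gene_lut[receptor]] > 0
    sources = {s for s, _, _ in network.edges}
    if receptor not in sources:
        warnings.warn(f"receptor {receptor!r} absent from network; all "
                      "receptor-expressing cells kept", RuntimeWarning,
                      stacklevel=2)
        return {u for u, ok in zip(expression.unit_names, expressed) if ok}
    scores = rwr_scores(network, receptor, restart_prob)
    tf_scores = {n: s for n, s in scores.items() if n in network.tf_nodes}
    if not tf_scores:
        warnings.warn("network has no TF nodes; all receptor-expressing "
                      "cells kept", RuntimeWarning, stacklevel=2)
        return {u for u, ok in zip(expression.unit_names, expressed) if ok}
    thr = np.percentile(list(tf_scores.values()), score_percentile)
    active_tfs = [n for n, s in tf_scores.items() if s > thr]
    if not active_tfs:  # degenerate all-equal scores
        active_tfs = [n for n, s in tf_scores.items() if s >= thr]
    tf_rows = [gene_lut[t] for t in active_tfs if t in gene_lut]
    if not tf_rows:
        return set()
    tf_on = (expression.values[tf_rows] > 0).any(axis=0)
    keep = expressed & tf_on
    return {u for u, ok in zip(expression.unit_names, keep) if ok}


def _pair_count(si: np.ndarray, ri: np.ndarray, labels: np.ndarray,
                sender_type: str, receiver_type: str,
                sender_ok: np.ndarray, receiver_ok: np.ndarray) -> int:
    """Ordered adjacent (sender, receiver) pairs passing all masks."""
    m = ((labels[si] == sender_type) & sender_ok[si]
         & (labels[ri] == receiver_type) & receiver_ok[ri])
    return int(m.sum())


def count_lr_pairs(graph: CellGraph, expression: ExpressionMatrix,
                   ligand: str, receptor: str, sender_type: str,
                   receiver_type: str,
                   eligible_receivers: set[str] | None = None,
                   annotation: CellTypeAnnotation | None = None,
                   labels: np.ndarray | None = None) -> int:
    """Observed count C0 of ordered 1-hop (sender, receiver) pairs where the
    sender (type A) expresses the ligand and the receiver (type B) is an
    eligible receptor cell. Sender == receiver index pairs never occur
    because the graph has no self-loops."""
    if labels is None:
        if annotation is None:
            raise ValueError("provide labels or an annotation")
        labels = annotation.labels_for(graph.cell_names)
    gene_lut = {g: i for i, g in enumerate(expression.gene_names)}
    n = len(graph.cell_names)
    lig_on = (expression.values[gene_lut[ligand]] > 0
              if ligand in gene_lut else np.zeros(n, dtype=bool))
    if eligible_receivers is None:
        rec_on = (expression.values[gene_lut[receptor]] > 0
                  if receptor in gene_lut else np.zeros(n, dtype=bool))
    else:
        rec_on = np.array([u in eligible_receivers
                           for u in graph.cell_names])
    si, ri = graph.edge_index
    return _pair_count(si, ri, np.asarray(labels, dtype=object),
                       sender_type, receiver_type, lig_on, rec_on)


def permutation_pvalue(graph: CellGraph, expression: ExpressionMatrix,
                       ligand: str, receptor: str, sender_type: str,
                       receiver_type: str, annotation: CellTypeAnnotation,
                       eligible_receivers: set[str] | None = None,
                       z: int = DEFAULT_Z, seed: int = 0,
                       plus_one_correction: bool = False) -> PermutationNull:
    """Permutation test on the pair count: cell-type labels are re-drawn
    (permuted over cells) Z times and p = |{x in C : x >= C0}| / Z.

    `plus_one_correction=True` switches to (card+1)/(Z+1).
    """
    if z < 1:
        raise ValueError("Z must be >= 1")
    labels = annotation.labels_for(graph.cell_names)
    gene_lut = {g: i for i, g in enumerate(expression.gene_names)}
    n = len(graph.cell_names)
    lig_on = (expression.values[gene_lut[ligand]] > 0
              if ligand in gene_lut else np.zeros(n, dtype=bool))
    if eligible_receivers is None:
        rec_on = (expression.values[gene_lut[receptor]] > 0
                  if receptor in gene_lut else np.zeros(n, dtype=bool))
    else:
        rec_on = np.array([u in eligible_receivers for u in graph.cell_names])
    si, ri = graph.edge_index
    c0 = _pair_count(si, ri, labels, sender_type, receiver_type,
                     lig_on, rec_on)
    rng = np.random.default_rng(seed)
    background = np.empty(z, dtype=int)
    for t in range(z):
        perm = rng.permutation(n)
        background[t] = _pair_count(si, ri, labels[perm], sender_type,
                                    receiver_type, lig_on, rec_on)
    card = int((background >= c0).sum())
    p = (card + 1) / (z + 1) if plus_one_correction else card / z
    return PermutationNull(c0, background, float(p))


def ccc_scores(graph: CellGraph, expression: ExpressionMatrix,
               lr_db: LRDatabase, annotation: CellTypeAnnotation,
               network: ReceptorTFNetwork | None = None,
               alpha: float = 0.05, z: int = DEFAULT_Z, seed: int = 0,
               restart_prob: float = DEFAULT_RESTART,
               tf_percentile: float = DEFAULT_TF_PERCENTILE,
               bh_correction: bool = False) -> pd.DataFrame:
    """Per-cell-pair communication scores for significant L-R/type combos.

    For every (sender type A, receiver type B, ligand L, receptor R) with
    permutation p-value below `alpha`, each adjacent eligible (i, j) pair
    with L_i > 0 yields score sqrt(L_i * R_j). Columns: sender, receiver,
    sender_type, receiver_type, ligand, receptor, score, pvalue.
    """
    if len(lr_db) == 0:
        raise ValueError("empty L-R database")
    labels = annotation.labels_for(graph.cell_names)
    types = [t for t in annotation.type_order
             if (labels == t).any()]
    gene_lut = {g: i for i, g in enumerate(expression.gene_names)}
    si, ri = graph.edge_index

    combos = []
    pvals = []
    for li, (lig, rec) in enumerate(lr_db):
        if lig not in gene_lut or rec not in gene_lut:
            continue
        if network is not None:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                eligible = tf_activity_filter(expression, network, rec,
                                              restart_prob, tf_percentile)
        else:
            eligible = {u for u, ok in zip(
                graph.cell_names,
                expression.values[gene_lut[rec]] > 0) if ok}
        for ia, ta in enumerate(types):
            for ib, tb in enumerate(types):
                null = permutation_pvalue(
                    graph, expression, lig, rec, ta, tb, annotation,
                    eligible_receivers=eligible, z=z,
                    seed=seed + 7919 * li + 101 * ia + ib)
                if null.observed == 0:
                    continue
                combos.append((lig, rec, ta, tb, eligible, null))
                pvals.append(null.p_value)

    if bh_correction and pvals:
        from statsmodels.stats.multitest import multipletests
        adj = multipletests(pvals, method="fdr_bh")[1]
    else:
        adj = pvals

    rows = []
    lig_cache: dict[str, np.ndarray] = {}
    for (lig, rec, ta, tb, eligible, null), p in zip(combos, adj):
        if p >= alpha:
            continue
        lig_on = lig_cache.setdefault(
            lig, expression.values[gene_lut[lig]])
        rec_vals = expression.values[gene_lut[rec]]
        elig_mask = np.array([u in eligible for u in graph.cell_names])
        m = ((labels[si] == ta) & (lig_on[si] > 0)
             & (labels[ri] == tb) & elig_mask[ri])
        for a, b in zip(si[m], ri[m]):
            score = float(np.sqrt(lig_on[a] * rec_vals[b]))
            rows.append([graph.cell_names[a], graph.cell_names[b], ta, tb,
                         lig, rec, score, float(p)])
    return pd.DataFrame(rows, columns=["sender", "receiver", "sender_type",
                                       "receiver_type", "ligand", "receptor",
                                       "score", "pvalue"])


def embed_ccc_events(score_table: pd.DataFrame, seed: int = 0,
                     ) -> pd.DataFrame:
    """2-D embedding of communication events.

    Events (receiver-cell × L-R usage rows) are pivoted into an events ×
    L-R-pair score matrix, scaled, reduced by PCA, connected by a
    neighborhood graph and embedded with UMAP. Returns (event, x, y).
    """
    if len(score_table) < 3:
        raise ValueError("need at least 3 events to embed")
    import anndata
    import scanpy as sc

    tab = score_table.copy()
    tab["event"] = tab["sender"].astype(str) + "->" + tab["receiver"].astype(str)
    tab["lr"] = tab["ligand"].astype(str) + "_" + tab["receptor"].astype(str)
    mat = tab.pivot_table(index="event", columns="lr", values="score",
                          aggfunc="sum", fill_value=0.0)
    if mat.shape[0] < 3:
        raise ValueError("need at least 3 distinct events to embed")
    ad = anndata.AnnData(mat.to_numpy(dtype=np.float64))
    ad.obs_names = list(mat.index)
    sc.pp.scale(ad)
    n_comps = int(min(30, ad.n_obs - 1, ad.n_vars - 1))
    if n_comps >= 1:
        sc.tl.pca(ad, n_comps=n_comps, random_state=seed)
        rep = "X_pca"
    else:
        rep = "X"
    sc.pp.neighbors(ad, n_neighbors=min(15, ad.n_obs - 1),
                    random_state=seed, use_rep=rep)
    sc.tl.umap(ad, random_state=seed)
    xy = ad.obsm["X_umap"]
    return pd.DataFrame({"event": list(mat.index),
                         "x": xy[:, 0], "y": xy[:, 1]})
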