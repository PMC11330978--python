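"""Subgraph-based attention network: random-walk context subgraphs,
masked-node pretraining and contextual link-prediction fine-tuning.

Node embeddings live column-wise (d × |V_c|). Each translation layer
computes a row-stochastic semantic association matrix from multi-head
attention logits and applies the printed residual update
H' = f_NN(W_s H A + H); per-node contextual embeddings concatenate the K
layer outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Hashable, Sequence

import networkx as nx
import numpy as np

from .autodiff import Adam, Parameter, Tensor, concat

__all__ = [
    "CCCNetConfig",
    "ContextSubgraph",
    "SubgraphGAT",
    "LinkScorer",
    "spectral_structural_embedding",
    "sample_subgraphs",
    "init_embeddings",
    "context_translate",
    "contextual_embedding",
    "pretrain_masked",
    "finetune_links",
]


@dataclass
class CCCNetConfig:
    dim: int = 64
    heads: int = 4
    n_translation_layers: int = 2   # K
    walk_length: int = 8
    n_walks: int = 5
    diameter_bound: int = 3
    struct_dim: int = 8
    f_nn: str = "relu"              # "relu" | "identity"
    pretrain_epochs: int = 30
    finetune_epochs: int = 30
    learning_rate: float = 1e-2
    negative_ratio: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.dim % self.heads != 0:
            raise ValueError("dim must be divisible by heads")
        if self.f_nn not in ("relu", "identity"):
            raise ValueError("f_nn must be 'relu' or 'identity'")


@dataclass
class ContextSubgraph:
    """Ordered node list with induced adjacency and an anchor node/pair."""

    nodes: list[Hashable]
    adj: np.ndarray
    anchor: Hashable | tuple[Hashable, Hashable]
    label: object | None = None

    def __post_init__(self):
        if len(self.nodes) < 2:
            raise ValueError("context subgraph needs at least 2 nodes")
        self.adj = np.asarray(self.adj, dtype=float)
        if self.adj.shape != (len(self.nodes), len(self.nodes)):
            raise ValueError("adjacency shape mismatch")
        anchors = self.anchor if isinstance(self.anchor, tuple) \
            else (self.anchor,)
        for a in anchors:
            if a not in self.nodes:
                raise ValueError(f"anchor {a!r} not in subgraph")

    def index_of(self, node: Hashable) -> int:
        return self.nodes.index(node)


def spectral_structural_embedding(graph: nx.Graph, dim: int = 8,
                                  ) -> dict[Hashable, np.ndarray]:
    """Deterministic structural vectors: leading eigenvectors of the
    symmetric normalized adjacency (sign-fixed), truncated/padded to `dim`.

    Serves as the pluggable replacement for an external embedding trainer.
    """
    nodes = list(graph.nodes())
    A = nx.to_numpy_array(graph, nodelist=nodes, weight="weight")
    deg = A.sum(axis=1)
    dinv = np.where(deg > 0, 1.0 / np.sqrt(deg), 0.0)
    S = dinv[:, None] * A * dinv[None, :]
    vals, vecs = np.linalg.eigh(S)
    order = np.argsort(vals)[::-1]
    k = min(dim, len(nodes))
    V = vecs[:, order[:k]]
    for j in range(V.shape[1]):  # fix sign per eigenvector
        i = int(np.argmax(np.abs(V[:, j])))
        if V[i, j] < 0:
            V[:, j] = -V[:, j]
    if k < dim:
        V = np.pad(V, ((0, 0), (0, dim - k)))
    return {n: V[i] for i, n in enumerate(nodes)}


def sample_subgraphs(graph: nx.Graph, anchor: Hashable, walk_length: int = 8,
                     n_walks: int = 5,
                     rng: np.random.Generator | None = None,
                     diameter_bound: int | None = None,
                     second_anchor: Hashable | None = None,
                     ) -> ContextSubgraph:
    """Union of `n_walks` random walks of `walk_length` steps from the
    anchor (and, for pair contexts, from the second anchor), with the
    induced adjacency. Nodes beyond `diameter_bound` hops from an anchor
    are dropped."""
    rng = rng or np.random.default_rng()
    if anchor not in graph:
        raise KeyError(f"anchor {anchor!r} not in graph")
    if graph.degree(anchor) == 0:
        raise ValueError(f"anchor {anchor!r} is isolated")
    starts = [anchor] if second_anchor is None else [anchor, second_anchor]
    nodes: list[Hashable] = []
    seen: set[Hashable] = set()

    def visit(n):
        if n not in seen:
            seen.add(n)
            nodes.append(n)

    for s in starts:
        visit(s)
    for s in starts:
        for _ in range(n_walks):
            cur = s
            for _ in range(walk_length):
                nbrs = list(graph.neighbors(cur))
                if not nbrs:
                    break
                cur = nbrs[rng.integers(len(nbrs))]
                visit(cur)
    if diameter_bound is not None:
        keep = set(starts)
        for s in starts:
            lengths = nx.single_source_shortest_path_length(
                graph, s, cutoff=diameter_bound)
            keep |= set(lengths)
        nodes = [n for n in nodes if n in keep]
    if len(nodes) < 2:
        raise ValueError("subgraph has fewer than 2 nodes "
                         "(walk_length too small or isolated anchor)")
    sub = graph.subgraph(nodes)
    adj = nx.to_numpy_array(sub, nodelist=nodes, weight=None)
    anc = anchor if second_anchor is None else (anchor, second_anchor)
    return ContextSubgraph(nodes, adj, anc)


def init_embeddings(subgraph: ContextSubgraph,
                    node_attributes: dict[Hashable, np.ndarray],
                    structural_vectors: dict[Hashable, np.ndarray],
                    W_e: Parameter | Tensor,
                    mask_node: Hashable | None = None,
                    mask_token: Parameter | None = None) -> Tensor:
    """Layer-0 embeddings H (d × |V_c|): h_i = W_e [attr_i || struct_i].

    When `mask_node` is given its attribute block is replaced by the
    learned `mask_token`, leaving structure untouched.
    """
    cols = []
    for n in subgraph.nodes:
        if n not in node_attributes:
            raise KeyError(f"missing attributes for node {n!r}")
        if mask_node is not None and n == mask_node:
            if mask_token is None:
                raise ValueError("mask_node given without mask_token")
            attr = mask_token
        else:
            attr = Tensor(np.asarray(node_attributes[n], dtype=float))
        struct = Tensor(np.asarray(structural_vectors[n], dtype=float))
        cols.append(concat([attr, struct], axis=0).reshape(-1, 1))
    F = concat(cols, axis=1)
    return W_e @ F


@dataclass
class TranslationLayerParams:
    W_s: Parameter
    W1: list[Parameter]
    W2: list[Parameter]
    f_nn: str = "relu"

    def parameters(self) -> list[Parameter]:
        return [self.W_s] + self.W1 + self.W2


def context_translate(H: Tensor, params: TranslationLayerParams,
                      ) -> tuple[Tensor, np.ndarray]:
    """One translation layer: H' = f_NN(W_s H A + H) with A the head-mean
    of row-stochastic attention matrices A_ij = softmax_j((W1 h_i)ᵀ W2 h_j).
    """
    n = H.shape[1]
    if n < 2:
        raise ValueError("context subgraph must hold at least 2 nodes")
    heads = len(params.W1)
    Abar: Tensor | None = None
    for h in range(heads):
        logits = (params.W1[h] @ H).T @ (params.W2[h] @ H)
        if not np.isfinite(logits.data).all():
            raise FloatingPointError("non-finite attention logits")
        Ah = logits.softmax(axis=1)
        Abar = Ah if Abar is None else Abar + Ah
    Abar = Abar * (1.0 / heads)
    out = params.W_s @ H @ Abar + H
    if params.f_nn == "relu":
        out = out.relu()
    return out, Abar.data


def contextual_embedding(per_layer: Sequence[Tensor]) -> Tensor:
    """Concatenate the K layer outputs along the feature axis (K·d × n)."""
    return concat(list(per_layer), axis=0)


class SubgraphGAT:
    """Parameters for pretraining and fine-tuning over one node graph."""

    def __init__(self, attr_dim: int, vocab: list[Hashable],
                 config: CCCNetConfig, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(config.seed)
        self.config = config
        self.vocab = list(vocab)
        self.vocab_index = {v: i for i, v in enumerate(self.vocab)}
        if len(self.vocab) < 2:
            raise ValueError("node vocabulary must have at least 2 entries")
        d = config.dim
        in_dim = attr_dim + config.struct_dim
        self.W_e = Parameter(np.random.default_rng(config.seed).normal(
            0.0, 1.0 / np.sqrt(in_dim), size=(d, in_dim)))
        self.mask_token = Parameter(np.zeros(attr_dim))
        s = 1.0 / np.sqrt(d)
        self.layers = [
            TranslationLayerParams(
                W_s=Parameter(rng.normal(0.0, s, size=(d, d)) * 0.1),
                W1=[Parameter(rng.normal(0.0, s, size=(d, d)))
                    for _ in range(config.heads)],
                W2=[Parameter(rng.normal(0.0, s, size=(d, d)))
                    for _ in range(config.heads)],
                f_nn=config.f_nn)
            for _ in range(config.n_translation_layers)]
        # masked-node head: zero-initialized so the initial predictive
        # distribution is exactly uniform over the vocabulary
        self.W_p = Parameter(np.zeros((len(self.vocab), d * len(self.layers))))
        self.b_p = Parameter(np.zeros(len(self.vocab)))

    def parameters(self) -> list[Parameter]:
        ps = [self.W_e, self.mask_token, self.W_p, self.b_p]
        for layer in self.layers:
            ps += layer.parameters()
        return ps

    def forward(self, subgraph: ContextSubgraph,
                attrs: dict[Hashable, np.ndarray],
                structs: dict[Hashable, np.ndarray],
                mask_node: Hashable | None = None) -> Tensor:
        H = init_embeddings(subgraph, attrs, structs, self.W_e,
                            mask_node=mask_node,
                            mask_token=(self.mask_token
                                        if mask_node is not None else None))
        outs = []
        for layer in self.layers:
            H, _ = context_translate(H, layer)
            outs.append(H)
        return contextual_embedding(outs)  # (K·d) × n


def _node_loss(model: SubgraphGAT, subgraph: ContextSubgraph,
               attrs, structs, masked: Hashable) -> Tensor:
    Ht = model.forward(subgraph, attrs, structs, mask_node=masked)
    j = subgraph.index_of(masked)
    onehot = np.zeros((Ht.shape[1], 1))
    onehot[j, 0] = 1.0
    h_masked = Ht @ Tensor(onehot)            # (K·d) × 1
    logits = (model.W_p @ h_masked).reshape(-1) + model.b_p
    target = model.vocab_index[masked]
    tvec = np.zeros(len(model.vocab))
    tvec[target] = 1.0
    return -(logits.log_softmax(axis=0) * tvec).sum()


def pretrain_masked(graph: nx.Graph, node_attributes: dict[Hashable, np.ndarray],
                    config: CCCNetConfig | None = None,
                    structural_hook: Callable[[nx.Graph, int], dict] | None = None,
                    model: SubgraphGAT | None = None,
                    ) -> tuple[SubgraphGAT, list[float]]:
    """Masked-node pretraining: per node, sample a context subgraph, mask a
    random member node's attributes and predict its identity over the full
    node vocabulary. Returns (model, per-epoch mean loss)."""
    config = config or CCCNetConfig()
    rng = np.random.default_rng(config.seed)
    hook = structural_hook or spectral_structural_embedding
    structs = hook(graph, config.struct_dim)
    nodes = [n for n in graph.nodes() if graph.degree(n) > 0]
    if len(nodes) < 2:
        raise ValueError("graph needs >= 2 connected nodes for pretraining")
    attr_dim = len(next(iter(node_attributes.values())))
    model = model or SubgraphGAT(attr_dim, list(graph.nodes()), config, rng)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    subgraphs = [sample_subgraphs(graph, n, config.walk_length,
                                  config.n_walks, rng,
                                  diameter_bound=config.diameter_bound)
                 for n in nodes]
    history = []
    for _ in range(config.pretrain_epochs):
        losses = []
        opt.zero_grad()
        total: Tensor | None = None
        for sub in subgraphs:
            masked = sub.nodes[rng.integers(len(sub.nodes))]
            loss = _node_loss(model, sub, node_attributes, structs, masked)
            total = loss if total is None else total + loss
            losses.append(loss.item())
        total.backward()
        opt.step()
        history.append(float(np.mean(losses)))
    return model, history


class LinkScorer:
    """Contextual link scorer S(i, j) = sigmoid(h̃_iᵀ h̃_j)."""

    def __init__(self, model: SubgraphGAT, graph: nx.Graph,
                 node_attributes: dict[Hashable, np.ndarray],
                 structs: dict[Hashable, np.ndarray], config: CCCNetConfig):
        self.model = model
        self.graph = graph
        self.attrs = node_attributes
        self.structs = structs
        self.config = config

    def _context_prob(self, sub: ContextSubgraph) -> Tensor:
        i, j = sub.anchor
        Ht = self.model.forward(sub, self.attrs, self.structs)
        n = Ht.shape[1]
        ei, ej = np.zeros((n, 1)), np.zeros((n, 1))
        ei[sub.index_of(i), 0] = 1.0
        ej[sub.index_of(j), 0] = 1.0
        hi = Ht @ Tensor(ei)
        hj = Ht @ Tensor(ej)
        return (hi * hj).sum().sigmoid()

    def _pair_prob(self, i: Hashable, j: Hashable,
                   rng: np.random.Generator) -> Tensor:
        sub = sample_subgraphs(self.graph, i, self.config.walk_length,
                               self.config.n_walks, rng,
                               diameter_bound=self.config.diameter_bound,
                               second_anchor=j)
        return self._context_prob(sub)

    def score(self, i: Hashable, j: Hashable, seed: int = 0,
              n_contexts: int = 3) -> float:
        """Mean edge probability over `n_contexts` sampled contexts."""
        rng = np.random.default_rng(seed)
        return float(np.mean([self._pair_prob(i, j, rng).item()
                              for _ in range(n_contexts)]))


def finetune_links(graph: nx.Graph, node_attributes: dict[Hashable, np.ndarray],
                   positive_edges: list[tuple[Hashable, Hashable]],
                   model: SubgraphGAT,
                   negative_edges: list[tuple[Hashable, Hashable]] | None = None,
                   config: CCCNetConfig | None = None,
                   structural_hook: Callable[[nx.Graph, int], dict] | None = None,
                   ) -> tuple[LinkScorer, list[float]]:
    """Fine-tune the pretrained model for contextual link prediction.

    Maximizes sum(log S) over positives plus sum(log(1-S)) over negatives;
    negatives default to uniformly sampled non-edges at
    `config.negative_ratio` per positive. Returns (scorer, loss history).
    """
    config = config or model.config
    if not positive_edges:
        raise ValueError("need at least one positive edge")
    rng = np.random.default_rng(config.seed + 1)
    hook = structural_hook or spectral_structural_embedding
    structs = hook(graph, config.struct_dim)
    if negative_edges is None:
        nodes = list(graph.nodes())
        existing = {frozenset(e) for e in graph.edges()} | \
            {frozenset(e) for e in positive_edges}
        negative_edges = []
        n_neg = int(round(config.negative_ratio * len(positive_edges)))
        guard = 0
        while len(negative_edges) < n_neg and guard < 100 * n_neg:
            guard += 1
            u, v = nodes[rng.integers(len(nodes))], nodes[rng.integers(len(nodes))]
            if u == v or frozenset((u, v)) in existing:
                continue
            if graph.degree(u) == 0 or graph.degree(v) == 0:
                continue
            negative_edges.append((u, v))
    scorer = LinkScorer(model, graph, node_attributes, structs, config)
    # contexts are sampled once per pair and reused across epochs
    pos_ctx = [sample_subgraphs(graph, u, config.walk_length, config.n_walks,
                                rng, diameter_bound=config.diameter_bound,
                                second_anchor=v)
               for (u, v) in positive_edges]
    neg_ctx = [sample_subgraphs(graph, u, config.walk_length, config.n_walks,
                                rng, diameter_bound=config.diameter_bound,
                                second_anchor=v)
               for (u, v) in negative_edges]
    opt = Adam(model.parameters(), lr=config.learning_rate)
    eps = 1e-9
    history = []
    for _ in range(config.finetune_epochs):
        opt.zero_grad()
        total: Tensor | None = None
        vals = []
        for sub in pos_ctx:
            loss = -(scorer._context_prob(sub) + eps).log()
            total = loss if total is None else total + loss
            vals.append(loss.item())
        for sub in neg_ctx:
            loss = -((1.0 - scorer._context_prob(sub)) + eps).log()
            total = loss if total is None else total + loss
            vals.append(loss.item())
        total.backward()
        opt.step()
        history.append(float(np.mean(vals)))
    return scorer, history
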