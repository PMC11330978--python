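"""Attention graph network linking dissociated cells to spatial units.

Both modalities are encoded as complete graphs over their units; layers
alternate self-attention (within a modality) and cross-attention (between
modalities) with residual MLP updates. Final linear projections give
matching descriptors whose pairwise inner products form the cell × spot
mapping matrix, trained by maximizing per-gene and per-spot cosine
similarity between the mapped reconstruction and the spatial truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .autodiff import Adam, Parameter, Tensor, concat
from .data_model import (CellTypeAnnotation, ExpressionMatrix, Resolution,
                         SpatialDataset)

__all__ = [
    "TrainConfig",
    "NodeState",
    "AttentionLayerParams",
    "MappingMatrix",
    "IntegrationNet",
    "encode_nodes",
    "attention_message",
    "gnn_forward",
    "similarity_and_loss",
    "fit_mapping",
    "celltype_probability_map",
    "assign_single_cell_types",
]


@dataclass
class TrainConfig:
    """Hyper-parameters of the integration network."""

    n_layers: int = 4
    dim: int = 64
    heads: int = 4
    epochs: int = 500
    learning_rate: float = 1e-3
    seed: int = 0
    device: str = "cpu"

    def __post_init__(self):
        if self.n_layers < 2 or self.n_layers % 2 != 0:
            raise ValueError("n_layers must be even and >= 2 so both "
                             "self- and cross-edges are used")
        if self.dim % self.heads != 0:
            raise ValueError("dim must be divisible by heads")


@dataclass
class NodeState:
    """Per-unit D-dimensional states for one modality at one layer."""

    x: Tensor
    modality: str  # "sc" | "st"

    def __post_init__(self):
        if not np.isfinite(self.x.data).all():
            raise ValueError("node state contains non-finite values")


class AttentionLayerParams:
    """One message-passing layer: per-head q/k/v projections plus the
    residual-update MLP. `edge_mode` selects self- vs cross-edges."""

    def __init__(self, dim: int, heads: int, edge_mode: str,
                 rng: np.random.Generator):
        if dim % heads != 0:
            raise ValueError("dim must be divisible by heads")
        if edge_mode not in ("self", "cross"):
            raise ValueError("edge_mode must be 'self' or 'cross'")
        self.dim, self.heads, self.edge_mode = dim, heads, edge_mode
        dh = dim // heads
        s = 1.0 / np.sqrt(dim)

        def mat():
            return Parameter(rng.normal(0.0, s, size=(dim, dh)))

        self.W1 = [mat() for _ in range(heads)]
        self.W2 = [mat() for _ in range(heads)]
        self.W3 = [mat() for _ in range(heads)]
        self.b1 = [Parameter(np.zeros(dh)) for _ in range(heads)]
        self.b2 = [Parameter(np.zeros(dh)) for _ in range(heads)]
        self.b3 = [Parameter(np.zeros(dh)) for _ in range(heads)]
        # residual MLP on [x || m]: 2D -> 2D -> D, output zero-initialized so
        # the untrained network starts at the residual identity
        self.Wm1 = Parameter(rng.normal(0.0, 1.0 / np.sqrt(2 * dim),
                                        size=(2 * dim, 2 * dim)))
        self.bm1 = Parameter(np.zeros(2 * dim))
        self.Wm2 = Parameter(np.zeros((2 * dim, dim)))
        self.bm2 = Parameter(np.zeros(dim))

    def parameters(self) -> list[Parameter]:
        return (self.W1 + self.W2 + self.W3 + self.b1 + self.b2 + self.b3
                + [self.Wm1, self.bm1, self.Wm2, self.bm2])


@dataclass
class MappingMatrix:
    """Cells × spots mapping weights (raw inner products)."""

    M: np.ndarray
    cell_names: list[str]
    spot_names: list[str]
    loss_history: list[float] = field(default_factory=list)

    def __post_init__(self):
        self.M = np.asarray(self.M, dtype=np.float64)
        if self.M.shape != (len(self.cell_names), len(self.spot_names)):
            raise ValueError("mapping matrix shape mismatch")
        if not np.isfinite(self.M).all():
            raise ValueError("mapping matrix contains non-finite values")

    def softmax_rows(self) -> np.ndarray:
        """Per-cell probabilities over spots (rows sum to 1)."""
        z = self.M - self.M.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.M, index=self.cell_names,
                            columns=self.spot_names)


class _PositionEncoder:
    """Two-layer MLP lifting 2-D positions to width D; zero-initialized
    output so MLP_enc(0) = 0 and untrained states equal the lifted
    expression."""

    def __init__(self, dim: int, hidden: int, rng: np.random.Generator):
        self.W1 = Parameter(rng.normal(0.0, 1.0 / np.sqrt(2), size=(2, hidden)))
        self.b1 = Parameter(np.zeros(hidden))
        self.W2 = Parameter(np.zeros((hidden, dim)))
        self.b2 = Parameter(np.zeros(dim))

    def __call__(self, pos: Tensor) -> Tensor:
        return ((pos @ self.W1 + self.b1).relu()) @ self.W2 + self.b2

    def parameters(self) -> list[Parameter]:
        return [self.W1, self.b1, self.W2, self.b2]


class IntegrationNet:
    """Full parameter set: expression lift, position encoder, L alternating
    attention layers and the final descriptor projection."""

    def __init__(self, n_genes: int, config: TrainConfig,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(config.seed)
        D = config.dim
        self.config = config
        self.W_lift = Parameter(rng.normal(0.0, 1.0 / np.sqrt(n_genes),
                                           size=(n_genes, D)))
        self.b_lift = Parameter(np.zeros(D))
        self.pos_enc = _PositionEncoder(D, hidden=16, rng=rng)
        self.layers = [
            AttentionLayerParams(D, config.heads,
                                 "self" if (l % 2 == 1) else "cross", rng)
            for l in range(1, config.n_layers + 1)]
        self.W_out = Parameter(rng.normal(0.0, 1.0 / np.sqrt(D), size=(D, D)))
        self.b_out = Parameter(np.zeros(D))

    def parameters(self) -> list[Parameter]:
        ps = [self.W_lift, self.b_lift, self.W_out, self.b_out]
        ps += self.pos_enc.parameters()
        for layer in self.layers:
            ps += layer.parameters()
        return ps


def encode_nodes(expr_units_by_genes: np.ndarray, positions: np.ndarray,
                 net: IntegrationNet, modality: str) -> NodeState:
    """Layer-0 states: linear lift of expression plus the positional MLP.

    `expr_units_by_genes` is units × genes; dissociated cells pass
    all-zero positions so the state reduces to the expression term.
    """
    expr = np.asarray(expr_units_by_genes, dtype=np.float64)
    positions = np.asarray(positions, dtype=np.float64)
    if expr.shape[0] != positions.shape[0] or positions.shape[1] != 2:
        raise ValueError("expression/position row mismatch or positions not 2-D")
    if expr.shape[1] != net.W_lift.shape[0]:
        raise ValueError(
            f"expression width {expr.shape[1]} != lift input "
            f"{net.W_lift.shape[0]}")
    d = Tensor(expr) @ net.W_lift + net.b_lift
    x0 = d + net.pos_enc(Tensor(positions))
    return NodeState(x0, modality)


def attention_message(states_query: Tensor, states_source: Tensor,
                      layer: AttentionLayerParams) -> Tensor:
    """Multi-head scaled dot-product attention message for every query unit.

    Per head: a_ij = softmax_j(q_i·k_j / sqrt(d_h)), m_i = sum_j a_ij v_j.
    Head outputs are concatenated back to width D.
    """
    if states_source.shape[0] == 0:
        raise ValueError("attention requires a nonempty source side")
    dh = layer.dim // layer.heads
    scale = 1.0 / np.sqrt(dh)
    head_messages = []
    for h in range(layer.heads):
        q = states_query @ layer.W1[h] + layer.b1[h]
        k = states_source @ layer.W2[h] + layer.b2[h]
        v = states_source @ layer.W3[h] + layer.b3[h]
        a = ((q @ k.T) * scale).softmax(axis=1)
        head_messages.append(a @ v)
    return concat(head_messages, axis=1)


def attention_weights(states_query: Tensor, states_source: Tensor,
                      layer: AttentionLayerParams) -> list[np.ndarray]:
    """Per-head attention matrices (rows sum to 1); diagnostic helper."""
    dh = layer.dim // layer.heads
    scale = 1.0 / np.sqrt(dh)
    out = []
    for h in range(layer.heads):
        q = (states_query @ layer.W1[h] + layer.b1[h]).data
        k = (states_source @ layer.W2[h] + layer.b2[h]).data
        logits = q @ k.T * scale
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        out.append(e / e.sum(axis=1, keepdims=True))
    return out


def _residual_update(x: Tensor, m: Tensor, layer: AttentionLayerParams) -> Tensor:
    h = (concat([x, m], axis=1) @ layer.Wm1 + layer.bm1).relu()
    return x + (h @ layer.Wm2 + layer.bm2)


def gnn_forward(sc_state0: NodeState, st_state0: NodeState,
                net: IntegrationNet) -> tuple[Tensor, Tensor]:
    """Run the alternating self/cross layers and project descriptors.

    Odd layers (1-based) aggregate along self-edges, even layers along
    cross-edges; each update is x + MLP([x || m]).
    """
    xa, xb = sc_state0.x, st_state0.x
    for i, layer in enumerate(net.layers, start=1):
        if layer.edge_mode == "self":
            ma = attention_message(xa, xa, layer)
            mb = attention_message(xb, xb, layer)
        else:
            ma = attention_message(xa, xb, layer)
            mb = attention_message(xb, xa, layer)
        xa = _residual_update(xa, ma, layer)
        xb = _residual_update(xb, mb, layer)
        if not (np.isfinite(xa.data).all() and np.isfinite(xb.data).all()):
            raise FloatingPointError(f"non-finite state after layer {i}")
    fA = xa @ net.W_out + net.b_out
    fB = xb @ net.W_out + net.b_out
    return fA, fB


def similarity_and_loss(fA: Tensor, fB: Tensor, sc_expr: np.ndarray,
                        st_expr: np.ndarray,
                        ) -> tuple[Tensor, Tensor, dict]:
    """Inner-product similarity matrix and the negated cosine objective.

    `sc_expr` (cells × genes) and `st_expr` (spots × genes) share the
    training-gene axis. The mapping is row-softmaxed over spots before
    reconstruction; zero-norm gene/spot terms are skipped with a warning.
    Returns (M, loss, info) where loss = -(sum of per-gene and per-spot
    cosine similarities).
    """
    A = np.asarray(sc_expr, dtype=np.float64)
    B = np.asarray(st_expr, dtype=np.float64)
    M = fA @ fB.T
    P = M.softmax(axis=1)
    pred = P.T @ Tensor(A)  # spots × genes

    eps = 1e-12
    gene_mask = (np.linalg.norm(B, axis=0) > 0) & (A.sum(axis=0) > 0)
    spot_mask = np.linalg.norm(B, axis=1) > 0
    n_skipped = int((~gene_mask).sum() + (~spot_mask).sum())
    if n_skipped:
        warnings.warn(f"skipping {n_skipped} zero-norm cosine terms",
                      RuntimeWarning, stacklevel=2)

    def masked_cos(x: Tensor, y: np.ndarray, axis: int, mask: np.ndarray):
        num = (x * y).sum(axis=axis)
        den = ((x * x).sum(axis=axis) + eps).sqrt() * \
            (np.sqrt((y * y).sum(axis=axis)) + eps)
        return ((num / den) * mask.astype(float)).sum()

    score = masked_cos(pred, B, 0, gene_mask) + masked_cos(pred, B, 1, spot_mask)
    loss = -score
    info = {"n_skipped_terms": n_skipped,
            "n_gene_terms": int(gene_mask.sum()),
            "n_spot_terms": int(spot_mask.sum())}
    return M, loss, info


def _prepare_features(sc: ExpressionMatrix, st: ExpressionMatrix,
                      genes: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """log1p + pooled per-gene std scaling; returns units × genes arrays."""
    A = np.log1p(sc.subset_genes(genes).values.T)
    B = np.log1p(st.subset_genes(genes).values.T)
    pooled = np.concatenate([A, B], axis=0)
    sd = pooled.std(axis=0)
    sd[sd == 0] = 1.0
    return A / sd, B / sd


def fit_mapping(sc_dataset: ExpressionMatrix | SpatialDataset,
                st_dataset: SpatialDataset,
                training_genes: list[str],
                config: TrainConfig | None = None) -> MappingMatrix:
    """Train the network and return the cell × spot mapping matrix.

    Fully seeded; `loss_history` on the result records the per-epoch
    objective (lower is better, objective is the negated cosine score).
    """
    config = config or TrainConfig()
    genes = list(training_genes)
    if len(genes) < 2:
        raise ValueError("need at least 2 training genes")
    sc_expr = sc_dataset.expr if isinstance(sc_dataset, SpatialDataset) \
        else sc_dataset
    A_raw = sc_expr.subset_genes(genes)
    B_raw = st_dataset.expr.subset_genes(genes)
    A_feat, B_feat = _prepare_features(sc_expr, st_dataset.expr, genes)

    # positions: spatial side standardized, dissociated side all-zero
    st_pos = st_dataset.coords.copy()
    st_pos = (st_pos - st_pos.mean(axis=0)) / (st_pos.std(axis=0) + 1e-9)
    sc_pos = np.zeros((A_feat.shape[0], 2))

    rng = np.random.default_rng(config.seed)
    net = IntegrationNet(len(genes), config, rng)
    opt = Adam(net.parameters(), lr=config.learning_rate)
    A_vals = A_raw.values.T  # cells × genes
    B_vals = B_raw.values.T  # spots × genes

    history: list[float] = []
    M_data = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for _ in range(config.epochs):
            sc_state = encode_nodes(A_feat, sc_pos, net, "sc")
            st_state = encode_nodes(B_feat, st_pos, net, "st")
            fA, fB = gnn_forward(sc_state, st_state, net)
            M, loss, _ = similarity_and_loss(fA, fB, A_vals, B_vals)
            opt.zero_grad()
            loss.backward()
            opt.step()
            history.append(loss.item())
            M_data = M.data
    return MappingMatrix(M_data, list(sc_expr.unit_names),
                         list(st_dataset.unit_names), history)


def celltype_probability_map(mapping: MappingMatrix,
                             sc_annotation: CellTypeAnnotation,
                             ) -> pd.DataFrame:
    """Spots × types cell-type probabilities.

    Row-softmaxed mapping weights are summed per type and renormalized per
    spot to sum to 1.
    """
    labels = sc_annotation.labels_for(mapping.cell_names)
    P = mapping.softmax_rows()
    types = [t for t in sc_annotation.type_order]
    out = np.zeros((len(mapping.spot_names), len(types)))
    for k, t in enumerate(types):
        out[:, k] = P[labels == t].sum(axis=0)
    totals = out.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    return pd.DataFrame(out / totals, index=mapping.spot_names, columns=types)


def assign_single_cell_types(prob_map: pd.DataFrame) -> pd.Series:
    """Hard label per spatial unit = argmax type probability."""
    return prob_map.idxmax(axis=1)
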