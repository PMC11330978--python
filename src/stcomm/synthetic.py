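"""Seeded generators for paired dissociated/spatial datasets, grid spots,
L-R databases and receptor→TF networks with retained ground truth.

Counts follow a negative-binomial model (mean/shape parameterization) with
type-specific marker up-regulation; spatial layouts place types in cortex-
like layers, blocky domains, or at random.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import (CellTypeAnnotation, ExpressionMatrix, LRDatabase,
                         ReceptorTFNetwork, Resolution, SpatialDataset)

__all__ = [
    "SimulationConfig",
    "simulate_paired_datasets",
    "simulate_grid_spots",
    "plant_lr_signal",
    "simulate_networks",
]


@dataclass
class SimulationConfig:
    n_types: int = 2
    n_genes: int = 60
    markers_per_type: int = 10
    cells_per_type: int = 100
    layout: str = "layered_cortex"  # layered_cortex | domains | random
    field_size_um: float = 1000.0
    spot_pitch_um: float = 100.0
    cells_per_spot_range: tuple[int, int] = (1, 18)
    marker_effect: float = 8.0
    dispersion: float = 10.0        # NB shape; larger = less overdispersed
    lr_pairs: list[tuple[str, str]] = field(default_factory=list)
    interaction_radius_um: float = 50.0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_types, self.n_genes, self.markers_per_type,
               self.cells_per_type) <= 0:
            raise ValueError("all counts must be positive")
        if self.n_types * self.markers_per_type > self.n_genes:
            raise ValueError("not enough genes for the requested markers")
        if self.interaction_radius_um > self.field_size_um:
            raise ValueError("interaction radius exceeds field size")
        if self.layout not in ("layered_cortex", "domains", "random"):
            raise ValueError(f"unknown layout {self.layout!r}")


def _type_means(config: SimulationConfig,
                rng: np.random.Generator) -> tuple[np.ndarray, list[str],
                                                   dict[str, list[str]]]:
    """Per-type mean matrix (genes × types) and marker bookkeeping."""
    genes = [f"G{i:04d}" for i in range(config.n_genes)]
    base = rng.lognormal(mean=0.0, sigma=0.5, size=config.n_genes) + 0.5
    means = np.tile(base[:, None], (1, config.n_types))
    markers: dict[str, list[str]] = {}
    for t in range(config.n_types):
        lo = t * config.markers_per_type
        hi = lo + config.markers_per_type
        means[lo:hi, t] *= (1.0 + config.marker_effect)
        markers[f"type{t}"] = genes[lo:hi]
    return means, genes, markers


def _nb_counts(means: np.ndarray, shape: float,
               rng: np.random.Generator) -> np.ndarray:
    p = shape / (shape + means)
    return rng.negative_binomial(shape, p).astype(float)


def _positions(config: SimulationConfig, type_ids: np.ndarray,
               rng: np.random.Generator) -> np.ndarray:
    L = config.field_size_um
    n = len(type_ids)
    pos = rng.uniform(0.0, L, size=(n, 2))
    if config.layout == "layered_cortex":
        band = L / config.n_types
        pos[:, 1] = type_ids * band + rng.uniform(0.0, band, size=n)
    elif config.layout == "domains":
        strip = L / config.n_types
        pos[:, 0] = type_ids * strip + rng.uniform(0.0, strip, size=n)
    return pos


def simulate_paired_datasets(config: SimulationConfig | None = None,
                             ) -> tuple[ExpressionMatrix, CellTypeAnnotation,
                                        SpatialDataset, CellTypeAnnotation]:
    """Generate a dissociated count matrix and a single-cell spatial map
    drawn from the same per-type negative-binomial expression model."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    means, genes, _ = _type_means(config, rng)
    type_names = [f"type{t}" for t in range(config.n_types)]

    def draw(prefix: str) -> tuple[ExpressionMatrix, CellTypeAnnotation,
                                   np.ndarray]:
        type_ids = np.repeat(np.arange(config.n_types), config.cells_per_type)
        counts = _nb_counts(means[:, type_ids], config.dispersion, rng)
        names = [f"{prefix}{i}" for i in range(len(type_ids))]
        expr = ExpressionMatrix(counts, genes, names, layer_tag="raw")
        ann = CellTypeAnnotation(
            {n: type_names[t] for n, t in zip(names, type_ids)},
            type_order=list(type_names))
        return expr, ann, type_ids

    sc_expr, sc_ann, _ = draw("sc_")
    st_expr, st_ann, st_type_ids = draw("cell_")
    coords = _positions(config, st_type_ids, rng)
    st_map = SpatialDataset(st_expr, coords, Resolution.single_cell)
    return sc_expr, sc_ann, st_map, st_ann


def simulate_grid_spots(single_cell_map: SpatialDataset,
                        annotation: CellTypeAnnotation,
                        pitch_um: float = 100.0,
                        max_cells: int | None = None,
                        ) -> tuple[SpatialDataset, pd.DataFrame]:
    """Bin placed cells into square spots of the given pitch.

    Spot expression sums member-cell counts; returns the spot dataset
    (coordinates at bin centers, `cells_per_spot` filled) and the true
    per-spot type-proportion table. Empty bins are dropped. When
    `max_cells` is given, occupancy outside [1, max_cells] raises.
    """
    coords = single_cell_map.coords
    ix = np.floor(coords[:, 0] / pitch_um).astype(int)
    iy = np.floor(coords[:, 1] / pitch_um).astype(int)
    labels = annotation.labels_for(single_cell_map.unit_names)
    types = annotation.type_order

    bins: dict[tuple[int, int], list[int]] = {}
    for i, key in enumerate(zip(ix, iy)):
        bins.setdefault(key, []).append(i)
    keys = sorted(bins)
    if max_cells is not None:
        worst = max(len(v) for v in bins.values())
        if worst > max_cells:
            raise ValueError(f"a spot holds {worst} cells > cap {max_cells}")

    X = single_cell_map.expr.values
    spot_names, spot_vals, spot_coords, cps, beta_rows = [], [], [], [], []
    for key in keys:
        members = bins[key]
        name = f"spot_{key[0]}_{key[1]}"
        spot_names.append(name)
        spot_vals.append(X[:, members].sum(axis=1))
        spot_coords.append(((key[0] + 0.5) * pitch_um,
                            (key[1] + 0.5) * pitch_um))
        cps.append(len(members))
        mem_labels = labels[members]
        beta_rows.append([float((mem_labels == t).mean()) for t in types])

    expr = ExpressionMatrix(np.column_stack(spot_vals),
                            list(single_cell_map.expr.gene_names),
                            spot_names, layer_tag=single_cell_map.expr.layer_tag)
    spots = SpatialDataset(expr, np.array(spot_coords), Resolution.spot,
                           cells_per_spot=np.array(cps))
    beta = pd.DataFrame(beta_rows, index=spot_names, columns=types)
    return spots, beta


def plant_lr_signal(single_cell_map: SpatialDataset,
                    annotation: CellTypeAnnotation,
                    lr_pair: tuple[str, str],
                    sender_type: str, receiver_type: str,
                    radius_um: float,
                    tf_gene: str | None = None,
                    boost: float = 20.0,
                    zero_background: bool = True,
                    seed: int = 0) -> tuple[SpatialDataset, pd.DataFrame]:
    """Plant a communication signal: senders with a receiver-type cell
    within `radius_um` get the ligand boosted; those receivers get the
    receptor (and optionally a downstream TF) boosted. Returns the
    modified map plus the truth table of planted (sender, receiver) pairs.

    With `zero_background` (default) the ligand/receptor/TF rows are
    cleared outside the boosted cells, so the binary expressing/NN pattern
    carries the planted signal rather than only its magnitude.
    """
    lig, rec = lr_pair
    expr = single_cell_map.expr
    vals = expr.values.copy()
    gl = {g: i for i, g in enumerate(expr.gene_names)}
    for g in (lig, rec) + ((tf_gene,) if tf_gene else ()):
        if g not in gl:
            raise KeyError(f"gene {g!r} not in map")
    labels = annotation.labels_for(expr.unit_names)
    coords = single_cell_map.coords
    senders = np.flatnonzero(labels == sender_type)
    receivers = np.flatnonzero(labels == receiver_type)
    pairs = []
    boosted_senders: set[int] = set()
    boosted_receivers: set[int] = set()
    if radius_um > 0 and len(senders) and len(receivers):
        d = np.linalg.norm(coords[senders][:, None, :]
                           - coords[receivers][None, :, :], axis=2)
        for a, i in enumerate(senders):
            close = receivers[d[a] <= radius_um]
            close = close[close != i]
            for j in close:
                pairs.append((expr.unit_names[i], expr.unit_names[j]))
                boosted_senders.add(i)
                boosted_receivers.add(int(j))
    rng = np.random.default_rng(seed)
    if zero_background:
        for g in (lig, rec) + ((tf_gene,) if tf_gene else ()):
            vals[gl[g], :] = 0.0
    for i in boosted_senders:
        vals[gl[lig], i] += 1 + rng.poisson(boost)
    for j in boosted_receivers:
        vals[gl[rec], j] += 1 + rng.poisson(boost)
        if tf_gene:
            vals[gl[tf_gene], j] += 1 + rng.poisson(boost)
    new_expr = ExpressionMatrix(vals, list(expr.gene_names),
                                list(expr.unit_names), expr.layer_tag)
    truth = pd.DataFrame(pairs, columns=["sender", "receiver"])
    new_map = SpatialDataset(new_expr, coords.copy(), Resolution.single_cell)
    return new_map, truth


def simulate_networks(gene_names: list[str],
                      planted_pairs: list[tuple[str, str]] | None = None,
                      n_extra_pairs: int = 5,
                      n_tfs_per_receptor: int = 2,
                      seed: int = 0) -> tuple[LRDatabase, ReceptorTFNetwork]:
    """Random L-R table containing every planted pair, plus a layered
    receptor→intermediate→TF DAG in which each receptor reaches >= 1 TF."""
    rng = np.random.default_rng(seed)
    planted = list(planted_pairs or [])
    pool = [g for g in gene_names
            if g not in {x for p in planted for x in p}]
    pairs = list(planted)
    while len(pairs) < len(planted) + n_extra_pairs and len(pool) >= 2:
        pick = rng.choice(len(pool), size=2, replace=False)
        cand = (pool[pick[0]], pool[pick[1]])
        if cand not in pairs:
            pairs.append(cand)
    db = LRDatabase(pairs)

    # downstream genes come from the measured gene panel so expression-based
    # TF activity checks can see them; roles are disjoint to keep the DAG
    lr_genes = {x for p in pairs for x in p}
    downstream = [g for g in gene_names if g not in lr_genes]
    need = len(pairs) * (1 + n_tfs_per_receptor)
    if len(downstream) < need:
        raise ValueError("gene panel too small for the requested network")
    edges: list[tuple[str, str, float]] = []
    tf_nodes: set[str] = set()
    cursor = 0
    for _, rec in pairs:
        mid = downstream[cursor]
        cursor += 1
        edges.append((rec, mid, float(rng.uniform(0.5, 2.0))))
        for _ in range(n_tfs_per_receptor):
            tf = downstream[cursor]
            cursor += 1
            tf_nodes.add(tf)
            edges.append((mid, tf, float(rng.uniform(0.5, 2.0))))
    return db, ReceptorTFNetwork(edges, tf_nodes)
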