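"""Single-cell reconstruction of spot-level spatial data.

Per spot: round cell-type proportions to integer cell counts, pick the
combination of dissociated cells whose summed profile best matches the
spot, then place each picked cell inside the spot's d_min/2 disc with
quadrant and radius probabilities driven by same-type abundance in the
neighboring spots.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import (CellTypeAnnotation, ExpressionMatrix, Resolution,
                         SpatialDataset)

__all__ = [
    "SpotGeometry",
    "PlacedCell",
    "integer_allocation",
    "choose_cell_subset",
    "place_cell",
    "spot_geometry",
    "reconstruct_single_cell_map",
]

DEFAULT_N_CELL = 20  # maximum cells per spot
DEFAULT_BUDGET = 1000


@dataclass
class SpotGeometry:
    """Placement geometry of one spot: center, nearest-neighbor distance
    and the per-quadrant nearest neighbor with its same-type ratio."""

    center: tuple[float, float]
    d_min: float
    quadrant_ratios: np.ndarray          # R_q, q = 1..Q (0 where empty)
    quadrant_neighbors: list[int | None]  # spot index per quadrant, or None
    self_ratio: float = 0.0              # R_{x0,y0}
    neighbor_ratios: np.ndarray | None = None  # R_{x',y'} per quadrant

    def __post_init__(self):
        if self.d_min <= 0:
            raise ValueError("d_min must be positive")
        self.quadrant_ratios = np.asarray(self.quadrant_ratios, dtype=float)
        if self.neighbor_ratios is None:
            self.neighbor_ratios = self.quadrant_ratios.copy()


@dataclass
class PlacedCell:
    source_cell: str
    cell_type: str
    x: float
    y: float
    parent_spot: str
    theta: float
    alpha: float


def integer_allocation(beta: np.ndarray, n_cell: int = DEFAULT_N_CELL,
                       ) -> np.ndarray:
    """Round per-type proportions to integer cell counts.

    omega_i = floor(N*beta_i) + 1 when frac(N*beta_i) >= 0.5, else the
    floor. If the total exceeds `n_cell`, types with the smallest
    fractional parts are decremented first (ties by type order) until the
    total fits. An all-zero allocation falls back to one cell of the
    largest-proportion type.
    """
    beta = np.asarray(beta, dtype=float)
    if (beta < 0).any():
        raise ValueError("proportions must be nonnegative")
    raw = n_cell * beta
    frac = raw - np.floor(raw)
    rounded_up = frac >= 0.5
    omega = np.floor(raw).astype(int) + rounded_up.astype(int)
    if omega.sum() == 0:
        omega[int(np.argmax(beta))] = 1
        return omega
    while omega.sum() > n_cell:
        # only rounded-up types can give a cell back (keeps every entry
        # within +/-1 of its exact share); smallest fractional part loses
        # first, ties by type order
        candidates = np.flatnonzero(rounded_up & (omega > 0))
        if candidates.size == 0:
            candidates = np.flatnonzero(omega > 0)
        i = candidates[np.lexsort((candidates, frac[candidates]))[0]]
        omega[i] -= 1
        rounded_up[i] = False
    return omega


def choose_cell_subset(spot_expr: np.ndarray,
                       candidates_by_type: dict[str, list[int]],
                       cell_profiles: np.ndarray,
                       omega: dict[str, int],
                       budget: int = DEFAULT_BUDGET,
                       rng: np.random.Generator | None = None,
                       ) -> list[int]:
    """Pick the per-type random combination minimizing the squared error
    between the spot profile and the summed member-cell profiles.

    `cell_profiles` is cells × genes (same gene axis as `spot_expr`).
    Draws `budget` seeded random subsets honoring the per-type counts and
    keeps the best; enumerates exhaustively when the candidate space is
    smaller than the budget and only one cell is requested per type.
    """
    rng = rng or np.random.default_rng()
    Y = np.asarray(spot_expr, dtype=float)
    for t, k in omega.items():
        pool = candidates_by_type.get(t, [])
        if k > len(pool):
            raise ValueError(
                f"type {t!r} requests {k} cells but pool has {len(pool)}")
    active = [(t, k) for t, k in omega.items() if k > 0]
    best_idx: list[int] | None = None
    best_obj = np.inf
    for _ in range(max(1, budget)):
        idx: list[int] = []
        for t, k in active:
            pool = candidates_by_type[t]
            take = rng.choice(len(pool), size=k, replace=False)
            idx.extend(pool[j] for j in take)
        obj = float(((Y - cell_profiles[idx].sum(axis=0)) ** 2).sum())
        if obj < best_obj:
            best_obj = obj
            best_idx = idx
        if best_obj == 0.0:
            break
    assert best_idx is not None
    return best_idx


def _quadrant_of(dx: float, dy: float) -> int:
    """Quadrant 1..4 from the angle of (dx, dy), theta in (90q-90, 90q]."""
    theta = np.degrees(np.arctan2(dy, dx)) % 360.0
    if theta == 0.0:
        theta = 360.0
    return int(np.ceil(theta / 90.0))


def spot_geometry(spot_index: int, coords: np.ndarray,
                  type_ratios: np.ndarray, q: int = 4) -> SpotGeometry:
    """Geometry of one spot given all spot coordinates and the per-spot
    ratio of the cell type being placed (`type_ratios`, one per spot)."""
    if q != 4:
        raise ValueError("only Q = 4 quadrants are supported")
    coords = np.asarray(coords, dtype=float)
    center = coords[spot_index]
    if len(coords) < 2:
        raise ValueError("spot geometry needs at least 2 spots")
    d = np.linalg.norm(coords - center, axis=1)
    d[spot_index] = np.inf
    d_min = float(d.min())
    neighbors: list[int | None] = [None] * q
    nbr_dist = [np.inf] * q
    for j in range(len(coords)):
        if j == spot_index:
            continue
        quad = _quadrant_of(coords[j, 0] - center[0], coords[j, 1] - center[1])
        if d[j] < nbr_dist[quad - 1]:
            nbr_dist[quad - 1] = d[j]
            neighbors[quad - 1] = j
    ratios = np.array([type_ratios[n] if n is not None else 0.0
                       for n in neighbors])
    return SpotGeometry(center=(float(center[0]), float(center[1])),
                        d_min=d_min, quadrant_ratios=ratios,
                        quadrant_neighbors=neighbors,
                        self_ratio=float(type_ratios[spot_index]),
                        neighbor_ratios=ratios)


def place_cell(geometry: SpotGeometry,
               rng: np.random.Generator | None = None,
               ) -> tuple[float, float, float, float]:
    """Draw (x', y', theta, alpha) for one cell inside its parent spot.

    Quadrant q is drawn with probability (R_q+1)/sum_i(R_i+1) over
    quadrants that have a neighbor (renormalized if some are empty; a lone
    spot falls back to a uniform angle). theta is uniform inside the
    quadrant's 90-degree arc. alpha's half-interval (0, 0.5] vs (0.5, 1]
    is drawn with probabilities proportional to R_center+1 vs
    R_neighbor+1, then alpha is uniform within the chosen half. The
    placement radius alpha*d_min/2 never exceeds d_min/2.
    """
    rng = rng or np.random.default_rng()
    if geometry.d_min <= 0:
        raise ValueError("d_min must be positive")
    have = [i for i, n in enumerate(geometry.quadrant_neighbors)
            if n is not None]
    if have:
        w = geometry.quadrant_ratios[have] + 1.0
        qi = have[rng.choice(len(have), p=w / w.sum())]
        theta = float(rng.uniform(90.0 * qi, 90.0 * (qi + 1)))
        if theta == 90.0 * qi:  # open interval (90q-90, 90q]
            theta = 90.0 * (qi + 1)
        r_nbr = float(geometry.neighbor_ratios[qi])
    else:
        theta = float(rng.uniform(0.0, 360.0)) or 360.0
        r_nbr = 0.0

    r0 = geometry.self_ratio
    p_inner = (r0 + 1.0) / (r0 + r_nbr + 2.0)
    if rng.uniform() < p_inner:
        alpha = float(rng.uniform(0.0, 0.5))
        alpha = alpha if alpha > 0 else 0.5
    else:
        alpha = float(rng.uniform(0.5, 1.0))
        alpha = alpha if alpha > 0.5 else 1.0
    x0, y0 = geometry.center
    x = x0 + alpha * geometry.d_min * np.cos(np.radians(theta)) / 2.0
    y = y0 + alpha * geometry.d_min * np.sin(np.radians(theta)) / 2.0
    return x, y, theta, alpha


def reconstruct_single_cell_map(st_spots: SpatialDataset,
                                proportions: pd.DataFrame,
                                sc_expr: ExpressionMatrix,
                                annotation: CellTypeAnnotation,
                                n_cell: int = DEFAULT_N_CELL,
                                budget: int = DEFAULT_BUDGET,
                                seed: int = 0,
                                ) -> tuple[SpatialDataset, CellTypeAnnotation,
                                           pd.DataFrame]:
    """Reconstruct a single-cell-resolution map from spots + proportions.

    Returns (single-cell SpatialDataset, per-cell annotation, placement
    table with parent spot / draw parameters). Per-spot maximum cell
    counts come from `st_spots.cells_per_spot` when present, else
    `n_cell`. Spots with all-zero proportions are skipped with a warning.
    """
    rng = np.random.default_rng(seed)
    types = list(proportions.columns)
    labels = annotation.labels_for(sc_expr.unit_names)
    pools = {t: [i for i, lab in enumerate(labels) if lab == t] for t in types}
    shared = [g for g in st_spots.expr.gene_names if g in set(sc_expr.gene_names)]
    if not shared:
        raise ValueError("no shared genes between spots and cell profiles")
    profiles = sc_expr.subset_genes(shared).values.T  # cells × genes
    spotX = st_spots.expr.subset_genes(shared).values.T  # spots × genes

    prop = proportions.loc[st_spots.unit_names].to_numpy(dtype=float)
    placed: list[PlacedCell] = []
    rows: list[list] = []
    counter = 0
    for s, spot_name in enumerate(st_spots.unit_names):
        beta = prop[s]
        if beta.sum() == 0:
            warnings.warn(f"spot {spot_name!r} has all-zero proportions; "
                          "skipped", RuntimeWarning, stacklevel=2)
            continue
        cap = (int(st_spots.cells_per_spot[s])
               if st_spots.cells_per_spot is not None else n_cell)
        omega_vec = integer_allocation(beta / beta.sum(), cap)
        omega = {t: int(w) for t, w in zip(types, omega_vec)
                 if w > 0 and pools[t]}
        omega = {t: min(w, len(pools[t])) for t, w in omega.items()}
        if not omega:
            warnings.warn(f"spot {spot_name!r}: no candidate cells for any "
                          "allocated type; skipped", RuntimeWarning,
                          stacklevel=2)
            continue
        chosen = choose_cell_subset(spotX[s], pools, profiles, omega,
                                    budget=budget, rng=rng)
        for ci in chosen:
            ctype = str(labels[ci])
            # ratio of this cell's type per spot drives the placement draw
            tcol = prop[:, types.index(ctype)]
            geom = spot_geometry(s, st_spots.coords, tcol) \
                if len(st_spots.unit_names) > 1 else SpotGeometry(
                    center=tuple(st_spots.coords[s]), d_min=100.0,
                    quadrant_ratios=np.zeros(4),
                    quadrant_neighbors=[None] * 4,
                    self_ratio=float(tcol[s]))
            x, y, theta, alpha = place_cell(geom, rng)
            name = f"{spot_name}.c{counter}"
            counter += 1
            placed.append(PlacedCell(sc_expr.unit_names[ci], ctype, x, y,
                                     spot_name, theta, alpha))
            rows.append([name, sc_expr.unit_names[ci], ctype, x, y,
                         spot_name, theta, alpha])

    if not rows:
        raise ValueError("no cells could be placed for any spot")
    table = pd.DataFrame(rows, columns=["cell", "source_cell", "cell_type",
                                        "x", "y", "parent_spot", "theta",
                                        "alpha"])
    expr_vals = sc_expr.subset_genes(shared).values[
        :, [sc_expr.unit_names.index(c) for c in table["source_cell"]]]
    expr = ExpressionMatrix(expr_vals, shared, table["cell"].tolist(),
                            layer_tag=sc_expr.layer_tag)
    ds = SpatialDataset(expr, table[["x", "y"]].to_numpy(dtype=float),
                        Resolution.single_cell)
    ann = CellTypeAnnotation(dict(zip(table["cell"], table["cell_type"])))
    return ds, ann, table
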