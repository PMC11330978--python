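"""Typed containers and plain-text readers/writers for every format the
pipeline touches.

Conventions
-----------
* Expression tables are genes × units (cells or spots); dense TSV has gene
  names in the first column and unit names in the header.
* Sparse matrices use Matrix-Market coordinate files (1-based on disk,
  0-based in memory) with sidecar gene/unit name files, one name per line.
* Coordinates are continuous micrometres in an arbitrary-origin Cartesian
  plane; coordinate tables have columns ``unit, x, y``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = [
    "ExpressionMatrix",
    "SpatialDataset",
    "CellTypeAnnotation",
    "LRDatabase",
    "ReceptorTFNetwork",
    "Resolution",
    "load_expression",
    "load_spatial",
    "load_lr_database",
    "load_network",
    "write_expression",
    "write_single_cell_map",
    "read_single_cell_map",
]


class Resolution(str, Enum):
    single_cell = "single_cell"
    spot = "spot"


def _check_unique(names: Sequence[str], what: str) -> None:
    seen: dict[str, int] = {}
    dups = []
    for n in names:
        seen[n] = seen.get(n, 0) + 1
        if seen[n] == 2:
            dups.append(n)
    if dups:
        raise ValueError(f"duplicate {what} names: {sorted(dups)}")


@dataclass
class ExpressionMatrix:
    """Genes × units nonnegative expression values with name indices."""

    values: np.ndarray
    gene_names: list[str]
    unit_names: list[str]
    layer_tag: str = "raw"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.gene_names = [str(g).strip() for g in self.gene_names]
        self.unit_names = [str(u).strip() for u in self.unit_names]
        if self.values.ndim != 2:
            raise ValueError("expression values must be 2-D (genes × units)")
        if self.values.shape != (len(self.gene_names), len(self.unit_names)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_names)} genes × {len(self.unit_names)} units")
        if np.isnan(self.values).any():
            raise ValueError("expression matrix contains NaN")
        if (self.values < 0).any():
            raise ValueError("expression matrix contains negative values")
        _check_unique(self.gene_names, "gene")
        _check_unique(self.unit_names, "unit")
        if self.layer_tag == "raw" and not np.allclose(
                self.values, np.round(self.values)):
            raise ValueError('layer_tag="raw" requires integer-valued counts')

    @property
    def n_genes(self) -> int:
        return len(self.gene_names)

    @property
    def n_units(self) -> int:
        return len(self.unit_names)

    def gene_index(self, genes: Sequence[str]) -> np.ndarray:
        lut = {g: i for i, g in enumerate(self.gene_names)}
        missing = [g for g in genes if g not in lut]
        if missing:
            raise KeyError(f"genes not present: {missing}")
        return np.array([lut[g] for g in genes], dtype=int)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = self.gene_index(genes)
        return ExpressionMatrix(self.values[idx], list(genes),
                                list(self.unit_names), self.layer_tag)

    def subset_units(self, units: Sequence[str]) -> "ExpressionMatrix":
        lut = {u: i for i, u in enumerate(self.unit_names)}
        missing = [u for u in units if u not in lut]
        if missing:
            raise KeyError(f"units not present: {missing}")
        idx = np.array([lut[u] for u in units], dtype=int)
        return ExpressionMatrix(self.values[:, idx], list(self.gene_names),
                                list(units), self.layer_tag)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_names,
                            columns=self.unit_names)


@dataclass
class SpatialDataset:
    """Expression plus per-unit 2-D coordinates (micrometres)."""

    expr: ExpressionMatrix
    coords: np.ndarray
    resolution: Resolution = Resolution.spot
    cells_per_spot: np.ndarray | None = None
    region_labels: list[str] | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64)
        self.resolution = Resolution(self.resolution)
        if self.coords.shape != (self.expr.n_units, 2):
            raise ValueError(
                f"coords shape {self.coords.shape} != ({self.expr.n_units}, 2)")
        if not np.isfinite(self.coords).all():
            raise ValueError("coordinates must be finite")
        if self.cells_per_spot is not None:
            self.cells_per_spot = np.asarray(self.cells_per_spot, dtype=int)
            if self.cells_per_spot.shape != (self.expr.n_units,):
                raise ValueError("cells_per_spot length mismatch")
            if (self.cells_per_spot <= 0).any():
                raise ValueError("cells_per_spot must be positive")

    @property
    def unit_names(self) -> list[str]:
        return self.expr.unit_names


@dataclass
class CellTypeAnnotation:
    """Mapping of unit names to cell-type labels with a fixed type order."""

    labels: Mapping[str, str]
    type_order: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.labels = dict(self.labels)
        if not self.type_order:
            self.type_order = sorted(set(self.labels.values()))
        else:
            _check_unique(self.type_order, "cell-type")
            extra = set(self.labels.values()) - set(self.type_order)
            if extra:
                raise ValueError(f"labels outside type_order: {sorted(extra)}")

    def labels_for(self, units: Sequence[str]) -> np.ndarray:
        missing = [u for u in units if u not in self.labels]
        if missing:
            raise KeyError(f"units without annotation: {missing[:10]}")
        return np.array([self.labels[u] for u in units], dtype=object)

    def validate_against(self, expr: ExpressionMatrix) -> None:
        extra = set(self.labels) - set(expr.unit_names)
        if extra:
            raise ValueError(
                f"annotated units absent from matrix: {sorted(extra)[:10]}")


@dataclass
class LRDatabase:
    """Ligand/receptor gene pairs, optionally tagged with a pathway."""

    pairs: list[tuple[str, str]]
    pathways: list[str] | None = None

    def __post_init__(self):
        cleaned = []
        for lig, rec in self.pairs:
            lig, rec = str(lig).strip(), str(rec).strip()
            if not lig or not rec:
                raise ValueError("empty gene symbol in L-R pair")
            cleaned.append((lig, rec))
        if len(set(cleaned)) != len(cleaned):
            raise ValueError("duplicate L-R pairs")
        self.pairs = cleaned

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)


@dataclass
class ReceptorTFNetwork:
    """Directed weighted gene network with TF flags on nodes."""

    edges: list[tuple[str, str, float]]
    tf_nodes: set[str] = field(default_factory=set)

    def __post_init__(self):
        cleaned = []
        for src, dst, w in self.edges:
            src, dst, w = str(src).strip(), str(dst).strip(), float(w)
            if w <= 0:
                raise ValueError(f"non-positive edge weight on {src}->{dst}")
            if src == dst:
                raise ValueError(f"self-loop on {src}")
            cleaned.append((src, dst, w))
        self.edges = cleaned
        self.tf_nodes = set(self.tf_nodes)

    @property
    def nodes(self) -> list[str]:
        out: list[str] = []
        seen = set()
        for s, d, _ in self.edges:
            for n in (s, d):
                if n not in seen:
                    seen.add(n)
                    out.append(n)
        return out


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def load_expression(path: str | Path, format_tag: str = "dense_tsv",
                    gene_names_path: str | Path | None = None,
                    unit_names_path: str | Path | None = None,
                    ) -> ExpressionMatrix:
    """Load a genes × units count matrix.

    ``format_tag="dense_tsv"``: tab-delimited, genes in rows (first column),
    unit names in the header. ``format_tag="matrix_market_triplet"``: a
    Matrix-Market coordinate file plus sidecar name files (one per line).
    """
    path = Path(path)
    if format_tag == "dense_tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        values = df.to_numpy(dtype=np.float64)
        genes = [str(g) for g in df.index]
        units = [str(c) for c in df.columns]
    elif format_tag == "matrix_market_triplet":
        if gene_names_path is None or unit_names_path is None:
            raise ValueError("matrix_market_triplet requires sidecar name files")
        mat = scipy.io.mmread(str(path))
        values = np.asarray(scipy.sparse.coo_matrix(mat).todense(),
                            dtype=np.float64)
        genes = Path(gene_names_path).read_text().split()
        units = Path(unit_names_path).read_text().split()
    else:
        raise ValueError(f"unknown format_tag {format_tag!r}")
    _check_unique(genes, "gene")
    if (values < 0).any():
        raise ValueError(f"negative counts in {path}")
    return ExpressionMatrix(values, genes, units, layer_tag="raw")


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="gene")


def _read_coords_table(path: str | Path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    required = {"unit", "x", "y"}
    if not required.issubset(df.columns):
        raise ValueError(f"coordinate table must have columns {sorted(required)}")
    df["unit"] = df["unit"].astype(str)
    return df


def load_spatial(expr_path: str | Path, coords_path: str | Path,
                 resolution: str | Resolution = Resolution.spot,
                 format_tag: str = "dense_tsv", **kwargs) -> SpatialDataset:
    """Load spatial expression and align coordinate rows to it by unit name."""
    expr = load_expression(expr_path, format_tag=format_tag, **kwargs)
    cdf = _read_coords_table(coords_path).set_index("unit")
    missing_in_expr = set(cdf.index) - set(expr.unit_names)
    if missing_in_expr:
        raise ValueError(
            f"units in coordinates but not expression: {sorted(missing_in_expr)}")
    missing_in_coords = set(expr.unit_names) - set(cdf.index)
    if missing_in_coords:
        raise ValueError(
            f"units missing coordinates: {sorted(missing_in_coords)}")
    coords = cdf.loc[expr.unit_names, ["x", "y"]].to_numpy(dtype=np.float64)
    cps = None
    if "cells_per_spot" in cdf.columns:
        cps = cdf.loc[expr.unit_names, "cells_per_spot"].to_numpy(dtype=int)
    return SpatialDataset(expr, coords, Resolution(resolution), cps)


def load_lr_database(path: str | Path) -> LRDatabase:
    df = pd.read_csv(path, sep="\t")
    cols = list(df.columns)
    if len(cols) < 2:
        raise ValueError("L-R table needs at least two columns")
    pairs = list(zip(df[cols[0]].astype(str), df[cols[1]].astype(str)))
    pathways = df[cols[2]].astype(str).tolist() if len(cols) > 2 else None
    return LRDatabase(pairs, pathways)


def load_network(path: str | Path,
                 tf_nodes_path: str | Path | None = None) -> ReceptorTFNetwork:
    df = pd.read_csv(path, sep="\t")
    cols = list(df.columns)
    if len(cols) < 3:
        raise ValueError("network table needs columns source, target, weight")
    edges = [(s, t, float(w)) for s, t, w in
             zip(df[cols[0]].astype(str), df[cols[1]].astype(str), df[cols[2]])]
    tfs: set[str] = set()
    if tf_nodes_path is not None:
        tfs = set(Path(tf_nodes_path).read_text().split())
    elif "is_tf" in df.columns:
        tfs = set(df.loc[df["is_tf"].astype(bool), cols[1]].astype(str))
    return ReceptorTFNetwork(edges, tfs)


def write_single_cell_map(dataset: SpatialDataset,
                          annotation: CellTypeAnnotation,
                          path: str | Path) -> None:
    """Write a placed single-cell map: `<path>.cells.tsv` (cell, x, y,
    cell_type) plus companion expression file `<path>.expr.tsv`."""
    if dataset.resolution is not Resolution.single_cell:
        raise ValueError("single-cell map requires single_cell resolution")
    labels = annotation.labels_for(dataset.unit_names)  # raises if missing
    path = Path(path)
    df = pd.DataFrame({
        "cell": dataset.unit_names,
        "x": dataset.coords[:, 0],
        "y": dataset.coords[:, 1],
        "cell_type": labels,
    })
    df.to_csv(path.with_suffix(".cells.tsv"), sep="\t", index=False,
              float_format="%.17g")
    write_expression(dataset.expr, path.with_suffix(".expr.tsv"))


def read_single_cell_map(path: str | Path,
                         ) -> tuple[SpatialDataset, CellTypeAnnotation]:
    path = Path(path)
    df = pd.read_csv(path.with_suffix(".cells.tsv"), sep="\t",
                     float_precision="round_trip")
    df["cell"] = df["cell"].astype(str)
    edf = pd.read_csv(path.with_suffix(".expr.tsv"), sep="\t", index_col=0)
    expr = ExpressionMatrix(edf.to_numpy(dtype=np.float64),
                            [str(g) for g in edf.index],
                            [str(c) for c in edf.columns],
                            layer_tag="normalized")
    expr = expr.subset_units(df["cell"].tolist())
    coords = df[["x", "y"]].to_numpy(dtype=np.float64)
    ann = CellTypeAnnotation(dict(zip(df["cell"], df["cell_type"].astype(str))))
    ds = SpatialDataset(expr, coords, Resolution.single_cell)
    return ds, ann
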