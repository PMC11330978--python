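"""Quality control, normalization, training-gene selection and
leave-one-out fold construction."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .data_model import CellTypeAnnotation, ExpressionMatrix

__all__ = [
    "QCThresholds",
    "TrainingGeneSet",
    "qc_filter",
    "normalize_counts",
    "select_training_genes",
    "loo_folds",
]

DEFAULT_MITO_PREFIXES = ("MT-", "mt-")


@dataclass
class QCThresholds:
    """Cell- and gene-level QC cutoffs.

    `max_mito_fraction` follows the 20% mitochondrial-content exclusion
    rule; count/gene ceilings default to disabled because they are
    dataset-specific.
    """

    max_mito_fraction: float = 0.20
    max_total_counts: float | None = None
    max_genes_per_cell: int | None = None
    min_cells_per_gene: int = 0
    min_genes_per_cell: int = 0

    def __post_init__(self):
        if not 0.0 <= self.max_mito_fraction <= 1.0:
            raise ValueError("max_mito_fraction must be in [0, 1]")


@dataclass
class TrainingGeneSet:
    """Deduplicated training genes plus the per-type ranked markers."""

    genes: list[str]
    per_type_markers: dict[str, list[str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.genes)


def qc_filter(matrix: ExpressionMatrix,
              mito_gene_prefixes: tuple[str, ...] = DEFAULT_MITO_PREFIXES,
              thresholds: QCThresholds | None = None) -> ExpressionMatrix:
    """Drop failing cells first, then genes below `min_cells_per_gene`.

    Cells fail on mitochondrial count fraction, total counts, or the number
    of expressed genes. Idempotent: a filtered matrix passes unchanged.
    """
    if matrix.layer_tag != "raw":
        raise ValueError("qc_filter expects raw counts")
    th = thresholds or QCThresholds()
    X = matrix.values
    mito_mask = np.array(
        [any(g.startswith(p) for p in mito_gene_prefixes)
         for g in matrix.gene_names])
    totals = X.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, X[mito_mask].sum(axis=0) / totals, 0.0)
    n_genes_per_cell = (X > 0).sum(axis=0)

    keep = mito_frac <= th.max_mito_fraction
    fail_counts = {"mito_fraction": int((~keep).sum())}
    if th.max_total_counts is not None:
        ok = totals <= th.max_total_counts
        fail_counts["total_counts"] = int((~ok).sum())
        keep &= ok
    if th.max_genes_per_cell is not None:
        ok = n_genes_per_cell <= th.max_genes_per_cell
        fail_counts["genes_per_cell_max"] = int((~ok).sum())
        keep &= ok
    if th.min_genes_per_cell > 0:
        ok = n_genes_per_cell >= th.min_genes_per_cell
        fail_counts["genes_per_cell_min"] = int((~ok).sum())
        keep &= ok
    if not keep.any():
        raise ValueError(f"all cells removed by QC; failures per criterion: "
                         f"{fail_counts}")

    units = [u for u, k in zip(matrix.unit_names, keep) if k]
    X = X[:, keep]
    gene_keep = (X > 0).sum(axis=1) >= th.min_cells_per_gene
    genes = [g for g, k in zip(matrix.gene_names, gene_keep) if k]
    return ExpressionMatrix(X[gene_keep], genes, units, layer_tag="raw")


def normalize_counts(matrix: ExpressionMatrix,
                     target_sum: float = 1e4) -> ExpressionMatrix:
    """Scale every unit (column) to a total of `target_sum`."""
    if matrix.layer_tag != "raw":
        raise ValueError("normalize_counts expects raw counts")
    totals = matrix.values.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        names = [matrix.unit_names[i] for i in zero[:10]]
        raise ValueError(f"zero-total units cannot be normalized: {names}")
    values = matrix.values / totals * target_sum
    return ExpressionMatrix(values, list(matrix.gene_names),
                            list(matrix.unit_names), layer_tag="normalized")


def _rank_sum_z(log_values: np.ndarray, in_group: np.ndarray) -> np.ndarray:
    """Vectorized one-vs-rest Wilcoxon rank-sum z per gene (tie-corrected)."""
    n1 = int(in_group.sum())
    n2 = log_values.shape[1] - n1
    ranks = np.apply_along_axis(rankdata, 1, log_values)
    rank_sum = ranks[:, in_group].sum(axis=1)
    n = n1 + n2
    mu = n1 * (n + 1) / 2.0
    # tie correction on the variance
    tie_term = np.zeros(log_values.shape[0])
    for i in range(log_values.shape[0]):
        _, counts = np.unique(log_values[i], return_counts=True)
        tie_term[i] = (counts ** 3 - counts).sum()
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(var > 0, (rank_sum - mu) / np.sqrt(var), 0.0)
    return z


def select_training_genes(sc_matrix: ExpressionMatrix,
                          sc_annotation: CellTypeAnnotation,
                          st_matrix: ExpressionMatrix,
                          n_top_per_type: int = 100) -> TrainingGeneSet:
    """Pick per-type marker genes in the dissociated data, take their
    deduplicated union, intersect with the spatial gene list, and drop any
    gene with an all-zero count in either modality.

    Markers are ranked by a one-vs-rest Wilcoxon rank-sum statistic on
    log1p-normalized values (ties broken by gene name).
    """
    if sc_matrix.layer_tag != "normalized" or st_matrix.layer_tag != "normalized":
        raise ValueError("select_training_genes expects normalized matrices")
    labels = sc_annotation.labels_for(sc_matrix.unit_names)
    types = sc_annotation.type_order
    if len([t for t in types if (labels == t).any()]) < 2:
        raise ValueError("need at least two cell types for marker selection")

    logX = np.log1p(sc_matrix.values)
    st_genes = set(st_matrix.gene_names)
    sc_nonzero = sc_matrix.values.sum(axis=1) > 0
    st_sums = dict(zip(st_matrix.gene_names, st_matrix.values.sum(axis=1)))

    per_type: dict[str, list[str]] = {}
    union: list[str] = []
    seen: set[str] = set()
    for t in types:
        in_group = labels == t
        if not in_group.any():
            continue
        z = _rank_sum_z(logX, in_group)
        order = sorted(range(sc_matrix.n_genes),
                       key=lambda i: (-z[i], sc_matrix.gene_names[i]))
        markers = [sc_matrix.gene_names[i] for i in order[:n_top_per_type]]
        per_type[t] = markers
        for g in markers:
            if g not in seen:
                seen.add(g)
                union.append(g)

    final = [g for i, g in enumerate(sc_matrix.gene_names)
             if g in seen and g in st_genes and sc_nonzero[i]
             and st_sums.get(g, 0.0) > 0]
    if not final:
        raise ValueError("no training genes survive intersection/zero filters")
    return TrainingGeneSet(final, per_type)


def loo_folds(training_genes: TrainingGeneSet | list[str],
              ) -> list[tuple[list[str], str]]:
    """Leave-one-out folds: fold k trains on all genes but gene k."""
    genes = list(training_genes.genes
                 if isinstance(training_genes, TrainingGeneSet)
                 else training_genes)
    if len(genes) < 2:
        raise ValueError("leave-one-out needs at least 2 genes")
    return [([g for g in genes if g != test], test) for test in genes]
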