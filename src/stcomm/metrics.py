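"""Benchmark metrics: per-gene PCC/SSIM/RMSE/JSD, the rank-based accuracy
score, the Wasserstein spatial-tendency ratio and the distance enrichment
score (DES)."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata, wasserstein_distance

__all__ = [
    "SpatialTendency",
    "gene_pcc",
    "gene_ssim",
    "gene_rmse",
    "gene_jsd",
    "metric_report",
    "accuracy_score",
    "wasserstein_ratio",
    "des",
]

SSIM_C1 = 0.01
SSIM_C2 = 0.03


def _as_vec(v) -> np.ndarray:
    v = np.asarray(v, dtype=np.float64)
    if v.ndim != 1:
        raise ValueError("expected a 1-D spatial expression vector")
    return v


def gene_pcc(truth, prediction) -> float:
    """Pearson correlation over spots; constant input gives 0 (warned)."""
    x, y = _as_vec(truth), _as_vec(prediction)
    if x.shape != y.shape:
        raise ValueError("vector length mismatch")
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        warnings.warn("constant vector: PCC set to 0", RuntimeWarning,
                      stacklevel=2)
        return 0.0
    return float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))


def gene_ssim(truth, prediction, c1: float = SSIM_C1,
              c2: float = SSIM_C2) -> float:
    """Single-window SSIM after scaling each vector by its own maximum.

    Uses population means/variances/covariance with stabilizers c1², c2².
    """
    x, y = _as_vec(truth), _as_vec(prediction)
    if x.shape != y.shape:
        raise ValueError("vector length mismatch")
    mx, my = x.max(), y.max()
    xs = x / mx if mx > 0 else np.zeros_like(x)
    ys = y / my if my > 0 else np.zeros_like(y)
    ux, uy = xs.mean(), ys.mean()
    vx, vy = xs.var(), ys.var()
    cov = ((xs - ux) * (ys - uy)).mean()
    num = (2 * ux * uy + c1 ** 2) * (2 * cov + c2 ** 2)
    den = (ux ** 2 + uy ** 2 + c1 ** 2) * (vx + vy + c2 ** 2)
    return float(num / den)


def _zscore(v: np.ndarray) -> np.ndarray:
    s = v.std()
    if s == 0:
        return np.zeros_like(v)
    return (v - v.mean()) / s


def gene_rmse(truth, prediction) -> float:
    """RMSE between per-gene z-scored spatial vectors (population sd)."""
    x, y = _as_vec(truth), _as_vec(prediction)
    if x.shape != y.shape:
        raise ValueError("vector length mismatch")
    return float(np.sqrt(np.mean((_zscore(y) - _zscore(x)) ** 2)))


def gene_jsd(truth, prediction) -> float:
    """Jensen-Shannon divergence (log base 2, in [0, 1]) between the
    sum-normalized spatial distributions of a gene."""
    x, y = _as_vec(truth), _as_vec(prediction)
    if x.shape != y.shape:
        raise ValueError("vector length mismatch")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("probabilities require nonnegative input")
    sx, sy = x.sum(), y.sum()
    if sx == 0 or sy == 0:
        warnings.warn("all-zero vector: JSD set to 1", RuntimeWarning,
                      stacklevel=2)
        return 1.0
    p, q = x / sx, y / sy
    m = (p + q) / 2.0

    def kl(a, b):
        mask = a > 0
        return float((a[mask] * np.log2(a[mask] / b[mask])).sum())

    return 0.5 * kl(q, m) + 0.5 * kl(p, m)


def metric_report(truth: np.ndarray, prediction: np.ndarray,
                  gene_names: list[str]) -> pd.DataFrame:
    """Per-gene metric table (rows = genes) plus an unweighted-mean
    aggregate row labeled 'AGGREGATE'. Inputs are genes × spots."""
    truth = np.asarray(truth, dtype=np.float64)
    prediction = np.asarray(prediction, dtype=np.float64)
    if truth.shape != prediction.shape or truth.shape[0] != len(gene_names):
        raise ValueError("shape mismatch between truth/prediction/genes")
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for g in range(truth.shape[0]):
            rows.append([gene_names[g],
                         gene_pcc(truth[g], prediction[g]),
                         gene_ssim(truth[g], prediction[g]),
                         gene_rmse(truth[g], prediction[g]),
                         gene_jsd(truth[g], prediction[g])])
    df = pd.DataFrame(rows, columns=["gene", "pcc", "ssim", "rmse", "jsd"])
    agg = ["AGGREGATE"] + df[["pcc", "ssim", "rmse", "jsd"]].mean().tolist()
    df.loc[len(df)] = agg
    return df


def accuracy_score(method_metrics: pd.DataFrame) -> pd.DataFrame:
    """Rank-combine per-method mean metrics into the accuracy score.

    Input rows = methods, columns pcc/ssim/rmse/jsd. PCC and SSIM are
    ranked ascending (best method gets rank N); RMSE and JSD descending
    (lowest, i.e. best, gets rank N). Ties receive average ranks. AS is
    the mean of the four ranks.
    """
    for col in ("pcc", "ssim", "rmse", "jsd"):
        if col not in method_metrics.columns:
            raise ValueError(f"missing metric column {col!r}")
    out = pd.DataFrame(index=method_metrics.index)
    out["rank_pcc"] = rankdata(method_metrics["pcc"])
    out["rank_ssim"] = rankdata(method_metrics["ssim"])
    out["rank_rmse"] = rankdata(-method_metrics["rmse"])
    out["rank_jsd"] = rankdata(-method_metrics["jsd"])
    out["AS"] = out[["rank_pcc", "rank_ssim", "rank_rmse", "rank_jsd"]].mean(axis=1)
    return out


@dataclass
class SpatialTendency:
    d_real: float
    d_simulation: np.ndarray
    d_ratio: float
    p_left: float
    p_right: float

    def __post_init__(self):
        if len(self.d_simulation) < 1:
            raise ValueError("need at least one permutation")


def _weighted_wasserstein_2d(coords_a: np.ndarray, weights_a: np.ndarray,
                             coords_b: np.ndarray, weights_b: np.ndarray,
                             ) -> float:
    """Mean of the 1-D Wasserstein distances along x and y between two
    expression-weighted empirical coordinate distributions. The single
    place defining the 2-D distance used by `wasserstein_ratio`."""
    d = 0.0
    for ax in (0, 1):
        d += wasserstein_distance(coords_a[:, ax], coords_b[:, ax],
                                  u_weights=weights_a, v_weights=weights_b)
    return d / 2.0


def wasserstein_ratio(ligand_expr, receptor_expr, coords,
                      n_perm: int = 1000, seed: int = 0) -> SpatialTendency:
    """Spatial communication tendency of an L-R pair.

    d_real is the weighted distance between the ligand- and
    receptor-expression spatial distributions; the null permutes the
    coordinates. d_ratio = d_real / mean(d_simulation); one-sided
    permutation p-values are reported for both tails (left: short-range /
    co-localization, right: long-range).
    """
    L = _as_vec(ligand_expr)
    R = _as_vec(receptor_expr)
    coords = np.asarray(coords, dtype=np.float64)
    if coords.shape != (L.size, 2) or R.size != L.size:
        raise ValueError("coords must be n × 2 matching expression length")
    if L.sum() <= 0 or R.sum() <= 0:
        raise ValueError("expression vectors must have positive mass")
    d_real = _weighted_wasserstein_2d(coords, L, coords, R)
    rng = np.random.default_rng(seed)
    sims = np.empty(n_perm)
    for t in range(n_perm):
        pl = coords[rng.permutation(L.size)]
        pr = coords[rng.permutation(L.size)]
        sims[t] = _weighted_wasserstein_2d(pl, L, pr, R)
    mean_sim = sims.mean()
    d_ratio = d_real / mean_sim if mean_sim > 0 else 0.0
    p_left = float((sims <= d_real).mean())
    p_right = float((sims >= d_real).mean())
    return SpatialTendency(float(d_real), sims, float(d_ratio),
                           p_left, p_right)


def des(expected: list[tuple[str, float]], observed: set[str]) -> float:
    """Distance enrichment score.

    `expected` is the ranked expected-interaction list as (interaction id,
    p-value) tuples; `observed` is the set of interactions a tool
    reported. Walking the expected list, a match adds its weight
    (1 - p) / sum of matched (1 - p); a miss subtracts 1/n_unmatched. The
    returned DES is the running sum's deviation of maximal magnitude from
    0 (signed: +1 when everything matches, -1 when nothing does).
    """
    if not expected:
        raise ValueError("expected list is empty")
    matched_w = sum(1.0 - p for lr, p in expected if lr in observed)
    n_unmatched = sum(1 for lr, _ in expected if lr not in observed)
    running = 0.0
    best = 0.0
    for lr, p in expected:
        if lr in observed:
            running += (1.0 - p) / matched_w if matched_w > 0 else 0.0
        else:
            running -= 1.0 / n_unmatched
        if abs(running) > abs(best):
            best = running
    return float(best)
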