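"""Gene ranking with the Welch t and Wilcoxon rank-sum filters.

Each filter scores every gene on the training portion of each of K stratified
folds; within a fold genes are ranked by descending score and receive the
Borda weight ``G - rank + 1`` (ties get the average rank). The global weight
of a gene is the sum of its K fold weights, and the final ranking is by
descending global weight. Running the filters across folds rather than once
on the full data damps the influence of any single subset of samples.

The Welch t statistic is t = (c1 - c2) / sqrt(s1^2/n + s2^2/m) with sample
variances; its filter score is |t|. The rank-sum filter counts the pairs
s = #{(i, j) : x1_j <= x0_i} over the N0 x N1 cross pairs and scores a gene
by its importance q = max(s, N0*N1 - s): q is N0*N1 for perfectly separated
classes in either direction and near N0*N1/2 for interleaved ones.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .dataset import ExpressionDataset

__all__ = [
    "TTResult",
    "WRSResult",
    "GeneScoreTable",
    "welch_t",
    "wrs_score",
    "kfold_filter_weights",
    "combine_tt_wrs",
    "select_top",
]


@dataclass
class TTResult:
    t: float
    p: float
    c1: float
    c2: float
    var1: float
    var2: float
    n: int
    m: int

    @property
    def score(self) -> float:
        """Filter score: |t|."""
        return abs(self.t)


@dataclass
class WRSResult:
    s: int
    q: int
    n0: int
    n1: int

    @property
    def score(self) -> float:
        """Filter score: the importance q."""
        return float(self.q)


@dataclass
class GeneScoreTable:
    """Per-gene fold weights, global weight and final rank."""

    gene_ids: list[str]
    fold_weights: np.ndarray  # (n_genes, K)
    weights: np.ndarray  # global weight w = fold_weights.sum(axis=1)
    ranks: np.ndarray  # permutation of 1..G, 1 = highest weight

    def ordered_gene_ids(self) -> list[str]:
        order = np.argsort(self.ranks)
        return [self.gene_ids[i] for i in order]

    def to_tsv(self, path) -> None:
        df = pd.DataFrame({"gene_id": self.gene_ids})
        df["weight"] = self.weights
        df["rank"] = self.ranks
        for k in range(self.fold_weights.shape[1]):
            df[f"fold{k + 1}_weight"] = self.fold_weights[:, k]
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def welch_t(x, y) -> TTResult:
    """Unequal-variance two-sample t with Welch–Satterthwaite two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each class needs at least 2 values")
    n, m = x.size, y.size
    c1, c2 = float(x.mean()), float(y.mean())
    v1, v2 = float(x.var(ddof=1)), float(y.var(ddof=1))
    se2 = v1 / n + v2 / m
    if se2 == 0.0:
        if c1 == c2:
            return TTResult(0.0, 1.0, c1, c2, v1, v2, n, m)
        warnings.warn("zero variance with unequal means: t is infinite")
        t = math.inf if c1 > c2 else -math.inf
        return TTResult(t, 0.0, c1, c2, v1, v2, n, m)
    t = (c1 - c2) / math.sqrt(se2)
    df = se2**2 / ((v1 / n) ** 2 / (n - 1) + (v2 / m) ** 2 / (m - 1))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return TTResult(t, p, c1, c2, v1, v2, n, m)


def wrs_score(x0, x1) -> WRSResult:
    """Rank-sum pair count s = #{(i,j): x1_j - x0_i <= 0} and q = max(s, N0*N1 - s)."""
    x0 = np.asarray(x0, dtype=float)
    x1 = np.asarray(x1, dtype=float)
    if x0.size == 0 or x1.size == 0:
        raise ValueError("both classes must be non-empty")
    s = int(np.sum(x1[None, :] <= x0[:, None]))
    q = max(s, x0.size * x1.size - s)
    return WRSResult(s, q, x0.size, x1.size)


def _tt_scores(values: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """|t| per gene, vectorized over the gene axis."""
    x = values[:, labels == 0]
    y = values[:, labels == 1]
    n, m = x.shape[1], y.shape[1]
    c1, c2 = x.mean(axis=1), y.mean(axis=1)
    v1, v2 = x.var(axis=1, ddof=1), y.var(axis=1, ddof=1)
    se2 = v1 / n + v2 / m
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (c1 - c2) / np.sqrt(se2)
    t = np.where(se2 == 0, np.where(c1 == c2, 0.0, np.inf), t)
    return np.abs(t)


def _wrs_scores(values: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """q per gene via broadcasting over the N0 x N1 pair grid."""
    x0 = values[:, labels == 0]
    x1 = values[:, labels == 1]
    n0, n1 = x0.shape[1], x1.shape[1]
    s = np.sum(x1[:, None, :] <= x0[:, :, None], axis=(1, 2))
    return np.maximum(s, n0 * n1 - s).astype(float)


_FILTERS = {"tt": _tt_scores, "wrs": _wrs_scores}


def _fold_weights_from_scores(scores: np.ndarray) -> np.ndarray:
    """Borda weight G - rank + 1 from a descending-score ranking, average ties."""
    g = scores.size
    ranks = stats.rankdata(-scores, method="average")
    return g - ranks + 1.0


def _final_ranks(weights: np.ndarray, gene_ids: list[str]) -> np.ndarray:
    """Strict 1..G ranking by descending weight, ties broken by gene id."""
    order = sorted(range(len(gene_ids)), key=lambda i: (-weights[i], gene_ids[i]))
    ranks = np.empty(len(gene_ids), dtype=int)
    for pos, i in enumerate(order):
        ranks[i] = pos + 1
    return ranks


def kfold_filter_weights(
    ds: ExpressionDataset,
    filter: str = "tt",
    K: int = 10,
    seed: int = 0,
) -> GeneScoreTable:
    """Aggregate a filter's per-fold Borda weights into global gene weights.

    Folds are stratified by class and shuffled under ``seed``; each fold's
    scores are computed on the training (K-1)/K portion. If the smaller class
    has fewer than K samples, K is reduced to that count with a warning.
    """
    if filter not in _FILTERS:
        raise ValueError(f"unknown filter {filter!r}; choose from {sorted(_FILTERS)}")
    if K < 1:
        raise ValueError("K must be >= 1")
    score_fn = _FILTERS[filter]
    min_class = int(min(np.sum(ds.labels == 0), np.sum(ds.labels == 1)))
    if K > min_class:
        warnings.warn(f"reducing folds from {K} to {min_class} (smallest class size)")
        K = min_class

    g = ds.n_genes
    fold_weights = np.empty((g, K))
    if K == 1:
        fold_weights[:, 0] = _fold_weights_from_scores(score_fn(ds.values, ds.labels))
    else:
        skf = StratifiedKFold(n_splits=K, shuffle=True, random_state=seed)
        for k, (train_idx, _test_idx) in enumerate(skf.split(ds.values.T, ds.labels)):
            scores = score_fn(ds.values[:, train_idx], ds.labels[train_idx])
            fold_weights[:, k] = _fold_weights_from_scores(scores)
    weights = fold_weights.sum(axis=1)
    return GeneScoreTable(
        list(ds.gene_ids), fold_weights, weights, _final_ranks(weights, ds.gene_ids)
    )


def _minmax(w: np.ndarray) -> np.ndarray:
    lo, hi = float(w.min()), float(w.max())
    if hi == lo:
        return np.full_like(w, 0.5)  # no information: neutral constant
    return (w - lo) / (hi - lo)


def combine_tt_wrs(table_a: GeneScoreTable, table_b: GeneScoreTable) -> GeneScoreTable:
    """Combine two rankings: mean of min-max-normalized global weights."""
    if table_a.gene_ids != table_b.gene_ids:
        raise ValueError("gene universes differ between the two tables")
    wa, wb = _minmax(table_a.weights), _minmax(table_b.weights)
    combined = (wa + wb) / 2.0
    fold_weights = np.stack([wa, wb], axis=1)
    return GeneScoreTable(
        list(table_a.gene_ids),
        fold_weights,
        combined,
        _final_ranks(combined, table_a.gene_ids),
    )


def select_top(
    table: GeneScoreTable, ds: ExpressionDataset, n: int = 200
) -> ExpressionDataset:
    """Restrict the dataset to the n highest-weight genes (ties by gene id)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > len(table.gene_ids):
        warnings.warn(
            f"requested {n} genes but only {len(table.gene_ids)} available; keeping all"
        )
        n = len(table.gene_ids)
    top = table.ordered_gene_ids()[:n]
    keep = set(top)
    # preserve the dataset's gene order among the selected genes
    ordered = [g for g in ds.gene_ids if g in keep]
    return ds.subset_genes(ordered)
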