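"""Final classification assessment and heatmap-matrix export.

Accuracy = (TP + TN) / (TP + TN + FN + FP) and precision = TP / (TP + FP),
reported as percentages. The evaluation repeats stratified K-fold CV,
pools the per-fold confusion counts, and reports mean +/- sd accuracy across
folds together with pooled precision. The positive class defaults to class 1
(the second, "disease" class of the spec), configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import DatasetError, ExpressionDataset
from .gbpso import SvmConfig, _cv_splitter

__all__ = [
    "ConfusionCounts",
    "EvaluationReport",
    "accuracy",
    "precision",
    "evaluate_subset",
    "heatmap_matrix",
]


@dataclass
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn, self.fp + other.fp, self.fn + other.fn
        )


def accuracy(c: ConfusionCounts) -> float:
    """(TP + TN) / all, as a fraction."""
    if c.total == 0:
        raise ValueError("no evaluated samples")
    return (c.tp + c.tn) / c.total


def precision(c: ConfusionCounts) -> float | None:
    """TP / (TP + FP) as a fraction; None when no positive predictions exist."""
    if c.tp + c.fp == 0:
        return None
    return c.tp / (c.tp + c.fp)


@dataclass
class EvaluationReport:
    """CV assessment of a gene subset, percentages on the 0-100 scale."""

    accuracy_pct: float
    accuracy_sd_pct: float
    precision_pct: float | None
    fold_counts: list[ConfusionCounts]
    n_selected_genes: int
    positive_class: int = 1

    @property
    def pooled_counts(self) -> ConfusionCounts:
        total = ConfusionCounts()
        for c in self.fold_counts:
            total = total + c
        return total

    def to_tsv(self, path) -> None:
        rows = [
            (i + 1, c.tp, c.tn, c.fp, c.fn, 100.0 * accuracy(c))
            for i, c in enumerate(self.fold_counts)
        ]
        df = pd.DataFrame(rows, columns=["fold", "TP", "TN", "FP", "FN", "accuracy_pct"])
        df.to_csv(path, sep="\t", index=False, float_format="%.4f")

    def summary(self) -> str:
        prec = "n/a" if self.precision_pct is None else f"{self.precision_pct:.2f}%"
        return (
            f"genes selected : {self.n_selected_genes}\n"
            f"accuracy       : {self.accuracy_pct:.2f}% +/- {self.accuracy_sd_pct:.2f}\n"
            f"precision      : {prec} (positive class = {self.positive_class})"
        )


def _fold_confusion(y_true, y_pred, positive: int) -> ConfusionCounts:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pos_t, pos_p = y_true == positive, y_pred == positive
    return ConfusionCounts(
        tp=int(np.sum(pos_t & pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
    )


def evaluate_subset(
    ds: ExpressionDataset,
    mask,
    svm: SvmConfig | None = None,
    repeats: int = 1,
    seed: int = 0,
    positive_class: int = 1,
) -> EvaluationReport:
    """Repeated stratified K-fold CV of the SVM on the masked genes.

    Repeat r shifts the fold seed to ``seed + r``, so ``repeats=1`` with the
    wrapper's CV seed scores the identical folds the wrapper used. Accuracy
    is the mean (+/- sd) over all folds of all repeats; precision is computed
    from the pooled confusion counts.
    """
    svm = svm or SvmConfig()
    mask = np.asarray(mask, dtype=bool)
    if mask.size != ds.n_genes:
        raise ValueError("mask length must equal the gene count")
    if not mask.any():
        raise ValueError("cannot evaluate an empty gene subset")
    X = ds.values[mask, :].T
    y = ds.labels
    fold_counts: list[ConfusionCounts] = []
    for r in range(repeats):
        skf = _cv_splitter(y, svm.cv_folds, seed + r)
        for train_idx, test_idx in skf.split(X, y):
            clf = svm.classifier()
            clf.fit(X[train_idx], y[train_idx])
            pred = clf.predict(X[test_idx])
            fold_counts.append(_fold_confusion(y[test_idx], pred, positive_class))
    fold_accs = np.array([accuracy(c) for c in fold_counts])
    pooled = ConfusionCounts()
    for c in fold_counts:
        pooled = pooled + c
    prec = precision(pooled)
    return EvaluationReport(
        accuracy_pct=100.0 * float(fold_accs.mean()),
        accuracy_sd_pct=100.0 * float(fold_accs.std(ddof=0)),
        precision_pct=None if prec is None else 100.0 * prec,
        fold_counts=fold_counts,
        n_selected_genes=int(mask.sum()),
        positive_class=positive_class,
    )


def heatmap_matrix(
    ds: ExpressionDataset,
    gene_ids: list[str],
    path=None,
    scale: bool = False,
    image_path=None,
) -> pd.DataFrame:
    """Genes x samples matrix of the selected genes, class 0 samples first.

    With ``scale=True`` each non-constant row is min-max scaled to [0, 1].
    ``path`` writes a TSV; ``image_path`` renders a PNG (cosmetic only).
    """
    unknown = [g for g in gene_ids if g not in ds.gene_ids]
    if unknown:
        raise DatasetError(f"unknown gene ids: {unknown}")
    order = np.argsort(ds.labels, kind="stable")
    sub = ds.subset_genes(list(gene_ids))
    mat = sub.values[:, order]
    if scale:
        lo = mat.min(axis=1, keepdims=True)
        rng = mat.max(axis=1, keepdims=True) - lo
        nonconst = rng[:, 0] > 0
        mat = np.where(nonconst[:, None], (mat - lo) / np.where(rng == 0, 1, rng), mat)
    df = pd.DataFrame(
        mat, index=gene_ids, columns=[ds.sample_ids[i] for i in order]
    )
    if path is not None:
        df.to_csv(path, sep="\t", float_format="%.6g")
    if image_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(max(6, len(df.columns) / 4), max(2, len(gene_ids) / 2)))
        im = ax.imshow(df.values, aspect="auto", cmap="viridis")
        ax.set_yticks(range(len(gene_ids)), gene_ids)
        ax.set_xlabel("samples (class 0 then class 1)")
        fig.colorbar(im, ax=ax, label="expression")
        fig.tight_layout()
        fig.savefig(image_path, dpi=120)
        plt.close(fig)
    return df
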