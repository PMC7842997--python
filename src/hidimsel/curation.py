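"""Dimensionality reduction by removing near-unity mean/median-ratio genes.

A gene whose class-wise central tendency is essentially the same in both
classes carries no class signal. For each gene a dispersion statistic (the
coefficient of variation over all samples) decides the criterion: genes with
dispersion >= 15% are compared by their class medians (robust to the very
spread that inflates the mean), the rest by their class means. The gene is
removed when the ratio of the two class statistics falls inside the
near-unity band [0.95, 1/0.95], endpoints included.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import DatasetError, ExpressionDataset

__all__ = [
    "CurationConfig",
    "CurationReport",
    "gene_dispersion",
    "curation_ratio",
    "curate",
]


@dataclass
class CurationConfig:
    """Band and dispersion settings for gene curation.

    dispersion_threshold : CV fraction at or above which the median criterion
        is used instead of the mean (default 0.15, i.e. 15%).
    band_low / band_high : the removal band around ratio 1
        (defaults 0.95 and 1/0.95; ``band_high`` must equal ``1/band_low`` so
        the band is symmetric under swapping the two classes).
    """

    dispersion_threshold: float = 0.15
    band_low: float = 0.95
    band_high: float = 1.0 / 0.95

    def __post_init__(self) -> None:
        if not (0 < self.band_low < 1 < self.band_high):
            raise ValueError("need 0 < band_low < 1 < band_high")
        if not math.isclose(self.band_high, 1.0 / self.band_low, rel_tol=1e-9):
            raise ValueError("band_high must equal 1/band_low")
        if self.dispersion_threshold < 0:
            raise ValueError("dispersion_threshold must be >= 0")


@dataclass
class CurationReport:
    """Per-gene curation record plus before/after counts."""

    records: pd.DataFrame  # columns: gene_id, criterion, dispersion, ratio, verdict
    before_count: int
    keep_count: int

    @property
    def remove_count(self) -> int:
        return self.before_count - self.keep_count

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False, float_format="%.6g")


def gene_dispersion(values) -> float:
    """Coefficient of variation std/|mean| of a gene's expression vector.

    Sample (ddof=1) standard deviation. Zero spread gives 0; zero mean with
    nonzero spread gives +inf.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values for dispersion")
    sd = float(np.std(v, ddof=1))
    if sd == 0.0:
        return 0.0
    mean = float(np.mean(v))
    if mean == 0.0:
        return math.inf
    return sd / abs(mean)


def curation_ratio(class1_values, class2_values, criterion: str) -> float:
    """Ratio of the class statistics (mean or median), class 1 over class 2.

    Sign handling: opposite-sign statistics return the (negative) signed
    ratio, which can never fall in the removal band — such genes are clearly
    differential. Both-negative statistics use absolute values. A zero
    denominator with nonzero numerator gives +inf (maximal dissimilarity);
    0/0 gives 1 (identical).
    """
    if criterion not in ("mean", "median"):
        raise ValueError(f"criterion must be 'mean' or 'median', got {criterion!r}")
    c1 = np.asarray(class1_values, dtype=float)
    c2 = np.asarray(class2_values, dtype=float)
    if c1.size == 0 or c2.size == 0:
        raise ValueError("both classes must be non-empty")
    stat = np.mean if criterion == "mean" else np.median
    s1, s2 = float(stat(c1)), float(stat(c2))
    if s1 == 0.0 and s2 == 0.0:
        return 1.0
    if s2 == 0.0:
        return math.inf
    if s1 * s2 < 0:
        return s1 / s2  # negative: outside any near-unity band
    if s1 < 0:  # both negative
        return abs(s1) / abs(s2)
    return s1 / s2


def curate(
    ds: ExpressionDataset, cfg: CurationConfig | None = None
) -> tuple[ExpressionDataset, CurationReport]:
    """Remove genes whose class-statistic ratio lies in the near-unity band.

    Returns the reduced dataset (gene order preserved) and the full report.
    Raises if every gene would be removed.
    """
    cfg = cfg or CurationConfig()
    x0 = ds.class_values(0)
    x1 = ds.class_values(1)
    rows = []
    keep_ids = []
    for i, gid in enumerate(ds.gene_ids):
        disp = gene_dispersion(ds.values[i, :])
        criterion = "median" if disp >= cfg.dispersion_threshold else "mean"
        ratio = curation_ratio(x0[i, :], x1[i, :], criterion)
        remove = cfg.band_low <= ratio <= cfg.band_high
        if not remove:
            keep_ids.append(gid)
        rows.append((gid, criterion, disp, ratio, "remove" if remove else "keep"))
    report = CurationReport(
        records=pd.DataFrame(
            rows, columns=["gene_id", "criterion", "dispersion", "ratio", "verdict"]
        ),
        before_count=ds.n_genes,
        keep_count=len(keep_ids),
    )
    if not keep_ids:
        raise DatasetError(
            "curation removed every gene; relax the band or dispersion threshold"
        )
    return ds.subset_genes(keep_ids), report
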