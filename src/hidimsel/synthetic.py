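"""Synthetic two-class expression data with planted differential genes.

The generator emulates a curated intensity matrix: background genes are
log-normal positive values drawn identically in both classes, a chosen few
"informative" genes receive an additive class-1 shift of ``effect_size``
standard deviations, and a fraction of genes are noisy duplicates of other
genes (the redundancy that curation and filtering are meant to squash).
Ground truth (the informative gene ids) is returned alongside the dataset so
recovery tests are self-validating. A serializer writes the same data as a
minimal valid GDS SOFT block for exercising the SOFT reader.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import ExpressionDataset

__all__ = ["SyntheticSpec", "make_dataset", "make_soft_fixture", "write_truth_sidecar"]


@dataclass
class SyntheticSpec:
    """Parameters of the planted-gene generator.

    effect_size is the standardized mean difference (in units of the
    background standard deviation) added to class-1 samples of informative
    genes. base_mean is the log-normal median intensity; base_sd the sigma of
    the underlying normal (0.25 gives a mildly skewed, positive intensity
    distribution with CV ~ 25%).
    """

    n_genes: int = 1000
    n_samples_per_class: int = 30
    n_informative: int = 5
    effect_size: float = 3.0
    base_mean: float = 100.0
    base_sd: float = 0.25
    redundant_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.n_informative > self.n_genes:
            raise ValueError("n_informative cannot exceed n_genes")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not 0 <= self.redundant_fraction < 1:
            raise ValueError("redundant_fraction must be in [0, 1)")
        if self.n_samples_per_class < 2:
            raise ValueError("need at least 2 samples per class")


def make_dataset(spec: SyntheticSpec) -> tuple[ExpressionDataset, list[str]]:
    """Generate a dataset and the list of planted informative gene ids.

    Samples are ordered class 0 first, then class 1. Informative genes are
    the first ``n_informative`` gene ids (``g0001`` ...); redundant genes are
    jittered copies of randomly chosen non-redundant genes and occupy the
    tail of the gene list.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples_per_class
    n_red = int(round(spec.redundant_fraction * spec.n_genes))
    n_base = spec.n_genes - n_red
    if n_base < spec.n_informative:
        raise ValueError("too few non-redundant genes for the requested informative count")

    # log-normal background: median base_mean, underlying sigma base_sd
    values = spec.base_mean * np.exp(spec.base_sd * rng.standard_normal((n_base, 2 * n)))
    # analytic sd of that log-normal, used to express the shift in sd units
    s2 = spec.base_sd**2
    bg_sd = spec.base_mean * np.exp(s2 / 2.0) * np.sqrt(np.exp(s2) - 1.0)
    values[: spec.n_informative, n:] += spec.effect_size * bg_sd

    if n_red > 0:
        src = rng.integers(0, n_base, size=n_red)
        jitter = 0.05 * spec.base_mean * rng.standard_normal((n_red, 2 * n))
        values = np.vstack([values, values[src, :] + jitter])

    width = len(str(spec.n_genes))
    gene_ids = [f"g{i + 1:0{width}d}" for i in range(spec.n_genes)]
    sample_ids = [f"A{i + 1}" for i in range(n)] + [f"B{i + 1}" for i in range(n)]
    labels = np.array([0] * n + [1] * n)
    ds = ExpressionDataset(gene_ids, sample_ids, values, labels, ("control", "case"))
    return ds, gene_ids[: spec.n_informative]


def write_truth_sidecar(truth_ids: list[str], path) -> None:
    """Two-column TSV (gene_id, role) recording the planted ground truth."""
    with open(path, "w") as fh:
        fh.write("gene_id\trole\n")
        for g in truth_ids:
            fh.write(f"{g}\tinformative\n")


def make_soft_fixture(
    spec: SyntheticSpec, path, null_rate: float = 0.0
) -> tuple[ExpressionDataset, list[str]]:
    """Serialize a generated dataset as a minimal GDS SOFT table block.

    ``null_rate`` independently replaces each expression cell with the
    literal ``null`` (exercising the reader's missing-value policy). Returns
    the source dataset and truth ids; the file's sample columns are GSM ids
    in class order, so the matching class spec is ``1-n;n+1-2n``.
    """
    if spec.n_genes < 1:
        raise ValueError("zero genes requested")
    ds, truth = make_dataset(spec)
    rng = np.random.default_rng(spec.seed + 1)
    nulls = rng.random(ds.values.shape) < null_rate if null_rate > 0 else None
    with open(path, "w") as fh:
        fh.write("^DATASET = synthetic\n")
        fh.write("!dataset_title = synthetic planted-gene fixture\n")
        fh.write("!dataset_table_begin\n")
        gsm = [f"GSM{i + 1:04d}" for i in range(ds.n_samples)]
        fh.write("ID_REF\tIDENTIFIER\t" + "\t".join(gsm) + "\n")
        for i, gid in enumerate(ds.gene_ids):
            cells = []
            for j in range(ds.n_samples):
                if nulls is not None and nulls[i, j]:
                    cells.append("null")
                else:
                    cells.append(f"{ds.values[i, j]:.6g}")
            fh.write(f"{gid}\t{gid}\t" + "\t".join(cells) + "\n")
        fh.write("!dataset_table_end\n")
    return ds, truth
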