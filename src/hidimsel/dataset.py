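"""Two-class expression datasets and their on-disk formats.

The in-memory container is :class:`ExpressionDataset`: a genes x samples real
matrix with gene identifiers, sample identifiers and a binary class label per
sample. On disk two formats are supported:

* curated CSV — samples as rows, genes as columns, the last column holding the
  class label (the machine-learning convention);
* raw GEO SOFT GDS files — the ``!dataset_table_begin`` … ``!dataset_table_end``
  expression block, with the two class membership ranges supplied by the user
  (GDS files carry no per-sample class annotation).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "SoftClassSpec",
    "DatasetError",
    "read_csv_dataset",
    "read_soft_gds",
    "write_dataset_csv",
    "write_gene_list",
]

SAMPLE_ID_HEADERS = {"", "sample_id", "sample", "id", "unnamed: 0"}


class DatasetError(ValueError):
    """Raised for malformed or degenerate dataset inputs."""


@dataclass
class ExpressionDataset:
    """A two-class expression matrix.

    Parameters
    ----------
    gene_ids : list of str
        Unique gene (or probe) identifiers, one per matrix row.
    sample_ids : list of str
        Unique sample identifiers, one per matrix column.
    values : ndarray of shape (n_genes, n_samples)
        Real expression values.
    labels : ndarray of int
        Per-sample class in {0, 1}; both classes must hold >= 2 samples.
    class_names : tuple of (str, str)
        Display names for class 0 and class 1.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    labels: np.ndarray
    class_names: tuple[str, str] = ("class0", "class1")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise DatasetError("expression values must be a 2-D matrix")
        n_genes, n_samples = self.values.shape
        if n_genes != len(self.gene_ids):
            raise DatasetError(
                f"matrix has {n_genes} rows but {len(self.gene_ids)} gene ids"
            )
        if n_samples != len(self.sample_ids) or n_samples != len(self.labels):
            raise DatasetError("sample ids / labels do not match matrix columns")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise DatasetError("gene ids are not unique")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DatasetError("duplicate sample ids")
        present = set(np.unique(self.labels).tolist())
        if present != {0, 1}:
            raise DatasetError(
                f"labels must contain exactly the classes {{0, 1}}, got {sorted(present)}"
            )
        for k in (0, 1):
            if int(np.sum(self.labels == k)) < 2:
                raise DatasetError(f"class {k} has fewer than 2 samples")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def class_values(self, k: int) -> np.ndarray:
        """Sub-matrix (genes x n_k) of the samples in class ``k``."""
        return self.values[:, self.labels == k]

    def subset_genes(self, gene_ids: list[str]) -> "ExpressionDataset":
        """Restrict to ``gene_ids`` (kept in the given order)."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in index]
        if missing:
            raise DatasetError(f"unknown gene ids: {missing}")
        rows = [index[g] for g in gene_ids]
        return ExpressionDataset(
            list(gene_ids),
            list(self.sample_ids),
            self.values[rows, :],
            self.labels.copy(),
            self.class_names,
        )

    def equals(self, other: "ExpressionDataset", rtol: float = 1e-9) -> bool:
        return (
            self.gene_ids == other.gene_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.labels, other.labels)
            and self.class_names == other.class_names
            and np.allclose(self.values, other.values, rtol=rtol, atol=1e-12)
        )


@dataclass
class SoftClassSpec:
    """User-supplied class membership for a GDS SOFT file.

    Ranges are 1-based inclusive intervals over the *sample* columns of the
    expression table (ID_REF and IDENTIFIER excluded), in table order.
    """

    class1_range: list[tuple[int, int]]
    class2_range: list[tuple[int, int]]
    names: tuple[str, str] = ("class1", "class2")

    def __post_init__(self) -> None:
        for rng in (self.class1_range, self.class2_range):
            if not rng:
                raise DatasetError("both classes need at least one interval")
            for lo, hi in rng:
                if lo < 1 or hi < lo:
                    raise DatasetError(f"bad 1-based interval ({lo}, {hi})")
        c1, c2 = set(self.columns(0)), set(self.columns(1))
        if c1 & c2:
            raise DatasetError(f"class ranges overlap at columns {sorted(c1 & c2)}")

    def columns(self, k: int) -> list[int]:
        """1-based sample-column indices of class ``k`` in interval order."""
        rng = self.class1_range if k == 0 else self.class2_range
        out: list[int] = []
        for lo, hi in rng:
            out.extend(range(lo, hi + 1))
        return out

    @classmethod
    def parse(cls, text: str, names: tuple[str, str] = ("class1", "class2")) -> "SoftClassSpec":
        """Parse ``"1-35;36-48"`` (classes split by ``;``, intervals by ``,``)."""
        parts = text.split(";")
        if len(parts) != 2:
            raise DatasetError("class spec must have exactly two ';'-separated ranges")

        def intervals(s: str) -> list[tuple[int, int]]:
            out = []
            for chunk in s.split(","):
                chunk = chunk.strip()
                m = re.fullmatch(r"(\d+)(?:-(\d+))?", chunk)
                if not m:
                    raise DatasetError(f"bad interval {chunk!r}")
                lo = int(m.group(1))
                hi = int(m.group(2)) if m.group(2) else lo
                out.append((lo, hi))
            return out

        return cls(intervals(parts[0]), intervals(parts[1]), names)


def read_csv_dataset(path, label_column: str | None = None) -> ExpressionDataset:
    """Read a curated CSV dataset (samples as rows, label in the last column).

    The label column (last column, or ``label_column`` by name) must contain
    exactly two distinct values; the first-appearing value maps to class 0.
    A leading sample-id column is detected by header name; otherwise sample
    ids ``S1..Sn`` are generated in row order.
    """
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except FileNotFoundError:
        raise DatasetError(f"no such file: {path}") from None
    if df.shape[0] < 2:
        raise DatasetError("need at least 2 data rows")

    if str(df.columns[0]).strip().lower() in SAMPLE_ID_HEADERS:
        sample_ids = df.iloc[:, 0].astype(str).tolist()
        df = df.iloc[:, 1:]
    else:
        sample_ids = [f"S{i + 1}" for i in range(df.shape[0])]

    if label_column is None:
        label_column = df.columns[-1]
    if label_column not in df.columns:
        raise DatasetError(f"label column {label_column!r} not found")
    raw_labels = df[label_column].astype(str).tolist()
    classes = list(dict.fromkeys(raw_labels))  # first-appearance order
    if len(classes) != 2:
        raise DatasetError(
            f"label column must have exactly 2 distinct values, got {len(classes)}"
        )
    labels = np.array([classes.index(v) for v in raw_labels], dtype=int)

    expr = df.drop(columns=[label_column])
    gene_ids = [str(c) for c in expr.columns]
    values = np.empty((len(gene_ids), len(sample_ids)), dtype=float)
    for j, g in enumerate(gene_ids):
        for i, cell in enumerate(expr[g].tolist()):
            try:
                values[j, i] = float(cell)
            except ValueError:
                raise DatasetError(
                    f"non-numeric expression value {cell!r} at row {i + 1}, column {g!r}"
                ) from None
    return ExpressionDataset(gene_ids, sample_ids, values, labels, (classes[0], classes[1]))


@dataclass
class SoftParseLog:
    """Per-row events from SOFT parsing (drops, imputations, renames)."""

    lines: list[str] = field(default_factory=list)

    def dropped(self, gene_id: str, reason: str) -> None:
        self.lines.append(f"DROPPED {gene_id} {reason}")

    def note(self, text: str) -> None:
        self.lines.append(text)

    @property
    def n_dropped(self) -> int:
        return sum(1 for ln in self.lines if ln.startswith("DROPPED "))


def read_soft_gds(
    path,
    classes: SoftClassSpec,
    missing_policy: str = "drop",
) -> tuple[ExpressionDataset, SoftParseLog]:
    """Read the expression table of a full-SOFT GDS file.

    Genes are the table rows keyed by ``ID_REF``; samples are the columns
    selected by ``classes`` (1-based over sample columns, class 1 first).
    ``missing_policy`` is ``"drop"`` (default: remove the gene row, log it) or
    ``"impute"`` (replace with the per-gene mean of the selected samples).
    """
    if missing_policy not in ("drop", "impute"):
        raise DatasetError(f"unknown missing policy {missing_policy!r}")
    try:
        with open(path) as fh:
            text = fh.read()
    except FileNotFoundError:
        raise DatasetError(f"no such file: {path}") from None

    lines = text.splitlines()
    try:
        begin = next(i for i, ln in enumerate(lines) if ln.startswith("!dataset_table_begin"))
        end = next(i for i, ln in enumerate(lines) if ln.startswith("!dataset_table_end"))
    except StopIteration:
        raise DatasetError("missing !dataset_table_begin/!dataset_table_end delimiters") from None
    if end <= begin + 1:
        raise DatasetError("empty dataset table")

    header = lines[begin + 1].split("\t")
    if len(header) < 3 or header[0] != "ID_REF" or header[1] != "IDENTIFIER":
        raise DatasetError("table header must start with ID_REF, IDENTIFIER, then samples")
    sample_columns = header[2:]

    log = SoftParseLog()
    cols_by_class = [classes.columns(0), classes.columns(1)]
    for k, cols in enumerate(cols_by_class):
        for c in cols:
            if c > len(sample_columns):
                raise DatasetError(
                    f"class range column {c} exceeds the {len(sample_columns)} sample columns"
                )
        if not cols:
            raise DatasetError(f"class {k + 1} is empty after range resolution")
    selected = cols_by_class[0] + cols_by_class[1]
    labels = np.array([0] * len(cols_by_class[0]) + [1] * len(cols_by_class[1]), dtype=int)
    sample_ids = [sample_columns[c - 1] for c in selected]

    gene_ids: list[str] = []
    rows: list[np.ndarray] = []
    seen: dict[str, int] = {}
    for ln in lines[begin + 2 : end]:
        if not ln.strip():
            continue
        fields = ln.split("\t")
        gid = fields[0]
        if gid in seen:
            seen[gid] += 1
            new_gid = f"{gid}#{seen[gid]}"
            log.note(f"RENAMED {gid} -> {new_gid} (duplicate ID_REF)")
            gid = new_gid
        else:
            seen[gid] = 0
        vals = np.full(len(selected), np.nan)
        for out_i, c in enumerate(selected):
            idx = 2 + c - 1
            cell = fields[idx].strip() if idx < len(fields) else ""
            if cell and cell.lower() not in ("null", "na", "nan"):
                try:
                    vals[out_i] = float(cell)
                except ValueError:
                    pass
        if np.isnan(vals).any():
            if missing_policy == "drop":
                log.dropped(gid, "missing or unparseable value")
                continue
            finite = vals[~np.isnan(vals)]
            if finite.size == 0:
                log.dropped(gid, "no parseable values")
                continue
            vals = np.where(np.isnan(vals), finite.mean(), vals)
            log.note(f"IMPUTED {gid} per-gene mean")
        gene_ids.append(gid)
        rows.append(vals)

    if not rows:
        raise DatasetError("no gene rows survived parsing")
    ds = ExpressionDataset(
        gene_ids, sample_ids, np.vstack(rows), labels, classes.names
    )
    return ds, log


def write_dataset_csv(ds: ExpressionDataset, path) -> None:
    """Write samples-as-rows CSV: sample_id, one column per gene, label last."""
    if ds.n_genes == 0:
        raise DatasetError("refusing to write a dataset with zero genes")
    df = pd.DataFrame(ds.values.T, columns=ds.gene_ids)
    df.insert(0, "sample_id", ds.sample_ids)
    df["label"] = [ds.class_names[k] for k in ds.labels]
    df.to_csv(path, index=False, float_format="%.12g")


def write_gene_list(gene_ids, scores, path) -> None:
    """Two-column CSV (gene_id, score) in descending-score order, ties by id."""
    pairs = sorted(zip(gene_ids, scores), key=lambda p: (-float(p[1]), str(p[0])))
    df = pd.DataFrame(pairs, columns=["gene_id", "score"])
    df.to_csv(path, index=False, float_format="%.12g")
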