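"""Expression-table I/O, label handling, standardization and train/test splitting.

The on-disk convention is plain delimited text: an expression matrix with one
header row and one identifier column (TSV or CSV, auto-detected from the file
extension), plus a two-column label file mapping sample id to class.  All
matrices are held in memory as ``numpy`` arrays oriented samples x genes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "SplitSpec",
    "read_expression_table",
    "write_expression_table",
    "split_train_test",
    "write_results",
    "standardize_fit",
    "standardize_apply",
]

#: floor applied to per-gene standard deviations so constant genes do not
#: produce infinities under z-scoring
SD_FLOOR = 1e-12


@dataclass
class ExpressionDataset:
    """An n x d expression matrix with sample/gene identifiers and binary labels.

    Labels are stored as {0, 1}; the signed {-1, +1} encoding used by the
    logistic loss is exposed through :attr:`y_signed`.
    """

    matrix: np.ndarray
    sample_ids: list[str]
    gene_ids: list[str]
    labels: np.ndarray
    class_names: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if self.matrix.ndim != 2:
            raise ValueError("expression matrix must be 2-dimensional")
        n, d = self.matrix.shape
        if len(self.sample_ids) != n or len(self.labels) != n:
            raise ValueError(
                f"matrix has {n} rows but {len(self.sample_ids)} sample ids "
                f"and {len(self.labels)} labels"
            )
        if len(self.gene_ids) != d:
            raise ValueError(
                f"matrix has {d} columns but {len(self.gene_ids)} gene ids"
            )
        if len(set(self.gene_ids)) != d:
            raise ValueError("gene ids must be unique")
        if not np.isfinite(self.matrix).all():
            raise ValueError("expression matrix contains non-finite values")
        distinct = set(np.unique(self.labels).tolist())
        if not distinct <= {0, 1}:
            raise ValueError(f"labels must be in {{0, 1}}, got {sorted(distinct)}")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def d(self) -> int:
        return self.matrix.shape[1]

    @property
    def y_signed(self) -> np.ndarray:
        """Labels mapped 0 -> -1, 1 -> +1, as used by the logistic loss."""
        return 2 * self.labels - 1

    def subset(self, idx: np.ndarray) -> "ExpressionDataset":
        """Row-subset the dataset by sample indices (order preserved)."""
        idx = np.asarray(idx, dtype=int)
        return ExpressionDataset(
            matrix=self.matrix[idx],
            sample_ids=[self.sample_ids[i] for i in idx],
            gene_ids=list(self.gene_ids),
            labels=self.labels[idx],
            class_names=self.class_names,
        )


@dataclass(frozen=True)
class SplitSpec:
    """How to split a dataset into train and test parts."""

    train_fraction: float
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie strictly between 0 and 1")


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression_table(
    path: str | Path,
    orientation: str = "samples_by_genes",
    label_path: str | Path | None = None,
) -> ExpressionDataset:
    """Read a delimited expression table plus a label file.

    Parameters
    ----------
    path
        Delimited text file with one header row and one identifier column.
        ``.csv`` files are comma-separated, anything else tab-separated.
    orientation
        ``"samples_by_genes"`` (rows are samples) or ``"genes_by_samples"``
        (rows are genes; the matrix is transposed on load).
    label_path
        Two-column file ``sample_id<sep>class``; a header line is tolerated.
        The lexicographically smaller class name maps to label 0.
    """
    path = Path(path)
    if orientation not in ("samples_by_genes", "genes_by_samples"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if orientation == "genes_by_samples":
        df = df.T
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric cells in expression table {path}") from exc
    sample_ids = [str(s) for s in df.index]
    gene_ids = [str(g) for g in df.columns]

    if label_path is None:
        raise ValueError("a label file is required")
    label_path = Path(label_path)
    lab = pd.read_csv(
        label_path, sep=_sep_for(label_path), header=None, dtype=str
    )
    if lab.shape[1] != 2:
        raise ValueError("label file must have exactly two columns")
    # tolerate a header line: drop the first row if its id is not a sample id
    if lab.iloc[0, 0] not in set(sample_ids):
        lab = lab.iloc[1:]
    mapping = dict(zip(lab.iloc[:, 0], lab.iloc[:, 1]))
    missing = [s for s in sample_ids if s not in mapping]
    if missing:
        raise ValueError(f"label file missing sample ids: {missing[:5]}")
    classes = sorted(set(mapping[s] for s in sample_ids))
    if len(classes) > 2:
        raise ValueError(f"more than two classes in labels: {classes}")
    class_to_int = {c: i for i, c in enumerate(classes)}
    labels = np.array([class_to_int[mapping[s]] for s in sample_ids], dtype=int)
    class_names = tuple(classes) if len(classes) == 2 else (classes[0], classes[0])
    return ExpressionDataset(values, sample_ids, gene_ids, labels, class_names)


def write_expression_table(
    ds: ExpressionDataset,
    path: str | Path,
    label_path: str | Path | None = None,
    orientation: str = "samples_by_genes",
    float_format: str = "%.10g",
) -> None:
    """Write a dataset in the format :func:`read_expression_table` consumes."""
    path = Path(path)
    df = pd.DataFrame(ds.matrix, index=ds.sample_ids, columns=ds.gene_ids)
    if orientation == "genes_by_samples":
        df = df.T
    df.to_csv(path, sep=_sep_for(path), float_format=float_format)
    if label_path is not None:
        label_path = Path(label_path)
        names = ds.class_names or ("0", "1")
        with open(label_path, "w") as fh:
            for sid, lab in zip(ds.sample_ids, ds.labels):
                fh.write(f"{sid}\t{names[lab]}\n")


def _stratified_counts(class_sizes: Sequence[int], fraction: float) -> list[int]:
    # round per class; each class keeps >=1 sample on both sides
    out = []
    for nc in class_sizes:
        k = int(round(fraction * nc))
        k = min(max(k, 1), nc - 1)
        out.append(k)
    return out


def split_train_test(
    ds: ExpressionDataset, spec: SplitSpec
) -> tuple[ExpressionDataset, ExpressionDataset]:
    """Deterministic train/test partition; stratified by class by default."""
    rng = np.random.default_rng(spec.seed)
    n = ds.n
    if spec.stratified:
        classes = np.unique(ds.labels)
        for c in classes:
            if int((ds.labels == c).sum()) < 2:
                raise ValueError(
                    f"class {c} has fewer than 2 samples; cannot stratify"
                )
        train_idx_parts = []
        test_idx_parts = []
        sizes = [int((ds.labels == c).sum()) for c in classes]
        takes = _stratified_counts(sizes, spec.train_fraction)
        for c, k in zip(classes, takes):
            members = np.flatnonzero(ds.labels == c)
            perm = rng.permutation(members)
            train_idx_parts.append(perm[:k])
            test_idx_parts.append(perm[k:])
        train_idx = np.sort(np.concatenate(train_idx_parts))
        test_idx = np.sort(np.concatenate(test_idx_parts))
    else:
        k = int(round(spec.train_fraction * n))
        k = min(max(k, 1), n - 1)
        perm = rng.permutation(n)
        train_idx = np.sort(perm[:k])
        test_idx = np.sort(perm[k:])
    return ds.subset(train_idx), ds.subset(test_idx)


def standardize_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene mean and SD (population, floored at :data:`SD_FLOOR`)."""
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale = np.maximum(scale, SD_FLOOR)
    return mean, scale


def standardize_apply(
    X: np.ndarray, mean: np.ndarray, scale: np.ndarray
) -> np.ndarray:
    return (X - mean) / scale


def write_results(
    selection,
    gene_ids: Sequence[str],
    metrics: dict,
    genes_path: str | Path,
    metrics_path: str | Path,
) -> None:
    """Write a ranked gene list (TSV) and a metrics dict (JSON).

    The TSV has columns ``gene_id, row_norm, selected`` sorted by descending
    row norm (ties broken by gene index); output is byte-stable for fixed
    inputs.
    """
    norms = np.asarray(selection.row_norms, dtype=float)
    selected = set(int(j) for j in selection.selected)
    order = np.lexsort((np.arange(len(norms)), -norms))
    with open(genes_path, "w") as fh:
        fh.write("gene_id\trow_norm\tselected\n")
        for j in order:
            fh.write(
                f"{gene_ids[j]}\t{norms[j]:.10g}\t{int(j in selected)}\n"
            )
    with open(metrics_path, "w") as fh:
        json.dump(metrics, fh, indent=2, sort_keys=True)
        fh.write("\n")
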