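"""Two-group expression data containers, loading, and within-group standardization.

The observed data are an N x P expression matrix (subjects in rows, genes in
columns once loaded) together with a binary group label per subject. All
downstream stages (correlation screening, the Bayesian interaction model,
classification) operate on these containers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "StandardizedDataset",
    "load_expression_table",
    "standardize_within_group",
    "write_expression_table",
]


@dataclass(frozen=True)
class ExpressionDataset:
    """Validated two-group expression data.

    Attributes
    ----------
    values : ndarray, shape (N, P)
        Expression values, subjects in rows, genes in columns.
    gene_names : tuple of str
        P unique gene identifiers.
    sample_ids : tuple of str
        N unique subject identifiers.
    labels : ndarray, shape (N,)
        Binary group labels in {0, 1}.
    label_mapping : dict
        Original class value -> {0, 1}. The lexicographically smaller
        original label maps to group 0 so that the sign of correlation
        differences and interaction coefficients is interpretable.
    """

    values: np.ndarray
    gene_names: tuple
    sample_ids: tuple
    labels: np.ndarray
    label_mapping: Mapping = field(default_factory=dict)

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        labels = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "gene_names", tuple(self.gene_names))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        n, p = values.shape
        if len(self.gene_names) != p:
            raise ValueError(f"{len(self.gene_names)} gene names for {p} columns")
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(set(self.gene_names)) != p:
            dupes = sorted({g for g in self.gene_names if self.gene_names.count(g) > 1})
            raise ValueError(f"duplicate gene names: {dupes}")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if not np.all(np.isfinite(values)):
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite expression value for gene {self.gene_names[j]!r}, "
                f"sample {self.sample_ids[i]!r}"
            )
        if labels.shape != (n,):
            raise ValueError("labels must be a length-N vector")
        if not np.isin(labels, (0, 1)).all():
            raise ValueError("labels must be binary (0/1)")
        n0 = int(np.sum(labels == 0))
        n1 = n - n0
        if n0 == 0 or n1 == 0:
            raise ValueError("both groups must be non-empty")
        if min(n0, n1) < 2:
            raise ValueError("each group needs at least 2 subjects")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def group_values(self, group: int) -> np.ndarray:
        """Rows belonging to one group."""
        return self.values[self.labels == group]

    def to_frame(self) -> pd.DataFrame:
        """Genes-in-rows DataFrame (the expression-matrix convention)."""
        return pd.DataFrame(
            self.values.T, index=list(self.gene_names), columns=list(self.sample_ids)
        )


@dataclass(frozen=True)
class StandardizedDataset(ExpressionDataset):
    """Expression data z-scored per gene within each group.

    ``group_means``/``group_sds`` are the (2, P) statistics used for the
    within-group transform; ``pooled_means``/``pooled_sds`` are per-gene
    statistics over all training subjects, retained so that unlabeled test
    subjects can later be standardized without knowing their group.
    """

    group_means: np.ndarray = None
    group_sds: np.ndarray = None
    pooled_means: np.ndarray = None
    pooled_sds: np.ndarray = None
    standardized: bool = True


def _read_table(path, delimiter=None) -> pd.DataFrame:
    """Read a delimited table with the first column as the index.

    Delimiter is auto-detected between tab and comma when not given.
    """
    path = Path(path)
    if delimiter is None:
        head = path.read_text().splitlines()[0] if path.exists() else ""
        delimiter = "\t" if head.count("\t") >= head.count(",") else ","
    return pd.read_csv(path, sep=delimiter, index_col=0, float_precision="round_trip")


def load_expression_table(
    path,
    orientation: str = "genes_in_rows",
    label_source=None,
    label_row: str | None = None,
    delimiter: str | None = None,
) -> ExpressionDataset:
    """Load a delimited expression table and group labels.

    Parameters
    ----------
    path : path-like
        TSV/CSV matrix with an index column. Default orientation is genes in
        rows, samples in columns.
    orientation : {"genes_in_rows", "samples_in_rows"}
    label_source : path-like, mapping, or sequence, optional
        Either a two-column TSV/CSV (sample_id, label), a mapping
        sample_id -> label, or a sequence aligned with the samples.
    label_row : str, optional
        Name of a row (genes_in_rows) or column (samples_in_rows) inside the
        matrix that carries the labels instead of an external source.

    Labels may be arbitrary values resolving to exactly two classes; the
    lexicographically smaller class becomes group 0.
    """
    if orientation not in ("genes_in_rows", "samples_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    frame = _read_table(path, delimiter)
    if orientation == "genes_in_rows":
        frame = frame.T
    # now samples in rows, genes in columns
    raw_labels = None
    if label_row is not None:
        if label_row not in frame.columns:
            raise ValueError(f"label row/column {label_row!r} not found")
        raw_labels = frame[label_row]
        frame = frame.drop(columns=[label_row])
    elif label_source is not None:
        if isinstance(label_source, (str, Path)):
            lab = _read_table(label_source, delimiter)
            col = lab.columns[0]
            raw_labels = lab[col].reindex(frame.index)
            if raw_labels.isna().any():
                missing = list(frame.index[raw_labels.isna()])
                raise ValueError(f"labels missing for samples: {missing}")
        elif isinstance(label_source, Mapping):
            try:
                raw_labels = pd.Series([label_source[s] for s in frame.index], index=frame.index)
            except KeyError as exc:
                raise ValueError(f"label missing for sample {exc.args[0]!r}") from exc
        else:
            raw_labels = pd.Series(list(label_source), index=frame.index)
    else:
        raise ValueError("labels required: pass label_source or label_row")

    if frame.isna().any().any():
        col = frame.columns[frame.isna().any()][0]
        row = frame.index[frame[col].isna()][0]
        raise ValueError(f"missing expression value for gene {col!r}, sample {row!r}")

    classes = sorted(pd.unique(raw_labels), key=str)
    if len(classes) != 2:
        raise ValueError(f"labels must resolve to exactly 2 classes, got {len(classes)}")
    mapping = {classes[0]: 0, classes[1]: 1}
    labels = raw_labels.map(mapping).to_numpy(dtype=int)

    return ExpressionDataset(
        values=frame.to_numpy(dtype=float),
        gene_names=tuple(str(g) for g in frame.columns),
        sample_ids=tuple(str(s) for s in frame.index),
        labels=labels,
        label_mapping=mapping,
    )


def standardize_within_group(data: ExpressionDataset, ddof: int = 1) -> StandardizedDataset:
    """Z-score each gene within each group (sample SD, n-1 denominator).

    Correlations are invariant to this affine map; within-group
    standardization additionally zeroes both group means, which is what lets
    the interaction-only logistic model drop main-effect terms.

    Raises
    ------
    ValueError
        If any gene has zero variance within a group (the caller may drop
        such genes and retry).
    """
    values = data.values.copy()
    p = data.n_genes
    group_means = np.empty((2, p))
    group_sds = np.empty((2, p))
    for g in (0, 1):
        mask = data.labels == g
        block = values[mask]
        if block.shape[0] < 2:
            raise ValueError(f"group {g} has fewer than 2 subjects")
        mu = block.mean(axis=0)
        sd = block.std(axis=0, ddof=ddof)
        if np.any(sd <= 0):
            bad = [data.gene_names[j] for j in np.flatnonzero(sd <= 0)]
            raise ValueError(f"zero variance within group {g} for genes: {bad}")
        values[mask] = (block - mu) / sd
        group_means[g] = mu
        group_sds[g] = sd
    return StandardizedDataset(
        values=values,
        gene_names=data.gene_names,
        sample_ids=data.sample_ids,
        labels=data.labels,
        label_mapping=dict(data.label_mapping),
        group_means=group_means,
        group_sds=group_sds,
        pooled_means=data.values.mean(axis=0),
        pooled_sds=data.values.std(axis=0, ddof=ddof),
        standardized=True,
    )


def write_expression_table(data: ExpressionDataset, path, labels_path=None) -> None:
    """Write the matrix back to TSV (genes in rows) and, optionally, labels.

    Floats use %.17g so the table round-trips bit-for-bit.
    """
    data.to_frame().to_csv(path, sep="\t", float_format="%.17g")
    if labels_path is not None:
        pd.DataFrame({"sample_id": list(data.sample_ids), "label": data.labels}).to_csv(
            labels_path, sep="\t", index=False
        )
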