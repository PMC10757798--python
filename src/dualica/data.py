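"""Reading, validating and preprocessing log-fold-change (LFC) matrices.

The unit of input for the whole package is a genes x conditions matrix of
log2 fold-changes, as produced upstream by differential-expression tools
(DESeq2, limma, ...), one column per condition. Preprocessing standardizes
each column to zero mean / unit (sample) standard deviation and then clips
extreme values symmetrically, which limits the leverage of rare outliers on
the ICA decompositions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .exceptions import (
    DegenerateColumnError,
    DuplicateLabelError,
    MatrixParseError,
    MissingValueError,
)

__all__ = [
    "LFCMatrix",
    "read_lfc_matrix",
    "write_lfc_matrix",
    "standardize_columns",
    "clip_values",
    "preprocess",
]

DEFAULT_CLIP_BOUND = 6.0


@dataclass
class LFCMatrix:
    """A labeled genes x conditions matrix of log-fold-changes.

    Parameters
    ----------
    values : ndarray of shape (n_genes, n_conditions)
        LFC values (or standardized units once ``preprocessed`` is True).
    gene_ids, condition_ids : list of str
        Unique row and column labels, in matrix order.
    preprocessed : bool
        Whether column standardization + clipping has been applied.
    """

    values: np.ndarray
    gene_ids: list[str]
    condition_ids: list[str]
    preprocessed: bool = False
    clip_bound: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.condition_ids = [str(c) for c in self.condition_ids]
        if self.values.ndim != 2:
            raise ValueError(f"values must be 2-D, got ndim={self.values.ndim}")
        n, m = self.values.shape
        if len(self.gene_ids) != n:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {n} rows"
            )
        if len(self.condition_ids) != m:
            raise ValueError(
                f"{len(self.condition_ids)} condition ids for {m} columns"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.condition_ids, "condition")
        if not np.all(np.isfinite(self.values)):
            g, c = np.argwhere(~np.isfinite(self.values))[0]
            raise MissingValueError(
                f"non-finite value at gene {self.gene_ids[g]!r}, "
                f"condition {self.condition_ids[c]!r}"
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.gene_ids, columns=self.condition_ids
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, preprocessed: bool = False) -> "LFCMatrix":
        return cls(
            values=df.to_numpy(dtype=float),
            gene_ids=list(map(str, df.index)),
            condition_ids=list(map(str, df.columns)),
            preprocessed=preprocessed,
        )

    def gene_index(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"unknown gene id {gene_id!r}") from None

    def condition_index(self, condition_id: str) -> int:
        try:
            return self.condition_ids.index(condition_id)
        except ValueError:
            raise KeyError(f"unknown condition id {condition_id!r}") from None


def _check_unique(labels: list[str], axis: str) -> None:
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise DuplicateLabelError(f"duplicate {axis} label {lab!r}")
        seen.add(lab)


def read_lfc_matrix(path, delimiter: str = "\t") -> LFCMatrix:
    """Read a labeled LFC matrix from a TSV/CSV file.

    The first row holds condition labels, the first column gene labels,
    and the body must be fully numeric: a missing or non-numeric cell is a
    hard error (the decompositions assume a complete matrix), never
    silently imputed.
    """
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split(delimiter)
    condition_ids = [c for c in header[1:]]
    _check_unique(condition_ids, "condition")

    df = pd.read_csv(path, sep=delimiter, index_col=0, header=0)
    _check_unique([str(g) for g in df.index], "gene")

    na_mask = df.isna()
    if na_mask.to_numpy().any():
        g, c = np.argwhere(na_mask.to_numpy())[0]
        raise MissingValueError(
            f"missing value at gene {df.index[g]!r}, condition {df.columns[c]!r} "
            f"in {path}"
        )
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & ~df[col].isna()
            gene = df.index[np.argmax(bad.to_numpy())]
            raise MatrixParseError(
                f"non-numeric cell at gene {gene!r}, condition {col!r}: "
                f"{df.loc[gene, col]!r}"
            )
    return LFCMatrix.from_frame(df)


def write_lfc_matrix(M: LFCMatrix, path, delimiter: str = "\t") -> None:
    """Write the matrix with labels; inverse of :func:`read_lfc_matrix`."""
    M.to_frame().to_csv(path, sep=delimiter)


def standardize_columns(M: LFCMatrix) -> LFCMatrix:
    """Z-score each column (condition): mean 0, sample (n-1) sd 1.

    Raises
    ------
    DegenerateColumnError
        If any column is constant (zero variance).
    """
    sd = M.values.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise DegenerateColumnError(
            f"condition {M.condition_ids[zero[0]]!r} has zero variance"
        )
    values = (M.values - M.values.mean(axis=0)) / sd
    return replace(M, values=values)


def clip_values(M: LFCMatrix, bound: float = DEFAULT_CLIP_BOUND) -> LFCMatrix:
    """Clip every entry symmetrically into [-bound, +bound].

    Entries already inside the interval pass through unchanged
    (bit-for-bit); only the tails are truncated.
    """
    if bound <= 0:
        raise ValueError(f"clip bound must be positive, got {bound}")
    return replace(M, values=np.clip(M.values, -bound, bound))


def preprocess(
    M: LFCMatrix,
    bound: float = DEFAULT_CLIP_BOUND,
    clip_first: bool = False,
) -> LFCMatrix:
    """Standardize columns, then clip to ``[-bound, +bound]``.

    ``clip_first=True`` swaps the order (clip the raw LFCs, then
    standardize), in which case the output is not guaranteed to stay
    inside the bound. The default order clips z-scores.
    """
    if clip_first:
        out = standardize_columns(clip_values(M, bound))
    else:
        out = clip_values(standardize_columns(M), bound)
    out.preprocessed = True
    out.clip_bound = float(bound)
    return out
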