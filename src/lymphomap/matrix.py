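"""Expression matrix container and text-format IO.

The whole pipeline works on one currency: a log2-scale gene-by-sample
matrix with unique row (gene) and column (sample) identifiers.  The
container wraps a :class:`pandas.DataFrame` (genes in rows) and enforces
the two invariants every downstream stage relies on: identifiers are
unique, and every value is finite.  Missing values are rejected at load
time — there is no imputation rule in this pipeline.

Supported on-disk formats are plain tab-separated text (first column =
gene ids, header row = sample ids) and GCT v1.2.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "read_expression", "write_expression"]


class MatrixFormatError(ValueError):
    """Raised when an expression file violates the format contract."""


@dataclass
class ExpressionMatrix:
    """Log2-scale gene × sample expression values.

    Parameters
    ----------
    data:
        DataFrame with genes in rows and samples in columns.  The index
        holds gene ids and the columns hold sample ids.
    """

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise MatrixFormatError(f"duplicate gene ids: {dups[:5]}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise MatrixFormatError(f"duplicate sample ids: {dups[:5]}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            bad = self.data.columns[
                [not np.issubdtype(d, np.number) for d in self.data.dtypes]
            ].tolist()
            raise MatrixFormatError(f"non-numeric columns: {bad[:5]}")
        if not np.all(np.isfinite(values)):
            rows = self.data.index[~np.isfinite(values).all(axis=1)].tolist()
            raise MatrixFormatError(
                f"non-finite values in rows: {rows[:5]} (missing values must be "
                "resolved before loading)"
            )

    # -- accessors ---------------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def values(self) -> np.ndarray:
        """Gene × sample value matrix (float64, no copy guarantee)."""
        return self.data.to_numpy(dtype=float)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise KeyError(f"unknown sample ids: {missing[:5]}")
        return ExpressionMatrix(self.data.loc[:, sample_ids].copy())

    def with_values(self, values: np.ndarray) -> "ExpressionMatrix":
        """Same ids, new values — used by transforms that preserve shape."""
        if values.shape != self.data.shape:
            raise ValueError(f"shape mismatch: {values.shape} vs {self.data.shape}")
        return ExpressionMatrix(
            pd.DataFrame(values, index=self.data.index, columns=self.data.columns)
        )


def read_expression(path: str | os.PathLike) -> ExpressionMatrix:
    """Read a TSV or GCT v1.2 expression file.

    GCT files are recognized by their ``#1.2`` first line; everything
    else is parsed as tab-separated text with gene ids in the first
    column.
    """
    with open(path) as fh:
        first = fh.readline()
    if first.strip() == "#1.2":
        return _read_gct(path)
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if frame.shape[1] == 0:
        raise MatrixFormatError(f"no sample columns found in {path}")
    return ExpressionMatrix(frame)


def _read_gct(path: str | os.PathLike) -> ExpressionMatrix:
    with open(path) as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise MatrixFormatError(f"unsupported GCT version line: {version!r}")
        dims = fh.readline().split()
        if len(dims) < 2:
            raise MatrixFormatError("GCT dimension line must hold two integers")
        n_rows, n_cols = int(dims[0]), int(dims[1])
        body = fh.read()
    frame = pd.read_csv(io.StringIO(body), sep="\t", index_col=0)
    frame = frame.drop(columns=["Description"], errors="ignore")
    if frame.shape != (n_rows, n_cols):
        raise MatrixFormatError(
            f"GCT dimension line says {n_rows}×{n_cols}, body is "
            f"{frame.shape[0]}×{frame.shape[1]}"
        )
    return ExpressionMatrix(frame)


def write_expression(
    m: ExpressionMatrix, path: str | os.PathLike, fmt: str = "tsv"
) -> None:
    """Write TSV (default) or GCT v1.2."""
    if fmt == "tsv":
        m.data.to_csv(path, sep="\t", index_label="gene_id")
    elif fmt == "gct":
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{m.n_genes}\t{m.n_samples}\n")
            out = m.data.copy()
            out.insert(0, "Description", m.data.index)
            out.to_csv(fh, sep="\t", index_label="NAME")
    else:
        raise ValueError(f"unknown format {fmt!r} (expected 'tsv' or 'gct')")
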