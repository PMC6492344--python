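"""Preprocessing: quantile normalization and gene-wise centralization.

The pipeline assumes a calibrated log2 expression matrix on input.  Two
transforms are applied before SOM training:

* **quantile normalization** forces every sample (column) onto the same
  value distribution — the row-wise mean of the per-column sorted
  values.  Tied values within a column receive the mean of the reference
  values at their tied ranks, which makes the transform symmetric,
  deterministic and idempotent.
* **centralization** subtracts each gene's location (mean by default,
  median optionally) across samples, so portraits later render the
  differential expression Δe of each gene relative to its cohort-wide
  level.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

__all__ = ["quantile_normalize", "centralize", "preprocess"]


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Map every column onto the common reference distribution.

    The reference is the row-wise mean of the sorted columns; each value
    is replaced by the reference value at its within-column rank, with
    ties averaged over their occupied rank positions.
    """
    if m.n_samples < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    if m.n_genes < 2:
        raise ValueError("quantile normalization needs at least 2 genes")
    values = m.values
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        sorted_vals = col[order]
        # ties = average: group contiguous equal values, average their
        # reference entries
        assigned = (
            pd.Series(reference)
            .groupby(pd.Series(sorted_vals), sort=False)
            .transform("mean")
            .to_numpy()
        )
        out[order, j] = assigned
    return m.with_values(out)


def centralize(m: ExpressionMatrix, method: str = "mean") -> ExpressionMatrix:
    """Subtract each gene's across-sample mean (or median)."""
    values = m.values
    if method == "mean":
        loc = values.mean(axis=1, keepdims=True)
    elif method == "median":
        loc = np.median(values, axis=1, keepdims=True)
    else:
        raise ValueError(f"unknown centralization method {method!r}")
    return m.with_values(values - loc)


def preprocess(
    m: ExpressionMatrix, skip_quantile: bool = False, center: str = "mean"
) -> ExpressionMatrix:
    """Standard preprocessing chain: quantile normalization then centralization."""
    if not skip_quantile:
        m = quantile_normalize(m)
    return centralize(m, method=center)
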