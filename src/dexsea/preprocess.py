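"""Quantile normalization across samples and per-gene row standardization.

Quantile normalization forces every sample's empirical distribution onto the
common reference formed by the mean order statistics across samples. Tied
values within a sample receive the mean of the reference values at their tied
ranks, so a column of ties maps to a single value rather than an arbitrary
ordering of reference values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class NormalizedMatrix(ExpressionMatrix):
    """Expression matrix with a provenance note of the normalization applied."""

    provenance: str = ""


def quantile_normalize(matrix: ExpressionMatrix) -> NormalizedMatrix:
    """Quantile-normalize a log2-scale matrix across its sample columns.

    After normalization every column's sorted value vector equals the
    reference (mean order statistic) vector; the map is rank-preserving
    within each column and idempotent.
    """
    if matrix.scale != "log2":
        raise ValueError("quantile_normalize expects a log2-scale matrix; "
                         "log-transform linear input first")
    x = matrix.values
    n_genes, n_samples = x.shape
    if n_samples < 2:
        raise ValueError("quantile normalization needs at least 2 samples")

    order = np.argsort(x, axis=0, kind="stable")
    reference = np.sort(x, axis=0).mean(axis=1)

    out = np.empty_like(x)
    rows = order
    out[rows, np.arange(n_samples)[None, :]] = reference[:, None]

    # Tie handling: average the reference values assigned to equal inputs.
    for j in range(n_samples):
        col = x[:, j]
        uniq, inv, counts = np.unique(col, return_inverse=True, return_counts=True)
        if len(uniq) == n_genes:
            continue
        sums = np.bincount(inv, weights=out[:, j])
        out[:, j] = (sums / counts)[inv]

    return NormalizedMatrix(
        pd.DataFrame(out, index=matrix.data.index, columns=matrix.data.columns),
        scale="log2",
        provenance="quantile normalization (mean order statistics, ties averaged)",
    )


def standardize_rows(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Scale each gene row to mean 0 and unit sample sd (n-1 denominator).

    Constant rows map to all-zeros with a logged warning; used for
    clustering and heatmap-ready export.
    """
    x = matrix.values
    if x.shape[1] < 2:
        raise ValueError("row standardization needs at least 2 samples")
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    constant = sd[:, 0] < 1e-300
    if constant.any():
        logger.warning(
            "standardize_rows: %d constant row(s) mapped to zeros", int(constant.sum())
        )
    safe_sd = np.where(sd < 1e-300, 1.0, sd)
    z = (x - mean) / safe_sd
    z[constant, :] = 0.0
    return ExpressionMatrix(
        pd.DataFrame(z, index=matrix.data.index, columns=matrix.data.columns),
        scale="log2",
    )
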