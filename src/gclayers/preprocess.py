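"""Expression pre-processing: log2 transform, valid-value filtering,
Perseus-style imputation and most-variable gene selection.

The processing order the pipeline uses is: log2 (unless the input is
already logged) → keep genes with ≥75% valid values → impute remaining
missing values from a down-shifted per-sample normal distribution →
keep the top 2000 genes by standard deviation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

log = logging.getLogger(__name__)

__all__ = [
    "log2_transform",
    "filter_valid",
    "impute_missing",
    "select_most_variable",
]


def log2_transform(matrix: ExpressionMatrix, offset: float = 1.0) -> ExpressionMatrix:
    """Replace every non-missing value x by log2(x + offset).

    ``offset`` acts as a pseudocount for raw abundance input; use 0 when
    values are strictly positive. Raises on any non-positive x + offset,
    naming the offending gene and sample.
    """
    vals = matrix.values
    bad = (vals + offset) <= 0
    if bad.any().any():
        g = bad.any(axis=1).idxmax()
        s = bad.loc[g].idxmax()
        raise ValueError(
            f"log2 undefined for gene {g!r}, sample {s!r}: "
            f"value {vals.loc[g, s]} + offset {offset} <= 0"
        )
    return ExpressionMatrix(np.log2(vals + offset))


def filter_valid(matrix: ExpressionMatrix, min_fraction: float = 0.75) -> ExpressionMatrix:
    """Keep genes whose fraction of valid (non-missing) values is ≥ ``min_fraction``.

    The boundary is inclusive; gene order is preserved. An empty result
    warns rather than raises.
    """
    if not 0 < min_fraction <= 1:
        raise ValueError(f"min_fraction must be in (0, 1], got {min_fraction}")
    frac = matrix.values.notna().mean(axis=1)
    keep = frac >= min_fraction
    if not keep.any():
        log.warning("filter_valid removed every gene at threshold %s", min_fraction)
    return ExpressionMatrix(matrix.values.loc[keep].copy())


def impute_missing(
    matrix: ExpressionMatrix,
    width: float = 0.3,
    downshift: float = 1.8,
    seed: int = 0,
) -> ExpressionMatrix:
    """Impute missing entries from a down-shifted normal, per sample column.

    For each sample, missing values are drawn from
    Normal(mean − downshift·sd, (width·sd)²), with mean/sd computed from
    that column's observed values — the "replace from normal
    distribution" scheme used for left-censored log-scale data, with its
    conventional defaults (width 0.3, downshift 1.8). Deterministic for a
    fixed seed.
    """
    if width <= 0:
        raise ValueError("width must be > 0")
    rng = np.random.default_rng(seed)
    vals = matrix.values.copy()
    for col in vals.columns:
        column = vals[col]
        miss = column.isna()
        if not miss.any():
            continue
        obs = column[~miss]
        if len(obs) < 2:
            raise ValueError(
                f"sample {col!r} has {len(obs)} valid values; sd undefined"
            )
        mu, sd = obs.mean(), obs.std(ddof=1)
        draws = rng.normal(mu - downshift * sd, width * sd, size=int(miss.sum()))
        vals.loc[miss, col] = draws
    return ExpressionMatrix(vals)


def select_most_variable(matrix: ExpressionMatrix, n: int = 2000) -> ExpressionMatrix:
    """Keep the ``n`` genes with the largest sample standard deviation.

    SD uses the unbiased (n_samples − 1) denominator. Ties at the cutoff
    are broken in favour of the lexicographically smaller gene id. The
    original gene order is preserved among the retained genes. Requires
    a complete matrix.
    """
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    if matrix.n_missing:
        raise ValueError("select_most_variable requires a complete matrix")
    if n >= matrix.n_genes:
        return matrix.copy()
    sd = matrix.values.std(axis=1, ddof=1)
    ranked = sorted(matrix.genes, key=lambda g: (-sd[g], g))
    chosen = set(ranked[:n])
    keep = [g for g in matrix.genes if g in chosen]
    return ExpressionMatrix(matrix.values.loc[keep].copy())
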