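"""Gene × sample expression container.

The whole pipeline operates on :class:`ExpressionMatrix`, a thin wrapper
around a pandas DataFrame with genes as rows and samples as columns.
Missing entries are encoded as NaN; the boolean ``mask`` property exposes
them explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "standardize_genes"]


@dataclass
class ExpressionMatrix:
    """Expression values on a (possibly log) scale, genes × samples.

    Parameters
    ----------
    values
        DataFrame indexed by unique gene ids with unique sample-id columns.
        NaN marks a missing measurement; all other entries must be finite.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        self.values = self.values.astype(float)
        arr = self.values.to_numpy()
        if np.isinf(arr).any():
            g, s = np.argwhere(np.isinf(arr))[0]
            raise ValueError(
                f"non-finite value for gene {idx[g]!r}, sample {cols[s]!r}"
            )

    # -- basic accessors ---------------------------------------------------
    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean DataFrame, True where the entry is missing."""
        return self.values.isna()

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy())

    def subset_genes(self, genes) -> "ExpressionMatrix":
        """Restrict to ``genes`` (kept in the given order)."""
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        return ExpressionMatrix(self.values.loc[list(genes)].copy())

    def subset_samples(self, samples) -> "ExpressionMatrix":
        missing = [s for s in samples if s not in self.values.columns]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:5]}")
        return ExpressionMatrix(self.values[list(samples)].copy())


def standardize_genes(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Z-score every gene across samples (ddof=1).

    Genes with zero variance are centred but left unscaled to avoid
    division by zero. Requires a complete (no-missing) matrix.
    """
    if matrix.n_missing:
        raise ValueError("standardize_genes requires a complete matrix")
    vals = matrix.values
    mu = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=1).replace(0.0, 1.0)
    return ExpressionMatrix(vals.sub(mu, axis=0).div(sd, axis=0))
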