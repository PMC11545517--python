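"""Combined molecular layer (CML).

The subtype-concordant layers' gene sets are merged into one panel, the
cohort is consensus-clustered on that panel, and the resulting CML
groups are cross-tabulated against subtype labels. A group can be
refined by a second layer's partition (e.g. splitting CIN into
CIN-classical vs CIN-MSI-like analogues).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2_contingency, fisher_exact, random_table

from .consensus import ConsensusResult, consensus_cluster
from .layers import Layer
from .matrix import standardize_genes

__all__ = ["CrossTab", "build_cml", "cluster_cml", "crosstab", "split_group_by_layer"]


class IntegrityError(ValueError):
    """Layer contract violated (non-disjoint gene sets)."""


@dataclass
class CrossTab:
    """Contingency table with the test that was applied to it."""

    table: pd.DataFrame  # counts, rows = labels_a, cols = labels_b
    test: str  # "chi-squared" | "chi-squared (Yates)" | "Fisher exact" | "Fisher (Monte Carlo)"
    statistic: float | None
    p_value: float


def build_cml(layers: list[Layer], include) -> list[str]:
    """Union of the included layers' gene sets.

    Layer gene sets must be pairwise disjoint (the recursion contract),
    so the CML size is the sum of the included sizes. ``include`` holds
    1-based layer indices.
    """
    by_index = {layer.index: layer for layer in layers}
    missing = [i for i in include if i not in by_index]
    if missing:
        raise KeyError(f"layers {missing} not available (have {sorted(by_index)})")
    genes: list[str] = []
    seen: set[str] = set()
    for i in include:
        overlap = seen & set(by_index[i].genes)
        if overlap:
            raise IntegrityError(
                f"layer {i} shares genes with an earlier included layer: "
                f"{sorted(overlap)[:5]}"
            )
        genes.extend(by_index[i].genes)
        seen |= set(by_index[i].genes)
    return genes


def cluster_cml(
    matrix,
    cml_genes,
    k_range=(2, 3, 4),
    n_resample: int = 500,
    p_sample: float = 0.8,
    seed: int = 0,
) -> tuple[pd.Series, ConsensusResult]:
    """Consensus-cluster samples on the CML gene panel.

    Returns labels named "CML1".."CMLk", assigned by ascending group
    size (largest group last), plus the full consensus result.
    """
    cml_genes = list(cml_genes)
    if len(cml_genes) < 2:
        raise ValueError("CML needs at least 2 genes")
    sub = standardize_genes(matrix.subset_genes(cml_genes))
    cc = consensus_cluster(
        sub, k_range=k_range, n_resample=n_resample, p_sample=p_sample, seed=seed
    )
    sizes = cc.labels.value_counts()
    order = sorted(sizes.index, key=lambda g: (sizes[g], g))
    name_of = {g: f"CML{i + 1}" for i, g in enumerate(order)}
    labels = cc.labels.map(name_of)
    return labels, cc


def _fisher_rxc_montecarlo(counts: np.ndarray, n_draws: int, seed: int) -> float:
    """Monte-Carlo Fisher exact test for an r×c table: the p-value is the
    probability mass of tables (with the observed margins) no more
    probable than the observed one, estimated from ``n_draws`` Patefield
    samples."""

    def log_pmf(tab: np.ndarray) -> float:
        r = tab.sum(axis=1)
        c = tab.sum(axis=0)
        n = tab.sum()
        return float(
            gammaln(r + 1).sum()
            + gammaln(c + 1).sum()
            - gammaln(n + 1)
            - gammaln(tab + 1).sum()
        )

    obs_lp = log_pmf(counts)
    rng = np.random.default_rng(seed)
    dist = random_table(counts.sum(axis=1), counts.sum(axis=0))
    draws = dist.rvs(n_draws, random_state=rng)
    lps = (
        gammaln(counts.sum(axis=1) + 1).sum()
        + gammaln(counts.sum(axis=0) + 1).sum()
        - gammaln(counts.sum() + 1)
        - gammaln(draws + 1).sum(axis=(1, 2))
    )
    hits = int((lps <= obs_lp + 1e-9).sum())
    return (hits + 1) / (n_draws + 1)


def crosstab(
    labels_a: pd.Series | dict,
    labels_b: pd.Series | dict,
    n_montecarlo: int = 100_000,
    seed: int = 0,
) -> CrossTab:
    """Cross-tabulate two labelings of the same samples and test association.

    Test selection: 2×2 tables use the Fisher exact test when any
    expected count is below 5, otherwise chi-squared with Yates
    correction; larger tables use plain chi-squared, falling back to a
    seeded Monte-Carlo Fisher test when any expected count is below 5.
    All p-values are two-sided.
    """
    a, b = pd.Series(labels_a), pd.Series(labels_b)
    common = a.index.intersection(b.index)
    if len(common) == 0:
        raise ValueError("labelings share no samples")
    table = pd.crosstab(a.loc[common], b.loc[common])
    counts = table.to_numpy()
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        return CrossTab(table=table, test="degenerate", statistic=None, p_value=1.0)
    expected = np.outer(counts.sum(1), counts.sum(0)) / counts.sum()
    small = (expected < 5).any()
    if counts.shape == (2, 2):
        if small:
            stat, p = fisher_exact(counts, alternative="two-sided")
            return CrossTab(table=table, test="Fisher exact", statistic=None, p_value=float(p))
        res = chi2_contingency(counts, correction=True)
        return CrossTab(table=table, test="chi-squared (Yates)",
                        statistic=float(res.statistic), p_value=float(res.pvalue))
    if small:
        p = _fisher_rxc_montecarlo(counts, n_montecarlo, seed)
        return CrossTab(table=table, test="Fisher (Monte Carlo)", statistic=None, p_value=p)
    res = chi2_contingency(counts, correction=False)
    return CrossTab(table=table, test="chi-squared",
                    statistic=float(res.statistic), p_value=float(res.pvalue))


def split_group_by_layer(
    group_labels: pd.Series | dict,
    splitting_labels: pd.Series | dict,
    target,
    sep: str = "-",
) -> pd.Series:
    """Refine one group by a second labeling.

    Samples in ``target`` are relabeled ``f"{target}{sep}{split}"``;
    all other samples keep their label.
    """
    groups = pd.Series(group_labels).copy()
    splits = pd.Series(splitting_labels)
    in_target = groups == target
    if not in_target.any():
        raise KeyError(f"no sample belongs to group {target!r}")
    uncovered = [s for s in groups.index[in_target] if s not in splits.index]
    if uncovered:
        raise ValueError(f"splitting labels missing for {uncovered[:5]}")
    groups = groups.astype(object)
    groups.loc[in_target] = [
        f"{target}{sep}{splits[s]}" for s in groups.index[in_target]
    ]
    return groups
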