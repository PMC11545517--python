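"""Recursive biological-layer discovery.

Each round runs sparse k-means on the surviving gene pool to weight
genes, takes the genes with non-negligible weight as the candidate
layer, fixes the group number and sample labels by consensus clustering
on those genes, records the layer, and removes its genes from the pool.
Layers are therefore pairwise disjoint by construction. The recursion
stops at ``max_layers``, when the candidate clustering is unstable
(PAC above ``stop_pac``), or when the pool runs out.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .consensus import ConsensusResult, consensus_cluster
from .matrix import ExpressionMatrix, standardize_genes
from .sparse_kmeans import sparse_kmeans, tune_sparsity

__all__ = ["Layer", "extract_layers", "redundancy_report"]

log = logging.getLogger(__name__)


@dataclass
class Layer:
    """One discovered biological layer."""

    index: int
    genes: list[str]
    weights: pd.Series
    labels: pd.Series  # 1..k
    k: int
    pac: float
    main_function: str | None = None
    enrichment: pd.DataFrame | None = None
    consensus: ConsensusResult | None = field(default=None, repr=False)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def group_sizes(self) -> dict[int, int]:
        return self.labels.value_counts().sort_index().to_dict()


def _default_s_grid(p: int) -> list[float]:
    hi = np.sqrt(p)
    grid = np.unique(np.round(np.geomspace(1.2, max(hi * 0.9, 1.3), 4), 3))
    return [float(s) for s in grid if 1.0 <= s <= hi]


def extract_layers(
    matrix: ExpressionMatrix,
    max_layers: int = 7,
    k_range=(2, 3, 4),
    stop_pac: float = 0.4,
    s: float | None = None,
    s_grid=None,
    n_resample: int = 500,
    p_sample: float = 0.8,
    n_starts: int = 5,
    n_tune_permutations: int = 6,
    weight_threshold_frac: float = 0.1,
    min_pool: int = 20,
    min_layer_genes: int = 2,
    min_gap: float = 0.3,
    min_gap_sd: float = 2.0,
    seed: int = 0,
) -> list[Layer]:
    """Recursively extract disjoint biological layers.

    Per round, genes in the pool are z-scored; for every k in ``k_range``
    a sparse k-means fit is produced (with ``s`` fixed, or tuned by the
    permutation gap statistic over ``s_grid``); the fit with the best
    objective per cluster dimension, O/(k−1), supplies the gene weights
    (the raw weighted BCSS grows mechanically with k, so it cannot be
    compared across k directly); genes with weight above
    ``weight_threshold_frac`` × max weight become the candidate layer;
    consensus clustering restricted to those genes fixes k* and the
    sample labels. A round is accepted only if (a) its permutation gap —
    log objective on the data minus the mean log objective on gene-wise
    permuted data — exceeds both ``min_gap`` and ``min_gap_sd``
    permutation SDs (this guards against the selection bias of scoring
    stability on genes picked to support a split: on structureless data
    the gap stays near zero while genuinely layered data sits far above
    it), and (b) the consensus PAC is ≤ ``stop_pac``. The recursion ends
    at the first rejected round. Deterministic per seed.
    """
    if matrix.n_missing:
        raise ValueError("extract_layers requires a complete matrix")
    rng = np.random.default_rng(seed)
    pool = list(matrix.genes)
    layers: list[Layer] = []
    while len(layers) < max_layers and len(pool) >= min_pool:
        sub = standardize_genes(matrix.subset_genes(pool))
        best_fit, best_score, best_gap = None, -np.inf, (0.0, 0.0)
        for k in sorted(set(k_range)):
            if k > sub.n_samples // 2:
                continue
            if s is not None:
                grid = [min(s, float(np.sqrt(sub.n_genes)))]
            else:
                grid = s_grid if s_grid is not None else _default_s_grid(sub.n_genes)
                grid = [g for g in grid if 1.0 <= g <= np.sqrt(sub.n_genes)]
                if not grid:
                    grid = [float(min(np.sqrt(sub.n_genes), 1.0))]
            s_k, gap_table = tune_sparsity(
                sub, k, grid,
                n_permutations=n_tune_permutations,
                seed=int(rng.integers(2**31 - 1)),
                n_starts=max(2, n_starts // 2),
            )
            row = gap_table.loc[gap_table["s"] == s_k].iloc[0]
            fit = sparse_kmeans(
                sub, k, s_k, n_starts=n_starts, seed=int(rng.integers(2**31 - 1))
            )
            score = fit.objective / (k - 1)
            if score > best_score:
                best_fit, best_score = fit, score
                best_gap = (
                    float(row["gap"]),
                    float(row["se"]) * np.sqrt(max(n_tune_permutations, 1)),
                )
        if best_fit is None:
            break
        gap, gap_sd = best_gap
        if gap < max(min_gap, min_gap_sd * gap_sd):
            log.info(
                "round %d: permutation gap %.3f (sd %.3f) below threshold; stopping",
                len(layers) + 1, gap, gap_sd,
            )
            break
        w = best_fit.weights
        selected = list(w.index[w > weight_threshold_frac * w.max()])
        if len(selected) < min_layer_genes:
            log.info("round %d: only %d genes selected; stopping", len(layers) + 1, len(selected))
            break
        cc = consensus_cluster(
            sub.subset_genes(selected),
            k_range=[k for k in sorted(set(k_range)) if k <= sub.n_samples // 2],
            n_resample=n_resample,
            p_sample=p_sample,
            seed=int(rng.integers(2**31 - 1)),
        )
        if cc.pac[cc.k_star] > stop_pac:
            log.info(
                "round %d: PAC %.3f above stop threshold %.3f; stopping",
                len(layers) + 1, cc.pac[cc.k_star], stop_pac,
            )
            break
        layers.append(
            Layer(
                index=len(layers) + 1,
                genes=selected,
                weights=w.loc[selected],
                labels=cc.labels,
                k=cc.k_star,
                pac=cc.pac[cc.k_star],
                consensus=cc,
            )
        )
        pool = [g for g in pool if g not in set(selected)]
    if not layers:
        log.warning("no layer passed the stability criteria")
    return layers


def redundancy_report(layers: list[Layer], warn_threshold: float = 0.7) -> pd.DataFrame:
    """Pairwise adjusted Rand index between layer labelings.

    Pairs above ``warn_threshold`` are logged as redundant (candidates
    for exclusion from the combined molecular layer).
    """
    rows = []
    for i, a in enumerate(layers):
        for b in layers[i + 1 :]:
            common = [s for s in a.labels.index if s in b.labels.index]
            ari = adjusted_rand_score(a.labels.loc[common], b.labels.loc[common])
            if ari > warn_threshold:
                log.warning(
                    "layers %d and %d are redundant (ARI %.2f)", a.index, b.index, ari
                )
            rows.append({"layer_a": a.index, "layer_b": b.index, "ari": float(ari)})
    return pd.DataFrame(rows, columns=["layer_a", "layer_b", "ari"])
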