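"""Sparse k-means with L1-constrained gene weights.

The Witten–Tibshirani formulation: maximize the weighted between-cluster
sum of squares Σ_g w_g·BCSS_g subject to ‖w‖₂ ≤ 1, ‖w‖₁ ≤ s, w ≥ 0, by
alternating k-means on sqrt(w)-scaled genes with a soft-threshold weight
update. The sparsity bound s is tuned by a permutation gap statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

__all__ = ["SparseKmeansFit", "sparse_kmeans", "tune_sparsity", "bcss_per_gene", "soft_threshold_weights"]


@dataclass
class SparseKmeansFit:
    """Weights, labels and objective of one sparse k-means fit."""

    weights: pd.Series  # per gene, >= 0, ||w||2 <= 1, ||w||1 <= s
    labels: pd.Series  # per sample, 1..k
    objective: float  # weighted BCSS
    s: float
    n_iter: int


def bcss_per_gene(X: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Between-cluster sum of squares per gene (row of X), i.e. total SS
    minus within-cluster SS, for the given sample labels."""
    total = ((X - X.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    within = np.zeros(X.shape[0])
    for lab in np.unique(labels):
        sub = X[:, labels == lab]
        within += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    return np.maximum(total - within, 0.0)


def soft_threshold_weights(bcss: np.ndarray, s: float, tol: float = 1e-10) -> np.ndarray:
    """Weight update: w ∝ (bcss − Δ)₊ normalized to ‖w‖₂ = 1, with Δ ≥ 0
    found by bisection so that ‖w‖₁ ≤ s (Δ = 0 when the constraint is
    slack)."""

    def w_of(delta: float) -> np.ndarray:
        raw = np.maximum(bcss - delta, 0.0)
        norm = np.linalg.norm(raw)
        if norm == 0:
            # all mass at the argmax in the Δ → max(bcss) limit
            raw = (bcss >= bcss.max() - 1e-15).astype(float)
            norm = np.linalg.norm(raw)
        return raw / norm

    w = w_of(0.0)
    if w.sum() <= s + 1e-12:
        return w
    lo, hi = 0.0, float(bcss.max())
    while hi - lo > tol:
        mid = (lo + hi) / 2
        if w_of(mid).sum() > s:
            lo = mid
        else:
            hi = mid
    return w_of(hi)


def sparse_kmeans(
    matrix,
    k: int,
    s: float,
    max_iter: int = 20,
    n_starts: int = 10,
    seed: int = 0,
    tol: float = 1e-4,
) -> SparseKmeansFit:
    """Fit sparse k-means on a gene-standardized matrix.

    Alternates (a) k-means over samples on gene-weighted data (gene g
    scaled by sqrt(w_g)) and (b) the soft-threshold weight update, until
    the relative L1 change in w falls below ``tol`` or ``max_iter``
    rounds. The best of ``n_starts`` restarts by objective is returned.
    ``s`` must lie in [1, sqrt(p)].
    """
    p, n = matrix.n_genes, matrix.n_samples
    if not 2 <= k <= n:
        raise ValueError(f"k must be in [2, {n}], got {k}")
    if not 1.0 <= s <= np.sqrt(p) + 1e-9:
        raise ValueError(f"s must be in [1, sqrt(p)={np.sqrt(p):.3f}], got {s}")
    X = matrix.values.to_numpy()
    rng = np.random.default_rng(seed)
    best: SparseKmeansFit | None = None
    for _ in range(n_starts):
        w = np.full(p, 1.0 / np.sqrt(p))
        labels = None
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            Xw = (X * np.sqrt(w)[:, None]).T  # samples × genes
            km = KMeans(
                n_clusters=k,
                n_init=1,
                random_state=int(rng.integers(2**31 - 1)),
            ).fit(Xw)
            labels = km.labels_
            bcss = bcss_per_gene(X, labels)
            w_new = soft_threshold_weights(bcss, s)
            change = np.abs(w_new - w).sum() / max(np.abs(w).sum(), 1e-12)
            w = w_new
            if change < tol:
                break
        objective = float((w * bcss_per_gene(X, labels)).sum())
        if best is None or objective > best.objective:
            best = SparseKmeansFit(
                weights=pd.Series(w, index=matrix.genes),
                labels=pd.Series(labels + 1, index=matrix.samples),
                objective=objective,
                s=s,
                n_iter=n_iter,
            )
    return best


def tune_sparsity(
    matrix,
    k: int,
    s_grid,
    n_permutations: int = 10,
    seed: int = 0,
    n_starts: int = 5,
    one_se: bool = False,
) -> tuple[float, pd.DataFrame]:
    """Choose the sparsity bound s by a permutation gap statistic.

    gap(s) = log O(s; data) − mean over permutations of log O(s; data
    with every gene's values independently permuted across samples),
    where O is the sparse k-means objective. Returns the s with the
    largest gap (or, with ``one_se``, the smallest s within one standard
    error of the best) and the per-s gap table.
    """
    s_grid = list(s_grid)
    if not s_grid:
        raise ValueError("empty sparsity grid")
    rng = np.random.default_rng(seed)
    from .matrix import ExpressionMatrix

    perms = []
    X = matrix.values.to_numpy()
    for _ in range(n_permutations):
        Xp = np.array([row[rng.permutation(X.shape[1])] for row in X])
        perms.append(
            ExpressionMatrix(
                pd.DataFrame(Xp, index=matrix.genes, columns=matrix.samples)
            )
        )
    rows = []
    for s in s_grid:
        fit = sparse_kmeans(matrix, k, s, n_starts=n_starts,
                            seed=int(rng.integers(2**31 - 1)))
        logo = np.log(max(fit.objective, 1e-300))
        perm_logs = []
        for pm in perms:
            pf = sparse_kmeans(pm, k, s, n_starts=max(1, n_starts // 2),
                               seed=int(rng.integers(2**31 - 1)))
            perm_logs.append(np.log(max(pf.objective, 1e-300)))
        perm_logs = np.array(perm_logs)
        se = perm_logs.std(ddof=1) / np.sqrt(len(perm_logs)) if len(perm_logs) > 1 else 0.0
        rows.append(
            {"s": s, "log_obj": logo, "gap": logo - perm_logs.mean(), "se": se,
             "n_nonzero": int((fit.weights > 0).sum())}
        )
    table = pd.DataFrame(rows)
    best_i = int(table["gap"].idxmax())
    if one_se:
        bound = table.loc[best_i, "gap"] - table.loc[best_i, "se"]
        ok = table[table["gap"] >= bound]
        s_star = float(ok["s"].min())
    else:
        s_star = float(table.loc[best_i, "s"])
    return s_star, table
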