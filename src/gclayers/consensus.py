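"""Consensus clustering over subsampled runs.

For each candidate group number k, samples are repeatedly subsampled and
clustered; the consensus matrix records, for every sample pair, the
fraction of co-sampled runs in which they co-clustered. The number of
groups is chosen by the delta-area of the consensus CDF; the proportion
of ambiguous clustering (PAC) is reported as a stability measure; final
labels come from average-linkage hierarchical clustering on 1 − M.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

__all__ = ["ConsensusResult", "consensus_cluster", "consensus_area", "pac_score"]


@dataclass
class ConsensusResult:
    """Consensus matrices and the selected clustering."""

    k_range: list[int]
    consensus: dict[int, pd.DataFrame]
    area: dict[int, float]
    delta_area: dict[int, float]
    pac: dict[int, float]
    k_star: int
    labels: pd.Series  # per sample, 1..k_star
    extras: dict = field(default_factory=dict)


def consensus_area(M: np.ndarray) -> float:
    """Area under the empirical CDF of the upper-triangle consensus
    entries; equals 1 − mean(entries) on [0, 1]."""
    entries = M[np.triu_indices_from(M, k=1)]
    if entries.size == 0:
        return 0.0
    return float(1.0 - entries.mean())


def pac_score(M: np.ndarray, lower: float = 0.1, upper: float = 0.9) -> float:
    """Proportion of ambiguous clustering: fraction of off-diagonal
    consensus entries strictly inside (lower, upper)."""
    entries = M[np.triu_indices_from(M, k=1)]
    if entries.size == 0:
        return 0.0
    return float(((entries > lower) & (entries < upper)).mean())


def consensus_cluster(
    matrix,
    k_range=(2, 3, 4),
    n_resample: int = 500,
    p_sample: float = 0.8,
    inner_restarts: int = 10,
    criterion: str = "pac",
    inner=None,
    seed: int = 0,
) -> ConsensusResult:
    """Consensus clustering of samples on the given (gene-wise) matrix.

    Per k: ``n_resample`` subsamples of ⌈p_sample·n⌉ samples are
    clustered with k-means (``inner_restarts`` restarts); the consensus
    matrix is the co-cluster count over the co-sample count (0 for never
    co-sampled pairs, diagonal 1). The delta-area of the consensus CDF
    (Δ(k₀)=A(k₀) for the smallest k₀, (A(k)−A(k−1))/A(k−1) after) and
    the PAC are computed for every k. By default k* minimizes the PAC
    (ties to the smaller k) — the CDF area grows with k even for pure
    noise, which biases the raw delta-area rule upward on unbalanced
    groups; ``criterion="delta"`` selects by maximum delta-area instead.
    Final labels are average-linkage hierarchical clusters of 1 − M_k*,
    cut at k*. ``inner`` may replace the subsample clusterer with any
    callable (X_subsample, k, random_state) → labels.
    """
    k_range = sorted(set(int(k) for k in k_range))
    n = matrix.n_samples
    if not k_range or k_range[0] < 2:
        raise ValueError("k_range must contain integers >= 2")
    if k_range[-1] > max(2, n // 2):
        raise ValueError(f"largest k {k_range[-1]} exceeds n_samples/2 = {n // 2}")
    if not 0 < p_sample <= 1:
        raise ValueError("p_sample must be in (0, 1]")
    if n_resample < 2:
        raise ValueError("n_resample must be >= 2")

    X = matrix.values.to_numpy().T  # samples × genes
    m = math.ceil(p_sample * n)
    rng = np.random.default_rng(seed)

    consensus: dict[int, pd.DataFrame] = {}
    area: dict[int, float] = {}
    pac: dict[int, float] = {}
    for k in k_range:
        co_cluster = np.zeros((n, n))
        co_sample = np.zeros((n, n))
        for _ in range(n_resample):
            idx = np.sort(rng.choice(n, size=m, replace=False))
            rs = int(rng.integers(2**31 - 1))
            if inner is None:
                labs = KMeans(
                    n_clusters=k, n_init=inner_restarts, random_state=rs
                ).fit(X[idx]).labels_
            else:
                labs = np.asarray(inner(X[idx], k, rs))
            co_sample[np.ix_(idx, idx)] += 1
            same = labs[:, None] == labs[None, :]
            co_cluster[np.ix_(idx, idx)] += same
        with np.errstate(invalid="ignore", divide="ignore"):
            M = np.where(co_sample > 0, co_cluster / np.maximum(co_sample, 1), 0.0)
        np.fill_diagonal(M, 1.0)
        M = (M + M.T) / 2
        consensus[k] = pd.DataFrame(M, index=matrix.samples, columns=matrix.samples)
        area[k] = consensus_area(M)
        pac[k] = pac_score(M)

    delta: dict[int, float] = {}
    prev = None
    for k in k_range:
        if prev is None:
            delta[k] = area[k]
        else:
            delta[k] = (area[k] - area[prev]) / area[prev] if area[prev] > 0 else 0.0
        prev = k
    if criterion == "pac":
        k_star = min(k_range, key=lambda k: (pac[k], k))
    elif criterion == "delta":
        k_star = max(k_range, key=lambda k: (delta[k], -k))
    else:
        raise ValueError(f"unknown selection criterion {criterion!r}")

    M = consensus[k_star].to_numpy()
    dist = 1.0 - M
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(Z, t=k_star, criterion="maxclust")
    return ConsensusResult(
        k_range=k_range,
        consensus=consensus,
        area=area,
        delta_area=delta,
        pac=pac,
        k_star=k_star,
        labels=pd.Series(labels, index=matrix.samples),
    )
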