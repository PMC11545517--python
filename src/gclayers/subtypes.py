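"""Molecular-subtype attribution.

A differential gene set among labeled samples is defined with a
multiclass SAM statistic (moderated between-class dispersion with a
permutation FDR); per-subtype centroids are the mean expression of that
panel; unlabeled samples are assigned to the subtype whose centroid they
correlate with best (Pearson).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SamResult",
    "SubtypeCentroids",
    "sam_multiclass",
    "compute_centroids",
    "assign_by_centroid",
    "assign_samples",
]

log = logging.getLogger(__name__)


@dataclass
class SamResult:
    """Multiclass SAM output: per-gene d statistic, fudge factor s0,
    permutation q-values and the significant set at the chosen FDR."""

    d: pd.Series
    s0: float
    q: pd.Series
    significant: list[str]
    fdr: float


@dataclass
class SubtypeCentroids:
    """Per-subtype mean-expression vectors over a gene panel."""

    panel: list[str]
    centroids: pd.DataFrame  # genes (panel) × subtypes

    def __post_init__(self):
        if list(self.centroids.index) != list(self.panel):
            raise ValueError("centroid index must equal the panel")
        if self.centroids.shape[1] < 2:
            raise ValueError("need at least 2 subtypes")

    @property
    def subtypes(self) -> list[str]:
        return list(self.centroids.columns)


def _class_indices(labels: pd.Series) -> tuple[list, np.ndarray]:
    classes = sorted(labels.unique())
    idx = np.array([classes.index(v) for v in labels])
    return classes, idx


def _multiclass_d(X: np.ndarray, cls_idx: np.ndarray, n_classes: int, s0: float):
    """d_g = sqrt(between-class mean square) / (s_g + s0).

    s_g is the pooled within-class standard deviation. Vectorized over
    genes (rows of X).
    """
    n = X.shape[1]
    counts = np.bincount(cls_idx, minlength=n_classes).astype(float)
    # per-class means: genes × classes
    onehot = np.zeros((n, n_classes))
    onehot[np.arange(n), cls_idx] = 1.0
    sums = X @ onehot
    means = sums / counts
    grand = X.mean(axis=1, keepdims=True)
    bcss = ((means - grand) ** 2 * counts).sum(axis=1)
    wss = (X**2 @ onehot - counts * means**2).sum(axis=1)
    wss = np.maximum(wss, 0.0)
    s = np.sqrt(wss / (n - n_classes))
    r = np.sqrt(bcss / (n_classes - 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        d = r / (s + s0)
    return d, s, r


def _choose_s0(s: np.ndarray, r: np.ndarray) -> float:
    """Fudge factor: the percentile of s minimizing the coefficient of
    variation of the d statistic across bins of s (Tusher-style)."""
    n_bins = min(20, max(2, len(s) // 10))
    order = np.argsort(s, kind="stable")
    bins = np.array_split(order, n_bins)
    best_s0, best_cv = None, np.inf
    for pct in range(0, 101, 5):
        s0 = float(np.percentile(s, pct))
        if s0 == 0.0 and s.min() == 0.0:
            continue  # would leave zero-variance genes with infinite d
        d = r / (s + s0)
        mads = []
        for b in bins:
            if len(b):
                db = d[b]
                mads.append(np.median(np.abs(db - np.median(db))) / 0.6745)
        mads = np.array(mads)
        mean = mads.mean()
        cv = mads.std(ddof=0) / mean if mean > 0 and np.isfinite(mean) else np.inf
        if cv < best_cv - 1e-12:
            best_cv, best_s0 = cv, s0
    if best_s0 is None or best_s0 == 0.0 and s.min() == 0.0:
        # fully degenerate pooled SDs: fall back to a small positive
        # fraction of the contrast scale so d stays finite
        pos = r[r > 0]
        best_s0 = 0.05 * float(np.median(pos)) if pos.size else 1e-6
    return float(best_s0)


def _label_permutations(cls_idx: np.ndarray, n_permutations: int, rng):
    """Yield permuted class-index vectors.

    When the number of distinct label arrangements is small enough, all
    of them are enumerated (exhaustive null); otherwise ``n_permutations``
    random shuffles are drawn.
    """
    n = len(cls_idx)
    counts = np.bincount(cls_idx)
    log_total = math.lgamma(n + 1) - sum(math.lgamma(c + 1) for c in counts)
    if log_total <= math.log(max(n_permutations, 2)) + 1e-9:
        from sympy.utilities.iterables import multiset_permutations

        for perm in multiset_permutations(list(cls_idx)):
            yield np.array(perm)
    else:
        for _ in range(n_permutations):
            yield rng.permutation(cls_idx)


def sam_multiclass(
    matrix,
    labels: pd.Series | dict,
    n_permutations: int = 100,
    fdr: float = 0.05,
    seed: int = 0,
) -> SamResult:
    """Multiclass SAM: moderated d statistic with a permutation FDR.

    ``labels`` maps a subset of the matrix samples to class names; every
    class needs ≥ 2 samples and the matrix must be complete. The fudge
    factor s0 is chosen as the percentile of the per-gene pooled SD that
    minimizes the coefficient of variation of d. For each gene the q-value
    is the (monotonized) median permutation false-positive count divided
    by the observed call count at that gene's threshold; genes with
    q < ``fdr`` form the significant set. Deterministic per seed; the
    permutation null is enumerated exhaustively when feasible.
    """
    labels = pd.Series(labels)
    if matrix.n_missing:
        raise ValueError("sam_multiclass requires a complete matrix")
    sub = matrix.subset_samples(list(labels.index))
    classes, cls_idx = _class_indices(labels.loc[sub.samples])
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    counts = np.bincount(cls_idx)
    if counts.min() < 2:
        small = classes[int(np.argmin(counts))]
        raise ValueError(f"class {small!r} has fewer than 2 samples")

    X = sub.values.to_numpy()
    genes = sub.genes
    _, s, r = _multiclass_d(X, cls_idx, len(classes), 0.0)
    s0 = _choose_s0(s, r)
    d, _, _ = _multiclass_d(X, cls_idx, len(classes), s0)

    rng = np.random.default_rng(seed)
    perm_ds = []
    for perm in _label_permutations(cls_idx, n_permutations, rng):
        pd_, _, _ = _multiclass_d(X, perm, len(classes), s0)
        perm_ds.append(pd_)
    perm_ds = np.sort(np.concatenate(perm_ds))

    order = np.argsort(-d, kind="stable")
    d_sorted = d[order]
    # expected false positives at each threshold: mean permutation count
    # of statistics >= d_g, per permutation
    exceed = len(perm_ds) - np.searchsorted(perm_ds, d_sorted, side="left")
    n_perm_total = max(1, len(perm_ds) // len(genes))
    expected_fp = exceed / n_perm_total
    called = np.arange(1, len(genes) + 1)
    fdr_at = np.minimum(expected_fp / called, 1.0)
    qvals_sorted = np.minimum.accumulate(fdr_at[::-1])[::-1]
    q = np.empty_like(qvals_sorted)
    q[order] = qvals_sorted
    q_series = pd.Series(q, index=genes)
    d_series = pd.Series(d, index=genes)
    significant = [g for g in genes if q_series[g] < fdr]
    return SamResult(d=d_series, s0=s0, q=q_series, significant=significant, fdr=fdr)


def compute_centroids(matrix, labels: pd.Series | dict, panel) -> SubtypeCentroids:
    """Per-subtype mean expression over ``panel`` genes."""
    labels = pd.Series(labels)
    panel = list(panel)
    sub = matrix.subset_genes(panel).subset_samples(list(labels.index))
    cols = {}
    for subtype in sorted(labels.unique()):
        members = [s for s in sub.samples if labels[s] == subtype]
        if not members:
            raise ValueError(f"subtype {subtype!r} has no labeled samples")
        cols[subtype] = sub.values[members].mean(axis=1)
    return SubtypeCentroids(panel=panel, centroids=pd.DataFrame(cols))


def assign_by_centroid(profile: pd.Series, centroids: SubtypeCentroids):
    """Nearest-centroid call by Pearson correlation over the panel.

    Returns (subtype, per-subtype correlations). Ties are broken by the
    centroid column order with a logged warning.
    """
    if len(centroids.panel) < 3:
        raise ValueError("panel must have at least 3 genes")
    x = profile.loc[centroids.panel].to_numpy(dtype=float)
    if np.std(x) == 0:
        raise ValueError("profile has zero variance; correlation undefined")
    corrs = {}
    for subtype in centroids.subtypes:
        c = centroids.centroids[subtype].to_numpy()
        if np.std(c) == 0:
            raise ValueError(f"centroid {subtype!r} has zero variance")
        corrs[subtype] = float(np.corrcoef(x, c)[0, 1])
    best = max(corrs.values())
    winners = [s for s in centroids.subtypes if corrs[s] >= best - 1e-12]
    if len(winners) > 1:
        log.warning("correlation tie among %s; keeping %s", winners, winners[0])
    return winners[0], corrs


def assign_samples(matrix, centroids: SubtypeCentroids, known: pd.Series | dict | None = None) -> pd.DataFrame:
    """Assign every sample of ``matrix`` by nearest centroid.

    Samples present in ``known`` keep their label (flagged
    ``was_preassigned``). Returns a table with the assigned subtype and
    all per-subtype correlations.
    """
    known = pd.Series(known) if known is not None else pd.Series(dtype=object)
    rows = []
    sub = matrix.subset_genes(centroids.panel)
    for s in sub.samples:
        subtype, corrs = assign_by_centroid(sub.values[s], centroids)
        pre = s in known.index and not pd.isna(known.get(s))
        rows.append(
            {
                "sample_id": s,
                "assigned_subtype": known[s] if pre else subtype,
                "was_preassigned": pre,
                **{f"r_{k}": v for k, v in corrs.items()},
            }
        )
    return pd.DataFrame(rows)
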