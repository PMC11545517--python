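"""Survival comparison and nonparametric group tests.

Kaplan–Meier curves with median OS, the log-rank test, two-group hazard
ratios from a single-covariate Cox model (Efron ties), and
Mann–Whitney / Kruskal–Wallis comparisons of functional-node activities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy.stats import false_discovery_control, kruskal, mannwhitneyu, norm, rankdata

__all__ = [
    "SurvivalCurve",
    "GroupTestResult",
    "kaplan_meier",
    "logrank_test",
    "hazard_ratio",
    "compare_activities",
    "dunn_posthoc",
    "plot_km",
]

log = logging.getLogger(__name__)


@dataclass
class SurvivalCurve:
    """Product-limit estimate: step function, event table and median."""

    times: np.ndarray  # distinct observed times (months)
    survival: np.ndarray  # S(t) immediately after each time
    at_risk: np.ndarray
    events: np.ndarray
    median: float | None  # None = median not reached

    def at(self, t: float) -> float:
        """S(t) of the right-continuous step function."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class GroupTestResult:
    """Outcome of a group-comparison test."""

    test: str
    statistic: float
    df: int | None
    p_value: float
    hr: float | None = None
    ci: tuple[float, float] | None = None


def _check_times(times, events):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) != len(events):
        raise ValueError("times and events must have equal length")
    if (times < 0).any():
        raise ValueError("negative survival time")
    return times, events


def kaplan_meier(times, events) -> SurvivalCurve:
    """Kaplan–Meier product-limit estimator.

    Censorings tied with events are taken to occur after them. The
    median is the smallest t with S(t) ≤ 0.5, or None ("not reached")
    when S never drops that far.
    """
    times, events = _check_times(times, events)
    kmf = KaplanMeierFitter().fit(times, events)
    grid = np.unique(times)
    tab = kmf.event_table.loc[grid]
    surv = kmf.survival_function_at_times(grid).to_numpy(dtype=float)
    med = float(kmf.median_survival_time_)
    return SurvivalCurve(
        times=grid,
        survival=surv,
        at_risk=tab["at_risk"].to_numpy(),
        events=tab["observed"].to_numpy(),
        median=None if np.isinf(med) else med,
    )


def logrank_test(times, events, groups) -> GroupTestResult:
    """Log-rank chi-squared test across ≥ 2 groups (df = groups − 1)."""
    times, events = _check_times(times, events)
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    res = multivariate_logrank_test(times, groups, events)
    return GroupTestResult(
        test="log-rank",
        statistic=float(res.test_statistic),
        df=len(levels) - 1,
        p_value=float(res.p_value),
    )


def hazard_ratio(times, events, groups) -> GroupTestResult:
    """Hazard ratio between two groups from a single-covariate Cox model.

    The covariate is 1 for the lexicographically larger group label;
    HR = exp(β̂) with a 95% Wald CI (Efron tie handling). Raises when
    there are no events.
    """
    times, events = _check_times(times, events)
    groups = np.asarray(groups)
    levels = sorted(pd.unique(groups))
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {len(levels)}")
    if events.sum() == 0:
        raise ValueError("no events; hazard ratio undefined")
    df = pd.DataFrame(
        {
            "t": times,
            "e": events,
            "x": (groups == levels[1]).astype(float),
        }
    )
    cph = CoxPHFitter()
    cph.fit(df, duration_col="t", event_col="e")
    beta = float(cph.params_["x"])
    se = float(cph.standard_errors_["x"])
    return GroupTestResult(
        test="cox",
        statistic=beta / se,
        df=1,
        p_value=float(cph.summary.loc["x", "p"]),
        hr=float(np.exp(beta)),
        ci=(float(np.exp(beta - 1.96 * se)), float(np.exp(beta + 1.96 * se))),
    )


def compare_activities(activity, groups) -> GroupTestResult:
    """Compare a per-sample activity across groups.

    Two groups → Mann–Whitney U (exact enumeration when the pooled n is
    ≤ 12 and tie-free, tie-corrected normal approximation otherwise);
    more → Kruskal–Wallis with tie correction. Constant activity across
    all samples yields p = 1 with a warning.
    """
    activity = np.asarray(activity, dtype=float)
    groups = np.asarray(groups)
    levels = sorted(pd.unique(groups))
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    parts = [activity[groups == g] for g in levels]
    if any(len(p) < 2 for p in parts):
        raise ValueError("every group needs at least 2 samples")
    if np.ptp(activity) == 0:
        log.warning("activity constant across all samples; p set to 1")
        return GroupTestResult(test="degenerate", statistic=0.0,
                               df=len(levels) - 1, p_value=1.0)
    if len(levels) == 2:
        n_total = len(activity)
        no_ties = len(np.unique(activity)) == n_total
        method = "exact" if (n_total <= 12 and no_ties) else "asymptotic"
        res = mannwhitneyu(parts[0], parts[1], alternative="two-sided", method=method)
        return GroupTestResult(test=f"mann-whitney ({method})",
                               statistic=float(res.statistic), df=None,
                               p_value=float(res.pvalue))
    res = kruskal(*parts)
    return GroupTestResult(test="kruskal-wallis", statistic=float(res.statistic),
                           df=len(levels) - 1, p_value=float(res.pvalue))


def dunn_posthoc(activity, groups) -> pd.DataFrame:
    """Dunn's pairwise z-tests on pooled ranks after Kruskal–Wallis, with
    Benjamini–Hochberg adjustment."""
    activity = np.asarray(activity, dtype=float)
    groups = np.asarray(groups)
    levels = sorted(pd.unique(groups))
    n = len(activity)
    ranks = rankdata(activity)
    # tie correction term
    _, counts = np.unique(activity, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12 * (n - 1)) if n > 1 else 0.0
    rows = []
    for i, a in enumerate(levels):
        for b in levels[i + 1 :]:
            ra, rb = ranks[groups == a], ranks[groups == b]
            na, nb = len(ra), len(rb)
            z = (ra.mean() - rb.mean()) / np.sqrt(
                (n * (n + 1) / 12 - tie_term) * (1 / na + 1 / nb)
            )
            rows.append({"group_a": a, "group_b": b, "z": float(z),
                         "p": float(2 * norm.sf(abs(z)))})
    df = pd.DataFrame(rows)
    df["q"] = false_discovery_control(df["p"].to_numpy(), method="bh")
    return df


def plot_km(times, events, groups, path) -> None:
    """Write a per-group Kaplan–Meier step plot to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    times, events = _check_times(times, events)
    groups = np.asarray(groups)
    fig, ax = plt.subplots(figsize=(6, 4))
    for g in sorted(pd.unique(groups)):
        m = groups == g
        KaplanMeierFitter().fit(times[m], events[m], label=str(g)).plot_survival_function(ax=ax)
    ax.set_xlabel("months")
    ax.set_ylabel("overall survival")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
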