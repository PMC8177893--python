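"""Temporal characterisation of HMM states and the factorial comparison
across conditions.

Definitions: a state's *fractional occupancy* (FO) is the fraction of total
time assigned to it; a *lifetime* (dwell time) is the duration of one visit;
an *interval* is the time between successive visits of the same state.
Visits shorter than 100 ms are unlikely to reflect neural processes and are
excluded from lifetime comparisons (the filter does not apply to FO or
intervals).

FO is analysed at the subject level with a two-way repeated-measures ANOVA
(state x condition, both within subject); lifetimes and intervals are pooled
at the visit level and analysed with a two-way fixed-effects ANOVA, matching
their much larger degrees of freedom.  Post hoc pairwise comparisons use
Tukey's HSD by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.formula.api import ols
from statsmodels.stats.anova import AnovaRM, anova_lm
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = ["TemporalMetrics", "AnovaResult", "compute_temporal_metrics",
           "anova_temporal", "metrics_table"]


def metrics_table(metrics: list["TemporalMetrics"]) -> pd.DataFrame:
    """Per subject x state x condition summary (FO, mean lifetime and
    interval with standard errors, visit counts) — one row per cell."""
    rows = []
    for m in metrics:
        for k in range(m.n_states):
            lt, iv = m.filtered_lifetimes_ms[k], m.intervals_ms[k]
            rows.append({
                "subject": m.subject_id, "condition": m.condition, "state": k,
                "fo": m.fractional_occupancy[k],
                "mean_lifetime_ms": lt.mean() if lt.size else np.nan,
                "sem_lifetime_ms": lt.std(ddof=1) / np.sqrt(lt.size) if lt.size > 1 else np.nan,
                "mean_interval_ms": iv.mean() if iv.size else np.nan,
                "sem_interval_ms": iv.std(ddof=1) / np.sqrt(iv.size) if iv.size > 1 else np.nan,
                "n_visits": int(m.n_visits[k]),
            })
    return pd.DataFrame(rows)


@dataclass
class TemporalMetrics:
    """One subject's per-state temporal statistics.

    ``lifetimes_ms[k]`` holds every visit duration; ``filtered_lifetimes_ms``
    only those exceeding the minimum-lifetime threshold (used for
    comparisons); ``intervals_ms[k]`` the gaps between successive visits.
    """

    fs: float
    n_states: int
    fractional_occupancy: np.ndarray
    lifetimes_ms: list[np.ndarray]
    filtered_lifetimes_ms: list[np.ndarray]
    intervals_ms: list[np.ndarray]
    n_visits: np.ndarray
    subject_id: str = "s0"
    condition: str = "A"
    min_lifetime_ms: float = 100.0


def compute_temporal_metrics(
    state_path: np.ndarray,
    fs: float,
    n_states: int | None = None,
    min_lifetime_ms: float = 100.0,
    subject_id: str = "s0",
    condition: str = "A",
) -> TemporalMetrics:
    """Run-length statistics of a hard state path.

    FO sums to 1 over states; each maximal run contributes one lifetime; the
    interval series of a state holds the gaps between consecutive runs.
    """
    path = np.asarray(state_path, dtype=int)
    if path.size == 0:
        raise ValueError("empty state path")
    K = int(n_states if n_states is not None else path.max() + 1)
    ms = 1000.0 / fs

    change = np.flatnonzero(np.diff(path)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [path.size]))
    run_states = path[starts]
    run_len = ends - starts

    fo = np.bincount(path, minlength=K) / path.size
    lifetimes = [run_len[run_states == k] * ms for k in range(K)]
    filtered = [lt[lt > min_lifetime_ms] for lt in lifetimes]
    intervals = []
    n_visits = np.zeros(K, dtype=int)
    for k in range(K):
        idx = np.flatnonzero(run_states == k)
        n_visits[k] = idx.size
        if idx.size > 1:
            gaps = starts[idx[1:]] - ends[idx[:-1]]
            intervals.append(gaps * ms)
        else:
            intervals.append(np.empty(0))
    return TemporalMetrics(
        fs=fs, n_states=K, fractional_occupancy=fo,
        lifetimes_ms=lifetimes, filtered_lifetimes_ms=filtered,
        intervals_ms=intervals, n_visits=n_visits,
        subject_id=subject_id, condition=condition, min_lifetime_ms=min_lifetime_ms,
    )


@dataclass
class AnovaResult:
    """Two-way ANOVA table plus post hoc pairwise comparisons."""

    metric: str
    table: pd.DataFrame
    post_hoc: pd.DataFrame | None = None
    excluded_states: list[int] = field(default_factory=list)

    def f_statistic(self, effect: str) -> float:
        return float(self.table.loc[effect, "F"])

    def p_value(self, effect: str) -> float:
        col = "p" if "p" in self.table.columns else "PR(>F)"
        return float(self.table.loc[effect, col])


def _visit_frame(metrics: list[TemporalMetrics], which: str) -> pd.DataFrame:
    rows = []
    for m in metrics:
        source = m.filtered_lifetimes_ms if which == "lifetime" else m.intervals_ms
        for k in range(m.n_states):
            for v in source[k]:
                rows.append((m.subject_id, m.condition, k, float(v)))
    return pd.DataFrame(rows, columns=["subject", "condition", "state", "value"])


def anova_temporal(
    metrics_A: list[TemporalMetrics],
    metrics_B: list[TemporalMetrics],
    metric: str = "fo",
    post_hoc: str = "tukey",
) -> AnovaResult:
    """Two-way ANOVA of a temporal metric across states and conditions.

    ``metric="fo"`` runs a repeated-measures ANOVA on subject-level FO
    (both factors within subject; subjects must appear in both conditions).
    ``"lifetime"``/``"interval"`` pool visits and run a fixed-effects
    two-way ANOVA (type II).  States with no qualifying observations in
    either condition are excluded with a warning.  The post hoc compares
    states pairwise on the pooled values (Tukey HSD or Bonferroni t-tests).
    """
    all_metrics = list(metrics_A) + list(metrics_B)
    if metric == "fo":
        rows = []
        for m in all_metrics:
            for k in range(m.n_states):
                rows.append((m.subject_id, m.condition, k, float(m.fractional_occupancy[k])))
        df = pd.DataFrame(rows, columns=["subject", "condition", "state", "value"])
        excluded: list[int] = []
        res = AnovaRM(df, depvar="value", subject="subject",
                      within=["state", "condition"]).fit()
        table = res.anova_table.rename(columns={"F Value": "F", "Pr > F": "p"})
        table = table.rename(index={
            "state": "state", "condition": "condition", "state:condition": "state:condition"})
    elif metric in ("lifetime", "interval"):
        df = _visit_frame(all_metrics, metric)
        counts = df.groupby(["state", "condition"]).size().unstack(fill_value=0)
        excluded = [int(k) for k in counts.index if (counts.loc[k] == 0).any()]
        if excluded:
            warnings.warn(f"states without qualifying visits excluded: {excluded}",
                          RuntimeWarning, stacklevel=2)
            df = df[~df["state"].isin(excluded)]
        if df["state"].nunique() < 2 or df["condition"].nunique() < 2:
            raise ValueError("need >= 2 states and both conditions after exclusion")
        model = ols("value ~ C(state) * C(condition)", data=df).fit()
        table = anova_lm(model, typ=2)
        table = table.rename(index={
            "C(state)": "state", "C(condition)": "condition",
            "C(state):C(condition)": "state:condition"})
    else:
        raise ValueError(f"unknown metric {metric!r}")

    if metric == "fo":
        ph_df = df
    else:
        ph_df = df
    if post_hoc == "tukey" and ph_df["state"].nunique() > 1:
        tk = pairwise_tukeyhsd(ph_df["value"], ph_df["state"].astype(str))
        ph = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
    elif post_hoc == "bonferroni":
        states = sorted(ph_df["state"].unique())
        from scipy import stats as sstats
        rows, n_comp = [], len(states) * (len(states) - 1) // 2
        for i, a in enumerate(states):
            for b in states[i + 1:]:
                t, p = sstats.ttest_ind(ph_df.loc[ph_df.state == a, "value"],
                                        ph_df.loc[ph_df.state == b, "value"])
                rows.append((a, b, t, min(p * n_comp, 1.0)))
        ph = pd.DataFrame(rows, columns=["group1", "group2", "t", "p_corrected"])
    else:
        ph = None
    return AnovaResult(metric=metric, table=table, post_hoc=ph, excluded_states=excluded)
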