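"""Inferential statistics for the animal cohorts.

One-way ANOVA across treatment groups with Bonferroni-corrected pairwise
post-hoc tests for the size and cytokine endpoints; Welch's unequal-variance
t for two-group comparisons; Kaplan–Meier medians and the log-rank test for
the survival endpoint.  Animals alive at the study termination day enter as
censored observations.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

__all__ = [
    "GroupSample",
    "SurvivalSample",
    "one_way_anova",
    "bonferroni_pairwise",
    "welch_t",
    "km_median",
    "logrank",
    "read_groups_csv",
    "read_survival_csv",
]


@dataclass(frozen=True)
class GroupSample:
    """Labelled measurements (tumor areas in mm² or cytokines in pg/ml)."""

    label: str
    values: tuple[float, ...]

    def __init__(self, label: str, values) -> None:
        values = tuple(float(v) for v in values)
        if not values:
            raise ValueError(f"group {label!r} is empty")
        if not all(np.isfinite(values)):
            raise ValueError(f"group {label!r} contains non-finite values")
        object.__setattr__(self, "label", label)
        object.__setattr__(self, "values", values)

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class SurvivalSample:
    """Survival times in days with event flags (1 death, 0 censored)."""

    times: tuple[float, ...]
    events: tuple[int, ...]

    def __init__(self, times, events) -> None:
        times = tuple(float(t) for t in times)
        events = tuple(int(e) for e in events)
        if len(times) != len(events):
            raise ValueError("times and events must have equal length")
        if not times:
            raise ValueError("survival sample is empty")
        if any(t <= 0 for t in times):
            raise ValueError("survival times must be positive")
        if any(e not in (0, 1) for e in events):
            raise ValueError("event flags must be 0 or 1")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "events", events)

    @property
    def n(self) -> int:
        return len(self.times)

    @property
    def n_events(self) -> int:
        return sum(self.events)


def one_way_anova(groups: list[GroupSample]) -> tuple[float, float]:
    """Classic fixed-effects one-way ANOVA: returns (F, p)."""
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two groups")
    for g in groups:
        if g.n < 2:
            raise ValueError(f"group {g.label!r} has fewer than two observations")
    pooled_within = sum(np.var(g.values, ddof=1) for g in groups)
    if pooled_within == 0:
        raise ValueError("zero within-group variance in every group")
    f, p = stats.f_oneway(*(g.values for g in groups))
    return float(f), float(p)


def welch_t(a: GroupSample, b: GroupSample) -> tuple[float, float, float]:
    """Welch's two-sample t-test: returns (t, Welch–Satterthwaite df, p)."""
    if a.n < 2 or b.n < 2:
        raise ValueError("each group needs at least two observations")
    va, vb = np.var(a.values, ddof=1), np.var(b.values, ddof=1)
    if va == 0 and vb == 0:
        if np.mean(a.values) == np.mean(b.values):
            # identical constants: no evidence of a difference
            return 0.0, float(a.n + b.n - 2), 1.0
        raise ValueError("both group variances are zero with unequal means")
    res = stats.ttest_ind(a.values, b.values, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def _pooled_t(a: GroupSample, b: GroupSample) -> tuple[float, float, float]:
    res = stats.ttest_ind(a.values, b.values, equal_var=True)
    return float(res.statistic), float(res.df), float(res.pvalue)


def bonferroni_pairwise(
    groups: list[GroupSample],
    welch: bool = False,
) -> pd.DataFrame:
    """All pairwise two-sample tests with Bonferroni correction.

    The adjusted p-value is ``min(1, raw_p * n_pairs)``.  The base test is
    the pooled-variance t by default (common post-hoc convention), or
    Welch's t with ``welch=True``.  Returns a symmetric matrix of adjusted
    p-values with NaN on the diagonal.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    labels = [g.label for g in groups]
    if len(set(labels)) != len(labels):
        raise ValueError("group labels must be unique")
    pairs = list(combinations(range(len(groups)), 2))
    n_pairs = len(pairs)
    mat = pd.DataFrame(np.nan, index=labels, columns=labels)
    test = welch_t if welch else _pooled_t
    for i, j in pairs:
        _, _, p = test(groups[i], groups[j])
        adj = min(1.0, p * n_pairs)
        mat.iloc[i, j] = adj
        mat.iloc[j, i] = adj
    return mat


def km_survival(s: SurvivalSample) -> KaplanMeierFitter:
    """Fitted Kaplan–Meier estimator for one sample."""
    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(s.times), event_observed=np.asarray(s.events))
    return kmf


def km_median(s: SurvivalSample) -> float | None:
    """Kaplan–Meier median: smallest time with S(t) <= 0.5.

    Returns None when the survival curve never reaches 0.5 (median
    undefined, e.g. all animals censored).
    """
    sf = km_survival(s).survival_function_.iloc[:, 0]
    # tolerance so an estimate of exactly 0.5 counts as reached
    crossed = sf[sf.values <= 0.5 + 1e-12]
    if crossed.empty:
        return None
    return float(crossed.index[0])


def logrank(a: SurvivalSample, b: SurvivalSample) -> tuple[float, float]:
    """Two-group log-rank test: returns (chi-square with 1 df, p)."""
    if a.n_events + b.n_events == 0:
        raise ValueError("log-rank test requires at least one event")
    res = logrank_test(
        np.asarray(a.times),
        np.asarray(b.times),
        event_observed_A=np.asarray(a.events),
        event_observed_B=np.asarray(b.events),
    )
    return float(res.test_statistic), float(res.p_value)


def read_groups_csv(path: str | Path, value_col: str = "value") -> list[GroupSample]:
    """Read labelled measurements from a CSV with columns group, value."""
    df = pd.read_csv(path)
    if "group" not in df.columns or value_col not in df.columns:
        raise ValueError(f"{path}: expected columns 'group' and {value_col!r}")
    return [
        GroupSample(str(label), sub[value_col].tolist())
        for label, sub in df.groupby("group", sort=False)
    ]


def read_survival_csv(path: str | Path) -> dict[str, SurvivalSample]:
    """Read survival records from a CSV with columns group, time_days, event."""
    df = pd.read_csv(path)
    required = {"group", "time_days", "event"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    return {
        str(label): SurvivalSample(sub["time_days"].tolist(), sub["event"].tolist())
        for label, sub in df.groupby("group", sort=False)
    }
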