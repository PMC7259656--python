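"""Two-fraction interval scans: predicted tumor size versus fraction gap.

Simulates 1-MT plus two 8-Gy fractions with the first fraction fixed
(day 7 by default) and the second delayed by a varying interval, recording
the predicted cross-section area at one or more evaluation days.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd

from .model_core import DEFAULT_MT_DAYS, ModelParams, TreatmentSchedule, simulate

__all__ = [
    "DEFAULT_INTERVALS",
    "DEFAULT_EVAL_DAYS",
    "scan_intervals",
    "optimal_interval",
    "plot_scan",
]

#: Default scanned gaps bracket the study's short (4 d) and long (7 d) arms.
DEFAULT_INTERVALS = tuple(range(1, 15))
#: Default evaluation days: the sacrifice day and two later time points.
DEFAULT_EVAL_DAYS = (18, 25, 32)


def scan_intervals(
    params: ModelParams,
    first_day: int = 7,
    dose: float = 8.0,
    intervals: Iterable[int] = DEFAULT_INTERVALS,
    mt_days: Iterable[int] = DEFAULT_MT_DAYS,
    eval_days: Iterable[int] = DEFAULT_EVAL_DAYS,
) -> pd.DataFrame:
    """Scan two-fraction schedules over inter-fraction intervals.

    Returns a table with one row per (interval, eval_day) pair and the
    predicted area in mm².  A second fraction falling after an evaluation
    day simply does not influence that day's prediction.
    """
    intervals = sorted({int(d) for d in intervals})
    eval_days = sorted({int(d) for d in eval_days})
    if not intervals:
        raise ValueError("no intervals to scan")
    if any(d < 1 for d in intervals):
        raise ValueError("intervals must be >= 1 day")
    if not eval_days:
        raise ValueError("no evaluation days")
    mt = frozenset(mt_days)
    horizon = max(eval_days + [first_day + max(intervals)])
    rows = []
    for delta in intervals:
        schedule = TreatmentSchedule(
            [(first_day, dose), (first_day + delta, dose)], mt
        )
        traj = simulate(params, schedule, horizon)
        for day in eval_days:
            rows.append(
                {"interval": delta, "eval_day": day, "area_mm2": traj.area_at(day)}
            )
    return pd.DataFrame(rows)


def optimal_interval(table: pd.DataFrame, eval_day: int) -> int:
    """Interval with the smallest predicted area at ``eval_day``.

    Ties are broken toward the smaller interval.
    """
    sub = table[table["eval_day"] == eval_day]
    if sub.empty:
        raise ValueError(f"evaluation day {eval_day} not present in the scan table")
    sub = sub.sort_values(["area_mm2", "interval"], kind="stable")
    return int(sub.iloc[0]["interval"])


def plot_scan(table: pd.DataFrame, path: str | Path) -> None:
    """Plot predicted area against the fraction interval, one curve per day."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for day, sub in table.groupby("eval_day"):
        sub = sub.sort_values("interval")
        ax.plot(sub["interval"], sub["area_mm2"], marker="o", label=f"day {day}")
    ax.set_xlabel("interval between fractions (days)")
    ax.set_ylabel("predicted cross-section area (mm$^2$)")
    ax.set_yscale("log")
    ax.legend(title="evaluation day")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
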