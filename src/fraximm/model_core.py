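"""Discrete-time tumor–immune dynamics under fractionated radiotherapy.

The model tracks the coronal cross-section area of an intracranial tumor
(mm²) on a daily grid.  Growth follows a Gompertz law with carrying
capacity ``K``.  Each radiation fraction kills a fraction of the tumor
according to the linear-quadratic survival model; the killed area is
recruited into an immune-stimulation state ``I`` (antigen release), which
decays geometrically and exerts a daily multiplicative kill on the tumor.
While the IDO1 inhibitor 1-methyl-tryptophan (1-MT) is active, the immune
kill is potentiated by a factor ``1 + sigma``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ModelParams",
    "TreatmentSchedule",
    "TumorState",
    "Trajectory",
    "gompertz_step",
    "lq_survival",
    "daily_update",
    "simulate",
    "DEFAULT_PARAMS",
]


@dataclass(frozen=True)
class ModelParams:
    """Rate constants of the tumor–immune model.

    Parameters
    ----------
    a : float
        Gompertz growth rate (per day, >= 0).
    K : float
        Carrying capacity of the coronal cross-section area (mm², > 0).
    C0 : float
        Tumor cross-section area at day 0 / inoculation (mm², 0 < C0 < K).
    alpha, beta : float
        Linear-quadratic radiosensitivities (per Gy and per Gy², >= 0).
    gamma : float
        Daily retention of the immune-stimulation state, in [0, 1).
    mu : float
        Immune kill efficiency (per unit stimulation per day, >= 0).
    sigma : float
        Dimensionless potentiation of the immune kill while 1-MT is
        active (>= 0).
    """

    a: float
    K: float
    C0: float
    alpha: float
    beta: float
    gamma: float
    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not (self.a >= 0):
            raise ValueError(f"growth rate a must be >= 0, got {self.a}")
        if not (self.K > 0):
            raise ValueError(f"carrying capacity K must be > 0, got {self.K}")
        if not (0 < self.C0 < self.K):
            raise ValueError(
                f"initial size C0 must satisfy 0 < C0 < K, got C0={self.C0}, K={self.K}"
            )
        if not (self.alpha >= 0 and self.beta >= 0):
            raise ValueError("radiosensitivities alpha, beta must be >= 0")
        if not (0 <= self.gamma < 1):
            raise ValueError(f"immune retention gamma must be in [0, 1), got {self.gamma}")
        if not (self.mu >= 0):
            raise ValueError(f"immune kill efficiency mu must be >= 0, got {self.mu}")
        if not (self.sigma >= 0):
            raise ValueError(f"1-MT potentiation sigma must be >= 0, got {self.sigma}")

    def with_values(self, **kwargs: float) -> "ModelParams":
        """Return a copy with some fields replaced (validated)."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class TreatmentSchedule:
    """Radiation events and drug-active days for one treatment arm.

    ``rt_events`` is a sequence of ``(day, dose_gy)`` pairs; ``mt_days``
    the set of days on which 1-MT is active.
    """

    rt_events: tuple[tuple[int, float], ...] = ()
    mt_days: frozenset[int] = field(default_factory=frozenset)

    def __init__(
        self,
        rt_events: Iterable[tuple[int, float]] = (),
        mt_days: Iterable[int] = (),
    ) -> None:
        events = tuple((int(d), float(dose)) for d, dose in rt_events)
        days = [d for d, _ in events]
        if len(set(days)) != len(days):
            raise ValueError(f"duplicate radiation days in schedule: {days}")
        for d, dose in events:
            if d < 0:
                raise ValueError(f"radiation day must be >= 0, got {d}")
            if dose <= 0:
                raise ValueError(f"radiation dose must be > 0 Gy, got {dose}")
        object.__setattr__(self, "rt_events", events)
        object.__setattr__(self, "mt_days", frozenset(int(d) for d in mt_days))

    def dose_on(self, day: int) -> float:
        for d, dose in self.rt_events:
            if d == day:
                return dose
        return 0.0

    def mt_active_on(self, day: int) -> bool:
        return day in self.mt_days

    @property
    def last_event_day(self) -> int:
        days = [d for d, _ in self.rt_events]
        return max(days) if days else 0


@dataclass(frozen=True)
class TumorState:
    """Tumor area C (mm²) and immune stimulation I at one day."""

    day: int
    C: float
    I: float

    def __post_init__(self) -> None:
        if self.C < 0 or self.I < 0:
            raise ValueError("tumor area and immune stimulation must be >= 0")


class Trajectory:
    """Daily sequence of :class:`TumorState` from day 0 to the horizon."""

    def __init__(self, states: Sequence[TumorState]) -> None:
        if not states:
            raise ValueError("trajectory must contain at least one state")
        for i, s in enumerate(states):
            if s.day != i:
                raise ValueError("trajectory days must be consecutive from 0")
        self._states = tuple(states)

    def __len__(self) -> int:
        return len(self._states)

    def __getitem__(self, day: int) -> TumorState:
        return self._states[day]

    def __iter__(self):
        return iter(self._states)

    @property
    def final(self) -> TumorState:
        return self._states[-1]

    def area_at(self, day: int) -> float:
        return self._states[day].C

    @property
    def areas(self) -> np.ndarray:
        return np.array([s.C for s in self._states])

    @property
    def immune(self) -> np.ndarray:
        return np.array([s.I for s in self._states])

    def to_frame(self) -> pd.DataFrame:
        """Trajectory as a DataFrame with columns day, C, I."""
        return pd.DataFrame(
            {
                "day": [s.day for s in self._states],
                "C": [s.C for s in self._states],
                "I": [s.I for s in self._states],
            }
        )


def gompertz_step(C: float, a: float, K: float, dt: float = 1.0) -> float:
    """One exact Gompertz step: ``C' = K * (C/K)**exp(-a*dt)``.

    Closed-form solution of ``dC/dt = a*C*ln(K/C)`` advanced by ``dt`` days.
    """
    if C <= 0 or K <= 0:
        raise ValueError(f"C and K must be > 0, got C={C}, K={K}")
    if dt < 0:
        raise ValueError(f"dt must be >= 0, got {dt}")
    if a < 0:
        raise ValueError(f"a must be >= 0, got {a}")
    return K * (C / K) ** math.exp(-a * dt)


def lq_survival(dose: float, alpha: float, beta: float) -> float:
    """Linear-quadratic surviving fraction ``exp(-alpha*d - beta*d**2)``."""
    if dose < 0:
        raise ValueError(f"dose must be >= 0 Gy, got {dose}")
    return math.exp(-alpha * dose - beta * dose * dose)


def daily_update(
    state: TumorState,
    params: ModelParams,
    dose: float = 0.0,
    mt_active: bool = False,
) -> TumorState:
    """Advance the tumor–immune state by one day.

    Sub-steps, in order: (1) Gompertz growth over one day; (2) if a dose
    is delivered, LQ kill with the killed area recruited into immune
    stimulation; (3) geometric decay of the immune state plus new
    recruitment; (4) immune-mediated kill, potentiated by ``1 + sigma``
    when 1-MT is active.
    """
    if dose < 0:
        raise ValueError(f"dose must be >= 0 Gy, got {dose}")
    C = state.C
    if C > 0:
        C = gompertz_step(C, params.a, params.K, 1.0)
    if dose > 0:
        S = lq_survival(dose, params.alpha, params.beta)
        recruited = C * (1.0 - S)
        C *= S
    else:
        recruited = 0.0
    I = params.gamma * state.I + recruited
    potentiation = 1.0 + (params.sigma if mt_active else 0.0)
    C *= math.exp(-params.mu * potentiation * I)
    return TumorState(day=state.day + 1, C=C, I=I)


def simulate(
    params: ModelParams,
    schedule: TreatmentSchedule,
    horizon: int,
) -> Trajectory:
    """Simulate one treatment arm from day 0 to ``horizon`` (inclusive).

    The trajectory starts at ``(day 0, C0, I=0)``; the events of day ``d``
    take effect within the update that produces day ``d``.
    """
    if horizon < 0:
        raise ValueError(f"horizon must be >= 0, got {horizon}")
    for d, _ in schedule.rt_events:
        if d > horizon:
            raise ValueError(f"radiation day {d} is beyond the horizon {horizon}")
    states = [TumorState(day=0, C=params.C0, I=0.0)]
    for day in range(1, horizon + 1):
        states.append(
            daily_update(
                states[-1],
                params,
                dose=schedule.dose_on(day),
                mt_active=schedule.mt_active_on(day),
            )
        )
    return Trajectory(states)


#: Packaged default parameter set for the day-18 fractionation setting:
#: moderate, short-lived immune stimulation that reproduces plausible
#: day-18 group sizes (untreated ~39 mm², single fraction ~12 mm², two
#: fractions ~1-2 mm²).  The virtual survival cohorts use a separate,
#: longer-lived immune parameterization (see ``synthetic_data``).
DEFAULT_PARAMS = ModelParams(
    a=0.10,
    K=200.0,
    C0=0.01,
    alpha=0.2,
    beta=0.02,
    gamma=0.6,
    mu=0.03,
    sigma=5.0,
)

#: Default drug window: daily 1-MT injections for ten days from day 7.
DEFAULT_MT_DAYS = frozenset(range(7, 17))


def standard_arms(
    dose: float = 8.0,
    first_day: int = 7,
    short_interval: int = 4,
    long_interval: int = 7,
    mt_days: Iterable[int] = DEFAULT_MT_DAYS,
) -> dict[str, TreatmentSchedule]:
    """The five treatment arms of the fractionation study.

    Untreated control; 1-MT alone; 1-MT with one 8-Gy fraction at day 7;
    1-MT with two fractions 4 days apart (days 7 and 11); and 1-MT with
    two fractions 7 days apart (days 7 and 14).
    """
    mt = frozenset(mt_days)
    return {
        "control": TreatmentSchedule(),
        "1mt": TreatmentSchedule([], mt),
        "1mt_rt1": TreatmentSchedule([(first_day, dose)], mt),
        "1mt_rt2_short": TreatmentSchedule(
            [(first_day, dose), (first_day + short_interval, dose)], mt
        ),
        "1mt_rt2_long": TreatmentSchedule(
            [(first_day, dose), (first_day + long_interval, dose)], mt
        ),
    }
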