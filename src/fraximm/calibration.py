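"""Least-squares calibration of the tumor–immune model to day-18 sizes.

The model is fitted to per-arm mean cross-section areas at a single
observation day by minimizing the sum of squared residuals between the
simulated and observed group means.  Uncertainty is quantified by a
case-resampling bootstrap: animals are resampled with replacement within
each treatment group, group means recomputed, and the fit repeated.

Only a subset of parameters is free by default.  A single dose level
(8 Gy) cannot separate the linear and quadratic radiosensitivities, the
inoculum size is far below the observable scale, and the drug potentiation
``sigma`` enters the day-18 group means almost exclusively through the
product ``mu * (1 + sigma)`` (the untreated and drug-only arms coincide in
the model, leaving four independent group means).  ``C0``, ``alpha``,
``beta`` and ``sigma`` are therefore fixed from external estimates, and
``{a, K, gamma, mu}`` are fitted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .model_core import ModelParams, TreatmentSchedule, simulate

__all__ = [
    "GroupObservation",
    "FitResult",
    "BootstrapResult",
    "DEFAULT_FREE_NAMES",
    "DEFAULT_BOUNDS",
    "objective",
    "fit",
    "bootstrap_fit",
]

#: Parameters fitted by default; the rest are taken from the init params.
DEFAULT_FREE_NAMES = ("a", "K", "gamma", "mu")

#: Box bounds per parameter (gamma strictly below 1 by construction).
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "a": (0.0, 2.0),
    "K": (1.0, 1000.0),
    "C0": (1e-6, 10.0),
    "alpha": (0.0, 2.0),
    "beta": (0.0, 0.5),
    "gamma": (0.0, 0.99),
    "mu": (0.0, 5.0),
    "sigma": (0.0, 100.0),
}


@dataclass(frozen=True)
class GroupObservation:
    """Observed tumor areas for one treatment arm at one day."""

    label: str
    schedule: TreatmentSchedule
    areas: tuple[float, ...]
    day: int = 18

    def __init__(
        self,
        label: str,
        schedule: TreatmentSchedule,
        areas,
        day: int = 18,
    ) -> None:
        areas = tuple(float(x) for x in areas)
        if not areas:
            raise ValueError(f"group {label!r} has no animals")
        if any(x < 0 for x in areas):
            raise ValueError(f"group {label!r} has negative areas")
        if day < 0:
            raise ValueError("observation day must be >= 0")
        object.__setattr__(self, "label", label)
        object.__setattr__(self, "schedule", schedule)
        object.__setattr__(self, "areas", areas)
        object.__setattr__(self, "day", day)

    @property
    def mean_area(self) -> float:
        return float(np.mean(self.areas))

    @property
    def n(self) -> int:
        return len(self.areas)


@dataclass(frozen=True)
class FitResult:
    params: ModelParams
    free_names: tuple[str, ...]
    rss: float
    converged: bool
    n_iterations: int

    @property
    def free_values(self) -> np.ndarray:
        return np.array([getattr(self.params, name) for name in self.free_names])


@dataclass(frozen=True)
class BootstrapResult:
    """Bootstrap parameter samples with percentile intervals.

    ``samples`` has one row per successful replicate; replicates whose
    refit failed to converge are counted in ``n_failed`` rather than
    silently dropped.
    """

    free_names: tuple[str, ...]
    samples: np.ndarray  # (n_ok, n_free)
    intervals: dict[str, tuple[float, float]]
    n_reps: int
    n_failed: int
    seed: int

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.samples, columns=list(self.free_names))


def _params_with(free_values, free_names, base: ModelParams) -> ModelParams:
    updates = dict(zip(free_names, (float(v) for v in free_values)))
    if "gamma" in updates:
        # keep inside the open upper bound when the optimizer sits on it
        updates["gamma"] = min(updates["gamma"], np.nextafter(0.99, 0))
    return base.with_values(**updates)


def _residuals(
    free_values,
    observations: list[GroupObservation],
    free_names,
    base: ModelParams,
    means: np.ndarray,
) -> np.ndarray:
    params = _params_with(free_values, free_names, base)
    pred = np.array(
        [simulate(params, obs.schedule, obs.day).area_at(obs.day) for obs in observations]
    )
    return pred - means


def objective(
    free_values,
    observations: list[GroupObservation],
    fixed: ModelParams,
    free_names=DEFAULT_FREE_NAMES,
) -> float:
    """Sum of squared group-mean residuals (mm⁴) at the given free values."""
    if not observations:
        raise ValueError("no group observations supplied")
    means = np.array([obs.mean_area for obs in observations])
    r = _residuals(np.asarray(free_values, dtype=float), observations, free_names, fixed, means)
    return float(np.dot(r, r))


def fit(
    observations: list[GroupObservation],
    init: ModelParams,
    free_names=DEFAULT_FREE_NAMES,
    bounds: dict[str, tuple[float, float]] | None = None,
    ftol: float = 1e-8,
    max_iterations: int = 500,
    _group_means: np.ndarray | None = None,
) -> FitResult:
    """Bounded least-squares fit of the free parameters to group means.

    Deterministic given the data and the initial values; the returned RSS
    is never above the RSS at the initialization.
    """
    if not observations:
        raise ValueError("no group observations supplied")
    free_names = tuple(free_names)
    if len(free_names) > len(observations):
        warnings.warn(
            f"{len(free_names)} free parameters but only {len(observations)} groups:"
            " the fit is under-determined",
            UserWarning,
            stacklevel=2,
        )
    bnds = dict(DEFAULT_BOUNDS)
    if bounds:
        bnds.update(bounds)
    lo = np.array([bnds[name][0] for name in free_names])
    hi = np.array([bnds[name][1] for name in free_names])
    x0 = np.clip([getattr(init, name) for name in free_names], lo, hi)
    means = (
        np.array([obs.mean_area for obs in observations])
        if _group_means is None
        else _group_means
    )

    r0 = _residuals(x0, observations, free_names, init, means)
    rss0 = float(np.dot(r0, r0))
    if not np.isfinite(rss0):
        raise ValueError("objective is not finite at the initial values")

    # scale steps by the initial magnitudes so mm²-scale (K) and per-day
    # scale (a, mu) parameters move comparably
    x_scale = np.where(np.abs(x0) > 0, np.abs(x0), 1.0)
    sol = least_squares(
        _residuals,
        x0,
        bounds=(lo, hi),
        args=(observations, free_names, init, means),
        ftol=ftol,
        xtol=1e-12,
        gtol=1e-12,
        max_nfev=max_iterations * max(len(free_names), 1),
        x_scale=x_scale,
    )
    rss = float(2.0 * sol.cost)
    if rss > rss0:  # optimizer contract: never worse than the start
        return FitResult(
            params=_params_with(x0, free_names, init),
            free_names=free_names,
            rss=rss0,
            converged=False,
            n_iterations=int(sol.nfev),
        )
    return FitResult(
        params=_params_with(sol.x, free_names, init),
        free_names=free_names,
        rss=rss,
        converged=bool(sol.success),
        n_iterations=int(sol.nfev),
    )


def bootstrap_fit(
    observations: list[GroupObservation],
    init: ModelParams,
    free_names=DEFAULT_FREE_NAMES,
    n_reps: int = 10_000,
    seed: int = 0,
    bounds: dict[str, tuple[float, float]] | None = None,
) -> BootstrapResult:
    """Case-resampling bootstrap of the least-squares fit.

    For each replicate the animals of every group are resampled with
    replacement (group sizes preserved), group means recomputed, and the
    fit rerun from ``init``.  Percentile 95% intervals are computed from
    the converged replicates; failures are reported, not dropped silently.
    """
    if n_reps < 1:
        raise ValueError(f"n_reps must be >= 1, got {n_reps}")
    for obs in observations:
        if obs.n < 1:
            raise ValueError(f"group {obs.label!r} has no animals")
    free_names = tuple(free_names)
    rng = np.random.default_rng(seed)
    rows = []
    n_failed = 0
    for _ in range(n_reps):
        means = np.array(
            [
                float(np.mean(rng.choice(obs.areas, size=obs.n, replace=True)))
                for obs in observations
            ]
        )
        res = fit(
            observations,
            init,
            free_names=free_names,
            bounds=bounds,
            _group_means=means,
        )
        if res.converged:
            rows.append(res.free_values)
        else:
            n_failed += 1
    samples = np.array(rows) if rows else np.empty((0, len(free_names)))
    intervals = {}
    for j, name in enumerate(free_names):
        if len(samples):
            lo_q, hi_q = np.percentile(samples[:, j], [2.5, 97.5])
        else:
            lo_q = hi_q = float("nan")
        intervals[name] = (float(lo_q), float(hi_q))
    return BootstrapResult(
        free_names=free_names,
        samples=samples,
        intervals=intervals,
        n_reps=n_reps,
        n_failed=n_failed,
        seed=seed,
    )
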