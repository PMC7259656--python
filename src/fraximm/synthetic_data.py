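"""Virtual cohorts with the statistical structure the analysis assumes.

Generates per-animal day-18 tumor sizes, threshold-crossing survival
records censored at day 100, a 12-analyte serum cytokine panel with one
inflammation marker (IL-1A) elevated in treated animals, and a two-group
log2 expression matrix with a spiked IDO1 effect — each reproducible from
a single master seed.

Two parameterizations of the dynamic model are packaged.  The day-18 size
cohorts use :data:`fraximm.model_core.DEFAULT_PARAMS` (moderate,
short-lived immune stimulation, giving plausible sacrifice-day sizes).
The survival cohorts use :data:`SURVIVAL_PARAMS`, a long-lived immune
variant calibrated so the untreated arm's median threshold-crossing time
is ~27 days and the 1-MT + two-fraction (7-day gap) arm's ~63 days.  A
single parameter set cannot reproduce both observables in this model: the
survival gain requires immune suppression deep enough to push the
simulated day-18 treated sizes far below one cell's area (see the methods
documentation).

Random streams are derived from the master seed as
``numpy.random.default_rng([seed, stream])`` with fixed stream indices:
0 size cohort, 1 survival, 2 cytokines, 3 expression.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .cohort_stats import SurvivalSample
from .geo_expression import ExpressionMatrix
from .model_core import (
    DEFAULT_PARAMS,
    ModelParams,
    TreatmentSchedule,
    simulate,
    standard_arms,
)

__all__ = [
    "SURVIVAL_PARAMS",
    "CYTOKINE_ANALYTES",
    "AnimalRecord",
    "GeneratorConfig",
    "DEFAULT_CONFIG",
    "synth_cohort",
    "cohort_frame",
    "synth_survival",
    "synth_cytokines",
    "synth_expression",
    "write_fixture_bundle",
]

#: Survival-study parameterization: longer-lived immune stimulation
#: (retention 0.95/day) calibrated to the virtual-cohort median targets.
SURVIVAL_PARAMS = DEFAULT_PARAMS.with_values(gamma=0.95, mu=0.3, sigma=8.0)

#: The 12 serum analytes of the multiplex panel.
CYTOKINE_ANALYTES = (
    "IL-1A",
    "IL-1B",
    "IL-2",
    "IL-4",
    "IL-5",
    "IL-6",
    "IL-10",
    "IL-12",
    "IL-13",
    "GM-CSF",
    "IFN-G",
    "TNF-A",
)

_STREAM_COHORT = 0
_STREAM_SURVIVAL = 1
_STREAM_CYTOKINES = 2
_STREAM_EXPRESSION = 3


@dataclass(frozen=True)
class AnimalRecord:
    """One virtual animal's arm and observed endpoints."""

    animal_id: str
    group: str
    day: int
    area_mm2: float


def _default_arms() -> dict[str, TreatmentSchedule]:
    return standard_arms()


def _default_baselines() -> dict[str, float]:
    # pg/ml; arbitrary but analyte-specific so panels are distinguishable
    return {name: 20.0 + 10.0 * i for i, name in enumerate(CYTOKINE_ANALYTES)}


@dataclass(frozen=True)
class GeneratorConfig:
    """Defaults defining the virtual study; all noise is seed-reproducible."""

    params: ModelParams = DEFAULT_PARAMS
    survival_params: ModelParams = SURVIVAL_PARAMS
    arms: dict[str, TreatmentSchedule] = field(default_factory=_default_arms)
    n_per_arm: int = 4
    observation_day: int = 18
    size_noise_sd: float = 0.2  # lognormal measurement noise, log scale
    growth_sd: float = 0.2  # per-animal growth-rate variability, log scale
    death_threshold_mm2: float = 100.0
    censor_day: int = 100
    cytokine_baselines: dict[str, float] = field(default_factory=_default_baselines)
    cytokine_sd: float = 10.0
    spiked_analyte: str = "IL-1A"
    cytokine_spike_sds: float = 3.0
    n_genes: int = 200
    n_control_samples: int = 5
    n_case_samples: int = 9
    expression_noise_sd: float = 1.0
    ido1_spike_log2: float = 2.73
    seed: int = 20200529

    def __post_init__(self) -> None:
        if self.n_per_arm < 1:
            raise ValueError("n_per_arm must be >= 1")
        if self.size_noise_sd < 0 or self.growth_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.censor_day <= self.observation_day:
            raise ValueError("censor day must be after the observation day")
        if self.death_threshold_mm2 <= 0:
            raise ValueError("death threshold must be > 0")
        if self.n_genes < 1:
            raise ValueError("need at least one gene")
        if self.n_control_samples < 2 or self.n_case_samples < 2:
            raise ValueError("each expression group needs at least two samples")
        if self.spiked_analyte not in self.cytokine_baselines:
            raise ValueError(f"unknown spiked analyte {self.spiked_analyte!r}")
        if not self.arms:
            raise ValueError("no treatment arms defined")

    def with_values(self, **kwargs) -> "GeneratorConfig":
        return replace(self, **kwargs)

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


#: The packaged default study conditions.
DEFAULT_CONFIG = GeneratorConfig()


def synth_cohort(cfg: GeneratorConfig) -> list[AnimalRecord]:
    """Per-animal tumor sizes at the observation day, one record per animal.

    Each animal's growth rate is scaled by a lognormal multiplier
    (sd ``growth_sd``), its arm's schedule simulated to the observation
    day, and the simulated area multiplied by lognormal measurement noise
    (sd ``size_noise_sd``).
    """
    rng = cfg.rng(_STREAM_COHORT)
    records = []
    for group, schedule in cfg.arms.items():
        for i in range(cfg.n_per_arm):
            g_mult = float(np.exp(rng.normal(0.0, cfg.growth_sd))) if cfg.growth_sd else 1.0
            m_mult = (
                float(np.exp(rng.normal(0.0, cfg.size_noise_sd)))
                if cfg.size_noise_sd
                else 1.0
            )
            params = cfg.params.with_values(a=cfg.params.a * g_mult)
            area = simulate(params, schedule, cfg.observation_day).final.C * m_mult
            records.append(
                AnimalRecord(
                    animal_id=f"{group}_{i + 1:02d}",
                    group=group,
                    day=cfg.observation_day,
                    area_mm2=area,
                )
            )
    return records


def cohort_frame(records: Iterable[AnimalRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "animal_id": r.animal_id,
                "group": r.group,
                "day": r.day,
                "area_mm2": r.area_mm2,
            }
            for r in records
        ]
    )


def synth_survival(
    cfg: GeneratorConfig,
    arm: TreatmentSchedule,
    n: int,
    stream: int = _STREAM_SURVIVAL,
) -> SurvivalSample:
    """Threshold-crossing survival times for ``n`` animals on one arm.

    Death is proxied by the first day the simulated area reaches the
    humane-endpoint threshold; animals never crossing it are censored at
    the study termination day.  Heterogeneity enters through the same
    lognormal growth-rate multiplier as in :func:`synth_cohort`.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = cfg.rng(stream)
    times, events = [], []
    for _ in range(n):
        g_mult = float(np.exp(rng.normal(0.0, cfg.growth_sd))) if cfg.growth_sd else 1.0
        params = cfg.survival_params.with_values(a=cfg.survival_params.a * g_mult)
        traj = simulate(params, arm, cfg.censor_day)
        crossing = next(
            (s.day for s in traj if s.day >= 1 and s.C >= cfg.death_threshold_mm2),
            None,
        )
        if crossing is None:
            times.append(float(cfg.censor_day))
            events.append(0)
        else:
            times.append(float(crossing))
            events.append(1)
    return SurvivalSample(times, events)


def synth_cytokines(cfg: GeneratorConfig) -> pd.DataFrame:
    """Serum panel: animals × 12 analytes, Gaussian around per-group means.

    By default only the spiked analyte differs across groups: its mean is
    raised by ``cytokine_spike_sds`` within-group standard deviations in
    every treated (non-control) arm.
    """
    rng = cfg.rng(_STREAM_CYTOKINES)
    rows = []
    for group in cfg.arms:
        treated = group != "control"
        for i in range(cfg.n_per_arm):
            row: dict[str, object] = {
                "animal_id": f"{group}_{i + 1:02d}",
                "group": group,
            }
            for analyte in CYTOKINE_ANALYTES:
                mean = cfg.cytokine_baselines[analyte]
                if treated and analyte == cfg.spiked_analyte:
                    mean += cfg.cytokine_spike_sds * cfg.cytokine_sd
                row[analyte] = float(rng.normal(mean, cfg.cytokine_sd))
            rows.append(row)
    return pd.DataFrame(rows)


def synth_expression(cfg: GeneratorConfig) -> ExpressionMatrix:
    """Two-group log2 expression matrix with a spiked IDO1 effect.

    Background genes share the same distribution in both groups; IDO1 is
    shifted by ``ido1_spike_log2`` units in the case group.  The default
    design mirrors a 5-control versus 9-case stem-cell comparison.
    """
    rng = cfg.rng(_STREAM_EXPRESSION)
    genes = ["IDO1"] + [f"G{i:04d}" for i in range(1, cfg.n_genes)]
    samples = [f"control_{i + 1:02d}" for i in range(cfg.n_control_samples)] + [
        f"case_{i + 1:02d}" for i in range(cfg.n_case_samples)
    ]
    groups = {s: ("control" if s.startswith("control") else "case") for s in samples}
    baselines = rng.normal(7.0, 1.0, size=len(genes))
    values = baselines[:, None] + rng.normal(
        0.0, cfg.expression_noise_sd, size=(len(genes), len(samples))
    )
    case_cols = np.array([groups[s] == "case" for s in samples])
    values[0, case_cols] += cfg.ido1_spike_log2
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), groups)


def write_fixture_bundle(cfg: GeneratorConfig, outdir: str | Path) -> dict[str, Path]:
    """Write a complete virtual-study bundle in the formats the readers use."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    sizes = cohort_frame(synth_cohort(cfg))
    paths["sizes"] = outdir / "tumor_sizes.csv"
    sizes.to_csv(paths["sizes"], index=False)

    surv_rows = []
    for stream_offset, (group, schedule) in enumerate(cfg.arms.items()):
        sample = synth_survival(
            cfg, schedule, cfg.n_per_arm, stream=_STREAM_SURVIVAL + 10 + stream_offset
        )
        for i, (t, e) in enumerate(zip(sample.times, sample.events)):
            surv_rows.append(
                {
                    "animal_id": f"{group}_{i + 1:02d}",
                    "group": group,
                    "time_days": t,
                    "event": e,
                }
            )
    paths["survival"] = outdir / "survival.csv"
    pd.DataFrame(surv_rows).to_csv(paths["survival"], index=False)

    paths["cytokines"] = outdir / "cytokines.csv"
    synth_cytokines(cfg).to_csv(paths["cytokines"], index=False)

    expr = synth_expression(cfg)
    paths["expression"] = outdir / "expression.tsv"
    expr.values.to_csv(paths["expression"], sep="\t", index_label="ID_REF")
    labels = pd.DataFrame(
        [{"sample_id": s, "group": g} for s, g in expr.groups.items()]
    )
    paths["labels"] = outdir / "expression_labels.csv"
    labels.to_csv(paths["labels"], index=False)
    return paths
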