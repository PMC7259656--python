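"""End-to-end orchestration: data in, fitted model and reports out.

``run_pipeline`` composes the analysis stages — tumor sizes (virtual or
from CSV), least-squares calibration, bootstrap uncertainty, two-fraction
interval scan, group statistics, and survival analysis — and writes a
report bundle atomically into the output directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
import tempfile
import tomllib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calibration import DEFAULT_FREE_NAMES, GroupObservation, bootstrap_fit, fit
from .cohort_stats import (
    GroupSample,
    bonferroni_pairwise,
    km_median,
    logrank,
    one_way_anova,
    read_survival_csv,
)
from .model_core import simulate
from .schedule_scan import DEFAULT_EVAL_DAYS, DEFAULT_INTERVALS, scan_intervals
from .synthetic_data import (
    DEFAULT_CONFIG,
    GeneratorConfig,
    cohort_frame,
    synth_cohort,
    synth_survival,
)
from .tumor_metrics import read_size_csv

__all__ = ["PipelineConfig", "load_config", "run_pipeline"]

log = logging.getLogger("fraximm")


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of one pipeline run.

    With ``synthetic`` set (the default), inputs are generated by the
    virtual-cohort module; otherwise ``sizes_csv`` (and optionally
    ``survival_csv``) are read.  ``seed`` drives every stochastic stage.
    """

    outdir: Path = Path("fraximm_out")
    seed: int = 20200529
    synthetic: bool = True
    sizes_csv: Path | None = None
    survival_csv: Path | None = None
    generator: GeneratorConfig = DEFAULT_CONFIG
    free_names: tuple[str, ...] = DEFAULT_FREE_NAMES
    n_reps: int = 10_000
    scan_first_day: int = 7
    scan_dose: float = 8.0
    scan_intervals: tuple[int, ...] = DEFAULT_INTERVALS
    scan_eval_days: tuple[int, ...] = DEFAULT_EVAL_DAYS
    survival_n: int | None = None  # animals per survival arm; default n_per_arm

    def with_values(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)


def load_config(path: str | Path) -> PipelineConfig:
    """Load a TOML pipeline configuration.

    Recognized keys (all optional): ``outdir``, ``seed``, ``synthetic``,
    ``sizes_csv``, ``survival_csv``, ``n_reps``, ``free_names``,
    ``survival_n``, and a ``[scan]`` table with ``first_day``, ``dose``,
    ``intervals``, ``eval_days``, plus a ``[generator]`` table overriding
    :class:`GeneratorConfig` scalar fields.
    """
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    cfg = PipelineConfig()
    scalars = {}
    for key in ("seed", "synthetic", "n_reps", "survival_n"):
        if key in raw:
            scalars[key] = raw[key]
    if "outdir" in raw:
        scalars["outdir"] = Path(raw["outdir"])
    for key in ("sizes_csv", "survival_csv"):
        if key in raw:
            scalars[key] = Path(raw[key])
    if "free_names" in raw:
        scalars["free_names"] = tuple(raw["free_names"])
    scan = raw.get("scan", {})
    if "first_day" in scan:
        scalars["scan_first_day"] = int(scan["first_day"])
    if "dose" in scan:
        scalars["scan_dose"] = float(scan["dose"])
    if "intervals" in scan:
        scalars["scan_intervals"] = tuple(int(d) for d in scan["intervals"])
    if "eval_days" in scan:
        scalars["scan_eval_days"] = tuple(int(d) for d in scan["eval_days"])
    gen_overrides = raw.get("generator", {})
    if gen_overrides:
        scalars["generator"] = DEFAULT_CONFIG.with_values(**gen_overrides)
    return cfg.with_values(**scalars)


def _config_hash(cfg: PipelineConfig) -> str:
    return hashlib.sha256(repr(cfg).encode()).hexdigest()[:16]


def _collect_observations(cfg: PipelineConfig, sizes: pd.DataFrame) -> list[GroupObservation]:
    arms = cfg.generator.arms
    observations = []
    for group, sub in sizes.groupby("group", sort=False):
        if group not in arms:
            raise ValueError(f"group {group!r} has no schedule definition")
        (day,) = set(sub["day"])
        observations.append(
            GroupObservation(str(group), arms[group], sub["area_mm2"].tolist(), int(day))
        )
    return observations


def run_pipeline(cfg: PipelineConfig) -> dict[str, Path]:
    """Run the full analysis and write the report bundle.

    Outputs are staged in a temporary directory and moved into
    ``cfg.outdir`` only on success, so a failed run leaves no partial
    bundle behind.  Returns the mapping of report names to paths.
    """
    generator = cfg.generator.with_values(seed=cfg.seed)
    if not cfg.synthetic:
        if cfg.sizes_csv is None:
            raise ValueError("sizes_csv is required when synthetic = false")
        if not Path(cfg.sizes_csv).exists():
            raise FileNotFoundError(f"input CSV not found: {cfg.sizes_csv}")
        if cfg.survival_csv is not None and not Path(cfg.survival_csv).exists():
            raise FileNotFoundError(f"input CSV not found: {cfg.survival_csv}")

    staging = Path(tempfile.mkdtemp(prefix="fraximm_stage_"))
    outputs: dict[str, Path] = {}
    try:
        # --- tumor sizes -------------------------------------------------
        if cfg.synthetic:
            sizes = cohort_frame(synth_cohort(generator))
            log.info("generated %d virtual animals (seed %d)", len(sizes), cfg.seed)
        else:
            sizes = read_size_csv(cfg.sizes_csv)
        sizes.to_csv(staging / "tumor_sizes.csv", index=False)
        outputs["sizes"] = cfg.outdir / "tumor_sizes.csv"

        # --- calibration -------------------------------------------------
        observations = _collect_observations(cfg, sizes)
        init = generator.params
        fit_res = fit(observations, init, free_names=cfg.free_names)
        predicted = {
            obs.label: simulate(fit_res.params, obs.schedule, obs.day).area_at(obs.day)
            for obs in observations
        }
        log.info("fit converged=%s rss=%.6g", fit_res.converged, fit_res.rss)
        boot = bootstrap_fit(
            observations,
            init,
            free_names=cfg.free_names,
            n_reps=cfg.n_reps,
            seed=cfg.seed,
        )
        log.info("bootstrap: %d reps, %d failed (seed %d)", boot.n_reps, boot.n_failed, cfg.seed)
        fit_report = {
            "free_names": list(fit_res.free_names),
            "params": {
                name: getattr(fit_res.params, name)
                for name in ("a", "K", "C0", "alpha", "beta", "gamma", "mu", "sigma")
            },
            "rss_mm4": fit_res.rss,
            "converged": fit_res.converged,
            "n_iterations": fit_res.n_iterations,
            "predicted_group_means_mm2": predicted,
            "observed_group_means_mm2": {o.label: o.mean_area for o in observations},
            "bootstrap": {
                "n_reps": boot.n_reps,
                "n_failed": boot.n_failed,
                "seed": boot.seed,
                "percentile_95_intervals": {
                    k: list(v) for k, v in boot.intervals.items()
                },
            },
        }
        (staging / "fit.json").write_text(json.dumps(fit_report, indent=2))
        outputs["fit"] = cfg.outdir / "fit.json"
        boot.to_frame().to_csv(staging / "bootstrap_samples.csv", index=False)
        outputs["bootstrap"] = cfg.outdir / "bootstrap_samples.csv"

        # --- interval scan ------------------------------------------------
        table = scan_intervals(
            fit_res.params,
            first_day=cfg.scan_first_day,
            dose=cfg.scan_dose,
            intervals=cfg.scan_intervals,
            eval_days=cfg.scan_eval_days,
        )
        table.to_csv(staging / "interval_scan.csv", index=False)
        outputs["scan"] = cfg.outdir / "interval_scan.csv"

        # --- group statistics ----------------------------------------------
        groups = [
            GroupSample(str(label), sub["area_mm2"].tolist())
            for label, sub in sizes.groupby("group", sort=False)
        ]
        f_stat, p_val = one_way_anova(groups)
        posthoc = bonferroni_pairwise(groups)
        stats_report = {
            "anova": {"F": f_stat, "p": p_val},
            "bonferroni_adjusted_p": json.loads(posthoc.to_json()),
        }
        (staging / "size_stats.json").write_text(json.dumps(stats_report, indent=2))
        outputs["stats"] = cfg.outdir / "size_stats.json"

        # --- survival -------------------------------------------------------
        survival_samples = None
        if cfg.synthetic:
            n = cfg.survival_n or generator.n_per_arm
            survival_samples = {
                "control": synth_survival(generator, generator.arms["control"], n),
                "1mt_rt2_long": synth_survival(
                    generator, generator.arms["1mt_rt2_long"], n, stream=11
                ),
            }
        elif cfg.survival_csv is not None:
            survival_samples = read_survival_csv(cfg.survival_csv)
        if survival_samples:
            report = {
                "median_days": {
                    k: km_median(s) for k, s in survival_samples.items()
                }
            }
            labels = list(survival_samples)
            if len(labels) >= 2:
                chi2, p = logrank(
                    survival_samples[labels[0]], survival_samples[labels[1]]
                )
                report["logrank"] = {
                    "groups": labels[:2],
                    "chi_square": chi2,
                    "p": p,
                }
            (staging / "survival.json").write_text(json.dumps(report, indent=2))
            outputs["survival"] = cfg.outdir / "survival.json"

        # --- run log ---------------------------------------------------------
        run_log = (
            f"fraximm {__version__}\n"
            f"seed: {cfg.seed}\n"
            f"config_hash: {_config_hash(cfg)}\n"
            f"numpy: {np.__version__}\n"
        )
        (staging / "run_log.txt").write_text(run_log)
        outputs["log"] = cfg.outdir / "run_log.txt"

        cfg.outdir.mkdir(parents=True, exist_ok=True)
        for name in list(staging.iterdir()):
            shutil.move(str(name), cfg.outdir / name.name)
    finally:
        shutil.rmtree(staging, ignore_errors=True)
    return outputs
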