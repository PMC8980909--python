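"""End-to-end orchestration: simulate -> score -> screen -> diverge -> detect.

`run_pipeline` executes the enabled stages against a configuration object,
writes plain-text artifacts (TSV tables, JSON fit summaries) under the
output directory, and stamps every run with the configuration hash and all
seeds so that identical configurations reproduce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .cohort import SimulationConfig, simulate_cohort, write_cohort
from .detection import DetectionSpec, earliest_detectable_age, detection_report_frame
from .divergence import (
    DivergenceModelSpec,
    ThresholdGrid,
    select_threshold,
    fit_to_dict,
    mspe_long_frame,
)
from .screen import ScreenModelSpec, screen_all, screen_report_frame

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """Declarative description of one pipeline run.

    Stages run in order simulate -> screen -> diverge -> detect; each can be
    toggled.  When ``run_screen`` is off, ``divergence_phenotypes`` must
    list the phenotypes to model (with the screen on, the Bonferroni
    selection feeds the divergence stage).
    """

    simulation: SimulationConfig
    out_dir: str
    run_screen: bool = True
    run_divergence: bool = True
    run_detection: bool = True
    alpha: float = 0.05
    covariates: tuple[str, ...] = ("sex", "assay")
    grid: ThresholdGrid = field(default_factory=ThresholdGrid)
    cv_folds: int = 10
    fold_seed: int = 0
    divergence_phenotypes: tuple[str, ...] = ()
    detection: DetectionSpec = field(default_factory=DetectionSpec)

    def validate(self) -> None:
        if self.run_divergence and not self.run_screen and not self.divergence_phenotypes:
            raise ValueError(
                "divergence stage enabled without the screen stage and without "
                "an explicit divergence_phenotypes list"
            )
        if self.run_detection and not self.run_divergence:
            raise ValueError("detection stage requires the divergence stage")

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    config_hash: str
    artifacts: dict[str, Path]
    screen_outcome: object | None
    divergence_fits: list
    detection_results: list


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the enabled stages, writing artifacts under ``config.out_dir``.

    Every output table carries deterministic content for a fixed config; a
    ``run_log.json`` records the config hash, seeds, per-phenotype sample
    sizes, selections and thresholds.  A stage failure raises, naming the
    stage.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    log: dict = {
        "config_hash": config.config_hash(),
        "seeds": {
            "simulation": config.simulation.seed,
            "folds": config.fold_seed,
        },
        "stages": {},
    }

    try:
        cohort = simulate_cohort(config.simulation)
        cohort_path = out / "cohort.tsv"
        write_cohort(cohort, config.simulation, cohort_path)
        artifacts["cohort"] = cohort_path
        log["stages"]["simulate"] = {"n": len(cohort)}
    except Exception as exc:
        raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc

    specs_by_name = {s.name: s for s in config.simulation.phenotype_specs}
    screen_outcome = None
    selected: list[str] = list(config.divergence_phenotypes)
    if config.run_screen:
        try:
            screen_specs = [
                ScreenModelSpec(
                    phenotype=s.name,
                    link="logit" if s.scale == "binary" else "identity",
                    covariates=config.covariates,
                    direction=s.direction,
                )
                for s in config.simulation.phenotype_specs
            ]
            screen_outcome = screen_all(cohort, screen_specs, alpha=config.alpha)
            report = screen_report_frame(screen_outcome)
            path = out / "screen_report.tsv"
            report.to_csv(path, sep="\t", index=False)
            artifacts["screen_report"] = path
            log["stages"]["screen"] = {
                "m": screen_outcome.m,
                "threshold": screen_outcome.threshold,
                "selected": screen_outcome.selected,
                "n_by_phenotype": {r.phenotype: r.n for r in screen_outcome.results},
                "failures": screen_outcome.failures,
            }
            if not config.divergence_phenotypes:
                selected = screen_outcome.selected
        except Exception as exc:
            raise RuntimeError(f"stage 'screen' failed: {exc}") from exc

    fits = []
    if config.run_divergence:
        try:
            for name in selected:
                sim_spec = specs_by_name.get(name)
                spec = DivergenceModelSpec(
                    phenotype=name,
                    link="logit" if sim_spec and sim_spec.scale == "binary" else "identity",
                    covariates=config.covariates,
                    grid=config.grid,
                    cv_folds=config.cv_folds,
                    fold_seed=config.fold_seed,
                    direction=sim_spec.direction if sim_spec else "higher_better",
                )
                fits.append(select_threshold(cohort, spec))
            fit_path = out / "divergence_fits.json"
            fit_path.write_text(
                json.dumps([fit_to_dict(f) for f in fits], indent=2, sort_keys=True)
            )
            artifacts["divergence_fits"] = fit_path
            if fits:
                mspe_path = out / "mspe_long.tsv"
                mspe_long_frame(fits).to_csv(mspe_path, sep="\t", index=False)
                artifacts["mspe_long"] = mspe_path
            log["stages"]["diverge"] = {
                f.phenotype: {
                    "selected_threshold": f.selected_threshold,
                    "boundary_flag": f.boundary_flag,
                    "n": f.n,
                }
                for f in fits
            }
        except Exception as exc:
            raise RuntimeError(f"stage 'diverge' failed: {exc}") from exc

    detections = []
    if config.run_detection:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                for fit in fits:
                    detections.append(
                        earliest_detectable_age(fit, cohort, config.detection)
                    )
            if detections:
                det_path = out / "detection_report.tsv"
                detection_report_frame(detections).to_csv(det_path, sep="\t", index=False)
                artifacts["detection_report"] = det_path
            log["stages"]["detect"] = {
                d.phenotype: d.earliest_detectable_age for d in detections
            }
        except Exception as exc:
            raise RuntimeError(f"stage 'detect' failed: {exc}") from exc

    log_path = out / "run_log.json"
    log_path.write_text(json.dumps(log, indent=2, sort_keys=True))
    artifacts["run_log"] = log_path
    return PipelineResult(
        config_hash=log["config_hash"],
        artifacts=artifacts,
        screen_outcome=screen_outcome,
        divergence_fits=fits,
        detection_results=detections,
    )
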