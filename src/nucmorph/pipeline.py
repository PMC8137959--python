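"""Pipeline configuration and end-to-end orchestration.

Stages: (simulate) -> per-nucleus features -> cell_shapes.csv ->
patient aggregation -> Cox fits per feature set -> survival_report.json.
Every stage logs its counts; any stage error aborts with the stage
name.  In simulate mode the synthetic cohort generator runs first, so
the whole pipeline executes with zero external inputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from . import aggregate as agg
from . import io as nio
from . import morphometry as morph
from . import survival as surv
from .synthetic import CohortConfig, gen_cohort

log = logging.getLogger(__name__)

MICRONS_PER_PIXEL = 0.25  # 40x scan resolution of the source data


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class PipelineConfig:
    """Resolved options for a pipeline run.

    Defaults: 224 px patches with stride 224, whiteness filter at level
    220 / fraction 0.5, sample (n-1) std aggregation with column-mean
    imputation, 1000 bootstrap replicates, Efron ties, 0.25 um/px.
    """

    out_dir: str = "nucmorph_out"
    cells_dir: Optional[str] = None
    clinical_csv: Optional[str] = None
    annotations_csv: Optional[str] = None
    # patches
    patch_size: int = 224
    patch_stride: Optional[int] = None
    white_level: int = 220
    max_white_fraction: float = 0.5
    # aggregation
    impute: str = "mean"  # or "drop"
    clinical_covariates: Optional[Sequence[str]] = None
    # survival
    feature_sets: Sequence[str] = ("both", "clinical", "geometric")
    n_bootstrap: int = 1000
    seed: int = 0
    penalizer: float = 0.0
    # morphometry
    ellipse_method: str = "fit"
    microns_per_pixel: float = MICRONS_PER_PIXEL

    def __post_init__(self):
        for name in ("patch_size", "n_bootstrap", "white_level"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        bad = set(self.feature_sets) - set(agg.FEATURE_SETS)
        if bad:
            raise ValueError(f"unknown feature sets: {sorted(bad)}")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: Union[str, Path]) -> None:
        d = dataclasses.asdict(self)
        d["feature_sets"] = list(self.feature_sets)
        if self.clinical_covariates is not None:
            d["clinical_covariates"] = list(self.clinical_covariates)
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


def compute_features_from_dir(
    cells_dir: Union[str, Path], ellipse_method: str = "fit"
) -> list[morph.NucleusFeatures]:
    """Run morphometry over every mask in a Cells/ tree."""
    feats = []
    for pid, patch_id, cell_no, path in nio.iter_cells_dir(cells_dir):
        mask = nio.read_mask(path)
        feats.append(
            morph.compute_features(
                mask, patient_id=pid, patch_id=patch_id, cell_number=cell_no,
                ellipse_method=ellipse_method,
            )
        )
    return feats


def run_survival_analysis(
    patient_features: pd.DataFrame,
    clinical: pd.DataFrame,
    config: PipelineConfig,
) -> dict:
    """Fit the configured feature sets; returns the report dictionary."""
    report = {}
    for fs in config.feature_sets:
        X, t, e = agg.assemble_design(
            patient_features, clinical, feature_set=fs,
            clinical_covariates=config.clinical_covariates, impute=config.impute,
        )
        res = surv.optimism_corrected_c(
            X, t, e, n_bootstrap=config.n_bootstrap, seed=config.seed,
            penalizer=config.penalizer,
        )
        report[fs] = {
            "apparent_c": res.apparent_c,
            "corrected_c": res.corrected_c,
            "mean_optimism": res.mean_optimism,
            "ci_low": res.ci_low,
            "ci_high": res.ci_high,
            "n_bootstrap": res.n_bootstrap,
            "n_failed": res.n_failed,
            "seed": res.seed,
            "n_patients": int(len(X)),
            "n_covariates": int(X.shape[1]),
        }
        log.info(
            "survival[%s]: apparent C=%.3f corrected C=%.3f (%.3f, %.3f), "
            "%d patients, %d covariates, %d/%d replicates failed",
            fs, res.apparent_c, res.corrected_c, res.ci_low, res.ci_high,
            len(X), X.shape[1], res.n_failed, res.n_bootstrap,
        )
    return report


def simulate_inputs(config: PipelineConfig, cohort: Optional[CohortConfig] = None) -> None:
    """Generate a synthetic cohort into out_dir (Cells/ + clinical.csv)."""
    out = Path(config.out_dir)
    cohort = cohort or CohortConfig(seed=config.seed)
    t0 = _time.perf_counter()
    masks, clinical = gen_cohort(cohort)
    n = nio.write_cohort_masks(masks, out / "Cells")
    nio.write_table(clinical, out / "clinical_data_cleaned.csv")
    config.cells_dir = str(out / "Cells")
    config.clinical_csv = str(out / "clinical_data_cleaned.csv")
    log.info(
        "simulate: %d patients, %d masks written in %.1fs",
        len(masks), n, _time.perf_counter() - t0,
    )


def run_pipeline(
    config: PipelineConfig,
    simulate: bool = False,
    cohort: Optional[CohortConfig] = None,
) -> dict:
    """Execute the full pipeline; returns the survival report dict.

    Writes cell_shapes.csv, patient_features.csv, survival_report.json
    and the resolved config under ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if simulate:
        try:
            simulate_inputs(config, cohort)
        except Exception as e:
            raise PipelineError("simulate", str(e)) from e

    if not config.cells_dir or not Path(config.cells_dir).is_dir():
        raise PipelineError("features", f"Cells directory not found: {config.cells_dir}")
    if not config.clinical_csv or not Path(config.clinical_csv).exists():
        raise PipelineError("aggregate", f"clinical table not found: {config.clinical_csv}")

    try:
        t0 = _time.perf_counter()
        feats = compute_features_from_dir(config.cells_dir, config.ellipse_method)
        cell_shapes = nio.write_cell_shapes(feats, out / "cell_shapes.csv")
        log.info(
            "features: %d nuclei processed in %.1fs", len(feats), _time.perf_counter() - t0
        )
    except (morph.MorphometryError, nio.FormatError) as e:
        raise PipelineError("features", str(e)) from e

    try:
        clinical = agg.clean_clinical(nio.read_clinical(config.clinical_csv))
        patient_features = agg.aggregate_patients(nio.read_cell_shapes(out / "cell_shapes.csv"))
        nio.write_table(patient_features, out / "patient_features.csv")
        log.info(
            "aggregate: %d patients with features, %d in clinical table",
            len(patient_features), len(clinical),
        )
    except (agg.AggregationError, nio.FormatError) as e:
        raise PipelineError("aggregate", str(e)) from e

    try:
        report = run_survival_analysis(patient_features, clinical, config)
    except (agg.AggregationError, surv.SurvivalError) as e:
        raise PipelineError("survival", str(e)) from e

    with open(out / "survival_report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    config.to_yaml(out / "config_resolved.yaml")
    return report
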