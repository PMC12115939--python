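"""End-to-end orchestration: simulate -> slopes -> inhibition -> screening ->
EC50 table -> activity model -> effect model -> held-out validation.

Every run is driven by one :class:`PipelineConfig` and one master seed; the
master seed splits into fixed per-stage seeds so reruns are byte-identical.
Every output CSV carries the seed and a config hash in comment headers.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import design as dsg
from .calibration import DEFAULT_ANCHORS, calibrate_generator
from .doseresponse import ec50_table, selected_ec50s
from .evaluation import screen_factors, validate
from .inhibition import inhibition_to_frame, pair_with_controls
from .kinetics import fit_all, slopes_to_frame
from .mlp import MLPArchitectureSearch, save_model
from .simulate import NoiseModel, PlateDataset, read_plate_csv, simulate_study, write_plate_csv

logger = logging.getLogger("pcptox")

#: fixed per-stage offsets used to split the master seed
STAGE_OFFSETS = {
    "simulate_training": 1,
    "simulate_validation": 2,
    "activity_model": 3,
    "effect_model": 4,
}

ACTIVITY_FEATURES = ["ph", "temperature_c"]
EFFECT_FEATURES = ["ph", "temperature_c", "conductivity_ms_cm", "pcp_mg_l"]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed (< 2**31)."""
    ss = np.random.SeedSequence([int(master_seed), STAGE_OFFSETS[stage]])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    """Configuration of one full analysis run."""

    master_seed: int = 0
    anchors: dict = field(default_factory=lambda: dict(DEFAULT_ANCHORS))
    slope_cv: float = 0.0309
    read_sd_au: float = 0.05
    baseline_au: float = 100.0
    n_restarts: int = 10
    n_cycles: int = 100
    alpha: float = 0.05
    training_plate_csv: str | None = None  # ingest instead of simulating
    validation_plate_csv: str | None = None
    run_activity_model: bool = True
    run_effect_model: bool = True
    run_ec50_table: bool = True
    run_validation: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _write_csv(df: pd.DataFrame, path: Path, config: PipelineConfig) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# seed={config.master_seed} config_hash={config.hash()}\n")
        df.to_csv(fh, index=False)


def _load_or_simulate(config: PipelineConfig, which: str) -> PlateDataset:
    path = getattr(config, f"{which}_plate_csv")
    if path is not None:
        if not Path(path).exists():
            raise FileNotFoundError(f"{which} plate CSV not found: {path}")
        return read_plate_csv(path)
    calib = calibrate_generator(config.anchors)
    noise = NoiseModel(slope_cv=config.slope_cv, read_sd_au=config.read_sd_au)
    design = (
        dsg.enumerate_training_design()
        if which == "training"
        else dsg.enumerate_validation_design()
    )
    seed = stage_seed(config.master_seed, f"simulate_{which}")
    return simulate_study(design, calib, noise, seed, config.baseline_au)


def run_full(config: PipelineConfig, outdir) -> dict:
    """Run the complete analysis; returns a dict of in-memory results.

    Artifacts written to ``outdir``: plate, slope, inhibition, screening and
    EC50 CSVs, model files, search reports, validation report and a JSON
    summary.  Any stage failure raises with the stage name.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for which in ("training", "validation"):
        path = getattr(config, f"{which}_plate_csv")
        if path is not None and not Path(path).exists():
            raise FileNotFoundError(f"{which} plate CSV not found: {path}")

    results: dict = {"config_hash": config.hash(), "master_seed": config.master_seed}

    def stage(name):
        logger.info("stage %s", name)

    stage("simulate/ingest")
    train_plate = _load_or_simulate(config, "training")
    val_plate = _load_or_simulate(config, "validation")
    write_plate_csv(train_plate, outdir / "training_plate.csv",
                    f"seed={config.master_seed} config_hash={config.hash()}")
    write_plate_csv(val_plate, outdir / "validation_plate.csv",
                    f"seed={config.master_seed} config_hash={config.hash()}")
    logger.info("training traces: %d, validation traces: %d", len(train_plate), len(val_plate))

    stage("kinetics")
    train_slopes = fit_all(train_plate)
    val_slopes = fit_all(val_plate)
    train_slope_df = slopes_to_frame(train_slopes, "training")
    val_slope_df = slopes_to_frame(val_slopes, "validation")
    _write_csv(train_slope_df, outdir / "training_slopes.csv", config)
    _write_csv(val_slope_df, outdir / "validation_slopes.csv", config)

    stage("inhibition")
    train_inh = inhibition_to_frame(pair_with_controls(train_slopes))
    val_inh = inhibition_to_frame(pair_with_controls(val_slopes))
    _write_csv(train_inh, outdir / "training_inhibition.csv", config)
    _write_csv(val_inh, outdir / "validation_inhibition.csv", config)
    results["n_train_inhibition"] = len(train_inh)
    results["n_val_inhibition"] = len(val_inh)

    stage("screening")
    controls = train_slope_df[train_slope_df["pcp_mg_l"] == 0]
    screening = screen_factors(controls, "slope_au", alpha=config.alpha)
    _write_csv(screening.table, outdir / "factor_screening.csv", config)
    results["screening"] = screening

    if config.run_ec50_table:
        stage("ec50")
        table = ec50_table(train_inh)
        _write_csv(table, outdir / "ec50_table.csv", config)
        results["ec50_table"] = table
        results["ec50_selected"] = selected_ec50s(table)

    if config.run_activity_model:
        stage("activity model")
        search = MLPArchitectureSearch(
            n_restarts=config.n_restarts,
            n_cycles=config.n_cycles,
            random_state=stage_seed(config.master_seed, "activity_model"),
        )
        search.fit(controls[ACTIVITY_FEATURES].to_numpy(float),
                   controls["slope_au"].to_numpy(float))
        _write_csv(search.report_, outdir / "activity_search.csv", config)
        save_model(search.best_model_, outdir / "activity_model.json")
        results["activity_search"] = search

    if config.run_effect_model:
        stage("effect model")
        search = MLPArchitectureSearch(
            n_restarts=config.n_restarts,
            n_cycles=config.n_cycles,
            random_state=stage_seed(config.master_seed, "effect_model"),
            output_bounds=(0.0, 1.0),
        )
        search.fit(train_inh[EFFECT_FEATURES].to_numpy(float),
                   train_inh["inhibition"].to_numpy(float))
        _write_csv(search.report_, outdir / "effect_search.csv", config)
        save_model(search.best_model_, outdir / "effect_model.json")
        results["effect_search"] = search

        if config.run_validation:
            stage("validation")
            train_abiotics = {
                tuple(r) for r in train_inh[
                    ["ph", "temperature_c", "conductivity_ms_cm"]
                ].drop_duplicates().to_numpy()
            }
            report = validate(
                search.best_model_, val_inh, training_abiotics=train_abiotics,
                feature_cols=EFFECT_FEATURES,
            )
            _write_csv(report.table, outdir / "validation_predictions.csv", config)
            results["validation"] = report
            logger.info("validation r2 = %.4f", report.r2)

    summary = {
        "master_seed": config.master_seed,
        "config_hash": config.hash(),
        "n_training_traces": len(train_plate),
        "n_validation_traces": len(val_plate),
        "n_train_inhibition": results.get("n_train_inhibition"),
        "screening_excluded": results["screening"].excluded,
        "effect_train_r2": results["effect_search"].train_r2_
        if "effect_search" in results else None,
        "validation_r2": results["validation"].r2 if "validation" in results else None,
    }
    with open(outdir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=1)
    results["summary"] = summary
    return results
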