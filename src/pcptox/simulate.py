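"""Synthetic 96-well resazurin kinetic traces.

Each well's fluorescence is read every 10 minutes for one hour (7 scheduled
timepoints).  The simulated trace is a straight line whose slope is the
ground-truth respiratory activity attenuated by the ground-truth inhibition,
perturbed by a multiplicative replicate effect on the slope and additive
per-read fluorescence noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import GeneratorCalibration, calibrate_generator, true_activity, true_inhibition
from .design import AbioticCondition, AssayCondition, StudyDesign

#: Scheduled read times in minutes ("every 10 min for 1 h").
SCHEDULED_TIMES_MIN = (0.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0)

#: Fixed fluorescence baseline at t = 0, in a.u.
DEFAULT_BASELINE_AU = 100.0

PLATE_COLUMNS = [
    "design_label",
    "ph",
    "temperature_c",
    "conductivity_ms_cm",
    "pcp_mg_l",
    "replicate",
    "time_min",
    "fluorescence_au",
]


@dataclass(frozen=True)
class NoiseModel:
    """Replicate and read noise of the simulated assay.

    slope_cv is the multiplicative coefficient of variation of the kinetic
    slope between replicates (default 0.0309, the study's reported replicate
    variability); read_sd_au is the additive per-timepoint fluorescence noise.
    """

    slope_cv: float = 0.0309
    read_sd_au: float = 0.05

    def __post_init__(self) -> None:
        if self.slope_cv < 0 or self.read_sd_au < 0:
            raise ValueError("noise magnitudes must be non-negative")


NOISE_FREE = NoiseModel(slope_cv=0.0, read_sd_au=0.0)


@dataclass
class KineticTrace:
    """Fluorescence readings over the 7 scheduled timepoints for one well."""

    condition: AssayCondition
    times_min: np.ndarray
    fluorescence_au: np.ndarray

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.fluorescence_au = np.asarray(self.fluorescence_au, dtype=float)
        if self.times_min.shape != self.fluorescence_au.shape:
            raise ValueError("times and readings must have equal length")
        if np.any(np.diff(self.times_min) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class PlateDataset:
    """A collection of kinetic traces with generation provenance."""

    design_label: str
    traces: list[KineticTrace]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.traces)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table, one row per fluorescence reading."""
        rows = []
        for tr in self.traces:
            c = tr.condition
            for t, f in zip(tr.times_min, tr.fluorescence_au):
                rows.append(
                    (
                        self.design_label,
                        c.abiotic.ph,
                        c.abiotic.temperature_c,
                        c.abiotic.conductivity_ms_cm,
                        c.pcp_mg_per_l,
                        c.replicate,
                        t,
                        f,
                    )
                )
        return pd.DataFrame(rows, columns=PLATE_COLUMNS)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, provenance: dict | None = None) -> "PlateDataset":
        missing = [c for c in PLATE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"plate table missing columns: {missing}")
        labels = df["design_label"].unique()
        label = str(labels[0]) if len(labels) == 1 else "mixed"
        traces = []
        keys = ["ph", "temperature_c", "conductivity_ms_cm", "pcp_mg_l", "replicate"]
        for (ph, t, cs, pcp, rep), grp in df.groupby(keys, sort=False):
            grp = grp.sort_values("time_min")
            cond = AssayCondition(
                AbioticCondition(float(ph), float(t), float(cs)), float(pcp), int(rep)
            )
            traces.append(
                KineticTrace(cond, grp["time_min"].to_numpy(), grp["fluorescence_au"].to_numpy())
            )
        return cls(label, traces, provenance or {})


def simulate_trace(
    cond: AssayCondition,
    calib: GeneratorCalibration,
    noise: NoiseModel,
    rng: np.random.Generator,
    baseline_au: float = DEFAULT_BASELINE_AU,
) -> KineticTrace:
    """Simulate one well: F(t) = F0 + s * t/60 + eps_t, readings floored at 0.

    The realised slope is ``true_activity * (1 - true_inhibition) * (1 + eta)``
    with ``eta ~ Normal(0, slope_cv)``; slopes are expressed per hour so the
    favourable control runs at 25.05 a.u. over the one-hour window.
    """
    s_true = true_activity(cond.abiotic, calib) * (1.0 - true_inhibition(cond, calib))
    eta = rng.normal(0.0, noise.slope_cv) if noise.slope_cv > 0 else 0.0
    s = s_true * (1.0 + eta)
    times = np.array(SCHEDULED_TIMES_MIN)
    readings = baseline_au + s * times / 60.0
    if noise.read_sd_au > 0:
        readings = readings + rng.normal(0.0, noise.read_sd_au, size=times.shape)
    return KineticTrace(cond, times, np.maximum(readings, 0.0))


def simulate_study(
    design: StudyDesign,
    calib: GeneratorCalibration | None = None,
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
    baseline_au: float = DEFAULT_BASELINE_AU,
) -> PlateDataset:
    """Simulate one trace per design entry; identical seed -> identical data."""
    if calib is None:
        calib = calibrate_generator()
    rng = np.random.default_rng(seed)
    traces = [simulate_trace(c, calib, noise, rng, baseline_au) for c in design]
    provenance = {
        "seed": seed,
        "slope_cv": noise.slope_cv,
        "read_sd_au": noise.read_sd_au,
        "baseline_au": baseline_au,
        "calibration": {
            "a_ref": calib.a_ref,
            "ph_activity_ratio": calib.ph_activity_ratio,
            "temp_activity_ratio": calib.temp_activity_ratio,
            "log_ec50_coeffs": list(calib.log_ec50_coeffs),
            "hill_slope_n": calib.hill_slope_n,
            "cond_log_factor": calib.cond_log_factor,
            "temp_ec50_log_factor": calib.temp_ec50_log_factor,
        },
    }
    return PlateDataset(design.label, traces, provenance)


def write_plate_csv(dataset: PlateDataset, path, header_comment: str | None = None) -> None:
    """Write the long-format plate CSV (one row per reading)."""
    df = dataset.to_frame()
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


def read_plate_csv(path) -> PlateDataset:
    """Read a plate CSV written by :func:`write_plate_csv` (``#`` lines ignored)."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"plate CSV {path} missing columns: {missing}")
    bad = df[PLATE_COLUMNS[1:]].isna().any(axis=1)
    if bad.any():
        rows = (df.index[bad] + 2).tolist()[:10]
        raise ValueError(f"plate CSV {path} has non-numeric or missing cells at rows {rows}")
    return PlateDataset.from_frame(df)
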