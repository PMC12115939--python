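"""Kinetic slope extraction: fluorescence time series -> respiratory activity.

Each well's readings are fit by ordinary least squares; the slope, rescaled
to a.u. per hour, is the well's respiratory-activity value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import AssayCondition
from .simulate import KineticTrace, PlateDataset

SLOPE_COLUMNS = [
    "design_label",
    "ph",
    "temperature_c",
    "conductivity_ms_cm",
    "pcp_mg_l",
    "replicate",
    "slope_au",
    "intercept_au",
    "fit_r2",
]


@dataclass
class SlopeEstimate:
    """OLS line through one well's kinetic trace.

    slope_au is expressed per hour so that magnitudes are directly comparable
    with the study's arbitrary-unit activity scale.
    """

    condition: AssayCondition
    slope_au: float
    intercept_au: float
    fit_r2: float


def fit_slope(trace: KineticTrace) -> SlopeEstimate:
    """Least-squares line through the trace; slope reported per hour.

    Requires at least 3 timepoints with at least 2 distinct times.
    """
    t = np.asarray(trace.times_min, dtype=float)
    y = np.asarray(trace.fluorescence_au, dtype=float)
    if t.size < 3:
        raise ValueError(f"need at least 3 timepoints, got {t.size}")
    if np.ptp(t) == 0:
        raise ValueError("all timepoints identical; slope undefined")
    res = stats.linregress(t, y)
    r2 = float(res.rvalue**2) if np.ptp(y) > 0 else 0.0
    return SlopeEstimate(
        condition=trace.condition,
        slope_au=float(res.slope) * 60.0,  # per-minute -> per-hour
        intercept_au=float(res.intercept),
        fit_r2=r2,
    )


def fit_all(dataset: PlateDataset) -> list[SlopeEstimate]:
    """One slope estimate per trace, order-preserving."""
    estimates = []
    for i, tr in enumerate(dataset.traces):
        try:
            estimates.append(fit_slope(tr))
        except ValueError as exc:
            c = tr.condition
            raise ValueError(
                f"trace {i} (pH {c.abiotic.ph}, {c.abiotic.temperature_c} C, "
                f"{c.abiotic.conductivity_ms_cm} mS/cm, {c.pcp_mg_per_l} mg/L, "
                f"rep {c.replicate}): {exc}"
            ) from exc
    return estimates


def slopes_to_frame(estimates: list[SlopeEstimate], design_label: str = "") -> pd.DataFrame:
    rows = [
        (
            design_label,
            e.condition.abiotic.ph,
            e.condition.abiotic.temperature_c,
            e.condition.abiotic.conductivity_ms_cm,
            e.condition.pcp_mg_per_l,
            e.condition.replicate,
            e.slope_au,
            e.intercept_au,
            e.fit_r2,
        )
        for e in estimates
    ]
    return pd.DataFrame(rows, columns=SLOPE_COLUMNS)
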