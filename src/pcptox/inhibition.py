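"""Inhibition rates: each exposed well versus its matched untreated control.

The inhibition rate of a well is one minus the ratio of its kinetic slope to
the mean control slope at the same abiotic combination, clamped to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .design import AssayCondition
from .kinetics import SlopeEstimate

INHIBITION_COLUMNS = [
    "ph",
    "temperature_c",
    "conductivity_ms_cm",
    "pcp_mg_l",
    "replicate",
    "inhibition_raw",
    "inhibition",
    "control_slope_au",
]


@dataclass
class InhibitionRecord:
    """Inhibition of one exposed well relative to its matched control mean."""

    condition: AssayCondition
    inhibition_raw: float  # 1 - slope/control, unbounded
    inhibition: float  # clamped to [0, 1]
    control_slope_au: float


def compute_inhibition(slope_pcp: float, slope_control: float) -> tuple[float, float]:
    """Raw and clamped inhibition: raw = 1 - slope_pcp / slope_control.

    The control slope must be positive — a control showing no activity leaves
    the rate undefined.  Negative raw values (stimulation or noise) clamp to 0,
    values above 1 clamp to 1; the raw value is kept alongside.
    """
    if slope_control <= 0:
        raise ValueError(
            f"control slope {slope_control} is not positive; inhibition undefined"
        )
    raw = 1.0 - slope_pcp / slope_control
    return raw, min(1.0, max(0.0, raw))


def pair_with_controls(slopes: list[SlopeEstimate]) -> list[InhibitionRecord]:
    """Pair every exposed well with the mean control slope of its abiotic combination.

    Control wells (PCP = 0) are averaged per abiotic combination and excluded
    from the output.  A combination with exposed wells but no control raises.
    """
    controls: dict[tuple, list[float]] = {}
    for e in slopes:
        if e.condition.is_control:
            controls.setdefault(e.condition.abiotic.as_tuple(), []).append(e.slope_au)
    control_means = {k: sum(v) / len(v) for k, v in controls.items()}

    records = []
    for e in slopes:
        if e.condition.is_control:
            continue
        key = e.condition.abiotic.as_tuple()
        if key not in control_means:
            raise ValueError(
                f"no control well for abiotic combination (pH {key[0]}, "
                f"{key[1]} C, {key[2]} mS/cm)"
            )
        raw, clamped = compute_inhibition(e.slope_au, control_means[key])
        records.append(InhibitionRecord(e.condition, raw, clamped, control_means[key]))
    return records


def inhibition_to_frame(records: list[InhibitionRecord]) -> pd.DataFrame:
    rows = [
        (
            r.condition.abiotic.ph,
            r.condition.abiotic.temperature_c,
            r.condition.abiotic.conductivity_ms_cm,
            r.condition.pcp_mg_per_l,
            r.condition.replicate,
            r.inhibition_raw,
            r.inhibition,
            r.control_slope_au,
        )
        for r in records
    ]
    return pd.DataFrame(rows, columns=INHIBITION_COLUMNS)
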