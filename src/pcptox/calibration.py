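"""Ground-truth response surface used by the synthetic plate generator.

The generator is anchored to the study's headline measurements:

* baseline respiratory slope 25.05 a.u. at the most favourable condition
  (30 C, pH 5), with activity fold-decreases of 20.2 (pH 5 -> 9) and
  6 (30 -> 10 C);
* EC50 values 7.3, 42.01 and 190.2 mg/L at pH 5/7/9 (30 C, 8.13 mS/cm);
* inhibition of 9.44% at 50 mg/L under (pH 9, 8.13 mS/cm) and 99.56% under
  (pH 5, 22.17 mS/cm).

Activity interpolates geometrically (log-linearly) between anchors in pH and
temperature and is independent of conductivity.  log10(EC50) is the quadratic
in pH through the three EC50 anchors, shifted linearly in conductivity (and
optionally temperature); a single Hill exponent, solved from the pH 9
inhibition anchor, is shared across conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .design import AbioticCondition, AssayCondition

#: Printed anchor values the default calibration reproduces exactly.
DEFAULT_ANCHORS = {
    "activity_ref_au": 25.05,  # slope at 30 C, pH 5
    "ph_activity_ratio": 20.2,  # activity fold-decrease pH 5 -> 9
    "temp_activity_ratio": 6.0,  # activity fold-decrease 30 -> 10 C
    "ec50_ph5_mg_l": 7.3,  # at 30 C, 8.13 mS/cm
    "ec50_ph7_mg_l": 42.01,
    "ec50_ph9_mg_l": 190.2,
    "inh_50mg_ph9_cs8": 0.0944,  # inhibition at 50 mg/L, pH 9, 8.13 mS/cm
    "inh_50mg_ph5_cs22": 0.9956,  # inhibition at 50 mg/L, pH 5, 22.17 mS/cm
}

_PH_REF = 5.0
_TEMP_REF_C = 30.0
_CS_REF_MS_CM = 8.13
_ANCHOR_DOSE_MG_L = 50.0
_CS_HIGH_MS_CM = 22.17


@dataclass(frozen=True)
class GeneratorCalibration:
    """Parameters of the ground-truth activity and dose-response surfaces.

    Attributes
    ----------
    a_ref : baseline respiratory slope (a.u. per hour) at 30 C, pH 5.
    ph_activity_ratio : activity fold-decrease from pH 5 to pH 9 (> 1).
    temp_activity_ratio : activity fold-decrease from 30 C to 10 C (> 1).
    log_ec50_coeffs : (c2, c1, c0) of the quadratic log10 EC50(pH) at the
        reference temperature and conductivity.
    hill_slope_n : shared Hill exponent of the true dose-response (> 0).
    cond_log_factor : change in log10 EC50 per mS/cm of conductivity above
        8.13 (negative: saltier samples potentiate PCP).
    temp_ec50_log_factor : change in log10 EC50 per degree C above 30
        (default 0; all EC50 anchors sit at 30 C).
    """

    a_ref: float
    ph_activity_ratio: float
    temp_activity_ratio: float
    log_ec50_coeffs: tuple[float, float, float]
    hill_slope_n: float
    cond_log_factor: float
    temp_ec50_log_factor: float = 0.0

    def __post_init__(self) -> None:
        if self.a_ref <= 0:
            raise ValueError("a_ref must be positive")
        if self.ph_activity_ratio <= 1 or self.temp_activity_ratio <= 1:
            raise ValueError("activity fold-decrease ratios must exceed 1")
        if self.hill_slope_n <= 0:
            raise ValueError("Hill exponent must be positive")

    def log10_ec50(self, abiotic: AbioticCondition) -> float:
        c2, c1, c0 = self.log_ec50_coeffs
        return (
            c2 * abiotic.ph**2
            + c1 * abiotic.ph
            + c0
            + self.cond_log_factor * (abiotic.conductivity_ms_cm - _CS_REF_MS_CM)
            + self.temp_ec50_log_factor * (abiotic.temperature_c - _TEMP_REF_C)
        )

    def ec50(self, abiotic: AbioticCondition) -> float:
        """True EC50 in mg/L at the given abiotic condition."""
        return 10.0 ** self.log10_ec50(abiotic)


def calibrate_generator(anchors: dict | None = None) -> GeneratorCalibration:
    """Solve the calibration so every printed anchor is reproduced exactly.

    The quadratic log10 EC50(pH) interpolates the three EC50 anchors; the Hill
    exponent is the closed-form solution of
    ``(50/EC50(pH9))^n = inh/(1-inh)`` at the pH 9 anchor; the conductivity
    shift is solved so the (pH 5, 22.17 mS/cm) inhibition anchor is matched
    exactly.
    """
    a = dict(DEFAULT_ANCHORS)
    if anchors:
        a.update(anchors)

    for key in ("inh_50mg_ph9_cs8", "inh_50mg_ph5_cs22"):
        if not 0.0 < a[key] < 1.0:
            raise ValueError(f"inhibition anchor {key}={a[key]} must lie in (0, 1)")

    # quadratic through the three EC50 anchors at (30 C, 8.13 mS/cm)
    phs = np.array([5.0, 7.0, 9.0])
    log_ec50 = np.log10(
        [a["ec50_ph5_mg_l"], a["ec50_ph7_mg_l"], a["ec50_ph9_mg_l"]]
    )
    c2, c1, c0 = np.polyfit(phs, log_ec50, 2)

    # Hill exponent from the pH 9 inhibition anchor: C^n/(E^n + C^n) = inh
    inh9 = a["inh_50mg_ph9_cs8"]
    ratio = _ANCHOR_DOSE_MG_L / a["ec50_ph9_mg_l"]
    if ratio == 1.0:
        raise ValueError("anchor dose equal to EC50 leaves the Hill exponent free")
    n = math.log(inh9 / (1.0 - inh9)) / math.log(ratio)
    if n <= 0:
        raise ValueError("anchors imply a non-positive Hill exponent")

    # conductivity shift from the (pH 5, 22.17 mS/cm) anchor: invert the Hill
    # form at the anchored inhibition to get the implied EC50, then spread the
    # log10 shift over the conductivity step.
    inh5 = a["inh_50mg_ph5_cs22"]
    implied_ec50 = _ANCHOR_DOSE_MG_L * ((1.0 - inh5) / inh5) ** (1.0 / n)
    base_log_ec50_ph5 = c2 * 25.0 + c1 * 5.0 + c0
    cond_log_factor = (math.log10(implied_ec50) - base_log_ec50_ph5) / (
        _CS_HIGH_MS_CM - _CS_REF_MS_CM
    )

    return GeneratorCalibration(
        a_ref=a["activity_ref_au"],
        ph_activity_ratio=a["ph_activity_ratio"],
        temp_activity_ratio=a["temp_activity_ratio"],
        log_ec50_coeffs=(float(c2), float(c1), float(c0)),
        hill_slope_n=float(n),
        cond_log_factor=float(cond_log_factor),
    )


def true_activity(abiotic: AbioticCondition, calib: GeneratorCalibration) -> float:
    """Uninhibited respiratory slope (a.u. per hour) at an abiotic condition.

    Geometric interpolation between the activity anchors:
    ``a_ref * ph_ratio^(-(pH-5)/4) * temp_ratio^((T-30)/20)``.
    Conductivity has no effect on baseline activity.
    """
    return (
        calib.a_ref
        * calib.ph_activity_ratio ** (-(abiotic.ph - _PH_REF) / 4.0)
        * calib.temp_activity_ratio ** ((abiotic.temperature_c - _TEMP_REF_C) / 20.0)
    )


def true_inhibition(cond: AssayCondition, calib: GeneratorCalibration) -> float:
    """Ground-truth inhibition fraction in [0, 1] for one assay condition.

    Hill form ``C^n / (EC50^n + C^n)`` with the abiotic-dependent EC50.
    """
    c = cond.pcp_mg_per_l
    if c == 0.0:
        return 0.0
    ec50 = calib.ec50(cond.abiotic)
    cn = c**calib.hill_slope_n
    return cn / (ec50**calib.hill_slope_n + cn)
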