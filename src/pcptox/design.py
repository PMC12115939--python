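"""Experimental designs for the PCP / *E. coli* respiration bioassay.

The study crosses three abiotic factors — pH, assay temperature and sample
conductivity — with eight pentachlorophenol (PCP) concentrations.  The
training design is the full factorial of three levels per abiotic factor
(27 abiotic combinations) x 8 concentrations x 3 replicates = 648 wells;
the validation design uses 24 novel abiotic combinations x 8 concentrations
x 2 replicates = 384 wells.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

PH_LEVELS = (5.0, 7.0, 9.0)
TEMPERATURE_LEVELS_C = (10.0, 20.0, 30.0)
CONDUCTIVITY_LEVELS_MS_CM = (8.13, 15.67, 22.17)
PCP_LEVELS_MG_L = (0.0, 10.0, 20.0, 50.0, 100.0, 200.0, 500.0, 1000.0)

TRAINING_REPLICATES = 3
VALIDATION_REPLICATES = 2


@dataclass(frozen=True)
class AbioticCondition:
    """One combination of the three abiotic factors.

    Parameters
    ----------
    ph : unitless, tested range 5-9.
    temperature_c : assay temperature in degrees Celsius, tested range 10-30.
    conductivity_ms_cm : sample conductivity in mS/cm at 25 C, tested range
        8.13-22.17.
    """

    ph: float
    temperature_c: float
    conductivity_ms_cm: float

    def __post_init__(self) -> None:
        if not 4.0 <= self.ph <= 10.0:
            raise ValueError(f"pH {self.ph} outside the supported range [4, 10]")
        if not 0.0 <= self.temperature_c <= 40.0:
            raise ValueError(
                f"temperature {self.temperature_c} C outside the supported range [0, 40]"
            )
        if self.conductivity_ms_cm <= 0:
            raise ValueError("conductivity must be positive")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.ph, self.temperature_c, self.conductivity_ms_cm)


@dataclass(frozen=True)
class AssayCondition:
    """One well's experimental condition: abiotic combination + PCP dose + replicate."""

    abiotic: AbioticCondition
    pcp_mg_per_l: float
    replicate: int

    def __post_init__(self) -> None:
        if self.pcp_mg_per_l < 0:
            raise ValueError("PCP concentration must be non-negative")
        if self.replicate < 1:
            raise ValueError("replicate index starts at 1")

    @property
    def is_control(self) -> bool:
        return self.pcp_mg_per_l == 0.0


@dataclass
class StudyDesign:
    """An ordered collection of assay conditions with a label."""

    label: str
    conditions: list[AssayCondition] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.conditions)

    def __iter__(self):
        return iter(self.conditions)

    def distinct_combinations(self) -> set[tuple[float, float, float, float]]:
        return {
            (*c.abiotic.as_tuple(), c.pcp_mg_per_l) for c in self.conditions
        }

    def abiotic_combinations(self) -> set[tuple[float, float, float]]:
        return {c.abiotic.as_tuple() for c in self.conditions}


def training_abiotic_grid() -> list[AbioticCondition]:
    """The 27 abiotic combinations of the training factorial."""
    return [
        AbioticCondition(ph, t, cs)
        for ph, t, cs in itertools.product(
            PH_LEVELS, TEMPERATURE_LEVELS_C, CONDUCTIVITY_LEVELS_MS_CM
        )
    ]


def enumerate_training_design() -> StudyDesign:
    """Full factorial training design: 216 conditions x 3 replicates = 648 wells.

    Ordering is deterministic: pH, then temperature, then conductivity,
    then PCP concentration, then replicate.
    """
    conditions = [
        AssayCondition(AbioticCondition(ph, t, cs), pcp, rep)
        for ph, t, cs, pcp, rep in itertools.product(
            PH_LEVELS,
            TEMPERATURE_LEVELS_C,
            CONDUCTIVITY_LEVELS_MS_CM,
            PCP_LEVELS_MG_L,
            range(1, TRAINING_REPLICATES + 1),
        )
    ]
    return StudyDesign("training", conditions)


# Stand-in for the 24 novel abiotic combinations of the validation campaign,
# which are reported only graphically: off-grid levels interleaved between the
# training levels.  Synthetic fixture, user-overridable.
DEFAULT_VALIDATION_ABIOTICS: tuple[AbioticCondition, ...] = tuple(
    AbioticCondition(ph, t, cs)
    for ph, t, cs in itertools.product(
        (5.5, 6.5, 8.0), (15.0, 25.0), (11.03, 18.14)
    )
) + tuple(
    AbioticCondition(ph, t, cs)
    for ph, t, cs in itertools.product((6.0, 7.5, 8.5), (12.0, 28.0), (9.5, 20.0))
)


def enumerate_validation_design(
    abiotic_combos: Sequence[AbioticCondition] | None = None,
) -> StudyDesign:
    """Validation design: 24 novel abiotic combinations x 8 doses x 2 replicates.

    Raises if the combinations are not exactly 24, contain duplicates, or
    coincide with a training combination (the validation campaign must be
    held out).
    """
    if abiotic_combos is None:
        abiotic_combos = DEFAULT_VALIDATION_ABIOTICS
    combos = list(abiotic_combos)
    if len(combos) != 24:
        raise ValueError(f"expected 24 abiotic combinations, got {len(combos)}")
    seen = {c.as_tuple() for c in combos}
    if len(seen) != 24:
        raise ValueError("duplicate abiotic combinations in validation set")
    training = {c.as_tuple() for c in training_abiotic_grid()}
    overlap = seen & training
    if overlap:
        raise ValueError(
            f"validation combinations coincide with training combinations: {sorted(overlap)}"
        )
    conditions = [
        AssayCondition(ab, pcp, rep)
        for ab, pcp, rep in itertools.product(
            combos, PCP_LEVELS_MG_L, range(1, VALIDATION_REPLICATES + 1)
        )
    ]
    return StudyDesign("validation", conditions)
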