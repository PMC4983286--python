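"""Domain types for submaximal cycle-ergometer test records.

A test consists of two consecutive 4-minute cycling stages: a fixed
standard work rate (0.5 kp at 60 rpm on a Monark ergometer, ≈30 W) and a
higher, individually chosen work rate. The steady-state heart rate on each
stage, together with sex and age, is what the prediction equations consume.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence, Tuple

from .exceptions import InvalidTestError

#: Age range (years) over which the sex-specific equations were developed.
VALID_AGE_RANGE = (20.0, 86.0)

#: Standard (first-stage) work rate in watts: 0.5 kp at 60 rpm.
STANDARD_WORK_RATE_W = 0.5 * 6.0 * 60.0 / 6.116

#: Protocol time offsets (seconds into the stage) whose HR readings are
#: averaged to give the steady-state HR: 3:15, 3:30, 3:45 and 4:00.
PROTOCOL_OFFSETS_S = (195, 210, 225, 240)


class Sex(str, Enum):
    """Biological sex as used by the prediction equations."""

    MALE = "M"
    FEMALE = "F"

    @classmethod
    def parse(cls, value) -> "Sex":
        if isinstance(value, Sex):
            return value
        key = str(value).strip().upper()
        aliases = {"M": cls.MALE, "MALE": cls.MALE, "MAN": cls.MALE,
                   "F": cls.FEMALE, "FEMALE": cls.FEMALE, "WOMAN": cls.FEMALE}
        if key not in aliases:
            raise InvalidTestError(f"unrecognised sex {value!r}")
        return aliases[key]


@dataclass(frozen=True)
class TestRecord:
    """One participant's submaximal test inputs.

    Parameters
    ----------
    sex : Sex
    age : float
        Years; decimals accepted. Ages outside 20–86 are accepted with a
        warning (range gating is advisory for the regression equations).
    po_standard, po_high : float
        Work rates in watts; ``po_high`` must exceed ``po_standard``.
    hr_standard, hr_high : float
        Steady-state heart rates (bpm) on the two stages;
        ``hr_high`` must exceed ``hr_standard``.
    body_mass : float, optional
        kg; required only for relative (mL·kg⁻¹·min⁻¹) output.
    measured_vo2max : float, optional
        Directly measured VO2max (L·min⁻¹) for validation.
    id : str
        Opaque participant label.
    """

    __test__ = False  # keep pytest collection away from the Test* name

    sex: Sex
    age: float
    hr_standard: float
    hr_high: float
    po_high: float
    po_standard: float = STANDARD_WORK_RATE_W
    body_mass: Optional[float] = None
    measured_vo2max: Optional[float] = None
    id: str = ""

    def __post_init__(self):
        object.__setattr__(self, "sex", Sex.parse(self.sex))
        if self.hr_standard <= 0:
            raise InvalidTestError(f"{self.id}: hr_standard must be > 0")
        if self.hr_high <= self.hr_standard:
            raise InvalidTestError(
                f"{self.id}: hr_high ({self.hr_high}) must exceed "
                f"hr_standard ({self.hr_standard})")
        if self.po_high <= self.po_standard:
            raise InvalidTestError(
                f"{self.id}: po_high ({self.po_high}) must exceed "
                f"po_standard ({self.po_standard})")
        if self.body_mass is not None and self.body_mass <= 0:
            raise InvalidTestError(f"{self.id}: body_mass must be > 0")
        if self.measured_vo2max is not None and self.measured_vo2max <= 0:
            raise InvalidTestError(f"{self.id}: measured_vo2max must be > 0")
        if not (VALID_AGE_RANGE[0] <= self.age <= VALID_AGE_RANGE[1]):
            _warnings.warn(
                f"record {self.id!r}: age {self.age} outside the "
                f"{VALID_AGE_RANGE[0]:.0f}-{VALID_AGE_RANGE[1]:.0f} y range "
                "the equations were developed on", stacklevel=3)


@dataclass(frozen=True)
class DerivedPredictors:
    """Predictors derived from the two-stage HR/power response.

    ``hr_per_po`` (ΔHR/ΔPO, bpm·W⁻¹) is the rise in steady-state HR per
    watt of added work rate — the central predictor of both equations.
    """

    delta_hr: float
    delta_po: float
    hr_per_po: float


@dataclass
class Estimate:
    """An estimated VO2max with method tag and validity flags.

    ``vo2max_rel`` is present iff the record carried a body mass;
    ``in_valid_range`` is False when the inputs or the estimate fall
    outside the range the method was developed on (see ``warnings``).
    """

    method: str
    vo2max_abs: float
    vo2max_rel: Optional[float] = None
    in_valid_range: bool = True
    warnings: list = field(default_factory=list)

    def rounded(self) -> "Estimate":
        """Reporting precision: 2 dp for L·min⁻¹, 1 dp for mL·kg⁻¹·min⁻¹."""
        return Estimate(
            method=self.method,
            vo2max_abs=round(self.vo2max_abs, 2),
            vo2max_rel=None if self.vo2max_rel is None else round(self.vo2max_rel, 1),
            in_valid_range=self.in_valid_range,
            warnings=list(self.warnings),
        )


@dataclass(frozen=True)
class HrSeries:
    """Ordered (time-offset s, HR bpm) samples within one stage."""

    readings: Tuple[Tuple[float, float], ...]

    def __init__(self, readings: Sequence[Tuple[float, float]]):
        object.__setattr__(self, "readings", tuple((float(t), float(h)) for t, h in readings))
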