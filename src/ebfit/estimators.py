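"""VO2max estimation from the two-stage submaximal cycle test.

Three estimators are provided:

* :func:`eb_new_estimate` — the sex-specific log-linear equations
  (ln VO2max regressed on age, ΔHR/ΔPO, ΔPO and HR at the standard work
  rate), valid for ages 20–86 y and a wide fitness range;
* :func:`eb_2012_estimate` — the original pooled linear equation
  (VO2max on ΔHR/ΔPO, sex and age), narrower validity;
* :func:`astrand_estimate` — the classical Åstrand–Ryhming nomogram with
  age-correction factors, driven by the high stage's work rate and HR
  (see :mod:`ebfit.astrand`).

Published coefficients are stored exactly as printed (5 decimals) and are
never refit or re-rounded; out-of-validity inputs yield warnings on the
:class:`~ebfit.records.Estimate`, not errors, except the nomogram's hard
120–170 bpm window.
"""

from __future__ import annotations

import math
from typing import Optional

from .exceptions import (
    IncompleteSeriesError,
    InvalidArgumentError,
    InvalidTestError,
)
from .records import (
    PROTOCOL_OFFSETS_S,
    VALID_AGE_RANGE,
    DerivedPredictors,
    Estimate,
    HrSeries,
    Sex,
    TestRecord,
)

# --------------------------------------------------------------------------
# Published coefficients (verbatim, 5 decimals)
# --------------------------------------------------------------------------

#: Sex-specific ln-VO2max equations:
#: ln VO2max = b0 + b_age*age + b_slope*(ΔHR/ΔPO) + b_dpo*ΔPO + b_hr*HR_std
#: ΔPO in watts, ΔHR/ΔPO in bpm·W⁻¹, HR_std in bpm, age in years.
EB_NEW_COEF = {
    Sex.MALE: {
        "intercept": 2.04900,
        "age": -0.00858,
        "hr_per_po": -0.90742,
        "delta_po": 0.00178,
        "hr_standard": -0.00290,
    },
    Sex.FEMALE: {
        "intercept": 1.84390,
        "age": -0.00673,
        "hr_per_po": -0.62578,
        "delta_po": 0.00175,
        "hr_standard": -0.00471,
    },
}

#: Pooled linear 2012 equation:
#: VO2max = b0 + b_slope*(ΔHR/ΔPO) + b_sex*sex + b_age*age, sex: women=0, men=1.
EB_2012_COEF = {
    "intercept": 4.98196,
    "hr_per_po": -2.88618,
    "sex_male": 0.65015,
    "age": -0.01712,
}

#: VO2max span (L·min⁻¹) of the cohort the sex-specific equations were fit on.
EB_NEW_VALID_VO2 = {Sex.FEMALE: (1.33, 3.94), Sex.MALE: (1.67, 5.97)}

#: Validity limits of the 2012 equation: ages 20–65 y and the original
#: cohort's VO2max span.
EB_2012_VALID_AGE = (20.0, 65.0)
EB_2012_VALID_VO2 = {Sex.FEMALE: (1.56, 3.73), Sex.MALE: (2.75, 4.49)}

#: kpm per minute in one watt (1 W = 6.116 kpm·min⁻¹).
KPM_PER_MIN_PER_WATT = 6.116

#: Flywheel travel per pedal revolution on Monark ergometers (metres).
MONARK_FLYWHEEL_M_PER_REV = 6.0


# --------------------------------------------------------------------------
# Protocol helpers
# --------------------------------------------------------------------------

def kp_rpm_to_watts(resistance_kp: float, cadence_rpm: float,
                    flywheel_m_per_rev: float = MONARK_FLYWHEEL_M_PER_REV) -> float:
    """Convert friction-braked ergometer settings to power in watts.

    Work rate in kpm·min⁻¹ is resistance × flywheel travel per revolution
    × cadence; dividing by 6.116 kpm·min⁻¹·W⁻¹ gives watts. The protocol's
    standard stage, 0.5 kp at 60 rpm, comes out at ≈29.4 W (nominally 30 W).
    """
    if resistance_kp < 0 or cadence_rpm < 0:
        raise InvalidArgumentError("resistance and cadence must be non-negative")
    return resistance_kp * flywheel_m_per_rev * cadence_rpm / KPM_PER_MIN_PER_WATT


def steady_state_hr(series: HrSeries) -> float:
    """Steady-state HR of a stage: the mean of the readings at 3:15, 3:30,
    3:45 and 4:00 min.

    Raises :class:`IncompleteSeriesError` naming any missing offsets.
    """
    by_offset = {t: hr for t, hr in series.readings}
    missing = [t for t in PROTOCOL_OFFSETS_S if t not in by_offset]
    if missing:
        pretty = ", ".join(f"{t // 60}:{t % 60:02d}" for t in missing)
        raise IncompleteSeriesError(f"HR series missing protocol time point(s) {pretty}")
    return sum(by_offset[t] for t in PROTOCOL_OFFSETS_S) / len(PROTOCOL_OFFSETS_S)


def derive_predictors(record: TestRecord) -> DerivedPredictors:
    """Compute ΔHR, ΔPO and ΔHR/ΔPO from a record, exactly and unrounded."""
    delta_hr = record.hr_high - record.hr_standard
    delta_po = record.po_high - record.po_standard
    if delta_po <= 0:
        raise InvalidTestError(f"{record.id}: ΔPO must be positive (got {delta_po})")
    if delta_hr <= 0:
        raise InvalidTestError(f"{record.id}: ΔHR must be positive (got {delta_hr})")
    return DerivedPredictors(delta_hr=delta_hr, delta_po=delta_po,
                             hr_per_po=delta_hr / delta_po)


def _attach_relative(est: Estimate, body_mass: Optional[float]) -> Estimate:
    if body_mass is not None:
        est.vo2max_rel = est.vo2max_abs * 1000.0 / body_mass
    return est


# --------------------------------------------------------------------------
# Estimators
# --------------------------------------------------------------------------

def eb_new_linear_predictor(sex: Sex, age: float, hr_per_po: float,
                            delta_po: float, hr_standard: float) -> float:
    """The sex-specific linear predictor on the ln VO2max scale."""
    c = EB_NEW_COEF[Sex.parse(sex)]
    return (c["intercept"] + c["age"] * age + c["hr_per_po"] * hr_per_po
            + c["delta_po"] * delta_po + c["hr_standard"] * hr_standard)


def eb_new_estimate(record: TestRecord) -> Estimate:
    """Estimate VO2max with the sex-specific log-linear equations.

    The exponential form guarantees a positive estimate. ``in_valid_range``
    is set to False, with explanatory warnings, when the age falls outside
    20–86 y or the estimate falls outside the development cohort's VO2max
    span for that sex.
    """
    p = derive_predictors(record)
    x = eb_new_linear_predictor(record.sex, record.age, p.hr_per_po,
                                p.delta_po, record.hr_standard)
    vo2 = math.exp(x)
    warnings = []
    if not (VALID_AGE_RANGE[0] <= record.age <= VALID_AGE_RANGE[1]):
        warnings.append(
            f"age {record.age:g} outside valid range "
            f"{VALID_AGE_RANGE[0]:.0f}-{VALID_AGE_RANGE[1]:.0f} y")
    lo, hi = EB_NEW_VALID_VO2[record.sex]
    if not (lo <= vo2 <= hi):
        warnings.append(
            f"estimated VO2max {vo2:.2f} L/min outside the development "
            f"range {lo:.2f}-{hi:.2f} L/min for {record.sex.name.lower()}s")
    est = Estimate(method="eb_new", vo2max_abs=vo2,
                   in_valid_range=not warnings, warnings=warnings)
    return _attach_relative(est, record.body_mass)


def eb_2012_estimate(record: TestRecord) -> Estimate:
    """Estimate VO2max with the original pooled linear equation.

    Being linear (not log-linear) the prediction is unbounded below; a
    non-positive or otherwise out-of-range result is flagged, never raised.
    """
    p = derive_predictors(record)
    c = EB_2012_COEF
    vo2 = (c["intercept"] + c["hr_per_po"] * p.hr_per_po
           + c["sex_male"] * (1.0 if record.sex is Sex.MALE else 0.0)
           + c["age"] * record.age)
    warnings = []
    if not (EB_2012_VALID_AGE[0] <= record.age <= EB_2012_VALID_AGE[1]):
        warnings.append(
            f"age {record.age:g} outside valid range "
            f"{EB_2012_VALID_AGE[0]:.0f}-{EB_2012_VALID_AGE[1]:.0f} y")
    lo, hi = EB_2012_VALID_VO2[record.sex]
    if not (lo <= vo2 <= hi):
        warnings.append(
            f"estimated VO2max {vo2:.2f} L/min outside the valid range "
            f"{lo:.2f}-{hi:.2f} L/min for {record.sex.name.lower()}s")
    if vo2 <= 0:
        warnings.append("linear equation produced a non-positive estimate")
    est = Estimate(method="eb_2012", vo2max_abs=vo2,
                   in_valid_range=not warnings, warnings=warnings)
    return _attach_relative(est, record.body_mass)


def astrand_estimate(record: TestRecord, table) -> Estimate:
    """Estimate VO2max with the Åstrand nomogram comparator.

    ``table`` is an :class:`ebfit.astrand.AstrandTable`. The high stage's
    work rate and HR enter the nomogram; the result is multiplied by the
    age-correction factor. HR outside 120–170 bpm is a hard
    :class:`NotApplicableError`, mirroring how such tests are excluded in
    method-comparison studies.
    """
    from .astrand import AstrandTable  # local import to avoid cycle

    if table is None:
        from .exceptions import ConfigurationError
        raise ConfigurationError("astrand_estimate requires an AstrandTable")
    if not isinstance(table, AstrandTable):
        raise TypeError("table must be an AstrandTable")
    vo2 = table.evaluate(record.sex, record.po_high, record.hr_high, record.age)
    est = Estimate(method="astrand", vo2max_abs=vo2, in_valid_range=True,
                   warnings=[])
    return _attach_relative(est, record.body_mass)


def prediction_halfwidth(cv_fraction: float, vo2max: float) -> float:
    """Half-width of the 95% individual prediction band, 1.96 × CV × VO2max.

    With a validation CV of 8.4% (men), an individual whose true VO2max is
    3.0 L·min⁻¹ is predicted within ±0.49 L·min⁻¹ in 95 cases out of 100.
    A VO2max of exactly 0 returns 0.
    """
    if cv_fraction <= 0 or vo2max < 0:
        raise InvalidArgumentError("cv_fraction must be > 0 and vo2max >= 0")
    return 1.96 * cv_fraction * vo2max


def estimate(record: TestRecord, method: str = "eb_new", table=None) -> Estimate:
    """Dispatch to one of the three estimators by name."""
    method = method.replace("-", "_").lower()
    if method == "eb_new":
        return eb_new_estimate(record)
    if method == "eb_2012":
        return eb_2012_estimate(record)
    if method == "astrand":
        return astrand_estimate(record, table)
    raise InvalidArgumentError(f"unknown method {method!r}")
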