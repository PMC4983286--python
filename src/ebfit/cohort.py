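"""Synthetic participant cohorts for testing the estimation pipeline.

Two generation modes:

``exact_model``
    Covariates are drawn directly (age, ΔHR/ΔPO, ΔPO, HR at the standard
    work rate) and ln VO2max is set *exactly* from the published
    sex-specific equation, plus optional Gaussian noise on the ln scale.
    With zero noise the estimator recovers the truth to machine precision,
    which makes this mode the oracle for coefficient-recovery tests.

``physiologic``
    VO2max, body mass, maximal and resting HR are drawn from sex-specific
    distributions matching the development cohort's marginals (men:
    age 48.3 ± 15.7 y, VO2max 3.73 ± 0.86 L·min⁻¹, mass 80.7 ± 9.0 kg;
    women: 46.1 ± 16.8 y, 2.55 ± 0.58 L·min⁻¹, 63.7 ± 8.5 kg). Each
    individual gets a linear HR–VO2 line through (resting VO2, resting HR)
    and (VO2max, HRmax); stage HRs are read off that line with bpm-level
    noise, and the high work rate targets ≈75% of HRmax — a stand-in for
    the protocol's "perceived exertion ≈14" guidance. Records violating
    the protocol invariants are redrawn (rejection sampling).

The default ln-scale noise SD of 0.085 is a calibration: it makes the
end-to-end validation CV of simulated cohorts land near the ≈8.7%
observed for the equations on real data. It is a package choice, not an
empirical residual SD (which is not publicly available).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import EB_2012_COEF, eb_new_linear_predictor
from .exceptions import SpecError
from .records import PROTOCOL_OFFSETS_S, STANDARD_WORK_RATE_W, HrSeries, Sex, TestRecord

#: Cycling economy used by physiologic mode: VO2 (L·min⁻¹) at power W.
ECONOMY_SLOPE = 0.0122
ECONOMY_INTERCEPT = 0.3

#: Columns of a generated cohort frame (also the CSV interface).
COHORT_COLUMNS = ("id", "sex", "age", "body_mass_kg", "po_standard_w",
                  "po_high_w", "hr_standard", "hr_high",
                  "measured_vo2max_l_min", "true_vo2max_l_min")


@dataclass(frozen=True)
class Normal:
    mean: float
    sd: float
    lo: float = -np.inf
    hi: float = np.inf

    def __post_init__(self):
        if self.sd <= 0:
            raise SpecError(f"SD must be > 0, got {self.sd}")
        if self.lo >= self.hi:
            raise SpecError("truncation bounds must be ordered lo < hi")
        if self.hi < self.mean - 4 * self.sd or self.lo > self.mean + 4 * self.sd:
            raise SpecError(
                f"truncation bounds ({self.lo}, {self.hi}) exclude "
                f"mean ± 4 SD ({self.mean} ± {4 * self.sd})")

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        a = (self.lo - self.mean) / self.sd
        b = (self.hi - self.mean) / self.sd
        return stats.truncnorm.rvs(a, b, loc=self.mean, scale=self.sd,
                                   size=n, random_state=rng)


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort.

    Defaults emulate the development cohort: 117 men and 100 women with
    the marginal age, mass and VO2max structure above. ``mode`` selects
    the generation strategy (see module docstring); ``ln_noise_sd`` only
    applies in exact_model mode.
    """

    n_male: int = 117
    n_female: int = 100
    mode: str = "physiologic"       # or "exact_model"
    seed: int = 0
    ln_noise_sd: float = 0.085

    age: dict = field(default_factory=lambda: {
        Sex.MALE: Normal(48.3, 15.7, 20.0, 86.0),
        Sex.FEMALE: Normal(46.1, 16.8, 20.0, 86.0)})
    body_mass: dict = field(default_factory=lambda: {
        Sex.MALE: Normal(80.7, 9.0, 45.0, 130.0),
        Sex.FEMALE: Normal(63.7, 8.5, 40.0, 110.0)})
    vo2max: dict = field(default_factory=lambda: {
        Sex.MALE: Normal(3.73, 0.86, 1.67, 5.97),
        Sex.FEMALE: Normal(2.55, 0.58, 1.33, 3.94)})

    # physiologic-mode physiology
    hrmax_intercept: float = 208.0   # HRmax = 208 - 0.7*age + N(0, hrmax_sd)
    hrmax_age_slope: float = 0.7
    hrmax_sd: float = 8.0
    resting_hr: Normal = field(default_factory=lambda: Normal(65.0, 8.0, 45.0, 90.0))
    hr_noise_sd: float = 3.0         # bpm noise on stage HRs
    high_hr_fraction: float = 0.75   # high stage targets this fraction of HRmax
    max_attempts: int = 1000         # rejection-sampling cap per record

    # exact_model covariate spans (uniform draws)
    exact_age_range: Tuple[float, float] = (20.0, 86.0)
    exact_hr_per_po_range: Tuple[float, float] = (0.25, 1.0)
    exact_delta_po_range: Tuple[float, float] = (60.0, 220.0)
    exact_hr_standard_range: Tuple[float, float] = (70.0, 115.0)

    def __post_init__(self):
        if self.mode not in ("physiologic", "exact_model"):
            raise SpecError(f"unknown mode {self.mode!r}")
        if self.n_male < 0 or self.n_female < 0 or self.n_male + self.n_female == 0:
            raise SpecError("cohort must contain at least one participant")
        if self.ln_noise_sd < 0 or self.hr_noise_sd < 0:
            raise SpecError("noise SDs must be >= 0")
        if not (0 < self.high_hr_fraction < 1):
            raise SpecError("high_hr_fraction must be in (0, 1)")


def generate(spec: CohortSpec) -> pd.DataFrame:
    """Generate a cohort frame; identical spec + seed gives an identical frame.

    The frame carries one row per participant with the CSV-interface
    columns plus ``true_vo2max_l_min``; ``measured_vo2max_l_min`` plays
    the role of the criterion (treadmill-measured) value.
    """
    rng = np.random.default_rng(spec.seed)
    blocks = []
    for sex, n in ((Sex.MALE, spec.n_male), (Sex.FEMALE, spec.n_female)):
        if n == 0:
            continue
        if spec.mode == "exact_model":
            blocks.append(_exact_model_block(spec, sex, n, rng))
        else:
            blocks.append(_physiologic_block(spec, sex, n, rng))
    df = pd.concat(blocks, ignore_index=True)
    df["id"] = [f"sim-{i:04d}" for i in range(len(df))]
    return df[list(COHORT_COLUMNS)]


def _exact_model_block(spec: CohortSpec, sex: Sex, n: int,
                       rng: np.random.Generator) -> pd.DataFrame:
    age = rng.uniform(*spec.exact_age_range, n)
    hr_per_po = rng.uniform(*spec.exact_hr_per_po_range, n)
    delta_po = rng.uniform(*spec.exact_delta_po_range, n)
    hr_standard = rng.uniform(*spec.exact_hr_standard_range, n)
    lp = np.array([eb_new_linear_predictor(sex, a, s, d, h)
                   for a, s, d, h in zip(age, hr_per_po, delta_po, hr_standard)])
    true_vo2 = np.exp(lp)
    noise = rng.normal(0.0, spec.ln_noise_sd, n) if spec.ln_noise_sd > 0 else 0.0
    measured = np.exp(lp + noise)
    mass = spec.body_mass[sex].draw(rng, n)
    return pd.DataFrame({
        "id": "", "sex": sex.value, "age": age, "body_mass_kg": mass,
        "po_standard_w": STANDARD_WORK_RATE_W,
        "po_high_w": STANDARD_WORK_RATE_W + delta_po,
        "hr_standard": hr_standard,
        "hr_high": hr_standard + hr_per_po * delta_po,
        "measured_vo2max_l_min": measured,
        "true_vo2max_l_min": true_vo2,
    })


def _physiologic_block(spec: CohortSpec, sex: Sex, n: int,
                       rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for _ in range(n):
        for attempt in range(spec.max_attempts):
            row = _draw_physiologic(spec, sex, rng)
            if row is not None:
                rows.append(row)
                break
        else:
            raise SpecError(
                f"could not draw a valid {sex.name.lower()} record in "
                f"{spec.max_attempts} attempts; spec likely infeasible")
    df = pd.DataFrame(rows)
    df.insert(0, "sex", sex.value)
    df.insert(0, "id", "")
    return df


def _draw_physiologic(spec: CohortSpec, sex: Sex, rng: np.random.Generator):
    age = float(spec.age[sex].draw(rng, 1)[0])
    mass = float(spec.body_mass[sex].draw(rng, 1)[0])
    vo2max = float(spec.vo2max[sex].draw(rng, 1)[0])
    hrmax = (spec.hrmax_intercept - spec.hrmax_age_slope * age
             + rng.normal(0.0, spec.hrmax_sd))
    hr_rest = float(spec.resting_hr.draw(rng, 1)[0])
    vo2_rest = ECONOMY_INTERCEPT
    if vo2max <= vo2_rest + 0.5 or hrmax <= hr_rest + 30:
        return None
    slope = (hrmax - hr_rest) / (vo2max - vo2_rest)   # bpm per L·min⁻¹

    def hr_at_power(watts: float) -> float:
        return hr_rest + slope * (ECONOMY_SLOPE * watts)

    po_std = STANDARD_WORK_RATE_W
    hr_std = hr_at_power(po_std) + rng.normal(0.0, spec.hr_noise_sd)
    # high stage: power whose on-line HR hits the target fraction of HRmax,
    # rounded to the nearest 5 W as on a friction-braked ergometer
    hr_target = spec.high_hr_fraction * hrmax
    po_high = (hr_target - hr_rest) / slope / ECONOMY_SLOPE
    po_high = 5.0 * round(po_high / 5.0)
    hr_high = hr_at_power(po_high) + rng.normal(0.0, spec.hr_noise_sd)
    if not (po_high > po_std + 10 and hr_std > 40 and hr_high > hr_std + 5
            and hr_high <= hrmax):
        return None
    return {
        "age": age, "body_mass_kg": mass, "po_standard_w": po_std,
        "po_high_w": po_high, "hr_standard": hr_std, "hr_high": hr_high,
        "measured_vo2max_l_min": vo2max, "true_vo2max_l_min": vo2max,
    }


def generate_eb2012_cohort(n: int = 400, seed: int = 0,
                           age_range: Tuple[float, float] = (21.0, 65.0),
                           ln_noise_sd: float = 0.0) -> pd.DataFrame:
    """Mixed-sex cohort whose VO2max follows the original pooled linear
    equation exactly (plus optional multiplicative noise).

    Half the records are men, half women; ages span the 2012 equation's
    validity range by default. Used for recovery tests of the pooled
    linear form.
    """
    rng = np.random.default_rng(seed)
    n_male = n // 2
    sexes = [Sex.MALE] * n_male + [Sex.FEMALE] * (n - n_male)
    age = rng.uniform(*age_range, n)
    hr_per_po = rng.uniform(0.25, 1.0, n)
    delta_po = rng.uniform(60.0, 220.0, n)
    hr_standard = rng.uniform(70.0, 115.0, n)
    male = np.array([1.0 if s is Sex.MALE else 0.0 for s in sexes])
    c = EB_2012_COEF
    vo2 = (c["intercept"] + c["hr_per_po"] * hr_per_po
           + c["sex_male"] * male + c["age"] * age)
    measured = vo2 * np.exp(rng.normal(0.0, ln_noise_sd, n)) if ln_noise_sd > 0 else vo2
    return pd.DataFrame({
        "id": [f"sim12-{i:04d}" for i in range(n)],
        "sex": [s.value for s in sexes], "age": age,
        "body_mass_kg": np.nan,
        "po_standard_w": STANDARD_WORK_RATE_W,
        "po_high_w": STANDARD_WORK_RATE_W + delta_po,
        "hr_standard": hr_standard,
        "hr_high": hr_standard + hr_per_po * delta_po,
        "measured_vo2max_l_min": measured,
        "true_vo2max_l_min": vo2,
    })


def add_derived_columns(df: pd.DataFrame) -> pd.DataFrame:
    """Attach ΔHR, ΔPO, ΔHR/ΔPO and ln VO2max columns for model fitting."""
    out = df.copy()
    out["delta_hr"] = out["hr_high"] - out["hr_standard"]
    out["delta_po"] = out["po_high_w"] - out["po_standard_w"]
    out["hr_per_po"] = out["delta_hr"] / out["delta_po"]
    out["ln_vo2max"] = np.log(out["measured_vo2max_l_min"])
    return out


def hr_series_for(record: TestRecord, stage: str = "standard",
                  jitter: int = 2, seed: Optional[int] = None,
                  rng: Optional[np.random.Generator] = None) -> HrSeries:
    """Emit a plausible four-point HR series for one stage of a record.

    Readings are positive integers at the protocol offsets (3:15 … 4:00)
    with integer jitter within ±``jitter`` bpm around the stored
    steady-state HR, constrained so that their mean stays within 1 bpm of
    it. ``jitter=0`` reproduces the stored HR exactly at every offset.
    """
    if stage not in ("standard", "high"):
        raise ValueError("stage must be 'standard' or 'high'")
    hr = record.hr_standard if stage == "standard" else record.hr_high
    base = int(round(hr))
    if jitter == 0:
        offsets = np.zeros(len(PROTOCOL_OFFSETS_S), int)
    else:
        rng = rng if rng is not None else np.random.default_rng(seed)
        while True:
            offsets = rng.integers(-jitter, jitter + 1, len(PROTOCOL_OFFSETS_S))
            if abs(int(offsets.sum())) <= 2:   # keeps |mean - hr| <= 1 bpm
                break
    readings = [(t, max(1, base + int(o)))
                for t, o in zip(PROTOCOL_OFFSETS_S, offsets)]
    return HrSeries(readings)


def records_from_frame(df: pd.DataFrame) -> list:
    """Materialise TestRecord objects from a cohort frame."""
    records = []
    for _, row in df.iterrows():
        mass = row.get("body_mass_kg")
        meas = row.get("measured_vo2max_l_min")
        records.append(TestRecord(
            sex=Sex.parse(row["sex"]), age=float(row["age"]),
            hr_standard=float(row["hr_standard"]), hr_high=float(row["hr_high"]),
            po_standard=float(row["po_standard_w"]), po_high=float(row["po_high_w"]),
            body_mass=None if pd.isna(mass) else float(mass),
            measured_vo2max=None if pd.isna(meas) else float(meas),
            id=str(row.get("id", ""))))
    return records


def write_cohort_csv(df: pd.DataFrame, path) -> None:
    """Write a cohort frame with a fixed float format (deterministic bytes)."""
    df.to_csv(path, index=False, float_format="%.6f", lineterminator="\n")
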