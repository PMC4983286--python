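"""Åstrand–Ryhming nomogram comparator.

The nomogram relates a single submaximal work rate and its steady-state HR
to an uncorrected VO2max, which is then multiplied by an age-correction
factor. The estimator here is table-driven and agnostic to the grid: any
long-format (sex, work_rate_w, hr_bpm, vo2max_l_min) table plus an
(age, factor) correction table can be plugged in, so a transcription of
the original published tables can be swapped in without code changes.

The tables shipped with the package (``data/astrand_vo2_synthetic.csv``)
are a *synthetic* reconstruction, not a transcription: they are generated
from the nomogram's underlying physiological model — linear HR–VO2
extrapolation to an assumed maximal HR,

    VO2max = VO2(work rate) × (HRmax_ref − HR0) / (HR − HR0),

with VO2(W) = 0.0122·W + 0.3 L·min⁻¹ (standard cycling economy), reference
maximal HRs of 195 (men) and 198 bpm (women) and HR offsets of 61 and
72 bpm — together with the classical age-correction factors. They
reproduce the structure and approximate magnitude of the published
nomogram and are intended for testing and demonstration; for comparator
studies, load a verified transcription of the original tables.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, NotApplicableError
from .records import Sex

#: HR window (bpm) within which the nomogram applies; tests outside it are
#: excluded outright in comparator analyses.
HR_WINDOW = (120.0, 170.0)

#: Classical age-correction factors (age in years → multiplicative factor).
CLASSICAL_AGE_FACTORS = (
    (15, 1.10), (25, 1.00), (35, 0.87), (40, 0.83), (45, 0.78),
    (50, 0.75), (55, 0.71), (60, 0.68), (65, 0.65),
)

# Parameters of the synthetic reconstruction (see module docstring).
_ECONOMY_SLOPE = 0.0122   # L·min⁻¹ per W
_ECONOMY_INTERCEPT = 0.3  # L·min⁻¹ at 0 W
_HRMAX_REF = {Sex.MALE: 195.0, Sex.FEMALE: 198.0}
_HR_OFFSET = {Sex.MALE: 61.0, Sex.FEMALE: 72.0}


@dataclass
class AstrandTable:
    """Sex-specific VO2max grids plus age-correction factors.

    ``grids`` maps Sex → (work_rates, hrs, vo2 2-D array); ``age_factors``
    is a sorted (ages, factors) pair. Evaluation is bilinear in
    (work rate, HR) and linear in age.
    """

    grids: dict
    age_factors: tuple

    # -- construction -----------------------------------------------------

    @classmethod
    def from_frames(cls, vo2: pd.DataFrame, factors: pd.DataFrame) -> "AstrandTable":
        """Build from long-format frames.

        ``vo2`` needs columns sex, work_rate_w, hr_bpm, vo2max_l_min;
        ``factors`` needs age, factor.
        """
        required = {"sex", "work_rate_w", "hr_bpm", "vo2max_l_min"}
        if not required.issubset(vo2.columns):
            raise ConfigurationError(
                f"nomogram table missing columns {sorted(required - set(vo2.columns))}")
        if not {"age", "factor"}.issubset(factors.columns):
            raise ConfigurationError("age-correction table needs 'age' and 'factor' columns")
        grids = {}
        for sex_label, sub in vo2.groupby("sex"):
            sex = Sex.parse(sex_label)
            pivot = sub.pivot_table(index="work_rate_w", columns="hr_bpm",
                                    values="vo2max_l_min")
            if pivot.isna().any().any():
                raise ConfigurationError(
                    f"nomogram grid for sex {sex_label!r} is not complete/rectangular")
            grids[sex] = (pivot.index.to_numpy(float),
                          pivot.columns.to_numpy(float),
                          pivot.to_numpy(float))
        fac = factors.sort_values("age")
        return cls(grids=grids,
                   age_factors=(fac["age"].to_numpy(float), fac["factor"].to_numpy(float)))

    @classmethod
    def from_csv(cls, vo2_path, factors_path) -> "AstrandTable":
        return cls.from_frames(pd.read_csv(vo2_path, comment="#"),
                               pd.read_csv(factors_path, comment="#"))

    @classmethod
    def default(cls) -> "AstrandTable":
        """The synthetic reconstruction shipped with the package."""
        pkg = resources.files("ebfit") / "data"
        vo2 = pd.read_csv(io.StringIO((pkg / "astrand_vo2_synthetic.csv").read_text()),
                          comment="#")
        fac = pd.read_csv(io.StringIO((pkg / "astrand_age_correction.csv").read_text()),
                          comment="#")
        return cls.from_frames(vo2, fac)

    # -- evaluation -------------------------------------------------------

    def uncorrected(self, sex: Sex, work_rate_w: float, hr_bpm: float) -> float:
        """Bilinear interpolation of the uncorrected VO2max grid."""
        sex = Sex.parse(sex)
        if not (HR_WINDOW[0] <= hr_bpm <= HR_WINDOW[1]):
            raise NotApplicableError(
                f"HR {hr_bpm:g} bpm outside the nomogram window "
                f"{HR_WINDOW[0]:.0f}-{HR_WINDOW[1]:.0f} bpm")
        if sex not in self.grids:
            raise ConfigurationError(f"no nomogram grid for sex {sex}")
        wr, hr, grid = self.grids[sex]
        if not (wr[0] <= work_rate_w <= wr[-1]):
            raise NotApplicableError(
                f"work rate {work_rate_w:g} W outside the tabulated span "
                f"{wr[0]:g}-{wr[-1]:g} W for {sex.name.lower()}s")
        i = int(np.clip(np.searchsorted(wr, work_rate_w) - 1, 0, len(wr) - 2))
        j = int(np.clip(np.searchsorted(hr, hr_bpm) - 1, 0, len(hr) - 2))
        tw = (work_rate_w - wr[i]) / (wr[i + 1] - wr[i])
        th = (hr_bpm - hr[j]) / (hr[j + 1] - hr[j])
        return float((1 - tw) * (1 - th) * grid[i, j]
                     + tw * (1 - th) * grid[i + 1, j]
                     + (1 - tw) * th * grid[i, j + 1]
                     + tw * th * grid[i + 1, j + 1])

    def age_factor(self, age: float) -> float:
        """Linear interpolation of the correction factor at ``age``."""
        ages, factors = self.age_factors
        if not (ages[0] <= age <= ages[-1]):
            raise NotApplicableError(
                f"age {age:g} outside the correction-factor span "
                f"{ages[0]:g}-{ages[-1]:g} y")
        return float(np.interp(age, ages, factors))

    def evaluate(self, sex: Sex, work_rate_w: float, hr_bpm: float, age: float) -> float:
        """Age-corrected nomogram estimate (L·min⁻¹)."""
        return self.uncorrected(sex, work_rate_w, hr_bpm) * self.age_factor(age)


def synthetic_nomogram_frames(decimals: int = 3):
    """Regenerate the shipped synthetic nomogram tables.

    Returns (vo2_frame, factor_frame) in the long CSV formats described in
    :meth:`AstrandTable.from_frames`. Grid: men 50–250 W in 25 W steps,
    women 50–175 W in 25 W steps, HR 120–170 bpm in 5 bpm steps.
    """
    rows = []
    spans = {Sex.MALE: np.arange(50, 251, 25), Sex.FEMALE: np.arange(50, 176, 25)}
    hrs = np.arange(120, 171, 5)
    for sex, work_rates in spans.items():
        for w in work_rates:
            vo2_work = _ECONOMY_SLOPE * w + _ECONOMY_INTERCEPT
            for h in hrs:
                vo2max = vo2_work * (_HRMAX_REF[sex] - _HR_OFFSET[sex]) / (h - _HR_OFFSET[sex])
                rows.append((sex.value, int(w), int(h), round(float(vo2max), decimals)))
    vo2 = pd.DataFrame(rows, columns=["sex", "work_rate_w", "hr_bpm", "vo2max_l_min"])
    fac = pd.DataFrame(CLASSICAL_AGE_FACTORS, columns=["age", "factor"])
    return vo2, fac
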