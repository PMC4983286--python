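"""Method-comparison statistics for estimated vs directly measured VO2max.

The statistic set follows standard method-comparison practice for exercise
tests: paired mean difference with 95% CI and t-test, coefficient of
variation, Bland–Altman limits of agreement, the regression of measured on
estimated values (adjusted R² and SEE), and the Spearman correlation of the
estimation error with fitness level. Reports can be stratified by sex, age
band and sex-specific VO2max quartiles.

Sign convention
---------------
Differences are **estimated − measured** throughout, so a positive mean
difference means the method *over*estimates. The convention lives in one
place (:func:`differences`); flip ``DIFF_SIGN`` to -1 to report
measured − estimated instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .exceptions import DegenerateRegressionError, InsufficientDataError
from .records import Sex

#: +1 → differences are estimated − measured (overestimation positive).
DIFF_SIGN = +1

#: Default age bands (years): <35, 35–49, 50–64, ≥65.
DEFAULT_AGE_EDGES = (35.0, 50.0, 65.0)


@dataclass
class PairedSample:
    """Paired measured/estimated VO2max values with optional strata labels."""

    measured: np.ndarray
    estimated: np.ndarray
    sex: Optional[Sequence[Sex]] = None
    age: Optional[np.ndarray] = None
    body_mass: Optional[np.ndarray] = None
    ids: Optional[Sequence[str]] = None

    def __post_init__(self):
        self.measured = np.asarray(self.measured, float)
        self.estimated = np.asarray(self.estimated, float)
        if self.measured.shape != self.estimated.shape or self.measured.ndim != 1:
            raise InsufficientDataError("measured and estimated must be equal-length 1-D")
        if len(self.measured) < 2:
            raise InsufficientDataError("need at least 2 paired observations")
        if not (np.all(np.isfinite(self.measured)) and np.all(np.isfinite(self.estimated))):
            raise InsufficientDataError("non-finite VO2max values in sample")
        if np.any(self.measured <= 0) or np.any(self.estimated <= 0):
            raise InsufficientDataError("VO2max values must be positive")
        for name in ("age", "body_mass"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, np.asarray(v, float))
        if self.sex is not None:
            self.sex = [Sex.parse(s) for s in self.sex]

    def __len__(self) -> int:
        return len(self.measured)

    def subset(self, mask: np.ndarray) -> "PairedSample":
        mask = np.asarray(mask, bool)
        return PairedSample(
            measured=self.measured[mask],
            estimated=self.estimated[mask],
            sex=None if self.sex is None else [s for s, m in zip(self.sex, mask) if m],
            age=None if self.age is None else self.age[mask],
            body_mass=None if self.body_mass is None else self.body_mass[mask],
            ids=None if self.ids is None else [i for i, m in zip(self.ids, mask) if m],
        )


def differences(sample: PairedSample) -> np.ndarray:
    """Per-pair differences under the package sign convention."""
    return DIFF_SIGN * (sample.estimated - sample.measured)


def cv_percent(sample: PairedSample, ddof: int = 1) -> float:
    """Coefficient of variation (%) of the method differences.

    SD of the per-pair differences (sample SD, n−1 by default) divided by
    the mean of the measured and estimated group means, times 100. CV is
    invariant to the difference sign convention.
    """
    d = differences(sample)
    if len(d) < 2:
        raise InsufficientDataError("cv_percent needs n >= 2")
    grand_mean = (sample.measured.mean() + sample.estimated.mean()) / 2.0
    return 100.0 * d.std(ddof=ddof) / grand_mean


def see_and_r2(sample: PairedSample) -> Tuple[float, float]:
    """SEE and adjusted R² of the OLS of measured on estimated VO2max.

    Measured VO2max is the dependent variable, the estimate the single
    predictor; SEE is the residual standard error (df = n−2) and R² is
    adjusted for the one predictor. Note this measures linear association,
    not identity: ``measured = 2×estimated`` exactly still gives SEE 0 and
    adjusted R² 1, which is why the mean difference is reported alongside.
    """
    n = len(sample)
    if n < 3:
        raise InsufficientDataError("see_and_r2 needs n >= 3")
    x, y = sample.estimated, sample.measured
    if np.ptp(x) == 0:
        raise DegenerateRegressionError("estimated values are constant")
    X = np.column_stack([np.ones(n), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    see = math.sqrt(ss_res / (n - 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return see, r2_adj


@dataclass
class BlandAltman:
    """Mean difference, 1.96-SD limits of agreement, and plot coordinates."""

    mean_diff: float
    loa_lower: float
    loa_upper: float
    pair_means: np.ndarray
    diffs: np.ndarray


def bland_altman(sample: PairedSample, ddof: int = 1) -> BlandAltman:
    """Bland–Altman agreement: mean difference ± 1.96 × SD(differences).

    ``pair_means``/``diffs`` are the per-point plot coordinates (mean of
    each measured/estimated pair on x, difference on y).
    """
    d = differences(sample)
    if len(d) < 2:
        raise InsufficientDataError("bland_altman needs n >= 2")
    mean_diff = float(d.mean())
    half = 1.96 * d.std(ddof=ddof)
    return BlandAltman(
        mean_diff=mean_diff,
        loa_lower=mean_diff - half,
        loa_upper=mean_diff + half,
        pair_means=(sample.measured + sample.estimated) / 2.0,
        diffs=d,
    )


@dataclass
class PairedT:
    mean_diff: float
    ci_lower: float
    ci_upper: float
    p_value: float
    note: str = ""


def paired_t(sample: PairedSample, alpha: float = 0.05) -> PairedT:
    """Two-sided paired t-test of the mean difference, with t-based CI.

    Zero-variance differences are degenerate for the t statistic: a zero
    mean is reported with p = 1, a nonzero mean with p = 0, both with an
    explanatory note.
    """
    d = differences(sample)
    n = len(d)
    if n < 2:
        raise InsufficientDataError("paired_t needs n >= 2")
    mean = float(d.mean())
    sd = d.std(ddof=1)
    if sd == 0:
        return PairedT(mean, mean, mean, 1.0 if mean == 0 else 0.0,
                       note="zero-variance differences; t statistic degenerate")
    se = sd / math.sqrt(n)
    t_stat = mean / se
    p = 2.0 * stats.t.sf(abs(t_stat), df=n - 1)
    half = stats.t.ppf(1 - alpha / 2, df=n - 1) * se
    return PairedT(mean, mean - half, mean + half, float(p))


def error_vs_level(sample: PairedSample) -> Tuple[float, float, str]:
    """Spearman rank correlation of the estimation error with measured
    VO2max level (average ranks for ties).

    Returns (rho, p, note); constant differences make the correlation
    undefined and are reported as rho 0 with a degeneracy note.
    """
    if len(sample) < 3:
        raise InsufficientDataError("error_vs_level needs n >= 3")
    d = differences(sample)
    if np.ptp(d) == 0 or np.ptp(sample.measured) == 0:
        return 0.0, float("nan"), "constant input; rank correlation undefined"
    res = stats.spearmanr(d, sample.measured)
    return float(res.statistic), float(res.pvalue), ""


@dataclass
class AgreementReport:
    """The full validation-statistic set for one estimator vs measurement."""

    n: int
    mean_diff: float
    ci_lower: float
    ci_upper: float
    paired_t_p: float
    cv_percent: float
    r2_adjusted: float
    see: float
    loa_lower: float
    loa_upper: float
    spearman_rho: float
    spearman_p: float
    notes: List[str] = field(default_factory=list)


def agreement_report(sample: PairedSample) -> AgreementReport:
    """Compute every agreement statistic for one paired sample.

    Statistics whose minimum n is not met (regression and Spearman need
    n ≥ 3) are reported as NaN with a note rather than failing the whole
    report.
    """
    notes: List[str] = []
    t = paired_t(sample)
    if t.note:
        notes.append(t.note)
    ba = bland_altman(sample)
    cv = cv_percent(sample)
    if len(sample) >= 3 and np.ptp(sample.estimated) > 0:
        see, r2 = see_and_r2(sample)
        rho, rho_p, note = error_vs_level(sample)
        if note:
            notes.append(note)
    else:
        see = r2 = rho = rho_p = float("nan")
        notes.append("n < 3 or constant estimates; regression and rank statistics undefined")
    return AgreementReport(
        n=len(sample), mean_diff=t.mean_diff, ci_lower=t.ci_lower,
        ci_upper=t.ci_upper, paired_t_p=t.p_value, cv_percent=cv,
        r2_adjusted=r2, see=see, loa_lower=ba.loa_lower, loa_upper=ba.loa_upper,
        spearman_rho=rho, spearman_p=rho_p, notes=notes)


# --------------------------------------------------------------------------
# Stratification
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class QuartileScheme:
    """Sex-specific fitness-quartile cut-points.

    Defaults are the published model-group quartiles of measured VO2max.
    Boundary policy: lower-inclusive — a value exactly on a cut-point is
    assigned to the higher quartile (2.59 L·min⁻¹ for a woman is Q3).
    """

    absolute: Dict[Sex, Tuple[float, float, float]] = field(default_factory=lambda: {
        Sex.FEMALE: (2.14, 2.59, 2.93),
        Sex.MALE: (3.07, 3.75, 4.33),
    })
    relative: Dict[Sex, Tuple[float, float, float]] = field(default_factory=lambda: {
        Sex.FEMALE: (32.5, 40.2, 47.4),
        Sex.MALE: (37.5, 47.6, 54.8),
    })

    def __post_init__(self):
        for cuts in list(self.absolute.values()) + list(self.relative.values()):
            if not all(a < b for a, b in zip(cuts, cuts[1:])):
                raise ValueError("quartile cut-points must be strictly increasing")

    def assign(self, sex: Sex, value: float, relative: bool = False) -> int:
        """Quartile (1–4) of ``value`` under the sex's cut-points."""
        cuts = (self.relative if relative else self.absolute)[Sex.parse(sex)]
        return 1 + sum(value >= c for c in cuts)


def age_band_label(age: float, edges: Sequence[float] = DEFAULT_AGE_EDGES) -> str:
    """Label the age band an age falls in; default <35, 35–49, 50–64, ≥65."""
    edges = sorted(edges)
    if age < edges[0]:
        return f"<{edges[0]:g}"
    for lo, hi in zip(edges, edges[1:]):
        if age < hi:
            return f"{lo:g}-{hi - 1:g}"
    return f">={edges[-1]:g}"


@dataclass
class StratumResult:
    label: str
    n: int
    report: Optional[AgreementReport]  # None when n < 2


def stratified_report(sample: PairedSample,
                      scheme: Optional[QuartileScheme] = None,
                      age_edges: Sequence[float] = DEFAULT_AGE_EDGES,
                      ) -> List[StratumResult]:
    """Agreement statistics overall and per stratum.

    Strata: overall; men/women (when sex labels exist); age bands (when
    ages exist); quartiles of measured absolute VO2max and — when body
    mass exists — of relative VO2max, both with sex-specific cut-points.
    A stratum with fewer than 2 pairs is reported as NA with its count.
    """
    scheme = scheme or QuartileScheme()
    results: List[StratumResult] = []

    def emit(label: str, mask: np.ndarray):
        n = int(mask.sum())
        results.append(StratumResult(
            label, n, agreement_report(sample.subset(mask)) if n >= 2 else None))

    all_mask = np.ones(len(sample), bool)
    emit("all", all_mask)
    if sample.sex is not None:
        sexes = np.array([s.value for s in sample.sex])
        emit("men", sexes == Sex.MALE.value)
        emit("women", sexes == Sex.FEMALE.value)
    if sample.age is not None:
        labels = np.array([age_band_label(a, age_edges) for a in sample.age])
        edges = sorted(age_edges)
        ordered = ([f"<{edges[0]:g}"]
                   + [f"{lo:g}-{hi - 1:g}" for lo, hi in zip(edges, edges[1:])]
                   + [f">={edges[-1]:g}"])
        for lab in ordered:
            emit(f"age {lab}", labels == lab)
    if sample.sex is not None:
        q_abs = np.array([scheme.assign(s, m) for s, m in zip(sample.sex, sample.measured)])
        for q in (1, 2, 3, 4):
            emit(f"absolute Q{q}", q_abs == q)
        if sample.body_mass is not None:
            rel = sample.measured * 1000.0 / sample.body_mass
            q_rel = np.array([scheme.assign(s, v, relative=True)
                              for s, v in zip(sample.sex, rel)])
            for q in (1, 2, 3, 4):
                emit(f"relative Q{q}", q_rel == q)
    return results
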