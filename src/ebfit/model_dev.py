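"""Reproduction of the prediction-equation development procedure.

The shipped estimators use the published coefficients verbatim; this
module exists to reproduce, and test, the *procedure* that produced them:
forward-stepwise OLS of ln VO2max on the candidate predictors (age,
ΔHR/ΔPO, ΔPO, HR at the standard work rate), sex-interaction screening
that motivates fitting men and women separately, and tolerance-based
collinearity checks.

Entry/removal follows the classical "probability of F" rule: at each step
the candidate with the smallest partial-F p-value given the current model
enters if p < p_enter (default 0.05); after each entry any included
predictor whose partial-F p exceeds p_remove (default 0.10) is dropped.
Statistical packages differ in how they phrase this criterion; partial-F
p-values (equivalently squared-t, identical p for a single added column)
are used here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    DegenerateRegressionError,
    InsufficientDataError,
    NotApplicableError,
)
from .records import Sex

#: Candidate predictors of ln VO2max, in the cohort frame's column names.
DEFAULT_CANDIDATES = ("age", "hr_per_po", "delta_po", "hr_standard")


@dataclass(frozen=True)
class SelectionConfig:
    """Stepwise-selection thresholds: probability of F to enter and remove."""

    p_enter: float = 0.05
    p_remove: float = 0.10
    candidates: Tuple[str, ...] = DEFAULT_CANDIDATES

    def __post_init__(self):
        if not (0 < self.p_enter <= self.p_remove <= 1):
            # p_enter = p_remove = 1 is allowed: it forces every candidate in,
            # reducing the procedure to full-model OLS.
            raise ValueError("need 0 < p_enter <= p_remove <= 1")


@dataclass
class ModelFit:
    """A fitted ln-VO2max regression with selection metadata."""

    sex_scope: str                       # "M", "F", "both", or "pooled"
    terms: List[str]                     # selected predictors, model order
    coef: Dict[str, float]               # includes "intercept"
    ci: Dict[str, Tuple[float, float]]   # 95% t-based CIs
    entry_order: List[str]
    tolerance: Dict[str, float]
    r2_adjusted: float
    resid_sd: float                      # residual SD on the response scale
    n: int
    notes: List[str] = field(default_factory=list)


def _design(data: pd.DataFrame, terms: Sequence[str]) -> np.ndarray:
    X = np.column_stack([np.ones(len(data))] + [data[t].to_numpy(float) for t in terms])
    return X


def _check_rank(X: np.ndarray, names: Sequence[str]):
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns by greedy rank growth
        bad = []
        kept = X[:, :1]
        for j, name in enumerate(names, start=1):
            cand = np.column_stack([kept, X[:, j]])
            if np.linalg.matrix_rank(cand) == kept.shape[1]:
                bad.append(name)
            else:
                kept = cand
        raise DegenerateRegressionError(
            f"design matrix is rank deficient; collinear column(s): {bad}")


def _ols(X: np.ndarray, y: np.ndarray):
    """Least squares with residual sum of squares and df."""
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    df = len(y) - X.shape[1]
    return beta, rss, df


def partial_f_pvalue(X_reduced: np.ndarray, X_full: np.ndarray, y: np.ndarray) -> float:
    """p-value of the partial F test for the columns added in X_full."""
    _, rss_r, _ = _ols(X_reduced, y)
    _, rss_f, df_f = _ols(X_full, y)
    q = X_full.shape[1] - X_reduced.shape[1]
    if df_f <= 0:
        raise InsufficientDataError("no residual degrees of freedom")
    if rss_f <= 0:
        return 0.0
    f = ((rss_r - rss_f) / q) / (rss_f / df_f)
    return float(stats.f.sf(max(f, 0.0), q, df_f))


def forward_select(data: pd.DataFrame, response: np.ndarray,
                   config: Optional[SelectionConfig] = None,
                   sex_scope: str = "both") -> ModelFit:
    """Forward-stepwise OLS of ``response`` on ``config.candidates``.

    At each step the not-yet-included candidate with the smallest
    partial-F p enters if p < ``p_enter``; after each entry any included
    predictor with partial-F p > ``p_remove`` is removed; the procedure
    stops when neither rule fires. With ``p_enter = 1`` (and ``p_remove``
    1-epsilon) every candidate enters, reducing to full-model OLS.
    """
    config = config or SelectionConfig()
    y = np.asarray(response, float)
    n = len(y)
    if n <= len(config.candidates) + 2:
        raise InsufficientDataError(
            f"n={n} too small for {len(config.candidates)} candidates")
    _check_rank(_design(data, config.candidates), config.candidates)

    included: List[str] = []
    entry_order: List[str] = []
    while True:
        changed = False
        # entry step
        remaining = [c for c in config.candidates if c not in included]
        if remaining:
            pvals = {c: partial_f_pvalue(_design(data, included),
                                         _design(data, included + [c]), y)
                     for c in remaining}
            best = min(pvals, key=pvals.get)
            if pvals[best] < config.p_enter:
                included.append(best)
                entry_order.append(best)
                changed = True
        # removal step
        if len(included) > 1:
            X_full = _design(data, included)
            worst, worst_p = None, -1.0
            for c in included:
                others = [t for t in included if t != c]
                p = partial_f_pvalue(_design(data, others), X_full, y)
                if p > worst_p:
                    worst, worst_p = c, p
            if worst_p > config.p_remove:
                included.remove(worst)
                changed = True
        if not changed:
            break

    return _fit(data, y, included, entry_order, sex_scope)


def _fit(data: pd.DataFrame, y: np.ndarray, terms: List[str],
         entry_order: List[str], sex_scope: str) -> ModelFit:
    X = _design(data, terms)
    beta, rss, df = _ols(X, y)
    names = ["intercept"] + list(terms)
    if df <= 0:
        raise InsufficientDataError("no residual degrees of freedom")
    sigma2 = rss / df
    XtX_inv = np.linalg.pinv(X.T @ X)
    se = np.sqrt(np.clip(np.diag(XtX_inv) * sigma2, 0, None))
    tcrit = stats.t.ppf(0.975, df)
    ci = {name: (float(b - tcrit * s), float(b + tcrit * s))
          for name, b, s in zip(names, beta, se)}
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - rss / ss_tot
    k = len(terms)
    r2_adj = 1.0 - (1.0 - r2) * (len(y) - 1) / df if df > 0 else float("nan")
    tol = tolerance_values(data, terms) if k >= 2 else {t: 1.0 for t in terms}
    return ModelFit(
        sex_scope=sex_scope, terms=list(terms),
        coef={name: float(b) for name, b in zip(names, beta)},
        ci=ci, entry_order=entry_order, tolerance=tol,
        r2_adjusted=r2_adj, resid_sd=math.sqrt(sigma2), n=len(y))


def ols_fit(data: pd.DataFrame, response: np.ndarray,
            terms: Sequence[str] = DEFAULT_CANDIDATES,
            sex_scope: str = "both") -> ModelFit:
    """Plain OLS on a fixed term set (no selection)."""
    y = np.asarray(response, float)
    _check_rank(_design(data, terms), terms)
    return _fit(data, y, list(terms), list(terms), sex_scope)


# --------------------------------------------------------------------------
# Interaction screening and collinearity diagnostics
# --------------------------------------------------------------------------

@dataclass
class InteractionScreen:
    p_sex_hr_standard: float
    p_sex_hr_per_po: float
    recommend_split: bool


def interaction_screen(data: pd.DataFrame, response: np.ndarray,
                       alpha: float = 0.05) -> InteractionScreen:
    """Screen a pooled two-sex cohort for sex × HR interactions.

    Fits ln VO2max on the four main-effect candidates plus sex and the
    sex × HR_standard and sex × (ΔHR/ΔPO) products, and returns the partial
    p-values of the two interaction terms. Either p below ``alpha`` flags
    the cohort for sex-separate modelling.
    """
    sexes = [Sex.parse(s) for s in data["sex"]]
    male = np.array([1.0 if s is Sex.MALE else 0.0 for s in sexes])
    if len(set(sexes)) < 2:
        raise NotApplicableError("interaction screen needs both sexes present")
    if len(data) < 20:
        raise InsufficientDataError("interaction screen needs n >= 20")
    y = np.asarray(response, float)
    aug = data.copy()
    aug["sex_male"] = male
    aug["sex_x_hr_standard"] = male * data["hr_standard"].to_numpy(float)
    aug["sex_x_hr_per_po"] = male * data["hr_per_po"].to_numpy(float)
    base = list(DEFAULT_CANDIDATES) + ["sex_male"]
    full = base + ["sex_x_hr_standard", "sex_x_hr_per_po"]
    X_full = _design(aug, full)
    _check_rank(X_full, full)
    p_hr = partial_f_pvalue(_design(aug, base + ["sex_x_hr_per_po"]), X_full, y)
    p_slope = partial_f_pvalue(_design(aug, base + ["sex_x_hr_standard"]), X_full, y)
    return InteractionScreen(
        p_sex_hr_standard=p_hr, p_sex_hr_per_po=p_slope,
        recommend_split=(p_hr < alpha) or (p_slope < alpha))


def tolerance_values(data: pd.DataFrame, terms: Sequence[str]) -> Dict[str, float]:
    """Tolerance (1 − R² of each predictor on the others) per predictor.

    Values at or below 0.2 conventionally indicate problematic
    multicollinearity; see :func:`tolerance_check` for flagging.
    """
    out: Dict[str, float] = {}
    for t in terms:
        others = [o for o in terms if o != t]
        y = data[t].to_numpy(float)
        X = _design(data, others)
        _, rss, _ = _ols(X, y)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 if ss_tot == 0 else 1.0 - rss / ss_tot
        out[t] = max(0.0, min(1.0, 1.0 - r2))
    return out


def tolerance_check(fit: ModelFit, data: pd.DataFrame,
                    threshold: float = 0.2) -> Dict[str, Tuple[float, bool]]:
    """Tolerances for a fitted model's predictors; flag True when ≤ threshold."""
    if len(fit.terms) < 2:
        return {t: (1.0, False) for t in fit.terms}
    tol = tolerance_values(data, fit.terms)
    return {t: (v, v <= threshold) for t, v in tol.items()}
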