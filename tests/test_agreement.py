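"""Agreement statistics vs hand calculations and brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ebfit.agreement import (
    PairedSample,
    QuartileScheme,
    age_band_label,
    agreement_report,
    bland_altman,
    cv_percent,
    differences,
    error_vs_level,
    paired_t,
    see_and_r2,
    stratified_report,
)
from ebfit.exceptions import DegenerateRegressionError, InsufficientDataError
from ebfit.records import Sex

MEASURED = np.array([2.0, 3.0, 4.0])
ESTIMATED = np.array([2.2, 2.9, 4.3])   # diffs (est - meas): 0.2, -0.1, 0.3


def sample(m=MEASURED, e=ESTIMATED, **kw):
    return PairedSample(measured=np.asarray(m, float),
                        estimated=np.asarray(e, float), **kw)


def random_sample(rng, n=10):
    m = rng.uniform(1.5, 5.0, n)
    e = m * np.exp(rng.normal(0, 0.1, n))
    return sample(m, e)


# --------------------------------------------------------------------------
# brute-force oracles, independent of the implementation path
# --------------------------------------------------------------------------

def oracle_sd(xs):
    mean = sum(xs) / len(xs)
    return math.sqrt(sum((x - mean) ** 2 for x in xs) / (len(xs) - 1))


def oracle_ols(x, y):
    """Normal-equations OLS of y on x: slope, intercept, residuals."""
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx, sxy = sum(v * v for v in x), sum(a * b for a, b in zip(x, y))
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    resid = [yi - (intercept + slope * xi) for xi, yi in zip(x, y)]
    return slope, intercept, resid


def oracle_ranks(xs):
    """Average ranks via explicit sort, ties averaged."""
    order = sorted(range(len(xs)), key=lambda i: xs[i])
    ranks = [0.0] * len(xs)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and xs[order[j + 1]] == xs[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def oracle_pearson(x, y):
    mx, my = sum(x) / len(x), sum(y) / len(y)
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
    return num / den


# --------------------------------------------------------------------------
# coefficient of variation
# --------------------------------------------------------------------------

def test_cv_zero_when_methods_agree():
    assert cv_percent(sample(MEASURED, MEASURED)) == 0.0


def test_cv_hand_value():
    # SD of diffs = 0.2081666, grand mean = (3.0 + 3.1333)/2 = 3.0667
    s = sample()
    expected = 100 * oracle_sd(differences(s).tolist()) / 3.0666666666666667
    assert cv_percent(s) == pytest.approx(expected, abs=1e-12)
    assert cv_percent(s) == pytest.approx(6.788, abs=1e-3)


def test_cv_shrinks_when_level_rises():
    base = cv_percent(sample())
    shifted = cv_percent(sample(MEASURED + 1.0, ESTIMATED + 1.0))
    assert shifted < base


def test_cv_invariant_to_pair_reordering(rng):
    s = random_sample(rng)
    perm = rng.permutation(len(s))
    assert cv_percent(s.subset(np.ones(len(s), bool))) == pytest.approx(
        cv_percent(sample(s.measured[perm], s.estimated[perm])), abs=1e-12)


def test_cv_needs_two_pairs():
    with pytest.raises(InsufficientDataError):
        PairedSample(measured=[3.0], estimated=[3.1])


# --------------------------------------------------------------------------
# SEE and adjusted R² (measured regressed on estimated)
# --------------------------------------------------------------------------

def test_perfect_fit_gives_zero_see_unit_r2():
    see, r2 = see_and_r2(sample(MEASURED, MEASURED))
    assert see == pytest.approx(0.0, abs=1e-12)
    assert r2 == pytest.approx(1.0, abs=1e-12)


def test_affine_relation_also_perfect():
    """Agreement is not identity: measured = 2 x estimated fits perfectly."""
    see, r2 = see_and_r2(sample(2 * MEASURED, MEASURED))
    assert see == pytest.approx(0.0, abs=1e-10)
    assert r2 == pytest.approx(1.0, abs=1e-12)


def test_see_r2_against_normal_equations_oracle():
    m = [2.0, 2.5, 3.0, 3.5, 4.0, 5.0]
    e = [2.2, 2.3, 3.2, 3.3, 4.4, 4.6]
    _, _, resid = oracle_ols(e, m)
    see_expected = math.sqrt(sum(r * r for r in resid) / (len(m) - 2))
    r = oracle_pearson(e, m)
    r2_adj_expected = 1 - (1 - r * r) * (len(m) - 1) / (len(m) - 2)
    see, r2 = see_and_r2(sample(m, e))
    assert see == pytest.approx(see_expected, abs=1e-12)
    assert r2 == pytest.approx(r2_adj_expected, abs=1e-12)


def test_see_r2_against_statsmodels():
    import statsmodels.api as sm
    rng = np.random.default_rng(11)
    s = random_sample(rng, 20)
    fit = sm.OLS(s.measured, sm.add_constant(s.estimated)).fit()
    see, r2 = see_and_r2(s)
    assert see == pytest.approx(np.sqrt(fit.mse_resid), abs=1e-10)
    assert r2 == pytest.approx(fit.rsquared_adj, abs=1e-10)


def test_constant_estimates_degenerate():
    with pytest.raises(DegenerateRegressionError):
        see_and_r2(sample(MEASURED, [3.0, 3.0, 3.0]))


# --------------------------------------------------------------------------
# Bland-Altman
# --------------------------------------------------------------------------

def test_bland_altman_identical_vectors():
    ba = bland_altman(sample(MEASURED, MEASURED))
    assert (ba.mean_diff, ba.loa_lower, ba.loa_upper) == (0.0, 0.0, 0.0)


def test_bland_altman_hand_value():
    # diffs (est-meas) = 0.2, -0.1, 0.3: mean 0.13333, SD 0.20817
    ba = bland_altman(sample())
    assert ba.mean_diff == pytest.approx(0.4 / 3, abs=1e-12)
    assert ba.loa_lower == pytest.approx(0.4 / 3 - 1.96 * 0.2081666, abs=1e-6)
    assert ba.loa_upper == pytest.approx(0.4 / 3 + 1.96 * 0.2081666, abs=1e-6)
    assert np.allclose(ba.pair_means, (MEASURED + ESTIMATED) / 2)


@given(st.integers(0, 1000))
def test_loa_width_is_392_sd(seed):
    rng = np.random.default_rng(seed)
    s = random_sample(rng, rng.integers(3, 12))
    ba = bland_altman(s)
    sd = oracle_sd(differences(s).tolist())
    assert ba.loa_upper - ba.loa_lower == pytest.approx(2 * 1.96 * sd, abs=1e-10)
    assert ba.loa_lower <= ba.mean_diff <= ba.loa_upper


# --------------------------------------------------------------------------
# paired t-test
# --------------------------------------------------------------------------

def test_paired_t_identical_vectors():
    t = paired_t(sample(MEASURED, MEASURED))
    assert t.mean_diff == 0.0
    assert t.p_value == 1.0


def test_paired_t_hand_statistic():
    m = [3.0, 3.2, 2.8, 3.5, 3.1]
    e = [3.3, 3.1, 3.0, 3.9, 3.2]
    d = [ei - mi for mi, ei in zip(m, e)]
    mean = sum(d) / 5
    se = oracle_sd(d) / math.sqrt(5)
    from scipy.stats import t as tdist
    p_expected = 2 * tdist.sf(abs(mean / se), 4)
    res = paired_t(sample(m, e))
    assert res.mean_diff == pytest.approx(mean, abs=1e-12)
    assert res.p_value == pytest.approx(p_expected, abs=1e-12)
    assert res.ci_lower < mean < res.ci_upper


@given(st.integers(0, 500))
def test_ci_excludes_zero_iff_p_below_alpha(seed):
    rng = np.random.default_rng(seed)
    s = random_sample(rng, int(rng.integers(3, 15)))
    res = paired_t(s)
    excludes = res.ci_lower > 0 or res.ci_upper < 0
    assert excludes == (res.p_value < 0.05)


def test_zero_variance_nonzero_mean_reports_degenerate_p():
    res = paired_t(sample(MEASURED, MEASURED + 0.2))
    assert res.p_value == 0.0
    assert "degenerate" in res.note


def test_bland_altman_and_t_mean_diff_agree(rng):
    s = random_sample(rng, 15)
    assert bland_altman(s).mean_diff == pytest.approx(
        paired_t(s).mean_diff, abs=1e-12)


# --------------------------------------------------------------------------
# error vs level (Spearman)
# --------------------------------------------------------------------------

def test_monotone_error_gives_rho_one():
    m = np.array([2.0, 2.5, 3.0, 3.5, 4.0])
    e = m + np.array([0.0, 0.1, 0.2, 0.3, 0.4])   # error increases with level
    rho, p, note = error_vs_level(sample(m, e))
    assert rho == pytest.approx(1.0)
    assert note == ""


def test_constant_error_degenerate():
    rho, p, note = error_vs_level(sample(MEASURED, MEASURED + 0.25))
    assert rho == 0.0
    assert "undefined" in note


def test_spearman_against_rank_oracle():
    m = [2.0, 2.5, 2.5, 3.6, 4.0, 3.1]
    e = [2.4, 2.4, 2.8, 3.5, 4.5, 3.1]
    s = sample(m, e)
    d = differences(s).tolist()
    expected = oracle_pearson(oracle_ranks(d), oracle_ranks(list(m)))
    rho, _, _ = error_vs_level(s)
    assert rho == pytest.approx(expected, abs=1e-12)


# --------------------------------------------------------------------------
# stratified reporting and quartiles
# --------------------------------------------------------------------------

def test_quartile_assignment_boundary_policy():
    scheme = QuartileScheme()
    # exact cut-point goes to the higher quartile
    assert scheme.assign(Sex.FEMALE, 2.60) == 3
    assert scheme.assign(Sex.FEMALE, 2.59) == 3
    assert scheme.assign(Sex.FEMALE, 2.58) == 2
    assert scheme.assign(Sex.FEMALE, 1.90) == 1
    assert scheme.assign(Sex.MALE, 4.50) == 4
    assert scheme.assign(Sex.MALE, 37.4, relative=True) == 1
    assert scheme.assign(Sex.MALE, 37.6, relative=True) == 2


def test_quartile_cutpoints_must_increase():
    with pytest.raises(ValueError):
        QuartileScheme(absolute={Sex.FEMALE: (2.6, 2.1, 2.9),
                                 Sex.MALE: (3.07, 3.75, 4.33)})


def test_age_band_labels():
    assert age_band_label(34.9) == "<35"
    assert age_band_label(35.0) == "35-49"
    assert age_band_label(49.9) == "35-49"
    assert age_band_label(50.0) == "50-64"
    assert age_band_label(65.0) == ">=65"


def test_stratified_single_stratum_equals_overall(rng):
    n = 12
    m = rng.uniform(3.2, 3.9, n)   # all male Q2/Q3-ish, one age band
    e = m * np.exp(rng.normal(0, 0.05, n))
    s = sample(m, e, sex=[Sex.MALE] * n, age=np.full(n, 40.0))
    res = {r.label: r for r in stratified_report(s)}
    overall, men = res["all"].report, res["men"].report
    assert overall.cv_percent == pytest.approx(men.cv_percent, abs=1e-12)
    assert overall.mean_diff == pytest.approx(men.mean_diff, abs=1e-12)
    assert res["women"].n == 0 and res["women"].report is None


def test_quartile_partition_exhaustive_and_disjoint(rng):
    n = 40
    m = rng.uniform(1.5, 5.5, n)
    e = m * np.exp(rng.normal(0, 0.08, n))
    sexes = [Sex.MALE if i % 2 else Sex.FEMALE for i in range(n)]
    mass = rng.uniform(55, 95, n)
    s = sample(m, e, sex=sexes, age=rng.uniform(20, 86, n), body_mass=mass)
    res = stratified_report(s)
    abs_q = [r for r in res if r.label.startswith("absolute Q")]
    rel_q = [r for r in res if r.label.startswith("relative Q")]
    age_bands = [r for r in res if r.label.startswith("age ")]
    assert sum(r.n for r in abs_q) == n
    assert sum(r.n for r in rel_q) == n
    assert sum(r.n for r in age_bands) == n


def test_agreement_report_is_complete(rng):
    s = random_sample(rng, 25)
    rep = agreement_report(s)
    assert rep.n == 25
    assert rep.loa_lower <= rep.mean_diff <= rep.loa_upper
    assert rep.cv_percent >= 0 and rep.see >= 0
    assert -1 <= rep.spearman_rho <= 1
    assert rep.ci_lower <= rep.mean_diff <= rep.ci_upper
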