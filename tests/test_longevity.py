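"""L50 intervals, the age regression, extrapolation and validation statistics."""

import numpy as np
import pytest
from scipy import stats

import seedlong as sl
from seedlong.reference import (
    AGE_L50_POINTS,
    GERMINATION_REPLICATES,
    QUADRATIC_COEFFICIENTS,
    WEIBULL4_COEFFICIENTS,
)


# ---------------------------------------------------------------------------
# quadratic age regression against the published fit


@pytest.fixture(scope="module")
def reference_regression():
    return sl.l50_age_regression(AGE_L50_POINTS, form="quadratic")


def test_quadratic_reproduces_published_coefficients(reference_regression):
    reg = reference_regression
    assert reg.coef_[0] == pytest.approx(2.403749, abs=1e-5)
    assert reg.coef_[1] == pytest.approx(-0.403234, abs=1e-5)
    assert reg.coef_[2] == pytest.approx(0.016114, abs=1e-5)
    assert reg.stderr_[0] == pytest.approx(0.112197, abs=1e-5)
    assert reg.rss_ == pytest.approx(0.096720, abs=1e-5)
    assert reg.r_squared_ == pytest.approx(0.98036, abs=1e-5)


def test_quadratic_information_criteria(reference_regression):
    assert reference_regression.aic_ == pytest.approx(-23.97, abs=0.01)
    assert reference_regression.bic_ == pytest.approx(-24.14, abs=0.01)


def test_exact_quadratic_is_interpolated():
    x = np.array([0.0, 1.0, 2.0, 5.0, 9.0])
    y = 2.0 - 0.4 * x + 0.016 * x**2
    reg = sl.L50AgeRegression().fit(x, y)
    assert np.allclose(reg.coef_, [2.0, -0.4, 0.016], atol=1e-10)
    assert reg.rss_ < 1e-20


def test_too_few_points_rejected():
    with pytest.raises(sl.DataError, match=">= 4"):
        sl.l50_age_regression([(0, 2.0), (1, 1.5), (2, 1.0)])
    with pytest.raises(sl.DataError, match=">= 5"):
        sl.l50_age_regression([(0, 2.0), (1, 1.5), (2, 1.0), (3, 0.5)], form="weibull4")


def test_quadratic_matches_normal_equations_oracle():
    rng = np.random.default_rng(0)
    for _ in range(10):
        x = rng.uniform(0, 15, size=9)
        y = rng.uniform(0, 3, size=9)
        reg = sl.L50AgeRegression().fit(x, y)
        V = np.vander(x, 3, increasing=True)
        oracle = np.linalg.solve(V.T @ V, V.T @ y)
        assert np.allclose(reg.coef_, oracle, atol=1e-10)


def test_regression_invariant_to_point_order():
    rng = np.random.default_rng(3)
    pts = list(AGE_L50_POINTS)
    reg1 = sl.l50_age_regression(pts)
    rng.shuffle(pts)
    reg2 = sl.l50_age_regression(pts)
    assert np.allclose(reg1.coef_, reg2.coef_, atol=1e-12)


# ---------------------------------------------------------------------------
# fixed-curve evaluation


def test_published_weibull_form_curve_metrics():
    w4 = sl.L50AgeRegression.from_coefficients("weibull4", WEIBULL4_COEFFICIENTS)
    rss, r2, aic, bic = sl.evaluate_regression(w4, AGE_L50_POINTS)
    assert rss == pytest.approx(0.31, abs=0.005)
    assert r2 == pytest.approx(0.94, abs=0.005)
    assert aic == pytest.approx(-13.81, abs=0.01)
    assert bic == pytest.approx(-14.02, abs=0.01)


def test_published_quadratic_curve_metrics():
    q = sl.L50AgeRegression.from_coefficients("quadratic", QUADRATIC_COEFFICIENTS)
    rss, *_ = sl.evaluate_regression(q, AGE_L50_POINTS)
    assert rss == pytest.approx(0.0967, abs=1e-4)


def test_fixed_curve_on_its_own_samples_has_zero_rss():
    q = sl.L50AgeRegression.from_coefficients("quadratic", (2.0, -0.3, 0.01))
    x = np.arange(6.0)
    rss, *_ = q.score_points(x, q.predict(x))
    assert rss == 0.0


def test_fitted_weibull4_not_worse_than_published_curve():
    reg = sl.l50_age_regression(AGE_L50_POINTS, form="weibull4")
    assert reg.rss_ <= 0.3106 + 1e-6
    quad = sl.l50_age_regression(AGE_L50_POINTS, form="quadratic")
    assert quad.aic_ < reg.aic_  # goodness-of-fit favours the polynomial


# ---------------------------------------------------------------------------
# roots and inversion


def test_longevity_bound_reproduces_published_roots(reference_regression):
    bound = sl.longevity_bound(reference_regression)
    assert bound.crossing
    assert bound.root_small == pytest.approx(9.79, abs=0.02)
    assert bound.root_large == pytest.approx(15.23, abs=0.02)
    assert bound.bound == bound.root_small


def test_roots_are_zeros_of_the_polynomial(reference_regression):
    bound = sl.longevity_bound(reference_regression)
    for r in (bound.root_small, bound.root_large):
        assert reference_regression.predict([r])[0] == pytest.approx(0.0, abs=1e-8)


def test_linear_degenerate_quadratic_single_root():
    reg = sl.L50AgeRegression.from_coefficients("quadratic", (1.0, -1.0, 0.0))
    bound = reg.longevity_bound()
    assert bound.root_small == pytest.approx(1.0) and bound.root_large is None


def test_no_crossing_reported():
    reg = sl.L50AgeRegression.from_coefficients("quadratic", (1.0, 0.0, 1.0))
    bound = reg.longevity_bound()
    assert not bound.crossing and bound.bound is None


def test_all_zero_quadratic_rejected():
    reg = sl.L50AgeRegression.from_coefficients("quadratic", (0.0, 0.0, 0.0))
    with pytest.raises(sl.DataError):
        reg.longevity_bound()


def test_equivalent_age_of_farmland_l50(reference_regression):
    # bisection oracle for the quadratic inversion at L50 = 1.59 d
    f = lambda x: reference_regression.predict([x])[0] - 1.59
    lo, hi = 0.0, 9.0
    for _ in range(80):
        mid = (lo + hi) / 2
        lo, hi = (mid, hi) if f(mid) > 0 else (lo, mid)
    age = sl.equivalent_age(reference_regression, 1.59)
    assert age == pytest.approx((lo + hi) / 2, abs=1e-8)
    assert age == pytest.approx(2.21, abs=0.01)


def test_equivalent_age_round_trips(reference_regression):
    reg = reference_regression
    assert reg.equivalent_age(float(reg.coef_[0])) == pytest.approx(0.0, abs=1e-9)
    target = reg.predict([3.0])[0]
    age = reg.equivalent_age(float(target))
    assert age == pytest.approx(3.0, abs=1e-8)
    assert reg.predict([age])[0] == pytest.approx(target, abs=1e-8)


def test_equivalent_age_rejects_fresher_than_reference(reference_regression):
    with pytest.raises(sl.DataError, match="fresher"):
        sl.equivalent_age(reference_regression, 99.0)


# ---------------------------------------------------------------------------
# L50 bootstrap interval


def test_noise_free_assay_gives_degenerate_interval(gy_noise_free_assay):
    # case resampling of identical replicates is exactly degenerate
    est = sl.l50_with_ci(gy_noise_free_assay, b_boot=50, rng_seed=0, method="case")
    assert est.l50 == pytest.approx(1.5449, abs=0.02)
    assert est.ci_high - est.ci_low < 1e-6
    # the parametric interval keeps binomial width but stays tight at n=1000
    est_p = sl.l50_with_ci(gy_noise_free_assay, b_boot=50, rng_seed=0)
    assert est_p.ci_low <= est_p.l50 <= est_p.ci_high
    assert est_p.ci_high - est_p.ci_low < 0.06


def test_l50_with_ci_is_deterministic(assay_factory):
    assay = assay_factory(rng_seed=9)
    a = sl.l50_with_ci(assay, b_boot=100, rng_seed=4)
    b = sl.l50_with_ci(assay, b_boot=100, rng_seed=4)
    assert a.to_dict() == b.to_dict()
    assert a.ci_low <= a.l50 <= a.ci_high


def test_single_replicate_interval_unavailable():
    params = sl.DecayParams("weibull3", (2.0, 4.0, -0.3))
    cfg = sl.SimulationConfig(params=params, replicates=1, rng_seed=0)
    assay = sl.simulate_assay(cfg)
    est = sl.l50_with_ci(assay, b_boot=50)
    assert est.ci_low is None and "interval unavailable" in est.warning
    assert est.l50 > 0


# ---------------------------------------------------------------------------
# ANOVA


def test_anova_identical_groups_f_zero():
    res = sl.anova_oneway([[1, 2, 3], [1, 2, 3]])
    assert res["F"] == 0.0 and res["p"] == 1.0


def test_anova_two_groups_equals_squared_t():
    rng = np.random.default_rng(5)
    for _ in range(10):
        a, b = rng.normal(size=6), rng.normal(loc=0.5, size=5)
        res = sl.anova_oneway([a, b])
        t, p = stats.ttest_ind(a, b)
        assert res["F"] == pytest.approx(t**2, rel=1e-10)
        assert res["p"] == pytest.approx(p, rel=1e-10)


def test_anova_matches_direct_sums_of_squares_and_scipy():
    rng = np.random.default_rng(11)
    groups = [rng.normal(loc=m, size=3) for m in range(6)]
    res = sl.anova_oneway(groups)
    F, p = stats.f_oneway(*groups)
    assert res["F"] == pytest.approx(F, rel=1e-10)
    assert res["p"] == pytest.approx(p, rel=1e-10)
    assert res["ss_between"] + res["ss_within"] == pytest.approx(
        res["ss_total"], rel=1e-10
    )
    assert res["df_between"] == 5 and res["df_within"] == 12


def test_anova_undefined_when_all_values_equal():
    res = sl.anova_oneway([[2.0, 2.0], [2.0, 2.0]])
    assert res["undefined"]


def test_anova_input_validation():
    with pytest.raises(sl.DataError):
        sl.anova_oneway([[1.0, 2.0]])
    with pytest.raises(sl.DataError):
        sl.anova_oneway([[1.0], [2.0, 3.0]])


# ---------------------------------------------------------------------------
# germination summaries


def test_germination_means_match_published_table():
    trials = {t.cohort: t for t in sl.germination_summary(GERMINATION_REPLICATES)}
    assert trials["2008"].mean == pytest.approx(0.00, abs=0.005)
    assert trials["2015"].mean == pytest.approx(10.56, abs=0.005)
    assert trials["2023"].mean == pytest.approx(86.67, abs=0.005)
    assert trials["2008"].sd == 0.0


def test_germination_letters_separate_viable_cohort():
    trials = {t.cohort: t for t in sl.germination_summary(GERMINATION_REPLICATES)}
    # the fresh lot differs from both old lots
    assert set(trials["2023"].letter).isdisjoint(trials["2008"].letter)
    assert set(trials["2023"].letter).isdisjoint(trials["2015"].letter)


def test_germination_summary_validation():
    with pytest.raises(sl.DataError):
        sl.germination_summary({"x": [50.0]})
    with pytest.raises(sl.DataError):
        sl.germination_summary({"x": [50.0, 120.0]})
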