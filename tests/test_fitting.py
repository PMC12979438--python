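"""Decay-curve fitting, information criteria and model competition."""

import math

import numpy as np
import pytest

import seedlong as sl
from seedlong.fitting import FitOptions


# ---------------------------------------------------------------------------
# information criteria


def test_information_criteria_quadratic_regression_anchor():
    # RSS/n/p of the published quadratic age regression
    aic, bic = sl.information_criteria(0.096720, 7, 3)
    assert aic == pytest.approx(-23.97, abs=0.01)
    assert bic == pytest.approx(-24.14, abs=0.01)


def test_information_criteria_weibull_form_anchor():
    # RSS of the published 4-parameter Weibull-form age regression
    aic, _ = sl.information_criteria(0.3106016, 7, 4)
    assert aic == pytest.approx(-13.81, abs=0.01)


def test_information_criteria_trivial_zero():
    aic, bic = sl.information_criteria(12.0, 12, 0)
    assert aic == 0.0 and bic == 0.0


def test_information_criteria_rejects_perfect_fit():
    with pytest.raises(sl.PerfectFitError):
        sl.information_criteria(0.0, 10, 3)


def test_information_criteria_input_validation():
    with pytest.raises(sl.DataError):
        sl.information_criteria(1.0, 3, 3)


def test_bic_minus_aic_identity():
    rng = np.random.default_rng(1)
    for _ in range(20):
        rss = float(rng.uniform(0.01, 5.0))
        n = int(rng.integers(5, 40))
        p = int(rng.integers(0, n - 1))
        aic, bic = sl.information_criteria(rss, n, p)
        assert bic - aic == pytest.approx(p * (math.log(n) - 2.0), abs=1e-12)
        if p + 1 < n:
            aic2, _ = sl.information_criteria(rss, n, p + 1)
            assert aic2 > aic


# ---------------------------------------------------------------------------
# fitting


def test_noise_free_reference_curve_recovers_l50(gy_noise_free_assay):
    fit = sl.fit_decay(gy_noise_free_assay)
    l50, ok = fit.l50()
    assert ok
    assert l50 == pytest.approx(1.5449, abs=0.02)
    # the parameter triple itself may wander along the ridge; the curve may not
    assert fit.rss < 1e-6


def test_binomial_assay_recovers_l50(assay_factory):
    assay = assay_factory(params=(2.0, 4.0, -0.3), rng_seed=42)
    fit = sl.fit_decay(assay)
    l50, ok = fit.l50()
    true_l50, _ = sl.l50_closed_form((2.0, 4.0, -0.3), "weibull3")
    assert ok and abs(l50 - true_l50) < 0.15


def test_fit_reports_ic_consistent_with_rss(assay_factory):
    fit = sl.fit_decay(assay_factory())
    aic, bic = sl.information_criteria(fit.rss, fit.n_obs, fit.n_params)
    assert fit.aic == pytest.approx(aic, abs=1e-12)
    assert fit.bic == pytest.approx(bic, abs=1e-12)


def test_all_zero_assay_refused():
    obs = [
        sl.ViabilityObservation(time=t, replicate=r, n_tested=50, n_viable=0)
        for t in (0.0, 1.0, 2.0)
        for r in (1, 2, 3)
    ]
    assay = sl.ViabilityAssay(lot_id="dead", observations=obs)
    with pytest.raises(sl.DegenerateAssayError, match="degenerate"):
        sl.fit_decay(assay)


def test_too_few_timepoints_refused():
    obs = [
        sl.ViabilityObservation(time=t, replicate=r, n_tested=50, n_viable=v)
        for (t, v) in ((0.0, 50), (1.0, 10))
        for r in (1, 2, 3)
    ]
    assay = sl.ViabilityAssay(lot_id="short", observations=obs)
    with pytest.raises(sl.DegenerateAssayError, match="distinct times"):
        sl.fit_decay(assay)


def test_refit_on_own_predictions_is_idempotent(assay_factory):
    fit = sl.fit_decay(assay_factory(rng_seed=7))
    t = np.repeat([0.0, 1.0, 2.0, 3.0, 4.0], 3)
    est = sl.DecayCurveFitter().fit(t, fit.predicted(t))
    l50, _ = fit.l50()
    assert est.l50_ == pytest.approx(l50, abs=1e-3)


def test_nested_weibull_rss_dominance(assay_factory):
    for seed in range(5):
        assay = assay_factory(params=(1.8, 3.0, -0.5), rng_seed=100 + seed)
        f3 = sl.fit_decay(assay, "weibull3")
        f2 = sl.fit_decay(assay, "weibull2")
        assert f3.rss <= f2.rss + 1e-12


def test_ill_conditioning_flagged_on_ridge_fit(gy_noise_free_assay):
    # the printed-style degenerate triple (huge lambda/k, offsetting c)
    fit = sl.fit_decay(gy_noise_free_assay)
    assert fit.condition_flag


# ---------------------------------------------------------------------------
# sklearn estimator surface


def test_estimator_sklearn_contract(assay_factory):
    from sklearn.base import clone

    est = sl.DecayCurveFitter(family="weibull3", random_state=3)
    params = est.get_params()
    assert params["family"] == "weibull3"
    est2 = clone(est)
    assay = assay_factory()
    est2.fit(assay.times.reshape(-1, 1), assay.viabilities)
    pred = est2.predict([[0.0], [2.0]])
    assert pred.shape == (2,)
    assert 0.0 <= pred[1] <= pred[0] <= 1.0
    assert est2.rss_ >= 0 and est2.converged_


def test_estimator_validates_inputs():
    est = sl.DecayCurveFitter()
    with pytest.raises(sl.DataError):
        est.fit([0.0, 1.0, 2.0], [0.5, 0.4])
    with pytest.raises(sl.DataError):
        est.fit([0.0, 1.0, 2.0], [1.5, 0.4, 0.2])


# ---------------------------------------------------------------------------
# model competition


def test_compare_models_needs_two_families(assay_factory):
    with pytest.raises(sl.DataError, match=">= 2"):
        sl.compare_models(assay_factory(), families=("weibull3",))


def test_compare_models_ranks_and_deltas(assay_factory):
    assay = assay_factory(params=(2.0, 4.0, -0.5), rng_seed=11)
    table = sl.compare_models(assay)
    assert list(table["aic"]) == sorted(table["aic"])
    assert table.loc[0, "delta_aic"] == 0.0
    # nesting: the 3-parameter Weibull can always match the 2-parameter one
    rss = dict(zip(table["family"], table["rss"]))
    assert rss["weibull3"] <= rss["weibull2"] + 1e-12
    assert (table["error"] == "").all()


def _grid_search_rss(assay, family, grids):
    """Brute-force RSS oracle over a parameter grid."""
    best = np.inf
    t, v = assay.times, assay.viabilities
    for theta in __import__("itertools").product(*grids):
        try:
            pred = sl.viability(t, theta, family)
        except sl.ParameterDomainError:
            continue
        best = min(best, float(np.sum((pred - v) ** 2)))
    return best


def test_compare_models_beats_grid_search_oracle(assay_factory):
    """Each family's fitted RSS is at least as good as a coarse exhaustive grid."""
    assay = assay_factory(params=(2.0, 5.0, -0.4), rng_seed=5)
    table = sl.compare_models(assay)
    rss = dict(zip(table["family"], table["rss"]))
    assert all(np.isfinite(table["aic"])) and all(np.isfinite(table["bic"]))
    lam_grid = np.geomspace(0.2, 50, 12)
    k_grid = np.geomspace(0.5, 200, 12)
    c_grid = np.linspace(-5, 0, 8)
    a_grid = np.linspace(0.3, 1.0, 6)
    m_grid = np.linspace(0.0, 4.0, 8)
    r_grid = np.geomspace(0.2, 20, 8)
    b_grid = np.geomspace(1e-3, 5, 8)
    g_grid = np.geomspace(0.2, 10, 8)
    oracles = {
        "weibull3": _grid_search_rss(assay, "weibull3", (lam_grid, k_grid, c_grid)),
        "weibull2": _grid_search_rss(assay, "weibull2", (lam_grid, k_grid)),
        "logistic": _grid_search_rss(assay, "logistic", (a_grid, m_grid, r_grid)),
        "gompertz": _grid_search_rss(assay, "gompertz", (a_grid, b_grid, g_grid)),
    }
    for family, oracle in oracles.items():
        assert rss[family] <= oracle + 1e-9, family


def test_sensitivity_options_give_consistent_l50(assay_factory):
    """Mean-level and weighted fits agree with the default on clean data."""
    assay = assay_factory(rng_seed=21)
    base = sl.fit_decay(assay).l50()[0]
    means = sl.fit_decay(assay, options=FitOptions(on_means=True))
    weighted = sl.fit_decay(assay, options=FitOptions(weighted=True))
    assert means.n_obs == 5  # one residual per timepoint
    assert means.l50()[0] == pytest.approx(base, abs=0.1)
    assert weighted.l50()[0] == pytest.approx(base, abs=0.1)
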