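import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import binom

import prevmap as pm
from prevmap.selection import (ClusterDesign, correlation_filter,
                               empirical_variogram, fit_nonspatial_glm,
                               select_covariates, univariate_screen)


def _design(n_sam, n_exam, X, names=None, coords=None):
    n = len(n_sam)
    X = np.asarray(X, dtype=float)
    names = names or [f"x{j}" for j in range(X.shape[1])]
    coords = coords if coords is not None else \
        np.column_stack([np.arange(n, dtype=float), np.zeros(n)])
    return ClusterDesign([f"c{i}" for i in range(n)], coords,
                         np.asarray(n_sam), np.asarray(n_exam), X, names)


def test_design_validation():
    with pytest.raises(ValueError, match="counts"):
        _design([5], [4], [[0.0]])
    with pytest.raises(ValueError, match="at least one child"):
        _design([0], [0], [[0.0]])


def test_intercept_only_aic_matches_hand_computed_likelihood():
    # clusters (2 of 10), (5 of 10), (8 of 10); pooled p = 0.5
    d = _design([2, 5, 8], [10, 10, 10], np.zeros((3, 1)))
    report = univariate_screen(d)
    ll = sum(binom.logpmf(y, 10, 0.5) for y in (2, 5, 8))
    assert report.intercept_aic == pytest.approx(-2 * ll + 2, abs=1e-6)


def test_screen_retains_strong_effect_and_drops_noise():
    rng = np.random.default_rng(42)
    n = 200
    x = rng.standard_normal(n)
    noise = rng.standard_normal(n)
    p = expit(-2.0 + 2.0 * x)
    y = rng.binomial(20, p)
    d = _design(y, np.full(n, 20), np.column_stack([x, noise]), ["signal", "noise"])
    report = univariate_screen(d)
    uni = report.univariate.set_index("name")
    assert bool(uni.loc["signal", "screened_in"])
    assert uni.loc["signal", "coefficient"] == pytest.approx(2.0, abs=0.4)
    assert not bool(uni.loc["noise", "screened_in"])


def test_zero_variance_covariate_flagged():
    d = _design([1, 2, 3, 4], [10, 10, 10, 10], np.zeros((4, 1)), ["flat"])
    report = univariate_screen(d)
    row = report.univariate.iloc[0]
    assert not row.screened_in and row.reason == "zero variance"


def test_duplicated_covariate_keeps_one_copy():
    rng = np.random.default_rng(0)
    x = rng.standard_normal(30)
    y = rng.binomial(12, expit(-2 + x))
    d = _design(y, np.full(30, 12), np.column_stack([x, x]), ["a", "b"])
    report = univariate_screen(d)
    report = correlation_filter(d, report, candidates=["a", "b"])
    assert len(report.retained) == 1


def test_independent_covariates_both_survive():
    rng = np.random.default_rng(1)
    X = rng.standard_normal((60, 2))
    y = rng.binomial(12, expit(-2 + X[:, 0] + X[:, 1]))
    d = _design(y, np.full(60, 12), X, ["a", "b"])
    report = univariate_screen(d)
    report = correlation_filter(d, report, candidates=["a", "b"])
    assert sorted(report.retained) == ["a", "b"]


def _correlated_triple(seed=3):
    """Three mutually correlated covariates with distinct predictive power."""
    rng = np.random.default_rng(seed)
    n = 150
    base = rng.standard_normal(n)
    X = np.column_stack([
        base,
        base + 0.3 * rng.standard_normal(n),
        base + 0.35 * rng.standard_normal(n),
    ])
    y = rng.binomial(15, expit(-2.0 + 1.2 * base))
    return _design(y, np.full(n, 15), X, ["exact", "noisy1", "noisy2"])


def test_triple_correlated_filter_matches_hand_enumeration():
    d = _correlated_triple()
    corr = np.corrcoef(d.X, rowvar=False)
    assert np.abs(corr[np.triu_indices(3, 1)]).min() > 0.8
    report = univariate_screen(d)
    report = correlation_filter(d, report, candidates=list(d.names))
    # hand enumeration: all pairs exceed the threshold, so the single
    # lowest-AIC covariate must be the sole survivor
    uni = report.univariate.set_index("name")
    best = uni.aic.idxmin()
    assert report.retained == [best]


def test_filter_invariant_to_column_order_and_idempotent():
    d = _correlated_triple()
    ref = correlation_filter(d, univariate_screen(d), candidates=list(d.names))
    perm = [2, 0, 1]
    d2 = ClusterDesign(d.cluster_ids, d.coords, d.n_sam, d.n_examined,
                       d.X[:, perm], [d.names[j] for j in perm])
    out2 = correlation_filter(d2, univariate_screen(d2), candidates=list(d2.names))
    assert ref.retained == out2.retained
    # re-running the filter on its own output is a no-op
    d3 = d.subset_covariates(ref.retained)
    out3 = correlation_filter(d3, univariate_screen(d3), candidates=ref.retained)
    assert out3.retained == ref.retained


def test_retained_set_respects_threshold(toy_data):
    stack = pm.generate_covariate_surfaces(toy_data["stack"].grid, 5, seed=8)
    design = pm.build_design(toy_data["survey"], stack)
    report = select_covariates(design)
    if len(report.retained) >= 2:
        sub = design.subset_covariates(report.retained)
        corr = np.corrcoef(sub.X, rowvar=False)
        assert np.abs(corr[np.triu_indices_from(corr, 1)]).max() <= 0.8


def test_saturated_single_cluster_fit():
    d = _design([3], [10], np.zeros((1, 0)), [])
    _, resid, fitted = fit_nonspatial_glm(d, [])
    assert fitted[0] == pytest.approx(0.3, abs=1e-8)


def test_null_model_pools_proportions():
    d = _design([1, 3], [10, 10], np.zeros((2, 0)), [])
    _, _, fitted = fit_nonspatial_glm(d, [])
    np.testing.assert_allclose(fitted, 0.2, atol=1e-9)


def test_glm_matches_independent_optimizer():
    rng = np.random.default_rng(5)
    X = rng.standard_normal((10, 2))
    y = rng.binomial(25, expit(-1.0 + X[:, 0] - 0.5 * X[:, 1]))
    d = _design(y, np.full(10, 25), X, ["a", "b"])
    res, _, _ = fit_nonspatial_glm(d)

    def negll(beta):
        eta = beta[0] + X @ beta[1:]
        return -np.sum(y * eta - 25 * np.logaddexp(0, eta))

    opt = minimize(negll, np.zeros(3), method="BFGS", tol=1e-12)
    np.testing.assert_allclose(np.asarray(res.params), opt.x, atol=1e-5)


def test_deviance_decreases_when_covariate_added():
    d = _correlated_triple()
    res0, _, _ = fit_nonspatial_glm(d, ["exact"])
    res1, _, _ = fit_nonspatial_glm(d, ["exact", "noisy1"])
    assert res1.deviance <= res0.deviance + 1e-8


def test_variogram_identical_residuals_zero():
    coords = np.random.default_rng(0).uniform(0, 10, (20, 2))
    v = empirical_variogram(np.full(20, 1.7), coords, n_bins=5, max_dist=10.0)
    nonempty = v[v["count"] > 0]
    np.testing.assert_allclose(nonempty.semivariance, 0.0, atol=1e-12)


def test_variogram_iid_noise_flat_at_variance():
    rng = np.random.default_rng(7)
    coords = rng.uniform(0, 50, (400, 2))
    z = rng.normal(0, 2.0, 400)
    v = empirical_variogram(z, coords, n_bins=6, max_dist=40.0)
    good = v[v["count"] > 500]
    np.testing.assert_allclose(good.semivariance, 4.0, rtol=0.15)


def test_variogram_three_point_hand_computation():
    coords = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 2.0]])
    z = np.array([1.0, 2.0, 4.0])
    v = empirical_variogram(z, coords, n_bins=3, max_dist=3.0)
    # pairs: d=1 -> 0.5*(1)^2; d=2 -> 0.5*(3)^2; d=sqrt(5) -> 0.5*(2)^2
    assert np.isnan(v.semivariance[0])          # empty [0,1) bin: missing, not 0
    assert v.semivariance[1] == pytest.approx(0.5)
    assert v.semivariance[2] == pytest.approx((4.5 + 2.0) / 2)
    assert v["count"].tolist() == [0, 1, 2]
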