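import numpy as np
import pytest
from scipy.special import expit, logit
from scipy.stats import binom, beta as beta_dist

import prevmap as pm
from prevmap.kernels import matern_correlation
from prevmap.model import FittedModel, ModelSpec, _simple_ess
from prevmap.selection import ClusterDesign


def _design(n_sam, n_exam, X, coords, names=None):
    n = len(n_sam)
    X = np.asarray(X, dtype=float)
    names = names or [f"x{j}" for j in range(X.shape[1])]
    return ClusterDesign([f"c{i}" for i in range(n)], np.asarray(coords, float),
                         np.asarray(n_sam), np.asarray(n_exam), X, names)


# ---------------------------------------------------------------- likelihood

def test_log_likelihood_closed_forms():
    d = _design([0], [10], np.zeros((1, 0)), [[0.0, 0.0]], [])
    # eta = 0 -> 10 log(1/2)
    assert pm.log_likelihood(d, np.zeros(1), np.zeros(1)) == \
        pytest.approx(10 * np.log(0.5), abs=1e-10)
    # eta -> -inf with y = 0 -> log C(10,0) = 0
    assert pm.log_likelihood(d, np.array([-40.0]), np.zeros(1)) == \
        pytest.approx(0.0, abs=1e-10)


def test_log_likelihood_matches_binomial_pmf():
    coords = [[0, 0], [1, 0], [0, 1]]
    d = _design([2, 5, 9], [10, 12, 15], [[0.3], [-1.0], [0.7]], coords)
    beta = np.array([-0.5, 1.2])
    field = np.array([0.1, -0.2, 0.4])
    eta = beta[0] + d.X[:, 0] * beta[1] + field
    expected = sum(binom.logpmf(y, n, expit(e))
                   for y, n, e in zip(d.n_sam, d.n_examined, eta))
    assert pm.log_likelihood(d, beta, field) == pytest.approx(expected, abs=1e-9)


def test_log_likelihood_validates_inputs():
    d = _design([2], [10], np.zeros((1, 0)), [[0, 0]], [])
    with pytest.raises(ValueError, match="dimension"):
        pm.log_likelihood(d, np.zeros(2), np.zeros(1))


# ------------------------------------------------------------------- fitting

def test_fit_is_deterministic_given_seed(toy_data):
    spec = pm.ModelSpec(n_posterior_samples=50, n_warmup=50, seed=3)
    a = pm.fit(toy_data["design"], spec)
    b = pm.fit(toy_data["design"], spec)
    np.testing.assert_array_equal(a.beta, b.beta)
    np.testing.assert_array_equal(a.sigma, b.sigma)
    np.testing.assert_array_equal(a.latent, b.latent)
    c = pm.fit(toy_data["design"], pm.ModelSpec(n_posterior_samples=50,
                                                n_warmup=50, seed=4))
    assert not np.array_equal(a.beta, c.beta)


def test_fit_rejects_singular_design():
    rng = np.random.default_rng(0)
    x = rng.standard_normal(20)
    coords = rng.uniform(0, 10, (20, 2))
    d = _design(rng.binomial(10, 0.2, 20), np.full(20, 10),
                np.column_stack([x, x]), coords, ["a", "b"])
    with pytest.raises(ValueError, match="collinear|singular"):
        pm.fit(d, pm.ModelSpec(n_posterior_samples=10, n_warmup=10))
    d0 = _design(rng.binomial(10, 0.2, 20), np.full(20, 10),
                 np.zeros((20, 1)), coords, ["flat"])
    with pytest.raises(ValueError, match="zero-variance"):
        pm.fit(d0, pm.ModelSpec(n_posterior_samples=10, n_warmup=10))


def test_posterior_probabilities_valid(toy_model):
    p = toy_model.cluster_probabilities()
    assert np.all((p > 0) & (p < 1))
    assert np.all(np.isfinite(toy_model.beta))
    assert np.all(toy_model.sigma > 0)
    assert np.all(toy_model.range_ > 0)
    assert toy_model.n_draws == toy_model.spec.n_posterior_samples


def test_nonspatial_limit_matches_conjugate_oracle():
    """All clusters at one location, sigma ~ 0: the model collapses to a
    single binomial proportion, whose posterior under a flat-ish prior is
    Beta(y + 1/2, n - y + 1/2)."""
    n_clu, y_tot, n_tot = 20, 40, 400
    y = np.full(n_clu, y_tot // n_clu)
    coords = np.tile([[5.0, 5.0]], (n_clu, 1))
    d = _design(y, np.full(n_clu, n_tot // n_clu), np.zeros((n_clu, 0)), coords, [])
    spec = pm.ModelSpec(n_posterior_samples=1500, n_warmup=500, seed=2,
                        fix_sigma=1e-4, fix_range=1.0)
    m = pm.fit(d, spec)
    p_draws = expit(m.beta[:, 0])
    oracle = beta_dist(y_tot + 0.5, n_tot - y_tot + 0.5)
    assert p_draws.mean() == pytest.approx(oracle.mean(), abs=0.012)
    assert p_draws.std() == pytest.approx(oracle.std(), rel=0.35)


def test_outlier_cluster_shrinks_toward_neighbors():
    rng = np.random.default_rng(11)
    n = 10
    coords = np.column_stack([5 + 0.3 * rng.standard_normal(n),
                              5 + 0.3 * rng.standard_normal(n)])
    y = np.full(n, 1)
    y[-1] = 15          # extreme outlier among close neighbors
    d = _design(y, np.full(n, 20), np.zeros((n, 0)), coords, [])
    m = pm.fit(d, pm.ModelSpec(n_posterior_samples=400, n_warmup=400, seed=1))
    post = m.cluster_probabilities().mean(axis=0)
    raw = 15 / 20
    neigh = np.mean(y[:-1] / 20)
    assert neigh < post[-1] < raw


# ------------------------------------------------------------ latent kriging

def _single_draw_model(coords, S, sigma, rho, nu=1.0, n_rep=1):
    """A FittedModel with n_rep identical draws of a known state."""
    n = len(coords)
    d = _design(np.zeros(n, dtype=int), np.full(n, 10),
                np.zeros((n, 0)), coords, [])
    return FittedModel(
        spec=ModelSpec(nu=nu, n_posterior_samples=n_rep),
        names=[], coords=np.asarray(coords, float),
        beta=np.zeros((n_rep, 1)),
        sigma=np.full(n_rep, sigma), range_=np.full(n_rep, rho),
        latent=np.tile(np.asarray(S, float), (n_rep, 1)),
        design=d, standardization={"means": [], "sds": []},
    )


def test_predict_latent_interpolates_at_cluster_location():
    coords = [[0.0, 0.0], [4.0, 0.0], [0.0, 3.0]]
    S = [0.8, -1.1, 0.3]
    m = _single_draw_model(coords, S, sigma=1.0, rho=5.0, n_rep=50)
    pred = pm.predict_latent(m, coords, seed=0)
    np.testing.assert_allclose(pred, np.tile(S, (50, 1)), atol=1e-3)


def test_predict_latent_reverts_to_prior_far_away():
    coords = [[0.0, 0.0], [1.0, 0.0]]
    m = _single_draw_model(coords, [0.9, 0.7], sigma=1.3, rho=2.0, n_rep=3000)
    far = pm.predict_latent(m, [[500.0, 500.0]], seed=1)[:, 0]
    assert far.mean() == pytest.approx(0.0, abs=0.1)
    assert far.var() == pytest.approx(1.3**2, rel=0.12)


def test_predict_latent_matches_brute_force_kriging():
    """Conditional mean and variance at a midpoint between clusters must
    match the closed-form Gaussian conditional computed with dense inverses."""
    coords = np.array([[0.0, 0.0], [6.0, 0.0], [3.0, 4.0]])
    S = np.array([1.0, -0.5, 0.2])
    sigma, rho, nu = 1.2, 5.0, 1.0
    target = np.array([[3.0, 0.0]])
    m = _single_draw_model(coords, S, sigma, rho, nu=nu, n_rep=4000)
    draws = pm.predict_latent(m, target, seed=3)[:, 0]

    dists = np.linalg.norm(coords[:, None] - coords[None], axis=-1)
    K = sigma**2 * matern_correlation(dists, rho, nu)
    k = sigma**2 * matern_correlation(
        np.linalg.norm(coords - target, axis=1), rho, nu)
    mean = k @ np.linalg.solve(K, S)
    var = sigma**2 - k @ np.linalg.solve(K, k)
    assert draws.mean() == pytest.approx(mean, abs=4 * np.sqrt(var / 4000) + 1e-3)
    assert draws.var() == pytest.approx(var, rel=0.12)


# -------------------------------------------------------------- persistence

def test_fitted_model_roundtrip(tmp_path, toy_model):
    toy_model.save(tmp_path / "m")
    back = FittedModel.load(tmp_path / "m")
    np.testing.assert_allclose(back.beta, toy_model.beta, atol=1e-9)
    np.testing.assert_allclose(back.latent, toy_model.latent, atol=1e-9)
    np.testing.assert_allclose(back.sigma, toy_model.sigma, atol=1e-9)
    assert back.names == toy_model.names
    np.testing.assert_allclose(back.design.X, toy_model.design.X, atol=1e-12)


def test_simple_ess_sane():
    rng = np.random.default_rng(0)
    iid = rng.standard_normal(500)
    assert _simple_ess(iid) > 250
    corr = np.cumsum(iid)  # random walk: tiny effective sample
    assert _simple_ess(corr) < 50
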