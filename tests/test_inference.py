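"""MAP estimation, Laplace posterior, predictive distribution and hyperparameters.

The closed-form Bayesian linear-regression posterior is the oracle for the
whole chain: on any model linear in theta, MAP, Hessian and predictive must be
exact.
"""

import numpy as np
import pytest
from scipy import linalg, stats

from mirnn.bioreactor import (
    build_design_space,
    default_feed_catalog,
    enumerate_feed_designs,
    sample_ecosystem,
    simulate,
)
from mirnn.inference import (
    LinearObservations,
    MiRNNObservations,
    estimate_sigma_y_em,
    fit_map,
    fit_posterior,
    heldout_loglik,
    laplace_hessian,
    log_evidence,
    neg_log_posterior,
    optimize_alpha,
    posterior_predictive,
    sensitivity,
)
from mirnn.model import (
    Dataset,
    Dimensions,
    ExperimentalCondition,
    MiRNN,
    MiRNNParams,
    Trajectory,
    count_params,
    init_params,
)


def _linear_problem(seed=0, n=15, p=4):
    rng = np.random.default_rng(seed)
    G = rng.normal(size=(n, p))
    sigma = np.diag(rng.uniform(0.5, 2.0, n))
    theta_true = rng.normal(size=p)
    y = G @ theta_true + rng.multivariate_normal(np.zeros(n), sigma)
    return G, sigma, y


def _ridge_solution(G, sigma, y, alpha):
    S_inv = np.linalg.inv(sigma)
    H = G.T @ S_inv @ G + alpha * np.eye(G.shape[1])
    return np.linalg.solve(H, G.T @ S_inv @ y), H


# ---------------------------------------------------------------------------
# objective
# ---------------------------------------------------------------------------


def test_neg_log_posterior_values(small_dims, small_model):
    # empty dataset at the prior mode
    obs = MiRNNObservations(small_model, Dataset([]), np.eye(small_dims.n_y))
    n_th = count_params(small_dims)
    assert neg_log_posterior(np.zeros(n_th), obs, 1.0) == 0.0

    # one condition, theta = 0: objective is the direct residual quadratic
    cond = ExperimentalCondition(
        s0=[0.5, 0.5], m0=[0.2], controls=np.zeros((3, 1)), times=[0, 1, 2]
    )
    values = np.array([[0.5, 0.5, 0.2], [0.4, 0.6, 0.1], [0.3, 0.4, 0.2]])
    sigma = np.diag([0.1, 0.2, 0.3])
    obs = MiRNNObservations(small_model, Dataset([Trajectory(cond, values)]), sigma)
    got = neg_log_posterior(np.zeros(n_th), obs, 1.0)
    # model at zero predicts zero for every output
    expected = 0.5 * sum(
        values[t] @ np.linalg.inv(sigma) @ values[t] for t in (1, 2)
    )
    assert got == pytest.approx(expected, rel=1e-12)

    # doubling alpha doubles the prior penalty term only
    theta = init_params(small_dims, 0).flatten()
    base = neg_log_posterior(theta, obs, 0.0 + 1e-12)
    one = neg_log_posterior(theta, obs, 1.0)
    two = neg_log_posterior(theta, obs, 2.0)
    assert two - base == pytest.approx(2 * (one - base), rel=1e-9)


# ---------------------------------------------------------------------------
# linear-Gaussian exactness
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_ridge_equivalence(seed):
    """MAP and Hessian reproduce closed-form Bayesian linear regression."""
    G, sigma, y = _linear_problem(seed)
    alpha = 0.8
    obs = LinearObservations(G, y, sigma)
    res = fit_map(obs, alpha, np.zeros(G.shape[1]), tol=1e-12)
    closed, H_closed = _ridge_solution(G, sigma, y, alpha)
    assert np.allclose(res.theta, closed, rtol=1e-8)
    assert res.converged
    H = laplace_hessian(obs, res.theta, alpha)
    assert np.allclose(H, H_closed, rtol=1e-10)
    # stationarity contract on this smooth problem
    assert res.grad_norm <= 1e-12 * max(1.0, float(np.abs(y).max()))


def test_fit_map_empty_dataset_returns_prior_mode(small_dims, small_model):
    obs = MiRNNObservations(small_model, Dataset([]), np.eye(small_dims.n_y))
    res = fit_map(obs, 1.0, init_params(small_dims, 0).flatten())
    assert np.allclose(res.theta, 0.0, atol=1e-8)


def test_fit_map_nonconvergence_is_flagged():
    G, sigma, y = _linear_problem(3)
    obs = LinearObservations(G, y, sigma)
    res = fit_map(obs, 0.5, np.zeros(G.shape[1]), tol=1e-16, max_iter=1, ftol=0.0)
    assert not res.converged
    assert "max_iter" in res.message or "stalled" in res.message


# ---------------------------------------------------------------------------
# sensitivities
# ---------------------------------------------------------------------------


def test_sensitivity_zero_rows_for_absent_species(small_dims, small_params):
    model = MiRNN(small_dims)
    cond = ExperimentalCondition(
        s0=[0.7, 0.0], m0=[0.2], controls=np.zeros((4, 1)), times=np.arange(4.0)
    )
    G = sensitivity(model, small_params.flatten(), cond)
    # rows of the absent species (output index 1 at every time step) vanish
    for t in range(3):
        assert np.all(G[t * 3 + 1] == 0.0)


def test_sensitivity_linear_model_recovered():
    """For a model linear in theta the sensitivity is the design matrix."""
    G, sigma, y = _linear_problem(1)
    obs = LinearObservations(G, y, sigma)
    _, J = obs.whitened(np.zeros(G.shape[1]))
    L = np.linalg.cholesky(sigma)
    assert np.allclose(L @ J, G, atol=1e-12)


def test_sensitivity_matches_finite_differences(small_dims, small_params, small_condition):
    model = MiRNN(small_dims)
    theta = small_params.flatten()
    G = sensitivity(model, theta, small_condition)
    eps = 1e-6
    for k in range(len(theta)):
        tp, tm = theta.copy(), theta.copy()
        tp[k] += eps
        tm[k] -= eps
        vp = model.predict_trajectory(
            MiRNNParams.unflatten(tp, small_dims), small_condition, "training"
        ).values[1:].ravel()
        vm = model.predict_trajectory(
            MiRNNParams.unflatten(tm, small_dims), small_condition, "training"
        ).values[1:].ravel()
        fd = (vp - vm) / (2 * eps)
        denom = np.maximum(np.abs(fd), 1e-3)
        assert np.all(np.abs(G[:, k] - fd) / denom < 1e-4)


# ---------------------------------------------------------------------------
# Laplace Hessian and predictive
# ---------------------------------------------------------------------------


def test_laplace_hessian_structure(small_dims, small_model, small_params, small_condition):
    n_th = count_params(small_dims)
    alpha = 0.3
    # empty dataset: H is the diagonal prior precision
    obs = MiRNNObservations(small_model, Dataset([]), np.eye(small_dims.n_y))
    H0 = laplace_hessian(obs, np.zeros(n_th), alpha)
    assert np.allclose(H0, alpha * np.eye(n_th))
    # one condition: H - prior = G^T Sigma^{-1} G
    values = small_model.predict_trajectory(
        small_params, small_condition, "training"
    ).values
    sigma = np.diag([0.2, 0.4, 0.3])
    obs = MiRNNObservations(
        small_model, Dataset([Trajectory(small_condition, values)]), sigma
    )
    theta = small_params.flatten()
    H = laplace_hessian(obs, theta, alpha)
    G = sensitivity(small_model, theta, small_condition)
    S_big = np.kron(np.eye(small_condition.n_tau), sigma)
    expected = alpha * np.eye(n_th) + G.T @ np.linalg.solve(S_big, G)
    assert np.allclose(H, expected, rtol=1e-9, atol=1e-12)
    # minimum eigenvalue is at least the prior precision
    assert np.linalg.eigvalsh(H).min() >= alpha - 1e-9


def test_posterior_predictive_linear_oracle():
    """Predictive covariance matches the dense closed form on a small instance."""
    G, sigma, y = _linear_problem(2, n=9, p=3)
    alpha = 0.5
    obs = LinearObservations(G, y, sigma)
    res = fit_map(obs, alpha, np.zeros(3), tol=1e-12)
    H = laplace_hessian(obs, res.theta, alpha)
    cov = sigma + G @ np.linalg.solve(H, G.T)
    # dense oracle computed independently
    _, H_closed = _ridge_solution(G, sigma, y, alpha)
    cov_closed = sigma + G @ np.linalg.inv(H_closed) @ G.T
    assert np.allclose(cov, cov_closed, rtol=1e-8)
    # epistemic part is PSD: cov - sigma >= 0
    assert np.linalg.eigvalsh(cov - sigma).min() >= -1e-10


def test_posterior_predictive_mirnn(small_dims, small_params, small_condition):
    model = MiRNN(small_dims)
    values = model.predict_trajectory(small_params, small_condition, "inference").values
    data = Dataset([Trajectory(small_condition, values)])
    post = fit_posterior(
        data, small_dims, alpha=1.0, sigma_y=0.05, theta0=small_params.flatten(),
        em_iters=0, tol=1e-6, max_iter=100,
    )
    pred = posterior_predictive(post, post.scaling.apply_condition(small_condition))
    # covariance minus Sigma_y is PSD at every step
    for t in range(pred.cov.shape[0]):
        assert np.linalg.eigvalsh(pred.cov[t] - post.sigma_y).min() >= -1e-10
    # huge-alpha limit: epistemic term vanishes, covariance -> Sigma_y
    post_big = fit_posterior(
        data, small_dims, alpha=1e12, sigma_y=0.05, em_iters=0, tol=1e-8,
    )
    pred_big = posterior_predictive(post_big, post_big.scaling.apply_condition(small_condition))
    assert np.allclose(pred_big.cov, np.broadcast_to(post_big.sigma_y, pred_big.cov.shape),
                       atol=1e-8)


def test_monotone_uncertainty():
    """Adding data never increases the linearised predictive variance."""
    rng = np.random.default_rng(6)
    p = 5
    H = np.eye(p) * 0.5
    G_new = rng.normal(size=(3, p))
    sigma = np.eye(3)
    H_after = H + G_new.T @ G_new
    G_q = rng.normal(size=(3, p))
    var_before = G_q @ np.linalg.solve(H, G_q.T)
    var_after = G_q @ np.linalg.solve(H_after, G_q.T)
    assert np.linalg.eigvalsh(var_before - var_after).min() >= -1e-10


# ---------------------------------------------------------------------------
# held-out log-likelihood
# ---------------------------------------------------------------------------


def _make_pred(cond, mean, covs, sigma):
    from mirnn.inference import PredictiveDistribution

    return PredictiveDistribution(cond, mean, covs, sigma)


def test_heldout_loglik_closed_form():
    cond = ExperimentalCondition(
        s0=[1.0], m0=[1.0], controls=np.zeros((2, 0)), times=[0.0, 1.0]
    )
    mean = np.array([[1.0, 1.0], [0.3, 0.7]])
    covs = np.eye(2)[None]
    obs_traj = Trajectory(cond, mean.copy())  # observation exactly at the mean
    ll = heldout_loglik([_make_pred(cond, mean, covs, np.eye(2))], [obs_traj])
    assert ll == pytest.approx(-np.log(2 * np.pi))


def test_heldout_loglik_tail_property_and_additivity():
    cond = ExperimentalCondition(
        s0=[1.0], m0=[], controls=np.zeros((2, 0)), times=[0.0, 1.0]
    )
    mean = np.array([[1.0], [0.0]])
    far = Trajectory(cond, np.array([[1.0], [5.0]]))
    small_cov = np.array([[[1.0]]])
    big_cov = np.array([[[30.0]]])
    ll_small = heldout_loglik([_make_pred(cond, mean, small_cov, np.eye(1))], [far])
    ll_big = heldout_loglik([_make_pred(cond, mean, big_cov, np.eye(1))], [far])
    assert ll_big > ll_small  # inflating covariance helps a far-off observation

    # batch score is the sum of per-item scores
    near = Trajectory(cond, np.array([[1.0], [0.2]]))
    both = heldout_loglik(
        [_make_pred(cond, mean, small_cov, np.eye(1))] * 2, [far, near]
    )
    sep = heldout_loglik(
        [_make_pred(cond, mean, small_cov, np.eye(1))], [far]
    ) + heldout_loglik([_make_pred(cond, mean, small_cov, np.eye(1))], [near])
    assert both == pytest.approx(sep, rel=1e-12)

    with pytest.raises(ValueError):
        heldout_loglik([], [], covariance_mode="bogus")


# ---------------------------------------------------------------------------
# noise covariance EM
# ---------------------------------------------------------------------------


def test_em_perfect_fit_collapses_to_floor(small_dims, small_params, small_condition):
    """Zero residuals drive the estimated noise variance to the floor."""
    model = MiRNN(small_dims)
    # data generated exactly by the prior mode theta = 0: residuals vanish at
    # the MAP, and a dominant prior makes the epistemic term negligible, so
    # the noise update collapses to (a small multiple of) the floor
    n_th = count_params(small_dims)
    zero = MiRNNParams.unflatten(np.zeros(n_th), small_dims)
    values = model.predict_trajectory(zero, small_condition, "training").values
    data = Dataset([Trajectory(small_condition, values)])
    obs = MiRNNObservations(model, data, np.full(small_dims.n_y, 1e-2))
    sigma, res = estimate_sigma_y_em(
        obs, 1e8, np.zeros(n_th), n_em_iter=3, floor=1e-8,
        fit_tol=1e-10, fit_max_iter=200,
    )
    diag = np.diag(sigma)
    assert np.all(diag <= 1e-6)
    assert np.allclose(sigma, sigma.T, atol=1e-12)


def test_em_recovers_known_noise_variance():
    """On a linear surrogate with known noise, EM recovers the variance within 20%."""
    rng = np.random.default_rng(8)
    n_s, n_m, n_h = 2, 1, 2
    dims = Dimensions(n_s=n_s, n_m=n_m, n_u=0, n_h=n_h)
    model = MiRNN(dims)
    gen = init_params(dims, 3)
    sigma_true = 0.02**2
    conds, trajs = [], []
    for i in range(40):
        s0 = rng.uniform(0.3, 1.0, n_s)
        cond = ExperimentalCondition(
            s0=s0, m0=rng.uniform(0.3, 1.0, n_m), controls=np.zeros((6, 0)),
            times=np.arange(6.0), condition_id=f"c{i}",
        )
        clean = model.predict_trajectory(gen, cond, "training").values
        noisy = clean.copy()
        noisy[1:] += rng.normal(0, np.sqrt(sigma_true), noisy[1:].shape)
        trajs.append(Trajectory(cond, noisy))
    data = Dataset(trajs)
    obs = MiRNNObservations(model, data, np.full(dims.n_y, 1e-2))
    sigma, res = estimate_sigma_y_em(
        obs, 1e-6, gen.flatten(), n_em_iter=4, fit_tol=1e-8, fit_max_iter=200,
    )
    diag = np.diag(sigma)
    assert np.all(np.abs(diag - sigma_true) / sigma_true < 0.2)


# ---------------------------------------------------------------------------
# evidence and alpha selection
# ---------------------------------------------------------------------------


def test_log_evidence_matches_linear_marginal_likelihood():
    G, sigma, y = _linear_problem(4, n=10, p=3)
    for alpha in (0.2, 1.0, 6.0):
        obs = LinearObservations(G, y, sigma)
        res = fit_map(obs, alpha, np.zeros(3), tol=1e-12)
        ev = log_evidence(obs, res.theta, alpha)
        marg_cov = sigma + G @ G.T / alpha
        exact = stats.multivariate_normal.logpdf(y, np.zeros(len(y)), marg_cov)
        assert ev == pytest.approx(exact, rel=1e-10)


def test_optimize_alpha_contracts():
    G, sigma, y = _linear_problem(5)
    obs = LinearObservations(G, y, sigma)
    # grid of one
    a, table = optimize_alpha(obs, [2.5], np.zeros(G.shape[1]))
    assert a == 2.5 and len(table) == 1
    # argmax contract
    a, table = optimize_alpha(obs, [0.01, 0.1, 1.0, 10.0], np.zeros(G.shape[1]))
    best = max(table, key=lambda r: r["evidence"])
    assert a == best["alpha"]
    with pytest.raises(ValueError):
        optimize_alpha(obs, [], np.zeros(G.shape[1]))
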