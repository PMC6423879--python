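"""PQL/REML fitting: normal equations, tau updates, and GLM limits."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy.optimize import minimize_scalar
from scipy.special import expit

from pea.errors import InputError
from pea.kernel import pathway_kernel
from pea.pql import FitControl, fit_null_model, irls_step, reml_loglik, update_tau


def _instance(seed, N=20, m=3, v=4):
    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones(N), rng.standard_normal((N, m - 1))])
    P = rng.random((N, v))
    K0 = pathway_kernel(P)
    y = (rng.random(N) < expit(X @ rng.normal(size=m))).astype(float)
    if y.min() == y.max():
        y[0] = 1 - y[0]
    return y, X, K0, rng


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_irls_step_matches_dense_block_solve(seed):
    """Schur-complement solution equals the explicitly assembled
    (m+N) x (m+N) normal-equation solve."""
    y, X, K0, rng = _instance(seed)
    N, m = X.shape
    tau = 0.5
    beta = rng.normal(size=m) * 0.1
    alpha = rng.normal(size=N) * 0.01
    beta_new, alpha_new, gamma, d, y_work = irls_step(y, X, K0, tau, beta, alpha)

    # oracle: dense assembly of the printed block system
    eta = X @ beta + K0 @ alpha
    g = np.clip(expit(eta), 1e-6, 1 - 1e-6)
    dd = g * (1 - g)
    yw = eta + (y - g) / dd
    D = np.diag(dd)
    A = np.block([[X.T @ D @ X, X.T @ D @ K0], [D @ X, np.eye(N) / tau + D @ K0]])
    b = np.concatenate([X.T @ D @ yw, D @ yw])
    sol = np.linalg.solve(A, b)
    np.testing.assert_allclose(beta_new, sol[:m], atol=1e-8)
    np.testing.assert_allclose(alpha_new, sol[m:], atol=1e-8)
    np.testing.assert_allclose(y_work, yw, atol=1e-12)


def test_irls_first_step_intercept_zero_when_balanced():
    """Balanced y with intercept-only X and no kernel contribution: the
    first step from (0, 0) keeps the intercept at logit(0.5) = 0.  (With an
    active kernel block the constant component of K0 shares the intercept
    with X, so the split between beta and alpha is penalty-dependent and the
    exact zero holds only for the degenerate kernel.)"""
    y = np.array([0.0, 1.0] * 10)
    X = np.ones((20, 1))
    beta, _, _, _, _ = irls_step(
        y, X, np.zeros((20, 20)), tau=0.5, beta=np.zeros(1), alpha=np.zeros(20)
    )
    assert beta[0] == pytest.approx(0.0, abs=1e-12)


def test_irls_with_zero_kernel_is_plain_logistic_step():
    """With K0 = 0 the fixed-effect block degenerates to the standard IRLS
    normal equations X'DX beta = X'D y~."""
    y, X, _, rng = _instance(3)
    N, m = X.shape
    beta = rng.normal(size=m) * 0.1
    beta_new, _, _, _, _ = irls_step(y, X, np.zeros((N, N)), 0.5, beta, np.zeros(N))
    eta = X @ beta
    g = expit(eta)
    d = g * (1 - g)
    yw = eta + (y - g) / d
    oracle = np.linalg.solve(X.T @ (X * d[:, None]), X.T @ (d * yw))
    np.testing.assert_allclose(beta_new, oracle, atol=1e-8)


def _gaussian_working_instance(seed, N=60, tau_star=0.8):
    rng = np.random.default_rng(seed)
    P = rng.random((N, 4))
    K0 = pathway_kernel(P)
    X = np.column_stack([np.ones(N), rng.standard_normal(N)])
    d = np.full(N, 0.25)
    V = np.diag(1 / d) + tau_star * K0
    yw = X @ np.array([0.3, -0.2]) + np.linalg.cholesky(V) @ rng.standard_normal(N)
    return yw, X, K0, d


@pytest.mark.parametrize("seed", [0, 5])
def test_tau_score_matches_numerical_reml_gradient(seed):
    """The update's score numerator (r'V^-1 K V^-1 r - tr(QK)) computed from
    an explicitly assembled Q equals twice the numerical derivative of the
    restricted log-likelihood."""
    yw, X, K0, d = _gaussian_working_instance(seed, N=15)
    tau = 0.6
    V = np.diag(1 / d) + tau * K0
    Vinv = np.linalg.inv(V)
    Q = Vinv - Vinv @ X @ np.linalg.inv(X.T @ Vinv @ X) @ X.T @ Vinv
    num = yw @ Q @ K0 @ Q @ yw - np.trace(Q @ K0)
    eps = 1e-6
    grad = (reml_loglik(yw, X, K0, d, tau + eps) - reml_loglik(yw, X, K0, d, tau - eps)) / (2 * eps)
    assert num / 2 == pytest.approx(grad, rel=1e-4, abs=1e-6)


def test_update_tau_never_decreases_reml():
    for seed in range(5):
        yw, X, K0, d = _gaussian_working_instance(seed)
        tau = 0.1
        for t in range(1, 8):
            tau_new = update_tau(yw, X, K0, d, tau, t)
            assert reml_loglik(yw, X, K0, d, tau_new) >= reml_loglik(yw, X, K0, d, tau) - 1e-9
            tau = tau_new


def test_update_tau_stationary_at_reml_optimum():
    yw, X, K0, d = _gaussian_working_instance(2, N=80)
    opt = minimize_scalar(
        lambda t: -reml_loglik(yw, X, K0, d, t), bounds=(1e-6, 20.0), method="bounded",
        options={"xatol": 1e-10},
    )
    tau_star = opt.x
    tau_new = update_tau(yw, X, K0, d, tau_star, t=1)
    assert tau_new == pytest.approx(tau_star, rel=1e-3, abs=1e-5)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_fit_reduces_to_logistic_regression_at_tau_floor(seed):
    """Variance component clamped to ~0: the kernel term vanishes and the
    fixed effects agree with an independent ML logistic fit."""
    y, X, K0, _ = _instance(seed, N=80)
    ctrl = FitControl(tau_init=1e-8, estimate_tau=False, max_outer_iter=100)
    fit = fit_null_model(y, X, K0, ctrl)
    ref = sm.Logit(y, X).fit(disp=0)
    np.testing.assert_allclose(fit.beta_C, ref.params, atol=1e-5)


def test_fit_with_zero_kernel_matches_logistic_regression():
    """A zero kernel carries no information about tau (the update is
    stationary) and the fixed effects reduce to plain logistic regression."""
    y, X, _, _ = _instance(7, N=80)
    fit = fit_null_model(y, X, np.zeros((80, 80)), FitControl(max_outer_iter=100))
    ref = sm.Logit(y, X).fit(disp=0)
    np.testing.assert_allclose(fit.beta_C, ref.params, atol=1e-4)


def test_fit_smoke_on_null_simulation():
    """Null-simulated data: fit converges, tau stays at/above the floor and
    fitted probabilities are valid."""
    from pea.simulate import SimulationConfig, simulate_dataset

    cfg = SimulationConfig(N=100, v=10, c=0.0, s=0.0)
    n_conv = 0
    for seed in range(20):
        ds = simulate_dataset(cfg, seed)
        fit = fit_null_model(ds.y, np.ones((100, 1)), pathway_kernel(ds.P))
        assert fit.tau >= 1e-8
        assert np.all((fit.gamma > 0) & (fit.gamma < 1))
        n_conv += fit.converged
    assert n_conv >= 19


def test_duplicating_individuals_leaves_beta_unchanged():
    """Replicating every individual leaves beta_C unchanged in the GLM limit
    (sufficiency under replication).  With an active kernel the duplicated
    random effect is shared across copies, so exact invariance requires
    halving tau to keep the effective penalty fixed; both forms are checked.
    REML-estimated tau is not invariant by design (identical duplicated
    responses look like clustering)."""
    y, X, K0, _ = _instance(4, N=40)
    y2 = np.concatenate([y, y])
    X2 = np.vstack([X, X])
    K2 = np.block([[K0, K0], [K0, K0]])

    glm = FitControl(tau_init=1e-8, estimate_tau=False, max_outer_iter=100)
    fit1 = fit_null_model(y, X, K0, glm)
    fit2 = fit_null_model(y2, X2, K2, glm)
    np.testing.assert_allclose(fit1.beta_C, fit2.beta_C, atol=1e-4)

    fixed = FitControl(tau_init=0.5, estimate_tau=False, max_outer_iter=100)
    fixed_half = FitControl(tau_init=0.25, estimate_tau=False, max_outer_iter=100)
    fit3 = fit_null_model(y, X, K0, fixed)
    fit4 = fit_null_model(y2, X2, K2, fixed_half)
    np.testing.assert_allclose(fit3.beta_C, fit4.beta_C, atol=1e-4)


def test_probability_clamp_respected_under_separation():
    N = 30
    x = np.linspace(-4, 4, N)
    y = (x > 0).astype(float)  # perfectly separated
    X = np.column_stack([np.ones(N), x])
    K0 = pathway_kernel(np.random.default_rng(0).random((N, 2)))
    clamp = 1e-4
    fit = fit_null_model(y, X, K0, FitControl(prob_clamp=clamp))
    assert fit.gamma.min() >= clamp
    assert fit.gamma.max() <= 1 - clamp


def test_input_errors():
    y, X, K0, _ = _instance(0)
    with pytest.raises(InputError):
        fit_null_model(np.ones_like(y), X, K0)  # single class
    with pytest.raises(InputError):
        fit_null_model(y, np.column_stack([X, X[:, 0]]), K0)  # rank deficient
    with pytest.raises(InputError):
        fit_null_model(y + 0.5, X, K0)  # non-binary
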