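"""Penalized quasi-likelihood (PQL) fit of the null kernel-machine logistic model.

Null model::

    logit P(y_i = 1) = X_i beta_C + h_i,      h ~ N(0, tau * K0)

with ``K0`` the null pathway kernel and ``h = K0 @ alpha``.  Fitting
alternates two steps until the coefficients and the variance component
stabilise:

1. a working-response Newton (IRLS) step for ``(beta_C, alpha)`` solving the
   mixed-model normal equations::

       [ X'DX      X'DK    ] [beta ]   [ X'D y~ ]
       [ DX    I/tau + DK  ] [alpha] = [ D  y~  ]

   where ``gamma = expit(X beta + K0 alpha)``, ``D = diag(gamma (1-gamma))``
   and the working response is ``y~ = eta + D^{-1} (y - gamma)``;

2. a damped Fisher-scoring update of ``tau`` on the restricted likelihood of
   the Gaussian working model ``y~ ~ N(X beta, V)``, ``V = D^{-1} + tau K0``,
   with step ``omega^t * (r' V^{-1} K V^{-1} r - tr(QK)) / (tr(QKQK)/2)``
   taken in the ascent direction of L_REML, where
   ``Q = V^{-1} - V^{-1} X (X' V^{-1} X)^{-1} X' V^{-1}`` and
   ``r = y~ - X beta`` at the profiled (GLS) coefficients.  The geometric
   damping factor ``omega = 0.5`` shrinks later steps; step-halving
   additionally guards against any decrease of the restricted likelihood.

The converged state (probabilities, weights, working response, V^{-1},
residual) is exactly the workspace the permutation score test reuses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import NDArray
from scipy import linalg as sla
from scipy.special import expit

from .errors import InputError, NumericalError

__all__ = ["FitControl", "NullModelFit", "irls_step", "update_tau", "reml_loglik", "fit_null_model"]


@dataclass
class FitControl:
    """Tuning knobs of the PQL/REML fit.

    damping is the geometric Newton-Raphson damping factor omega (the tau
    step at outer iteration t is scaled by omega**t); tau_floor keeps the
    variance component positive so V stays invertible; prob_clamp bounds the
    fitted probabilities away from 0/1 so D^{-1} stays finite under
    separation-prone small-sample fits.
    """

    max_outer_iter: int = 50
    max_tau_iter: int = 50
    tol_beta: float = 1e-5
    tol_tau: float = 1e-5
    tau_init: float = 0.1
    tau_floor: float = 1e-8
    damping: float = 0.5
    prob_clamp: float = 1e-6
    estimate_tau: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.damping <= 1):
            raise InputError("damping must be in (0, 1]")
        if not (0 < self.prob_clamp < 0.5):
            raise InputError("prob_clamp must be in (0, 0.5)")
        for name in ("tau_init", "tau_floor", "tol_beta", "tol_tau"):
            if getattr(self, name) <= 0:
                raise InputError(f"{name} must be positive")


@dataclass
class NullModelFit:
    """Converged null-model state.

    d holds the diagonal of the IRLS weight matrix D (d_i = gamma_i(1-gamma_i));
    y_work is the working response y~; resid = y~ - X beta_C; Vinv is the
    inverse of V = D^{-1} + tau*K0.
    """

    beta_C: NDArray
    alpha: NDArray
    tau: float
    gamma: NDArray
    d: NDArray
    y_work: NDArray
    Vinv: NDArray
    resid: NDArray
    converged: bool
    n_iter: int
    reml: float = field(default=np.nan)

    @property
    def D(self) -> NDArray:
        return np.diag(self.d)


def irls_step(
    y: NDArray,
    X: NDArray,
    K0: NDArray,
    tau: float,
    beta: NDArray,
    alpha: NDArray,
    prob_clamp: float = 1e-6,
) -> tuple[NDArray, NDArray, NDArray, NDArray, NDArray]:
    """One working-response Newton step for (beta_C, alpha) at fixed tau.

    Solves the block normal equations by Schur-complement elimination of the
    alpha block (the dense (m+N) x (m+N) solve is kept only as a test
    oracle).  Returns ``(beta', alpha', gamma, d, y_work)`` where gamma, d
    and y_work are evaluated at the *current* iterate.
    """
    if tau <= 0:
        raise InputError("tau must be positive")
    N, m = X.shape
    eta = X @ beta + K0 @ alpha
    gamma = np.clip(expit(eta), prob_clamp, 1.0 - prob_clamp)
    d = gamma * (1.0 - gamma)
    y_work = eta + (y - gamma) / d

    DX = X * d[:, None]
    DK = K0 * d[:, None]
    A22 = np.eye(N) / tau + DK
    try:
        W = np.linalg.solve(A22, np.column_stack([DX, d * y_work]))
    except np.linalg.LinAlgError as exc:  # pragma: no cover - pathological
        raise NumericalError(
            "singular alpha-block in the normal equations; consider a larger "
            "tau_floor or check the kernel rank"
        ) from exc
    W1, w2 = W[:, :m], W[:, m]
    XtDK = X.T @ DK
    S = X.T @ DX - XtDK @ W1
    rhs = X.T @ (d * y_work) - XtDK @ w2
    try:
        beta_new = np.linalg.solve(S, rhs)
    except np.linalg.LinAlgError as exc:
        raise NumericalError(
            "singular fixed-effect normal equations; check that X has full "
            "column rank"
        ) from exc
    alpha_new = w2 - W1 @ beta_new
    if not (np.all(np.isfinite(beta_new)) and np.all(np.isfinite(alpha_new))):
        raise NumericalError("non-finite coefficient update")
    return beta_new, alpha_new, gamma, d, y_work


def _chol_logdet(A: NDArray) -> tuple[NDArray, float]:
    c, low = sla.cho_factor(A, lower=True, check_finite=False)
    return (c, low), 2.0 * float(np.sum(np.log(np.diag(c))))


def _reml_parts(y_work: NDArray, X: NDArray, K0: NDArray, d: NDArray, tau: float):
    """V, V^{-1}, Q, and L_REML at the given tau (beta profiled out by GLS)."""
    N = y_work.shape[0]
    V = np.diag(1.0 / d) + tau * K0
    try:
        cV, logdetV = _chol_logdet(V)
    except np.linalg.LinAlgError as exc:
        raise NumericalError(f"working covariance V not positive definite at tau={tau!r}") from exc
    Vinv = sla.cho_solve(cV, np.eye(N), check_finite=False)
    VinvX = Vinv @ X
    XtVinvX = X.T @ VinvX
    try:
        cB, logdetB = _chol_logdet(XtVinvX)
    except np.linalg.LinAlgError as exc:
        raise NumericalError("X'V^{-1}X not positive definite (rank-deficient X?)") from exc
    Q = Vinv - VinvX @ sla.cho_solve(cB, VinvX.T, check_finite=False)
    quad = float(y_work @ Q @ y_work)
    reml = -0.5 * (logdetV + logdetB + quad)
    return V, Vinv, Q, reml


def reml_loglik(y_work: NDArray, X: NDArray, K0: NDArray, d: NDArray, tau: float) -> float:
    """Restricted log-likelihood of the Gaussian working model at tau,
    with the fixed effects profiled out:
    -1/2 (log|V| + log|X'V^{-1}X| + r' V^{-1} r), r the GLS residual."""
    return _reml_parts(y_work, X, K0, d, tau)[3]


def update_tau(
    y_work: NDArray,
    X: NDArray,
    K0: NDArray,
    d: NDArray,
    tau: float,
    t: int,
    control: FitControl | None = None,
) -> float:
    """One damped Fisher-scoring update of the variance component tau.

    The raw step is num/info with
    ``num = r' V^{-1} K V^{-1} r - tr(QK)`` (twice the REML score) and
    ``info = tr(QKQK)/2`` (twice the average information up to the same
    factor), scaled by omega**t, taken so that L_REML increases, halved on
    any decrease, and clamped at tau_floor.
    """
    control = control or FitControl()
    if tau <= 0:
        raise InputError("tau must be positive")
    _, _, Q, reml0 = _reml_parts(y_work, X, K0, d, tau)
    QK = Q @ K0
    Qy = Q @ y_work  # = V^{-1} (y~ - X beta_GLS)
    num = float(Qy @ K0 @ Qy - np.trace(QK))
    info = float(np.sum(QK * QK.T)) / 2.0  # tr(QKQK)/2
    if not np.isfinite(num) or not np.isfinite(info):
        raise NumericalError("non-finite REML score/information for tau update")
    if info <= 0:
        if abs(num) < 1e-10:
            return tau  # zero gradient and zero information: stationary (e.g. K0 = 0)
        raise NumericalError("degenerate REML information for tau update")

    step = (control.damping ** t) * num / info
    for _ in range(control.max_tau_iter):
        tau_new = max(tau + step, control.tau_floor)
        if tau_new == tau:
            return tau
        try:
            reml1 = reml_loglik(y_work, X, K0, d, tau_new)
        except NumericalError:
            reml1 = -np.inf
        if reml1 >= reml0 - 1e-10:
            if not np.isfinite(tau_new):
                raise NumericalError("non-finite tau update")
            return tau_new
        step /= 2.0
    return tau


def fit_null_model(
    y: NDArray,
    X: NDArray,
    K0: NDArray,
    control: FitControl | None = None,
) -> NullModelFit:
    """Fit the null kernel-machine logistic model by PQL with REML tau.

    Alternates one IRLS coefficient step with one damped tau update per
    outer iteration; convergence is declared when the sup-norm changes of
    beta_C, of h = K0 alpha and of tau all fall below their tolerances.  The
    state is returned even at the iteration cap (converged=False).
    """
    control = control or FitControl()
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    K0 = np.asarray(K0, dtype=float)
    N = y.shape[0]
    if X.shape[0] != N or K0.shape != (N, N):
        raise InputError(
            f"inconsistent shapes: y has {N} samples, X is {X.shape}, K0 is {K0.shape}"
        )
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise InputError("phenotype must be binary 0/1")
    if y.min() == y.max():
        raise InputError("phenotype has a single class; both cases and controls required")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise InputError("design matrix X is rank deficient")

    m = X.shape[1]
    beta = np.zeros(m)
    alpha = np.zeros(N)
    tau = control.tau_init
    converged = False
    n_iter = 0
    for t in range(1, control.max_outer_iter + 1):
        n_iter = t
        beta_new, alpha_new, _, d, y_work = irls_step(
            y, X, K0, tau, beta, alpha, control.prob_clamp
        )
        tau_new = update_tau(y_work, X, K0, d, tau, t, control) if control.estimate_tau else tau
        d_beta = float(np.max(np.abs(beta_new - beta)))
        d_h = float(np.max(np.abs(K0 @ (alpha_new - alpha))))
        d_tau = abs(tau_new - tau)
        beta, alpha, tau = beta_new, alpha_new, tau_new
        if max(d_beta, d_h) < control.tol_beta and d_tau < control.tol_tau:
            converged = True
            break

    # final state at the accepted coefficients
    eta = X @ beta + K0 @ alpha
    gamma = np.clip(expit(eta), control.prob_clamp, 1.0 - control.prob_clamp)
    d = gamma * (1.0 - gamma)
    y_work = eta + (y - gamma) / d
    _, Vinv, _, reml = _reml_parts(y_work, X, K0, d, tau)
    resid = y_work - X @ beta
    return NullModelFit(
        beta_C=beta,
        alpha=alpha,
        tau=tau,
        gamma=gamma,
        d=d,
        y_work=y_work,
        Vinv=Vinv,
        resid=resid,
        converged=converged,
        n_iter=n_iter,
        reml=reml,
    )
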