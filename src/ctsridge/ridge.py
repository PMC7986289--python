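"""Ridge-regularized estimation of cell-type-specific effects.

Interaction terms W_h X_k are nearly collinear whenever the coefficients of
variation of the cell-type proportions are small, so the unpenalized
estimates of the cell-type-specific effects beta are wildly unstable.  The
remedy implemented here penalizes beta (never alpha or gamma):

    minimize  RSS(theta) + lambda * sum_{h,k} beta_{h,k}^2

The regularization parameter is picked per marker from the SVD
(d mu/d beta) = U D V^T of the beta-Jacobian via the bias-corrected
statistic

    kappa = (1/sum_m d_m^2) * sum_m { d_m^2 (v_m^T beta_ols)^2 / sigma^2 - 1 }

with lambda = 1/kappa when kappa > 0 and d_1^2 otherwise.  kappa estimates
the weighted harmonic information about the per-direction optimal penalties
lambda_m = sigma^2 / (v_m^T beta)^2 (a bias-corrected Hoerl-Kennard rule).
Inference uses a sandwich covariance built from a ridge-adapted Fisher
matrix Q (observed, with a residual-weighted Hessian correction, or
expected, without it) and a non-exact t-type test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .model import (ModelEvaluation, OmicsDataset, ParameterVector,
                    bulk_mean, model_derivatives)
from .scales import get_scale

# singular values below this multiple of d_1 are treated as exactly zero in
# the variance terms of the MSE decomposition; kappa keeps every direction's
# bias-subtraction term regardless (the selection rule is used as printed)
_SV_TRUNC = 1e-10


class DegenerateSigmaError(ValueError):
    """sigma^2 = 0: kappa is undefined; callers fall back to lambda = 0."""


# ---------------------------------------------------------------------------
# spectrum, kappa, lambda
# ---------------------------------------------------------------------------

@dataclass
class RidgeSpectrum:
    """Singular values and right singular vectors of the beta-Jacobian."""

    d: np.ndarray            # descending, length M
    V: np.ndarray            # (M, M), columns v_1..v_M
    kappa: Optional[float] = None
    lambda_: Optional[float] = None


@dataclass
class RidgeCovariance:
    """Sandwich covariance of (beta_hat(lambda), gamma_hat(lambda))."""

    Q: np.ndarray
    variance: np.ndarray
    fisher_mode: str
    singular: bool = False
    negative_diagonal: bool = False


def ridge_objective(theta: ParameterVector, data: OmicsDataset, scale,
                    y_normalized, lambda_: float) -> float:
    """RSS plus the L2 penalty on the beta block only."""
    if lambda_ < 0:
        raise ValueError("lambda must be nonnegative")
    mu = bulk_mean(theta, data, scale)
    rss = float(np.sum((np.asarray(y_normalized) - mu) ** 2))
    return rss + lambda_ * float(np.sum(theta.beta**2))


def beta_spectrum(jacobian_beta: np.ndarray) -> RidgeSpectrum:
    """SVD of the (samples x M) beta-Jacobian with a deterministic sign
    convention (largest-magnitude entry of each right vector positive)."""
    J = np.asarray(jacobian_beta, dtype=float)
    n, M = J.shape
    U, s, Vt = np.linalg.svd(J, full_matrices=n < M)
    V = Vt.T[:, :min(n, M)] if n < M else Vt.T
    if s.size < M:
        # rank-deficient tall-in-M case: complete the basis, zero singulars
        s = np.concatenate([s, np.zeros(M - s.size)])
        full = np.linalg.svd(J, full_matrices=True)[2].T
        V = full
    signs = np.sign(V[np.argmax(np.abs(V), axis=0), np.arange(M)])
    signs[signs == 0] = 1.0
    return RidgeSpectrum(d=s, V=V * signs)


def kappa_statistic(spectrum: RidgeSpectrum, beta_ols: np.ndarray,
                    sigma2: float) -> float:
    """Bias-corrected estimate of the reciprocal optimal penalty.

    May be nonpositive (small effects); sigma2 = 0 is a degenerate marker.
    """
    if sigma2 <= 0:
        raise DegenerateSigmaError("sigma^2 must be positive to compute kappa")
    d2 = spectrum.d**2
    proj = spectrum.V.T @ np.asarray(beta_ols, dtype=float).ravel()
    return float(np.sum(d2 * proj**2 / sigma2 - 1.0) / np.sum(d2))


def select_lambda(kappa: float, d1: float) -> float:
    """lambda = 1/kappa when kappa > 0, else d_1^2 (instead of +inf)."""
    if kappa > 0:
        return 1.0 / kappa
    return float(d1) ** 2


# ---------------------------------------------------------------------------
# minimizer
# ---------------------------------------------------------------------------

def _levenberg_marquardt(fun_jac, x0, max_iter=200, rtol=1e-8, gtol=1e-12):
    """Minimize ||r(x)||^2 by damped Gauss-Newton (Levenberg-Marquardt).

    ``fun_jac(x)`` returns the residual vector and its Jacobian.  Entirely
    deterministic; returns (x, converged).  For linear residuals this
    converges in one accepted step.
    """
    x = np.asarray(x0, dtype=float).copy()
    r, J = fun_jac(x)
    cost = float(r @ r)
    A = J.T @ J
    g = J.T @ r
    mu = 1e-3 * max(np.max(np.diag(A)), 1e-30)
    nu = 2.0
    eye = np.eye(x.size)
    for _ in range(max_iter):
        if np.max(np.abs(g)) < gtol * max(1.0, cost):
            return x, True
        try:
            step = np.linalg.solve(A + mu * eye, -g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(A + mu * eye, -g, rcond=None)[0]
        x_new = x + step
        r_new, J_new = fun_jac(x_new)
        cost_new = float(r_new @ r_new)
        predicted = float(step @ (mu * step - g))  # > 0 for a descent step
        actual = cost - cost_new
        if predicted > 0 and actual > 0:
            rho = actual / predicted
            x, r, J, prev_cost = x_new, r_new, J_new, cost
            cost = cost_new
            A = J.T @ J
            g = J.T @ r
            mu *= max(1.0 / 3.0, 1.0 - (2.0 * rho - 1.0) ** 3)
            nu = 2.0
            if prev_cost - cost <= rtol * max(cost, 1e-300):
                return x, True
        else:
            mu *= nu
            nu *= 2.0
            if mu > 1e30:
                # no descent direction even under extreme damping: the
                # gradient is numerically zero at x
                return x, True
    return x, False


def ridge_minimize(theta_init: ParameterVector, data: OmicsDataset, scale,
                   y_normalized, lambda_: float,
                   frozen_alpha: bool = True):
    """Minimize RSS + lambda*||beta||^2 over (beta, gamma), or over all of
    theta with ``frozen_alpha=False``.

    The penalty is absorbed as M pseudo-observations sqrt(lambda)*beta with
    target zero, making the problem ordinary nonlinear least squares.
    Returns (ParameterVector, converged).
    """
    if lambda_ < 0:
        raise ValueError("lambda must be nonnegative")
    scale = get_scale(scale)
    y = np.asarray(y_normalized, dtype=float)
    H, K, L = data.n_cell_types, data.n_traits, data.n_covariates
    M = H * K
    alpha0 = theta_init.alpha.copy()
    sql = np.sqrt(lambda_)

    if frozen_alpha:
        x0 = np.concatenate([theta_init.beta.ravel(), theta_init.gamma])

        def fun_jac(x):
            th = ParameterVector(alpha0, x[:M].reshape(H, K), x[M:])
            ev = model_derivatives(th, data, scale, with_hessian=False)
            r = np.concatenate([y - ev.mu, -sql * x[:M]]) if lambda_ else y - ev.mu
            Jd = -ev.jacobian[:, H:]
            if lambda_:
                P = np.zeros((M, M + L))
                P[:, :M] = -sql * np.eye(M)
                Jd = np.vstack([Jd, P])
            return r, Jd

        x, converged = _levenberg_marquardt(fun_jac, x0)
        theta = ParameterVector(alpha0, x[:M].reshape(H, K), x[M:])
    else:
        x0 = theta_init.flatten()

        def fun_jac(x):
            th = ParameterVector.from_flat(x, H, K, L)
            ev = model_derivatives(th, data, scale, with_hessian=False)
            bet = x[H:H + M]
            r = np.concatenate([y - ev.mu, -sql * bet]) if lambda_ else y - ev.mu
            Jd = -ev.jacobian
            if lambda_:
                P = np.zeros((M, H + M + L))
                P[:, H:H + M] = -sql * np.eye(M)
                Jd = np.vstack([Jd, P])
            return r, Jd

        x, converged = _levenberg_marquardt(fun_jac, x0)
        theta = ParameterVector.from_flat(x, H, K, L)
    return theta, converged


# ---------------------------------------------------------------------------
# covariance and test
# ---------------------------------------------------------------------------

def ridge_covariance(theta_hat: ParameterVector, data: OmicsDataset, scale,
                     y_normalized, lambda_: float, sigma2: float,
                     fisher_mode: str = "observed") -> RidgeCovariance:
    """Sandwich covariance sigma2 * Q^-1 (J'J) Q^-1 of (beta_hat, gamma_hat).

    Q = J'J + lambda * diag(1 on beta coords) minus, in observed mode, the
    residual-weighted Hessian contraction sum_i r_i * H_i.  Expected mode
    (Q*) drops the Hessian term.  On the identity scale the two coincide.
    """
    if fisher_mode not in ("observed", "expected"):
        raise ValueError("fisher_mode must be 'observed' or 'expected'")
    scale = get_scale(scale)
    H = data.n_cell_types
    M = theta_hat.n_beta
    ev = model_derivatives(theta_hat, data, scale,
                           with_hessian=(fisher_mode == "observed"))
    Jbg = ev.jacobian[:, H:]
    JtJ = Jbg.T @ Jbg
    Q = JtJ.copy()
    Q[np.arange(M), np.arange(M)] += lambda_
    if fisher_mode == "observed":
        resid = np.asarray(y_normalized, dtype=float) - ev.mu
        Q -= np.einsum("i,ijk->jk", resid, ev.hessian_bg)
    singular = False
    try:
        Qinv = np.linalg.inv(Q)
    except np.linalg.LinAlgError:
        Qinv = np.linalg.pinv(Q)
        singular = True
    var = sigma2 * Qinv @ JtJ @ Qinv
    neg = bool(np.any(np.diag(var) < 0))
    return RidgeCovariance(Q=Q, variance=var, fisher_mode=fisher_mode,
                           singular=singular, negative_diagonal=neg)


def ridge_t_test(estimates, covariance: RidgeCovariance, df: int):
    """Non-exact t-type test: estimate / sqrt(Var_ss) referred to t_df.

    Coordinates with nonpositive variance get NaN statistics/p-values.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    est = np.asarray(estimates, dtype=float).ravel()
    v = np.diag(covariance.variance).copy()
    ok = v > 0
    t = np.full(est.shape, np.nan)
    t[ok] = est[ok] / np.sqrt(v[ok])
    p = np.full(est.shape, np.nan)
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df)
    se = np.where(ok, np.sqrt(np.abs(v)), np.nan)
    return t, p, se


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def mse_decomposition(spectrum: RidgeSpectrum, beta_true, sigma2: float,
                      lambda_: float):
    """Bias^2, trace variance and MSE of the ridge estimator at ``lambda_``.

    Per singular direction m: bias factor -lambda/(d_m^2+lambda) on v_m'beta,
    variance sigma2 * d_m^2/(d_m^2+lambda)^2.  Directions with d_m (nearly)
    zero contribute only bias.  MSE = ||Bias||^2 + tr(Var) identically.
    """
    d = np.asarray(spectrum.d, dtype=float)
    d1 = d[0] if d.size else 0.0
    zero = d < _SV_TRUNC * max(d1, 1.0)
    d2 = np.where(zero, 0.0, d**2)
    proj = spectrum.V.T @ np.asarray(beta_true, dtype=float).ravel()
    denom = d2 + lambda_
    with np.errstate(divide="ignore", invalid="ignore"):
        bias_frac = np.where(denom > 0, lambda_ / denom, 0.0)
        var_terms = np.where(~zero, sigma2 * d2 / np.where(denom > 0, denom, 1.0) ** 2,
                             0.0)
        # at lambda = 0 the variance term is sigma2 / d_m^2
        if lambda_ == 0:
            var_terms = np.where(~zero, sigma2 / np.where(zero, 1.0, d2), 0.0)
    bias2 = float(np.sum((bias_frac * proj) ** 2))
    trvar = float(np.sum(var_terms))
    return bias2, trvar, bias2 + trvar
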