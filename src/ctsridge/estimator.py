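"""Per-marker fitting procedures and dataset-level drivers.

The nonlinear ridge fit of one marker follows an 8-step procedure: (1) fit
the basal levels alpha alone by nonlinear OLS (trait effects are assumed
much smaller than basal levels, so this stabilizes the fit) and Wald-test
them; (2) estimate sigma^2 from those residuals with df = n - #alpha;
(3) fit (beta, gamma) by OLS with alpha frozen; (4) take the SVD of the
beta-Jacobian at the OLS solution; (5) compute kappa and the penalty
lambda; (6) refit (beta, gamma) under the ridge penalty, alpha still
frozen; (7) build the sandwich covariance from the ridge-adapted Fisher
matrix; (8) test each coefficient with the non-exact t-type test.

The driver loops markers independently (results do not depend on execution
order), with vectorized whole-dataset shortcuts for the linear full and
marginal baselines whose design matrix is shared across markers.  A linear
fast path for QTL scans residualizes the response once per marker and then
handles each SNP with closed-form linear ridge algebra.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .model import (MarkerFit, OmicsDataset, ParameterVector, _coef_frame,
                    bulk_mean, coefficient_labels, fit_linear_full,
                    fit_linear_marginal, full_design, marginal_design,
                    model_derivatives, rss_and_sigma2)
from .ridge import (DegenerateSigmaError, _levenberg_marquardt, beta_spectrum,
                    kappa_statistic, ridge_covariance, ridge_minimize,
                    ridge_t_test, select_lambda)
from .scales import DomainError, get_scale, normalize

logger = logging.getLogger("ctsridge")

RESULT_COLUMNS = ["marker", "method", "cell_type", "trait", "estimate", "SE",
                  "statistic", "p", "lambda", "kappa", "converged"]

NONLINEAR_METHODS = tuple(
    f"nls.{s}{r}" for s in ("identity", "log", "logit") for r in ("", ".ridge"))
LINEAR_METHODS = ("full", "full.log", "full.logit", "marginal",
                  "marginal.log", "marginal.logit", "marginal.full005")
METHODS = NONLINEAR_METHODS + LINEAR_METHODS


# ---------------------------------------------------------------------------
# 8-step per-marker fit
# ---------------------------------------------------------------------------

def _fit_alpha_only(y, data, scale):
    """Step 1: nonlinear OLS of alpha under beta = gamma = 0."""
    H, K, L = data.n_cell_types, data.n_traits, data.n_covariates
    if scale.name == "identity":
        alpha, *_ = np.linalg.lstsq(data.W, y, rcond=None)
        return alpha, True

    def fun_jac(a):
        th = ParameterVector(a, np.zeros((H, K)), np.zeros(L))
        ev = model_derivatives(th, data, scale, with_hessian=False)
        return y - ev.mu, -ev.jacobian[:, :H]

    a0 = np.full(H, float(np.mean(y)))
    alpha, converged = _levenberg_marquardt(fun_jac, a0)
    return alpha, converged


def _nan_fit(data, marker, method, reason):
    logger.warning("marker %s (%s): fit failed (%s); emitting missing row",
                   marker, method, reason)
    kinds, cts, trs = coefficient_labels(data)
    nan = np.full(len(kinds), np.nan)
    coef = _coef_frame(kinds, cts, trs, nan, nan, nan, nan)
    return MarkerFit(marker=marker, method=method, coef=coef, sigma2=np.nan,
                     df=0, converged=False)


def fit_marker(data: OmicsDataset, marker, scale="logit",
               use_ridge: bool = True, fisher_mode: str = "observed",
               df_mode: str = "basal") -> MarkerFit:
    """Fit one marker by the 8-step nonlinear (ridge) procedure.

    ``use_ridge=False`` stops after the OLS step and tests the unpenalized
    estimates.  ``df_mode`` selects the t-test degrees of freedom:
    ``"basal"`` uses n - #alpha (matching the sigma^2 estimate), ``"total"``
    uses n minus the full parameter count.
    """
    scale = get_scale(scale)
    method = f"nls.{scale.name}" + (".ridge" if use_ridge else "")
    n = data.n_samples
    H, K, L = data.n_cell_types, data.n_traits, data.n_covariates
    M = H * K
    try:
        y = data.y_normalized(marker, scale)
    except DomainError as exc:
        return _nan_fit(data, marker, method, str(exc))

    try:
        # steps 1-2: basal levels and the error variance
        alpha_hat, conv1 = _fit_alpha_only(y, data, scale)
        theta_a = ParameterVector(alpha_hat, np.zeros((H, K)), np.zeros(L))
        ev_a = model_derivatives(theta_a, data, scale, with_hessian=False)
        rss_a, sigma2 = rss_and_sigma2(y, ev_a.mu, H)
        df_sigma = n - H

        Ja = ev_a.jacobian[:, :H]
        JtJa = Ja.T @ Ja
        try:
            cov_alpha = sigma2 * np.linalg.inv(JtJa)
        except np.linalg.LinAlgError:
            cov_alpha = sigma2 * np.linalg.pinv(JtJa)
        se_a = np.sqrt(np.clip(np.diag(cov_alpha), 0, None))
        with np.errstate(divide="ignore", invalid="ignore"):
            t_a = np.where(se_a > 0, alpha_hat / se_a, np.nan)
        p_a = 2.0 * stats.t.sf(np.abs(t_a), df_sigma)

        # step 3: OLS of (beta, gamma) with alpha frozen
        theta0, conv3 = ridge_minimize(theta_a, data, scale, y, 0.0,
                                       frozen_alpha=True)

        lam = None
        kappa = None
        if use_ridge:
            # steps 4-5: spectrum of the beta-Jacobian, kappa, lambda
            ev0 = model_derivatives(theta0, data, scale, with_hessian=False)
            spectrum = beta_spectrum(ev0.jacobian[:, H:H + M])
            try:
                kappa = kappa_statistic(spectrum, theta0.beta.ravel(), sigma2)
                lam = select_lambda(kappa, spectrum.d[0])
            except DegenerateSigmaError:
                logger.warning("marker %s: sigma^2 = 0, using lambda = 0", marker)
                lam = 0.0
            # step 6: ridge refit, warm-started at the OLS solution
            theta_hat, conv6 = ridge_minimize(theta0, data, scale, y, lam,
                                              frozen_alpha=True)
        else:
            theta_hat, conv6 = theta0, True

        # steps 7-8: sandwich covariance and the t-type test
        cov = ridge_covariance(theta_hat, data, scale, y,
                               lam if use_ridge and lam else 0.0, sigma2,
                               fisher_mode=fisher_mode)
        df_test = df_sigma if df_mode == "basal" else n - (H + M + L)
        bg = np.concatenate([theta_hat.beta.ravel(), theta_hat.gamma])
        t_bg, p_bg, se_bg = ridge_t_test(bg, cov, df_test)
    except (DomainError, np.linalg.LinAlgError) as exc:
        return _nan_fit(data, marker, method, str(exc))

    kinds, cts, trs = coefficient_labels(data)
    est = np.concatenate([alpha_hat, bg])
    se = np.concatenate([se_a, se_bg])
    t = np.concatenate([t_a, t_bg])
    p = np.concatenate([p_a, p_bg])
    coef = _coef_frame(kinds, cts, trs, est, se, t, p)
    return MarkerFit(
        marker=marker, method=method, coef=coef, sigma2=sigma2, df=df_sigma,
        lambda_=(lam if use_ridge else None), kappa=kappa,
        converged=bool(conv1 and conv3 and conv6),
        rank_deficient=cov.singular,
    )


# ---------------------------------------------------------------------------
# whole-dataset drivers
# ---------------------------------------------------------------------------

def _batch_ols(D: np.ndarray, Y: np.ndarray):
    """OLS of every row of Y (markers x n) on the shared design D.

    Returns (coef, se, t, p, sigma2, df, rank_deficient); identical to the
    per-marker statsmodels fit, vectorized across markers.
    """
    n, q = D.shape
    rank = np.linalg.matrix_rank(D)
    pinvD = np.linalg.pinv(D)
    coef = Y @ pinvD.T                               # markers x q
    resid = Y - coef @ D.T
    rss = np.sum(resid**2, axis=1)
    df = n - rank
    sigma2 = rss / df
    diag = np.diag(np.linalg.pinv(D.T @ D))
    se = np.sqrt(np.clip(sigma2[:, None] * diag[None, :], 0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, coef / se, np.nan)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return coef, se, t, p, sigma2, df, rank < q


def _response_matrix(data, method):
    """Raw Y or normalized f(Y), marker-wise, per the method label suffix."""
    if method.endswith(".log") or method.endswith(".logit"):
        scale = get_scale(method.rsplit(".", 1)[1])
        return normalize(data.Y, scale, names=data.markers)
    return data.Y


def _rows_from_batch(data, method, cell_types, coef, se, t, p, beta_cols):
    """Tidy beta/alpha/gamma rows from a batch OLS over a shared design."""
    rows = []
    markers = data.markers
    for (h, k), col in beta_cols.items():
        rows.append(pd.DataFrame({
            "marker": markers, "method": method, "cell_type": h, "trait": k,
            "estimate": coef[:, col], "SE": se[:, col],
            "statistic": t[:, col], "p": p[:, col],
            "lambda": np.nan, "kappa": np.nan, "converged": True,
        }))
    return pd.concat(rows, ignore_index=True)


def _fit_dataset_full(data, method):
    D = full_design(data)
    Y = _response_matrix(data, method)
    coef, se, t, p, *_ = _batch_ols(D, Y)
    H, K = data.n_cell_types, data.n_traits
    beta_cols = {(h, k): H + hi * K + ki
                 for hi, h in enumerate(data.cell_types)
                 for ki, k in enumerate(data.traits)}
    return _rows_from_batch(data, method, data.cell_types, coef, se, t, p,
                            beta_cols)


def _fit_dataset_marginal(data, method):
    Y = _response_matrix(data, method)
    H, K = data.n_cell_types, data.n_traits
    out = []
    for h in data.cell_types:
        D = marginal_design(data, h)
        coef, se, t, p, *_ = _batch_ols(D, Y)
        beta_cols = {(h, k): H + ki for ki, k in enumerate(data.traits)}
        out.append(_rows_from_batch(data, method, [h], coef, se, t, p,
                                    beta_cols))
    return pd.concat(out, ignore_index=True)


def _fit_dataset_nls(data, method):
    parts = method.split(".")
    scale = parts[1]
    use_ridge = method.endswith(".ridge")
    rows = []
    n_failed = 0
    for marker in data.markers:
        fit = fit_marker(data, marker, scale=scale, use_ridge=use_ridge)
        n_failed += not fit.converged
        tab = fit.beta_table()
        rows.append(pd.DataFrame({
            "marker": marker, "method": method,
            "cell_type": tab["cell_type"].to_numpy(),
            "trait": tab["trait"].to_numpy(),
            "estimate": tab["estimate"].to_numpy(),
            "SE": tab["se"].to_numpy(),
            "statistic": tab["statistic"].to_numpy(),
            "p": tab["p"].to_numpy(),
            "lambda": fit.lambda_ if fit.lambda_ is not None else np.nan,
            "kappa": fit.kappa if fit.kappa is not None else np.nan,
            "converged": fit.converged,
        }))
    if n_failed:
        logger.warning("%s: %d/%d markers flagged non-converged/failed",
                       method, n_failed, data.n_markers)
    return pd.concat(rows, ignore_index=True)


def fit_dataset(data: OmicsDataset, method: str) -> pd.DataFrame:
    """Fit every marker under one method; one row per beta coefficient.

    Markers are processed independently, so the output is invariant to
    processing order (rows are emitted in dataset marker order).  Linear
    full/marginal methods share one design matrix across markers and are
    computed in a single vectorized pass.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    if method == "marginal.full005":
        return _fit_dataset_hybrid(data)
    if method.startswith("full"):
        out = _fit_dataset_full(data, method)
    elif method.startswith("marginal"):
        out = _fit_dataset_marginal(data, method)
    else:
        out = _fit_dataset_nls(data, method)
    return out[RESULT_COLUMNS]


# ---------------------------------------------------------------------------
# hybrid marginal/full caller
# ---------------------------------------------------------------------------

def hybrid_z(marginal_estimate, marginal_p, full_estimate, full_p,
             alpha_level: float = 0.05):
    """Z-score of the hybrid caller for one (marker, cell type, trait).

    The marginal Z (recovered from the two-sided p and the effect sign) is
    retained only when the marginal and full effect directions agree and the
    full-model coefficient has p below ``alpha_level``; otherwise Z = 0.
    Zero estimates carry no direction and count as disagreement.  Missing
    inputs give a missing Z.
    """
    me = np.asarray(marginal_estimate, dtype=float)
    mp = np.asarray(marginal_p, dtype=float)
    fe = np.asarray(full_estimate, dtype=float)
    fp = np.asarray(full_p, dtype=float)
    missing = ~(np.isfinite(me) & np.isfinite(mp) & np.isfinite(fe)
                & np.isfinite(fp))
    sign = np.sign(me)
    z_marg = sign * stats.norm.isf(np.clip(mp, 1e-320, 1.0) / 2.0)
    keep = (sign != 0) & (np.sign(fe) == sign) & (fp < alpha_level)
    z = np.where(keep, z_marg, 0.0)
    return np.where(missing, np.nan, z)


def hybrid_marginal_full(marginal_fits, full_fit, alpha_level: float = 0.05):
    """Hybrid z per (cell type, trait) from per-cell-type marginal fits and
    one full fit of the same marker (MarkerFit inputs)."""
    out = {}
    for h, mfit in marginal_fits.items():
        for _, row in mfit.beta_table().iterrows():
            frow = full_fit.beta_row(h, row["trait"])
            z = hybrid_z(row["estimate"], row["p"],
                         frow["estimate"], frow["p"], alpha_level)
            out[(h, row["trait"])] = float(z)
    return out


def _fit_dataset_hybrid(data, alpha_level: float = 0.05):
    marg = _fit_dataset_marginal(data, "marginal")
    full = _fit_dataset_full(data, "full")
    key = ["marker", "cell_type", "trait"]
    merged = marg.merge(full[key + ["estimate", "p"]], on=key,
                        suffixes=("", "_full"))
    z = hybrid_z(merged["estimate"], merged["p"],
                 merged["estimate_full"], merged["p_full"], alpha_level)
    p = 2.0 * stats.norm.sf(np.abs(z))  # z = 0 maps to p = 1
    out = merged[key].copy()
    out["method"] = "marginal.full005"
    out["estimate"] = np.where(z != 0, merged["estimate"], 0.0)
    out["SE"] = np.nan
    out["statistic"] = z
    out["p"] = p
    out["lambda"] = np.nan
    out["kappa"] = np.nan
    out["converged"] = True
    return out[RESULT_COLUMNS]


# ---------------------------------------------------------------------------
# QTL fast path
# ---------------------------------------------------------------------------

def qtl_fast_fit(data: OmicsDataset, genotypes, snp_names=None,
                 scale="identity", fisher_mode: str = "expected") -> pd.DataFrame:
    """Rounds-of-linear-regression shortcut for QTL scans.

    Per marker, alpha and gamma are fit once by OLS of f(Y) on [W | C] under
    beta = 0, and the residuals replace the response.  Per SNP (centered
    genotypes as the trait), beta is fit by OLS on the interaction design
    W * x, the penalty is chosen from the spectrum/kappa rule, and beta(lam)
    with its t-test comes from closed-form linear ridge.  Monomorphic SNPs
    yield missing rows.
    """
    scale = get_scale(scale)
    if isinstance(genotypes, pd.DataFrame):
        snp_names = list(genotypes.index)
        G = genotypes.to_numpy(dtype=float)
    else:
        G = np.atleast_2d(np.asarray(genotypes, dtype=float))
        if snp_names is None:
            snp_names = [f"snp{i}" for i in range(G.shape[0])]
    n = data.n_samples
    if G.shape[1] != n:
        raise ValueError("genotypes must be SNPs x samples, aligned to Y")
    H, L = data.n_cell_types, data.n_covariates

    Ynorm = normalize(data.Y, scale, names=data.markers)
    D0 = np.hstack([data.W, data.C])
    pinv0 = np.linalg.pinv(D0)
    R = Ynorm - (Ynorm @ pinv0.T) @ D0.T             # markers x n residuals
    df = n - np.linalg.matrix_rank(D0)
    sigma2 = np.sum(R**2, axis=1) / df               # per marker

    frames = []
    for s, name in enumerate(snp_names):
        x = G[s] - G[s].mean()
        if np.allclose(x, 0.0):
            logger.warning("SNP %s is monomorphic; emitting missing rows", name)
            frames.append(pd.DataFrame({
                "snp": name, "marker": data.markers, "method": "qtl.ridge",
                "cell_type": [data.cell_types] * data.n_markers,
                "estimate": np.nan, "SE": np.nan, "statistic": np.nan,
                "p": np.nan, "lambda": np.nan, "kappa": np.nan,
                "converged": False,
            }).explode("cell_type"))
            continue
        Ds = data.W * x[:, None]                     # n x H interaction design
        spec = beta_spectrum(Ds)
        d2 = spec.d**2
        B0 = R @ np.linalg.pinv(Ds).T                # markers x H OLS betas
        proj = B0 @ spec.V                           # markers x H, v_m' beta
        with np.errstate(divide="ignore", invalid="ignore"):
            kap = np.sum(d2[None, :] * proj**2 / sigma2[:, None] - 1.0,
                         axis=1) / np.sum(d2)
        lam = np.where(kap > 0, 1.0 / np.where(kap > 0, kap, 1.0), d2[0])
        # closed-form linear ridge in the V basis, per-marker lambda
        c = proj * d2[None, :]                       # V' Ds' r
        denom = d2[None, :] + lam[:, None]
        Blam = (c / denom) @ spec.V.T                # markers x H
        var = sigma2[:, None] * ((spec.V**2) @
                                 (d2[None, :] / denom**2).T).T
        se = np.sqrt(np.clip(var, 0, None))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, Blam / se, np.nan)
        p = 2.0 * stats.t.sf(np.abs(t), df)
        frames.append(pd.DataFrame({
            "snp": np.repeat(name, data.n_markers * H),
            "marker": np.repeat(data.markers, H),
            "method": "qtl.ridge",
            "cell_type": np.tile(data.cell_types, data.n_markers),
            "estimate": Blam.ravel(), "SE": se.ravel(),
            "statistic": t.ravel(), "p": p.ravel(),
            "lambda": np.repeat(lam, H), "kappa": np.repeat(kap, H),
            "converged": True,
        }))
    return pd.concat(frames, ignore_index=True)
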