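"""Mean models for bulk omics with heterogeneous cell types.

A bulk measurement is a composition-weighted mixture of cell-type-specific
levels.  On the normalized scale the mean for sample ``i`` is

    mu_i = f( sum_h W_{h,i} g( alpha_h + sum_k beta_{h,k} X_{i,k} ) )
           + sum_l gamma_l C_{i,l}

with f/g a normalizing scale pair, W the cell-type composition, X the
centered trait(s) with cell-type-specific effects and C the centered
tissue-uniform covariates.  With the identity scale this collapses to the
classical *full* linear interaction model

    Y_i = sum_h alpha_h W_{h,i} + sum_{h,k} beta_{h,k} W_{h,i} X_{i,k}
          + sum_l gamma_l C_{i,l} + eps_i

and the *marginal* model keeps the interaction terms of a single tested cell
type.  This module holds the data container, the nonlinear mean and its
analytic derivatives, and the two linear baselines with Wald tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .scales import NormalizingScale, get_scale, normalize

logger = logging.getLogger("ctsridge")


class DegreesOfFreedomError(ValueError):
    """Raised when a fit has no residual degrees of freedom."""


class AlignmentError(ValueError):
    """Raised when input matrices do not share the sample axis."""


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

@dataclass
class OmicsDataset:
    """Aligned bulk omics matrices.

    Orientation convention (fixed throughout the package): ``Y`` is
    markers x samples on the linear scale, ``W`` is samples x cell types,
    ``X`` and ``C`` are samples x columns.  ``X`` and ``C`` are mean-centered
    at construction; the removed offsets are recorded.
    """

    Y: np.ndarray
    W: np.ndarray
    X: np.ndarray
    C: np.ndarray
    markers: list
    samples: list
    cell_types: list
    traits: list
    covariates: list
    trait_offsets: np.ndarray = field(default=None)
    covariate_offsets: np.ndarray = field(default=None)

    def __post_init__(self):
        self.Y = np.asarray(self.Y, dtype=float)
        self.W = np.asarray(self.W, dtype=float)
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.C = np.asarray(self.C, dtype=float).reshape(self.W.shape[0], -1)
        n = self.W.shape[0]
        if self.Y.shape[1] != n or self.X.shape[0] != n or self.C.shape[0] != n:
            raise AlignmentError(
                f"sample axis mismatch: Y has {self.Y.shape[1]} samples, "
                f"W {self.W.shape[0]}, X {self.X.shape[0]}, C {self.C.shape[0]}"
            )
        if np.any(self.W < 0):
            raise ValueError("composition entries must be nonnegative")
        rowsum = self.W.sum(axis=1)
        tol = 0.05
        if np.any(np.abs(rowsum - 1.0) > tol):
            logger.warning(
                "composition rows of %d sample(s) sum outside [%.2f, %.2f]",
                int(np.sum(np.abs(rowsum - 1.0) > tol)), 1 - tol, 1 + tol,
            )
        # center traits and covariates (Eq. for X assumes zero column means)
        if self.trait_offsets is None:
            self.trait_offsets = self.X.mean(axis=0)
            self.X = self.X - self.trait_offsets
        if self.covariate_offsets is None:
            self.covariate_offsets = (self.C.mean(axis=0)
                                      if self.C.size else np.zeros(0))
            if self.C.size:
                self.C = self.C - self.covariate_offsets

    # -- construction ---------------------------------------------------------

    @classmethod
    def from_frames(cls, expression: pd.DataFrame, composition: pd.DataFrame,
                    traits: pd.DataFrame,
                    covariates: Optional[pd.DataFrame] = None) -> "OmicsDataset":
        """Build from pandas frames, aligning everything on sample names.

        ``expression`` is markers x samples; the other frames are
        samples x columns.
        """
        samples = list(expression.columns)
        for name, frame in (("composition", composition), ("traits", traits),
                            ("covariates", covariates)):
            if frame is None:
                continue
            missing = [s for s in samples if s not in frame.index]
            if missing:
                raise AlignmentError(
                    f"sample(s) {missing[:5]} present in expression but "
                    f"missing from {name}")
        composition = composition.loc[samples]
        traits = traits.loc[samples]
        if covariates is not None:
            covariates = covariates.loc[samples]
            C = covariates.to_numpy(dtype=float)
            cov_names = list(covariates.columns)
        else:
            C = np.zeros((len(samples), 0))
            cov_names = []
        return cls(
            Y=expression.to_numpy(dtype=float),
            W=composition.to_numpy(dtype=float),
            X=traits.to_numpy(dtype=float),
            C=C,
            markers=list(expression.index),
            samples=samples,
            cell_types=list(composition.columns),
            traits=list(traits.columns),
            covariates=cov_names,
        )

    # -- shape helpers --------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.W.shape[0]

    @property
    def n_markers(self) -> int:
        return self.Y.shape[0]

    @property
    def n_cell_types(self) -> int:
        return self.W.shape[1]

    @property
    def n_traits(self) -> int:
        return self.X.shape[1]

    @property
    def n_covariates(self) -> int:
        return self.C.shape[1]

    def marker_index(self, marker) -> int:
        try:
            return self.markers.index(marker)
        except ValueError:
            raise KeyError(f"unknown marker {marker!r}") from None

    def y(self, marker) -> np.ndarray:
        """Linear-scale expression row for one marker."""
        return self.Y[self.marker_index(marker)]

    def y_normalized(self, marker, scale) -> np.ndarray:
        return normalize(self.y(marker), scale, names=self.samples)


@dataclass
class ParameterVector:
    """Parameters (alpha per cell type, beta per cell type x trait, gamma
    per covariate) for one marker, on the normalized scale.

    Flattening order is fixed everywhere (alpha block, then beta cell-type
    major / trait minor, then gamma); the ridge penalty and the SVD act on
    the beta block in this order.
    """

    alpha: np.ndarray
    beta: np.ndarray  # shape (H, K)
    gamma: np.ndarray

    def __post_init__(self):
        self.alpha = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        self.beta = np.asarray(self.beta, dtype=float).reshape(len(self.alpha), -1)
        self.gamma = np.atleast_1d(np.asarray(self.gamma, dtype=float))

    @property
    def n_beta(self) -> int:
        """M = H*K, the number of penalized coefficients."""
        return self.beta.size

    @property
    def n_total(self) -> int:
        return self.alpha.size + self.beta.size + self.gamma.size

    def flatten(self) -> np.ndarray:
        return np.concatenate([self.alpha, self.beta.ravel(), self.gamma])

    @classmethod
    def from_flat(cls, flat, n_cell_types: int, n_traits: int,
                  n_covariates: int) -> "ParameterVector":
        flat = np.asarray(flat, dtype=float)
        H, K, L = n_cell_types, n_traits, n_covariates
        if flat.size != H + H * K + L:
            raise ValueError("flat parameter vector has wrong length")
        return cls(alpha=flat[:H],
                   beta=flat[H:H + H * K].reshape(H, K),
                   gamma=flat[H + H * K:])

    @classmethod
    def zeros(cls, n_cell_types, n_traits, n_covariates) -> "ParameterVector":
        return cls(np.zeros(n_cell_types),
                   np.zeros((n_cell_types, n_traits)),
                   np.zeros(n_covariates))


@dataclass
class ModelEvaluation:
    """Mean vector, Jacobian, and the (beta, gamma)-block Hessian array."""

    mu: np.ndarray           # (n,)
    jacobian: np.ndarray     # (n, H + M + L), parameter order as flattened
    hessian_bg: np.ndarray   # (n, M + L, M + L); gamma rows/cols are zero


@dataclass
class MarkerFit:
    """Estimates and tests for one marker under one method.

    ``coef`` has one row per coefficient with columns
    (kind, cell_type, trait, estimate, se, statistic, p).
    """

    marker: object
    method: str
    coef: pd.DataFrame
    sigma2: float
    df: int
    lambda_: Optional[float] = None
    kappa: Optional[float] = None
    converged: bool = True
    rank_deficient: bool = False
    clipped_inputs: bool = False

    def beta_table(self) -> pd.DataFrame:
        return self.coef[self.coef["kind"] == "beta"]

    def beta_row(self, cell_type, trait=None):
        tab = self.beta_table()
        sel = tab["cell_type"] == cell_type
        if trait is not None:
            sel &= tab["trait"] == trait
        rows = tab[sel]
        if len(rows) != 1:
            raise KeyError(f"no unique beta coefficient for {cell_type!r}/{trait!r}")
        return rows.iloc[0]


def _coef_frame(kinds, cell_types, traits, estimate, se, statistic, p):
    return pd.DataFrame({
        "kind": kinds, "cell_type": cell_types, "trait": traits,
        "estimate": estimate, "se": se, "statistic": statistic, "p": p,
    })


def coefficient_labels(data: OmicsDataset):
    """(kind, cell_type, trait) labels in flattened parameter order."""
    kinds, cts, trs = [], [], []
    for h in data.cell_types:
        kinds.append("alpha"); cts.append(h); trs.append(None)
    for h in data.cell_types:
        for k in data.traits:
            kinds.append("beta"); cts.append(h); trs.append(k)
    for l in data.covariates:
        kinds.append("gamma"); cts.append(None); trs.append(l)
    return kinds, cts, trs


# ---------------------------------------------------------------------------
# nonlinear mean model
# ---------------------------------------------------------------------------

def _mixture(theta: ParameterVector, data: OmicsDataset, scale: NormalizingScale):
    """Return (eta, S): cell-type normalized levels and their linear mix."""
    eta = theta.alpha[None, :] + data.X @ theta.beta.T          # (n, H)
    S = np.sum(data.W * scale.g(eta), axis=1)                   # (n,)
    return eta, S


def _check_mixture_domain(S, scale):
    lo, hi = scale.valid_domain
    if np.any(S <= lo) or np.any(S >= hi):
        from .scales import DomainError
        raise DomainError(
            f"mixture mean leaves the open {scale.name} domain; "
            "marker is not evaluable at these parameters")


def bulk_mean(theta: ParameterVector, data: OmicsDataset, scale) -> np.ndarray:
    """Normalized-scale mean mu_i of the bulk level for every sample."""
    scale = get_scale(scale)
    eta, S = _mixture(theta, data, scale)
    if scale.name != "identity":
        _check_mixture_domain(S, scale)
    mu = scale.f(S)
    if theta.gamma.size:
        mu = mu + data.C @ theta.gamma
    return mu


def model_derivatives(theta: ParameterVector, data: OmicsDataset,
                      scale, with_hessian: bool = True) -> ModelEvaluation:
    """Analytic Jacobian d mu/d theta and (beta, gamma)-block Hessian.

    gamma enters additively, so its Hessian rows/columns vanish; on the
    identity scale the whole Hessian is zero and the beta columns of the
    Jacobian reduce to the interaction terms W_h X_k.  ``with_hessian=False``
    skips the Hessian (``hessian_bg`` is ``None``); the optimizer only needs
    the Jacobian.
    """
    scale = get_scale(scale)
    n, H = data.W.shape
    K, L = data.n_traits, data.n_covariates
    M = H * K
    eta, S = _mixture(theta, data, scale)
    if scale.name != "identity":
        _check_mixture_domain(S, scale)
    mu = scale.f(S)
    if theta.gamma.size:
        mu = mu + data.C @ theta.gamma

    fp = scale.f_prime(S)                       # (n,)
    gp = scale.g_prime(eta)                     # (n, H)
    A = fp[:, None] * data.W * gp               # d mu / d alpha_h, (n, H)

    jac = np.empty((n, H + M + L))
    jac[:, :H] = A
    jac[:, H:H + M] = np.einsum("ih,ik->ihk", A, data.X).reshape(n, M)
    jac[:, H + M:] = data.C

    if not with_hessian:
        return ModelEvaluation(mu=mu, jacobian=jac, hessian_bg=None)

    # Hessian of mu w.r.t. (beta, gamma): only the beta block is nonzero.
    hess = np.zeros((n, M + L, M + L))
    if scale.name != "identity":
        fpp = scale.f_double_prime(S)
        gpp = scale.g_double_prime(eta)
        B = data.W * gp                          # (n, H)
        # d2 mu / d eta_h d eta_h' = fpp * B_h * B_h' + delta_hh' * fp * W_h * gpp_h
        Heta = fpp[:, None, None] * B[:, :, None] * B[:, None, :]
        diag = fp[:, None] * data.W * gpp
        ii = np.arange(H)
        Heta[:, ii, ii] += diag
        hb = np.einsum("ihg,ik,il->ihkgl", Heta, data.X, data.X)
        hess[:, :M, :M] = hb.reshape(n, M, M)
    return ModelEvaluation(mu=mu, jacobian=jac, hessian_bg=hess)


def rss_and_sigma2(y_normalized, mu, p: int):
    """Residual sum of squares and the unbiased error-variance estimate
    sigma2 = RSS / (n - p)."""
    y_normalized = np.asarray(y_normalized, dtype=float)
    mu = np.asarray(mu, dtype=float)
    n = y_normalized.size
    if n <= p:
        raise DegreesOfFreedomError(f"n={n} samples but p={p} parameters")
    rss = float(np.sum((y_normalized - mu) ** 2))
    return rss, rss / (n - p)


# ---------------------------------------------------------------------------
# linear baselines
# ---------------------------------------------------------------------------

def _ols_marker_fit(data, marker, D, labels, method, normalized_input, scale):
    scale = get_scale(scale)
    if normalized_input:
        y = data.y_normalized(marker, scale)
    else:
        y = data.y(marker)
    rank = np.linalg.matrix_rank(D)
    res = sm.OLS(y, D).fit()
    kinds, cts, trs = labels
    coef = _coef_frame(kinds, cts, trs, res.params, res.bse,
                       res.tvalues, res.pvalues)
    rank_def = rank < D.shape[1]
    if rank_def:
        logger.warning("marker %s: rank-deficient design (%d < %d)",
                       marker, rank, D.shape[1])
    return MarkerFit(
        marker=marker, method=method, coef=coef,
        sigma2=float(res.scale), df=int(res.df_resid),
        rank_deficient=rank_def,
    )


def full_design(data: OmicsDataset) -> np.ndarray:
    """[W | W*X interactions (cell-type major) | C]; no extra intercept —
    the alpha*W columns play that role."""
    n, H = data.W.shape
    inter = np.einsum("ih,ik->ihk", data.W, data.X).reshape(n, -1)
    return np.hstack([data.W, inter, data.C])


def marginal_design(data: OmicsDataset, cell_type) -> np.ndarray:
    """[W (all cell types) | W_h * X for the tested cell type only | C]."""
    h = data.cell_types.index(cell_type)
    inter = data.W[:, [h]] * data.X
    return np.hstack([data.W, inter, data.C])


def fit_linear_full(data: OmicsDataset, marker, normalized_input=False,
                    scale="identity") -> MarkerFit:
    """Full linear interaction model with per-coefficient Wald t-tests.

    With ``normalized_input`` the response is f(Y) (e.g. the M-value
    variant); otherwise raw linear-scale Y.
    """
    D = full_design(data)
    method = "full" + (f".{get_scale(scale).name}" if normalized_input else "")
    return _ols_marker_fit(data, marker, D, coefficient_labels(data),
                           method, normalized_input, scale)


def fit_linear_marginal(data: OmicsDataset, marker, cell_type,
                        normalized_input=False, scale="identity") -> MarkerFit:
    """Marginal linear model: all basal-level columns but interaction terms
    for one tested cell type only."""
    D = marginal_design(data, cell_type)
    kinds, cts, trs = [], [], []
    for h in data.cell_types:
        kinds.append("alpha"); cts.append(h); trs.append(None)
    for k in data.traits:
        kinds.append("beta"); cts.append(cell_type); trs.append(k)
    for l in data.covariates:
        kinds.append("gamma"); cts.append(None); trs.append(l)
    method = "marginal" + (f".{get_scale(scale).name}" if normalized_input else "")
    return _ols_marker_fit(data, marker, D, (kinds, cts, trs),
                           method, normalized_input, scale)
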