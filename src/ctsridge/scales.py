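"""Normalizing scales for bulk omics analysis.

Methylation beta-values live in (0, 1) and are analyzed on the logit scale
(M-values); expression levels live in (0, inf) and are analyzed on the log
scale; conventional linear analysis corresponds to the identity scale.  A
scale is a pair of maps: ``f`` from the linear (measurement) scale to the
normalized (analysis) scale, and its inverse ``g``.  The nonlinear mean model
needs ``g`` together with its first two derivatives, and the variance
formulas additionally need the derivatives of ``f``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger("ctsridge")

# exp() overflows float64 near 709; saturating the argument keeps g finite
# while preserving monotonicity.  Markers that hit the guard are flagged
# upstream.
_EXP_GUARD = 700.0


class DomainError(ValueError):
    """Raised when linear-scale values fall outside a scale's domain."""


@dataclass(frozen=True)
class NormalizingScale:
    """One of the identity / log / logit normalizing transformations.

    ``f`` maps linear-scale values to the normalized scale, ``g`` is its
    inverse.  ``clip_epsilon`` is the slack allowed when pulling inputs onto
    the open domain (beta-values of exactly 0 or 1 occur in real arrays).
    """

    name: str
    clip_epsilon: float = 1e-6

    def __post_init__(self):
        if self.name not in ("identity", "log", "logit"):
            raise ValueError(f"unknown scale {self.name!r}")

    # -- linear -> normalized -------------------------------------------------

    def f(self, y):
        y = np.asarray(y, dtype=float)
        if self.name == "identity":
            return y
        if self.name == "log":
            return np.log(y)
        return np.log(y) - np.log1p(-y)  # logit

    def f_prime(self, y):
        y = np.asarray(y, dtype=float)
        if self.name == "identity":
            return np.ones_like(y)
        if self.name == "log":
            return 1.0 / y
        return 1.0 / (y * (1.0 - y))

    def f_double_prime(self, y):
        y = np.asarray(y, dtype=float)
        if self.name == "identity":
            return np.zeros_like(y)
        if self.name == "log":
            return -1.0 / y**2
        return (2.0 * y - 1.0) / (y * (1.0 - y)) ** 2

    # -- normalized -> linear -------------------------------------------------

    def g(self, x):
        x = np.asarray(x, dtype=float)
        if self.name == "identity":
            return x
        if self.name == "log":
            return np.exp(np.minimum(x, _EXP_GUARD))
        # logistic, numerically stable in both tails
        xc = np.clip(x, -_EXP_GUARD, _EXP_GUARD)
        out = np.empty_like(xc)
        pos = xc >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-xc[pos]))
        ex = np.exp(xc[~pos])
        out[~pos] = ex / (1.0 + ex)
        return out

    def g_prime(self, x):
        x = np.asarray(x, dtype=float)
        if self.name == "identity":
            return np.ones_like(x)
        if self.name == "log":
            return np.exp(np.minimum(x, _EXP_GUARD))
        p = self.g(x)
        return p * (1.0 - p)

    def g_double_prime(self, x):
        x = np.asarray(x, dtype=float)
        if self.name == "identity":
            return np.zeros_like(x)
        if self.name == "log":
            return np.exp(np.minimum(x, _EXP_GUARD))
        p = self.g(x)
        return p * (1.0 - p) * (1.0 - 2.0 * p)

    # -- domain ---------------------------------------------------------------

    @property
    def valid_domain(self):
        """Open interval of admissible linear-scale inputs."""
        if self.name == "identity":
            return (-np.inf, np.inf)
        if self.name == "log":
            return (0.0, np.inf)
        return (0.0, 1.0)


_REGISTRY = {name: NormalizingScale(name) for name in ("identity", "log", "logit")}


def get_scale(scale) -> NormalizingScale:
    """Resolve a scale name or pass a NormalizingScale through."""
    if isinstance(scale, NormalizingScale):
        return scale
    try:
        return _REGISTRY[scale]
    except KeyError:
        raise ValueError(f"unknown scale {scale!r}") from None


def normalize(values, scale, names=None):
    """Apply f element-wise after clipping into the open domain.

    Values outside the domain by at most ``clip_epsilon`` are clipped (the
    count is logged); larger violations raise :class:`DomainError` naming the
    offending entries via ``names`` when given.
    """
    scale = get_scale(scale)
    values = np.asarray(values, dtype=float)
    lo, hi = scale.valid_domain
    eps = scale.clip_epsilon
    bad = (values < lo - eps) | (values > hi + eps) | ~np.isfinite(values)
    if np.any(bad):
        idx = np.argwhere(bad)[:5]
        labels = [str(tuple(i)) if names is None else str(names[i[0]]) for i in idx]
        raise DomainError(
            f"{bad.sum()} value(s) outside the {scale.name} domain "
            f"({lo}, {hi}) beyond clip tolerance {eps}; first offenders: {labels}"
        )
    if scale.name == "identity":
        return scale.f(values)
    # pull boundary/near-boundary values strictly inside the open interval
    lo_open = lo + eps if np.isfinite(lo) else -np.inf
    hi_open = hi - eps if np.isfinite(hi) else np.inf
    clipped = np.clip(values, lo_open, hi_open)
    n_clip = int(np.sum(clipped != values))
    if n_clip:
        logger.info("normalize(%s): clipped %d value(s) into the open domain",
                    scale.name, n_clip)
    return scale.f(clipped)


def scale_derivatives(x, scale):
    """Return ``(g(x), g'(x), g''(x))`` element-wise on the normalized scale."""
    scale = get_scale(scale)
    x = np.asarray(x, dtype=float)
    return scale.g(x), scale.g_prime(x), scale.g_double_prime(x)
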