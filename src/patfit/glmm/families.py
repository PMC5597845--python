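"""Observation families: log-likelihoods and eta-derivatives.

Each family exposes ``loglik(y, eta)``, ``d1(y, eta)`` and ``d2(y, eta)``
(first/second derivative of the per-observation log likelihood with respect
to the linear predictor), which is all the quadrature engine and the Newton
mode-finder need.  ``mean(eta)`` maps to the response scale.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln

from .links import cauchit_link, logistic


def hurdle_poisson_logpmf(y, pi0, lam):
    """Log pmf of the hurdle-Poisson: P(0) = pi0, positives zero-truncated.

    P(k>=1) = (1 - pi0) * Poisson(k; lam) / (1 - exp(-lam)); computed in log
    space so large rates do not overflow.
    """
    y = np.asarray(y)
    if np.any(y < 0):
        raise ValueError("counts must be non-negative")
    pi0 = np.asarray(pi0, dtype=float)
    lam = np.asarray(lam, dtype=float)
    if np.any((pi0 <= 0) | (pi0 >= 1)) or np.any(lam <= 0):
        raise ValueError("require pi0 in (0,1) and lam > 0")
    log_trunc = _log1mexp(lam)  # log(1 - e^{-lam})
    pos = (
        np.log1p(-pi0)
        + y * np.log(lam)
        - lam
        - gammaln(y + 1.0)
        - log_trunc
    )
    return np.where(y == 0, np.log(pi0), pos)


def _log1mexp(lam):
    """log(1 - exp(-lam)) for lam > 0, stable for both tails."""
    lam = np.asarray(lam, dtype=float)
    small = lam < 0.693
    out = np.empty_like(lam)
    out[small] = np.log(-np.expm1(-lam[small]))
    out[~small] = np.log1p(-np.exp(-lam[~small]))
    return out


class PoissonLog:
    name = "poisson_log"

    @staticmethod
    def loglik(y, eta):
        return y * eta - np.exp(eta) - gammaln(y + 1.0)

    @staticmethod
    def d1(y, eta):
        return y - np.exp(eta)

    @staticmethod
    def d2(y, eta):
        return -np.exp(eta)

    @staticmethod
    def mean(eta):
        return np.exp(eta)


class ZTPoissonLog:
    """Zero-truncated Poisson with a log link (count part of the hurdle)."""

    name = "ztpoisson_log"

    @staticmethod
    def loglik(y, eta):
        lam = np.exp(eta)
        return y * eta - lam - gammaln(y + 1.0) - _log1mexp(lam)

    @staticmethod
    def d1(y, eta):
        lam = np.exp(eta)
        # y - lam / (1 - e^{-lam}); the ratio -> 1 as lam -> 0
        ratio = lam / -np.expm1(-lam)
        return y - ratio

    @staticmethod
    def d2(y, eta):
        lam = np.exp(eta)
        em = -np.expm1(-lam)  # 1 - e^{-lam}
        ratio = lam / em
        # d(ratio)/deta = ratio * (1 - lam * e^{-lam} / em)
        return -ratio * (1.0 - (lam * np.exp(-lam)) / em)

    @staticmethod
    def mean(eta):
        lam = np.exp(eta)
        return lam / -np.expm1(-lam)


class BernoulliLogit:
    name = "bernoulli_logit"

    @staticmethod
    def loglik(y, eta):
        # y*eta - log(1 + e^eta), stable
        return y * eta - np.logaddexp(0.0, eta)

    @staticmethod
    def d1(y, eta):
        return y - logistic(eta)

    @staticmethod
    def d2(y, eta):
        p = logistic(eta)
        return -p * (1.0 - p)

    @staticmethod
    def mean(eta):
        return logistic(eta)


class BernoulliCauchit:
    """Bernoulli with a cauchit link.

    Not log-concave in eta; the mode-finder uses damped Newton steps.
    """

    name = "bernoulli_cauchit"

    @staticmethod
    def loglik(y, eta):
        p = cauchit_link(eta)
        p = np.clip(p, 1e-300, 1.0 - 1e-16)
        return np.where(y == 1, np.log(p), np.log1p(-p))

    @staticmethod
    def d1(y, eta):
        p = cauchit_link(eta)
        d = 1.0 / (np.pi * (1.0 + eta**2))
        p = np.clip(p, 1e-12, 1.0 - 1e-12)
        return np.where(y == 1, d / p, -d / (1.0 - p))

    @staticmethod
    def d2(y, eta):
        p = np.clip(cauchit_link(eta), 1e-12, 1.0 - 1e-12)
        d = 1.0 / (np.pi * (1.0 + eta**2))
        dprime = -2.0 * eta / (np.pi * (1.0 + eta**2) ** 2)
        term1 = np.where(y == 1, -(d / p) ** 2, -(d / (1.0 - p)) ** 2)
        term2 = np.where(y == 1, dprime / p, -dprime / (1.0 - p))
        return term1 + term2

    @staticmethod
    def mean(eta):
        return cauchit_link(eta)


class NormalIdentity:
    """Gaussian outcome with unit residual variance (profiled externally)."""

    name = "normal_identity"

    @staticmethod
    def loglik(y, eta):
        return -0.5 * (y - eta) ** 2 - 0.5 * np.log(2.0 * np.pi)

    @staticmethod
    def d1(y, eta):
        return y - eta

    @staticmethod
    def d2(y, eta):
        return -np.ones_like(np.asarray(eta, dtype=float))

    @staticmethod
    def mean(eta):
        return eta


FAMILIES = {
    f.name: f
    for f in (PoissonLog, ZTPoissonLog, BernoulliLogit, BernoulliCauchit, NormalIdentity)
}


def get_family(name: str):
    try:
        return FAMILIES[name]
    except KeyError:
        raise ValueError(f"unknown family {name!r}; known: {sorted(FAMILIES)}") from None
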