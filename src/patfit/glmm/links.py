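"""Link functions.

The cauchit link is the inverse of the standard Cauchy cdf.  Its tails are
much heavier than the logit's, so extreme linear predictors translate into
probabilities that approach 0/1 only slowly — single outlying observations
pull the fit around far less than under a logit link.
"""

from __future__ import annotations

import numpy as np


def cauchit_link(eta):
    """Standard Cauchy cdf: eta -> p = 1/2 + arctan(eta)/pi."""
    return 0.5 + np.arctan(eta) / np.pi


def cauchit_inverse(p):
    """Standard Cauchy quantile: p in (0,1) -> eta; signals at the boundary."""
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError("cauchit inverse is unbounded at p = 0 or 1")
    return np.tan(np.pi * (p - 0.5))


def logistic(eta):
    eta = np.asarray(eta, dtype=float)
    out = np.empty_like(eta)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    ex = np.exp(eta[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out
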