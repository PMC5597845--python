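"""Low-rank penalized-smooth basis for the nonlinear paternal-age term.

A natural cubic regression basis on quantile knots, with the span of
``{1, x}`` regressed out of every column so the smooth is identifiable
alongside the model's intercept and linear age term.  The residualization
coefficients are estimated on the fitting data and stored, so the basis can
be evaluated at new ages (marginal-effect curves).
"""

from __future__ import annotations

import numpy as np


class SplineError(ValueError):
    pass


def _natural_cubic_raw(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """df = len(knots) - 2 natural-cubic basis columns (beyond 1 and x)."""
    K = len(knots)
    xK, xK1 = knots[-1], knots[-2]

    def d(k):
        num = np.clip(x - knots[k], 0, None) ** 3 - np.clip(x - xK, 0, None) ** 3
        return num / (xK - knots[k])

    dK1 = d(K - 2)
    return np.column_stack([d(k) - dK1 for k in range(K - 2)])


class SplineBasis:
    """Centered natural-cubic basis fitted on a vector of ages."""

    def __init__(self, x, df: int = 8):
        x = np.asarray(x, dtype=float)
        if df < 3:
            raise SplineError("spline df must be >= 3")
        uniq = np.unique(x)
        if len(uniq) < df + 2:
            raise SplineError(
                f"need at least df+2={df + 2} distinct ages, got {len(uniq)}"
            )
        self.df = df
        qs = np.linspace(0, 1, df + 2)
        knots = np.quantile(x, qs)
        # de-duplicate knots if quantiles coincide
        knots = np.unique(knots)
        if len(knots) < df + 2:
            knots = np.linspace(uniq.min(), uniq.max(), df + 2)
        self.knots = knots
        B = _natural_cubic_raw(x, self.knots)
        A = np.column_stack([np.ones_like(x), x])
        # residualize each raw column on {1, x}
        self._proj, *_ = np.linalg.lstsq(A, B, rcond=None)
        Bc = B - A @ self._proj
        self._scale = Bc.std(axis=0)
        self._scale[self._scale == 0] = 1.0
        self.x_range = (float(x.min()), float(x.max()))

    def transform(self, xnew) -> np.ndarray:
        xnew = np.asarray(xnew, dtype=float)
        B = _natural_cubic_raw(xnew, self.knots)
        A = np.column_stack([np.ones_like(xnew), xnew])
        return (B - A @ self._proj) / self._scale

    def column_names(self, prefix: str = "spline") -> list[str]:
        return [f"{prefix}_{k + 1}" for k in range(self.knots.shape[0] - 2)]


def spline_basis(paternal_age, df: int = 8) -> SplineBasis:
    """Fit a centered smooth basis to paternal ages (see :class:`SplineBasis`)."""
    return SplineBasis(paternal_age, df=df)
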