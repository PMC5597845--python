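"""Effect sizes on the response scale: per-decade effects, episode contrasts,
marginal-effect curves, and the m1-m4 model set.

The reported paternal-age effect is the percentage change in the
model-expected outcome for a 10-year within-family increase in paternal age,
holding all other covariates at their mean (continuous) or reference
(categorical) level and the between-family mean-age term at its sample mean.
For a pure log-link model this reduces exactly to ``(exp(10*beta_pa)-1)*100``;
for the hurdle model it combines the hurdle and count processes through
``E[Y] = P(clear hurdle) * E[Y | Y > 0]``.

Interval endpoints propagate coefficient uncertainty by sampling the Laplace
normal approximation (seeded, so results are reproducible); the point
estimate is the plug-in transform of the MAP coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .glmm.design import ModelSpec
from .glmm.families import get_family
from .glmm.fit import FitError, FitPart, FitResult, fit_glmm
from .glmm.compare import compare_models


@dataclass(frozen=True)
class EffectEstimate:
    kind: str  # per_decade_pct | episode_contrast_pct
    point: float
    lo: float
    hi: float
    model_tag: str = ""
    scenario_tag: str = ""

    def __post_init__(self):
        if not (self.lo <= self.point <= self.hi) and np.isfinite(self.point):
            raise ValueError("interval must bracket the point estimate")


def _draw_betas(part: FitPart, n_draws: int, rng) -> np.ndarray:
    p = len(part.beta)
    cov = part.cov[:p, :p]
    cov = np.nan_to_num(0.5 * (cov + cov.T))
    # eigenvalue floor keeps near-singular Laplace covariances sampleable
    vals, vecs = np.linalg.eigh(cov)
    vals = np.clip(vals, 0.0, None)
    A = vecs * np.sqrt(vals)
    z = rng.standard_normal((n_draws, p))
    return part.beta + z @ A.T


def _expected_response(fit: FitResult, rows: np.ndarray, betas_by_part) -> np.ndarray:
    """Model-expected outcome at design rows for given coefficient draws."""
    if fit.spec.family == "hurdle_poisson_log":
        bh = betas_by_part["hurdle"]
        bc = betas_by_part["count"]
        p_clear = get_family("bernoulli_logit").mean(rows @ bh.T)
        mu_pos = get_family("ztpoisson_log").mean(rows @ bc.T)
        return p_clear * mu_pos
    part_key = "mean"
    fam = get_family(fit.parts[part_key].family)
    return fam.mean(rows @ betas_by_part[part_key].T)


def _betas(fit: FitResult, n_draws, rng, point=False):
    out = {}
    for key, part in fit.parts.items():
        out[key] = part.beta[None, :] if point else _draw_betas(part, n_draws, rng)
    return out


def _ratio_effect(fit: FitResult, row_lo, row_hi, n_draws, seed) -> tuple[float, float, float]:
    rows = np.vstack([row_lo, row_hi])
    pt = _expected_response(fit, rows, _betas(fit, 1, None, point=True))
    point = (pt[1, 0] / pt[0, 0] - 1.0) * 100.0
    rng = np.random.default_rng(seed)
    dr = _expected_response(fit, rows, _betas(fit, n_draws, rng))
    ratio = (dr[1] / dr[0] - 1.0) * 100.0
    lo, hi = np.percentile(ratio, [2.5, 97.5])
    return float(point), float(min(lo, point)), float(max(hi, point))


def per_decade_effect(
    fit: FitResult, delta: float = 10.0, n_draws: int = 4000, seed: int = 0
) -> EffectEstimate:
    """Percent change in expected outcome for a +``delta``-year paternal age.

    Requires a linear paternal-age term; spline-only fits should be summarized
    with :func:`marginal_effect_curve` instead.
    """
    d = fit.count_part.design
    if d.pa_dev_col is None and d.pa_raw_col is None:
        raise FitError("no linear paternal-age term; use marginal_effect_curve")
    if d.spline is not None:
        # m4: the linear term alone does not carry the whole age effect
        raise FitError("spline model: use marginal_effect_curve")
    center = d.pa_mean_reference
    row_lo, row_hi = d.contrast_rows(center - delta / 2.0, center + delta / 2.0)
    if fit.spec.family in ("poisson_log",):
        # exact monotone transform of the single coefficient
        b, se = fit.beta_pa()
        point = (np.exp(delta * b) - 1.0) * 100.0
        lo = (np.exp(delta * (b - 1.96 * se)) - 1.0) * 100.0
        hi = (np.exp(delta * (b + 1.96 * se)) - 1.0) * 100.0
        return EffectEstimate("per_decade_pct", float(point), float(lo), float(hi),
                              model_tag=fit.spec.tag)
    point, lo, hi = _ratio_effect(fit, row_lo, row_hi, n_draws, seed)
    return EffectEstimate("per_decade_pct", point, lo, hi, model_tag=fit.spec.tag)


def episode_contrast(
    fit: FitResult,
    age_lo: float = 25.0,
    age_hi: float = 35.0,
    n_draws: int = 4000,
    seed: int = 0,
) -> EffectEstimate:
    """Percent change in the episode outcome, children of ``age_hi``- vs
    ``age_lo``-year-old fathers, other covariates at mean/reference level."""
    d = fit.count_part.design
    row_lo, row_hi = d.contrast_rows(age_lo, age_hi)
    point, lo, hi = _ratio_effect(fit, row_lo, row_hi, n_draws, seed)
    return EffectEstimate("episode_contrast_pct", point, lo, hi, model_tag=fit.spec.tag)


def marginal_effect_curve(
    fit: FitResult,
    age_grid,
    n_draws: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Predicted outcome over paternal ages with a 95% band and linear overlay.

    The overlay is a straight line fitted through the curve's posterior-draw
    medians, weighted inversely by each grid point's standard error — a check
    of whether the smooth deviates from linearity.
    """
    ages = np.asarray(age_grid, dtype=float)
    if ages.size == 0:
        raise ValueError("empty age grid")
    d = fit.count_part.design
    lo_obs = d.pa_mean_reference + (d.spline.x_range[0] if d.spline else -np.inf)
    hi_obs = d.pa_mean_reference + (d.spline.x_range[1] if d.spline else np.inf)
    if ages.min() < lo_obs - 1e-9 or ages.max() > hi_obs + 1e-9:
        import warnings

        warnings.warn("age grid extends beyond observed ages; extrapolating")
    rows = np.vstack([d.contrast_rows(a, a)[0] for a in ages])
    point = _expected_response(fit, rows, _betas(fit, 1, None, point=True))[:, 0]
    rng = np.random.default_rng(seed)
    dr = _expected_response(fit, rows, _betas(fit, n_draws, rng))
    lo, hi = np.percentile(dr, [2.5, 97.5], axis=1)
    se = dr.std(axis=1)
    w = 1.0 / np.maximum(se, 1e-12) ** 2
    A = np.column_stack([np.ones_like(ages), ages])
    coef, *_ = np.linalg.lstsq(A * np.sqrt(w)[:, None], point * np.sqrt(w), rcond=None)
    linear = A @ coef
    return pd.DataFrame(
        {"age": ages, "fit": point, "lo": lo, "hi": hi, "linear": linear}
    )


@dataclass
class ModelSetResult:
    fits: dict[str, FitResult]
    comparison: pd.DataFrame | None
    effects: dict[str, EffectEstimate]

    @property
    def sign_flip(self) -> float:
        """m1 minus m3 per-decade estimate — positive when between-family
        confounding inflates the naive model."""
        return self.effects["m1"].point - self.effects["m3"].point


def model_set_specs(base: ModelSpec) -> dict[str, ModelSpec]:
    return {
        "m1": base.with_(paternal_age_term="linear_raw", group_term="none", tag="m1"),
        "m2": base.with_(paternal_age_term="none", group_term="family_intercept", tag="m2"),
        "m3": base.with_(paternal_age_term="linear_dev_plus_mean",
                         group_term="family_intercept", tag="m3"),
        "m4": base.with_(paternal_age_term="spline_dev_plus_mean",
                         group_term="family_intercept", tag="m4"),
    }


def run_model_set(
    anchors: pd.DataFrame,
    base_spec: ModelSpec | None = None,
    compare: bool = True,
    K: int = 10,
    seed: int = 0,
    n_nodes: int = 21,
) -> ModelSetResult:
    """Fit the four-model set (naive, family-only, sibling comparison, spline)
    and optionally compare them by K-fold elpd."""
    base = base_spec or ModelSpec()
    specs = model_set_specs(base)
    fits = {k: fit_glmm(s, anchors, n_nodes=n_nodes) for k, s in specs.items()}
    effects = {}
    for k in ("m1", "m3"):
        effects[k] = per_decade_effect(fits[k], seed=seed)
    comparison = (
        compare_models(list(fits.values()), anchors, K=K, seed=seed, n_nodes=n_nodes)
        if compare
        else None
    )
    return ModelSetResult(fits=fits, comparison=comparison, effects=effects)
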