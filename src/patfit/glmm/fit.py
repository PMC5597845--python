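"""Penalized maximum marginal likelihood (MAP) fitting with Laplace intervals.

The default estimator maximizes the quadrature-based marginal log likelihood
plus the log prior (see :class:`patfit.glmm.design.PriorSet`) over the fixed
effects and the log random-effect sd(s), using the analytic score (posterior
expectation of the complete-data score).  95% intervals come from the inverse
of a finite-difference Hessian of the penalized objective at the optimum —
a normal approximation to the posterior.

The hurdle-Poisson family factorizes exactly: a logit model for clearing the
hurdle (any children at all) on all rows, and a zero-truncated Poisson —
carrying the family random intercept — on the positive counts.  Both parts
share the fixed-effect design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Any

import numpy as np
from scipy import optimize

from .design import DesignInfo, ModelSpec, PriorSet, build_design
from .families import get_family
from .quadrature import group_marginal_core


class FitError(RuntimeError):
    pass


@dataclass
class FitPart:
    """One fitted linear predictor (count part or hurdle part)."""

    names: list[str]
    beta: np.ndarray
    cov: np.ndarray           # includes log-sigma rows/cols at the end if present
    sigma: np.ndarray | None  # random-effect sd(s)
    loglik: float
    converged: bool
    design: DesignInfo
    family: str
    n_sigma: int = 0

    def se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov)[: len(self.beta)], 0, None))

    def coef_table(self) -> dict[str, tuple[float, float, float]]:
        se = self.se()
        return {
            nm: (b, b - 1.96 * s, b + 1.96 * s)
            for nm, b, s in zip(self.names, self.beta, se)
        }


@dataclass
class FitResult:
    """Fitted model: one or two parts plus spec-level metadata."""

    spec: ModelSpec
    parts: dict[str, FitPart]
    n_obs: int
    n_groups: int
    diagnostics: dict[str, Any] = dc_field(default_factory=dict)

    @property
    def count_part(self) -> FitPart:
        return self.parts["count"] if "count" in self.parts else self.parts["mean"]

    @property
    def hurdle_part(self) -> FitPart | None:
        return self.parts.get("hurdle")

    @property
    def sigma_family(self) -> float:
        s = self.count_part.sigma
        return float(s[0]) if s is not None and len(s) else 0.0

    def beta_pa(self) -> tuple[float, float]:
        """Point estimate and se of the per-year paternal-age coefficient."""
        part = self.count_part
        d = part.design
        j = d.pa_dev_col if d.pa_dev_col is not None else d.pa_raw_col
        if j is None:
            raise FitError("model has no linear paternal-age term")
        return float(part.beta[j]), float(part.se()[j])

    def to_dict(self) -> dict:
        out = {
            "family": self.spec.family,
            "outcome": self.spec.outcome,
            "tag": self.spec.tag,
            "n_obs": self.n_obs,
            "n_groups": self.n_groups,
            "parts": {},
            "diagnostics": {
                k: (bool(v) if isinstance(v, (bool, np.bool_)) else v)
                for k, v in self.diagnostics.items()
            },
        }
        for key, p in self.parts.items():
            out["parts"][key] = {
                "coefficients": {
                    nm: {"estimate": float(b), "lo95": float(lo), "hi95": float(hi)}
                    for nm, (b, lo, hi) in p.coef_table().items()
                },
                "sigma_family": None if p.sigma is None else [float(s) for s in p.sigma],
                "loglik": float(p.loglik),
                "converged": bool(p.converged),
            }
        return out


def _prior_logpdf_and_grad(beta, log_sig, prior: PriorSet, scale_vec, sigma_scale):
    """Log prior and gradients; flat -> zeros."""
    if prior.flat:
        return 0.0, np.zeros_like(beta), np.zeros_like(log_sig)
    with np.errstate(divide="ignore"):
        sd = np.where(
            scale_vec == 0.0, prior.intercept_scale, prior.coef_scale / scale_vec
        )
    lp = -0.5 * np.sum((beta / sd) ** 2)
    g_beta = -beta / sd**2
    g_ls = np.zeros_like(log_sig)
    if len(log_sig):
        sig = np.exp(log_sig)
        # half-normal prior on sigma plus the log-Jacobian of the log transform
        lp += np.sum(-0.5 * (sig / sigma_scale) ** 2 + log_sig)
        g_ls = -(sig / sigma_scale) ** 2 + 1.0
    return lp, g_beta, g_ls


def _initial_beta(family: str, y, p):
    beta0 = np.zeros(p)
    m = float(np.mean(y))
    if family in ("poisson_log", "ztpoisson_log"):
        beta0[0] = np.log(max(m, 0.05))
    elif family in ("bernoulli_logit", "bernoulli_cauchit"):
        mm = min(max(m, 0.01), 0.99)
        beta0[0] = np.log(mm / (1 - mm)) if family == "bernoulli_logit" else np.tan(
            np.pi * (mm - 0.5)
        )
    else:
        beta0[0] = m
    return beta0


def fit_part(
    family: str,
    design: DesignInfo,
    prior: PriorSet,
    n_nodes: int = 21,
    random_slope_col: int | None = None,
    sigma_init: float = 0.5,
    compute_cov: bool = True,
) -> FitPart:
    """MAP fit of one linear predictor; random effects if design has groups."""
    fam = get_family(family)
    y = design.y
    n, p = design.X.shape
    # standardize columns internally: unit-sd continuous predictors make the
    # objective well conditioned, and the coefficient priors become isotropic
    col_scale = np.where(design.prior_sd_scale == 0.0, 1.0, design.prior_sd_scale)
    X = design.X / col_scale
    scaled_prior_scale = np.ones(p)
    scaled_prior_scale[design.prior_sd_scale == 0.0] = 0.0  # intercept marker
    has_re = design.n_groups > 0
    d_re = 0
    Zre = None
    if has_re:
        d_re = 1 if random_slope_col is None else 2
        if d_re == 1:
            Zre = np.ones((n, 1))
        else:
            Zre = np.column_stack([np.ones(n), design.X[:, random_slope_col]])
    warm = {"u": None}

    def objective(theta):
        beta = theta[:p]
        log_sig = theta[p:]
        if has_re:
            sig = np.exp(log_sig)
            eta = X @ beta
            ll_f, aux = group_marginal_core(
                fam, y, eta, design.groups, design.n_groups, Zre, sig, n_nodes,
                want_grad=True, X=X, u0=warm["u"],
            )
            warm["u"] = aux["u_hat"]
            ll = float(ll_f.sum())
            g_beta, g_ls = aux["grad_beta"], aux["dlogsig"]
        else:
            eta = X @ beta
            ll = float(fam.loglik(y, eta).sum())
            g_beta = X.T @ fam.d1(y, eta)
            g_ls = np.zeros(0)
        lp, pg_beta, pg_ls = _prior_logpdf_and_grad(
            beta, log_sig, prior, scaled_prior_scale, prior.sigma_scale
        )
        f = -(ll + lp)
        g = -np.concatenate([g_beta + pg_beta, g_ls + pg_ls])
        return f, g

    theta0 = np.concatenate(
        [_initial_beta(family, y, p), np.full(d_re, np.log(sigma_init))]
    )

    theta = None
    converged = False
    if not has_re:
        # no random effect: penalized Newton with the closed-form Hessian
        theta, converged = _newton_fixed(
            fam, X, y, theta0[:p], prior, scaled_prior_scale
        )
    if theta is None:
        bounds = [(None, None)] * p + [(np.log(1e-3), np.log(10.0))] * d_re
        res = optimize.minimize(
            objective, theta0, jac=True, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 400, "ftol": 1e-10, "gtol": 1e-5},
        )
        theta = res.x
        converged = bool(res.success) or res.status == 1  # status 1: maxiter

    cov_s = np.full((p + d_re, p + d_re), np.nan)
    if compute_cov:
        if has_re:
            cov_s = _fd_covariance(objective, theta)
        else:
            # no random effect: the Hessian is available in closed form
            eta = X @ theta[:p]
            w = -fam.d2(y, eta)
            H = (X * w[:, None]).T @ X
            if not prior.flat:
                with np.errstate(divide="ignore"):
                    sd = np.where(
                        scaled_prior_scale == 0.0,
                        prior.intercept_scale,
                        prior.coef_scale / scaled_prior_scale,
                    )
                H = H + np.diag(1.0 / sd**2)
            try:
                cov_s = np.linalg.inv(H)
            except np.linalg.LinAlgError:
                cov_s = np.linalg.pinv(H)

    # back-transform to the original column scale
    D = np.concatenate([1.0 / col_scale, np.ones(d_re)])
    beta = theta[:p] / col_scale
    cov = cov_s * D[:, None] * D[None, :]
    sigma = np.exp(theta[p:]) if d_re else None
    neg_post = objective(theta)[0]
    ll_final = -neg_post - _prior_logpdf_and_grad(
        theta[:p], theta[p:], prior, scaled_prior_scale, prior.sigma_scale
    )[0]
    return FitPart(
        names=list(design.names),
        beta=beta,
        cov=cov,
        sigma=sigma,
        loglik=float(ll_final),
        converged=converged,
        design=design,
        family=family,
        n_sigma=d_re,
    )


def _newton_fixed(fam, X, y, beta0, prior, scale_vec, max_iter=60, tol=1e-9):
    """Penalized Newton (IRLS-style) for models without random effects.

    Returns (theta, converged) or (None, False) to fall back to L-BFGS when
    curvature turns indefinite (possible under the cauchit link).
    """
    def penalized(beta):
        lp, g_pen, _ = _prior_logpdf_and_grad(
            beta, np.zeros(0), prior, scale_vec, 1.0
        )
        eta = X @ beta
        return float(fam.loglik(y, eta).sum()) + lp, eta, g_pen

    with np.errstate(divide="ignore"):
        sd = np.where(
            scale_vec == 0.0, prior.intercept_scale, prior.coef_scale / scale_vec
        )
    prec = np.zeros(len(beta0)) if prior.flat else 1.0 / sd**2

    beta = beta0.copy()
    f, eta, g_pen = penalized(beta)
    for _ in range(max_iter):
        g = X.T @ fam.d1(y, eta) + g_pen
        if np.max(np.abs(g)) < tol * max(1.0, len(y) / 100.0):
            return beta, True
        w = -fam.d2(y, eta)
        if np.any(w < 0):  # non-concave region (cauchit): use Fisher-like floor
            w = np.maximum(w, 1e-6)
        H = (X * w[:, None]).T @ X + np.diag(prec) + 1e-10 * np.eye(X.shape[1])
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            return None, False
        t = 1.0
        for _ in range(25):
            f_new, eta_new, g_pen = penalized(beta + t * step)
            if f_new >= f - 1e-12:
                break
            t *= 0.5
        else:
            return None, False
        beta = beta + t * step
        f, eta = f_new, eta_new
    return beta, True


def _fd_covariance(objective, theta, h0: float = 1e-6):
    """Covariance from a forward finite-difference Hessian of the gradient."""
    k = len(theta)
    H = np.empty((k, k))
    _, g0 = objective(theta)
    for j in range(k):
        h = h0 * (1.0 + abs(theta[j]))
        tp = theta.copy(); tp[j] += h
        _, gp = objective(tp)
        H[:, j] = (gp - g0) / h
    H = 0.5 * (H + H.T)
    try:
        cov = np.linalg.inv(H)
        if np.any(np.diag(cov) <= 0):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
        bad = np.diag(cov) <= 0
        if np.any(bad):
            warnings.warn("non-positive-definite Hessian; intervals unreliable")
            cov[bad, bad] = np.nan
    return cov


def _fit_normal(spec: ModelSpec, anchors, prior: PriorSet) -> "FitResult":
    """Gaussian-outcome variant via statsmodels OLS (a standard step, not the
    package's core).  Family structure enters through cluster-robust standard
    errors rather than a random intercept: the point estimates coincide and
    the sandwich covariance is stable under the battery's collinear designs.
    """
    import statsmodels.api as sm

    design = build_design(anchors, spec)
    X, y = design.X, design.y
    model = sm.OLS(y, X)
    if design.n_groups > 0:
        ols = model.fit(cov_type="cluster", cov_kwds={"groups": design.groups})
    else:
        ols = model.fit()
    part = FitPart(
        names=list(design.names),
        beta=np.asarray(ols.params),
        cov=np.asarray(ols.cov_params()),
        sigma=None,
        loglik=float(ols.llf),
        converged=True,
        design=design,
        family="normal_identity",
        n_sigma=0,
    )
    return FitResult(spec=spec, parts={"mean": part}, n_obs=design.n_obs,
                     n_groups=design.n_groups, diagnostics={"backend": "statsmodels"})


def subset_design(design: DesignInfo, mask: np.ndarray) -> DesignInfo:
    """Row-subset of a design, keeping the column set; group codes refactorized."""
    if design.n_groups:
        sub = design.groups[mask]
        uniq, codes = np.unique(sub, return_inverse=True)
        codes = codes.astype(np.int64)
        n_g = len(uniq)
    else:
        codes, n_g = np.array([], dtype=np.int64), 0
    return DesignInfo(**{
        **vars(design),
        "X": design.X[mask],
        "y": design.y[mask],
        "groups": codes,
        "n_groups": n_g,
        "n_obs": int(mask.sum()),
    })


def fit_design(
    spec: ModelSpec,
    design: DesignInfo,
    n_nodes: int = 21,
    compute_cov: bool = True,
) -> FitResult:
    """Fit a model to a prebuilt design (see :func:`fit_glmm`)."""
    prior = spec.prior_set()
    slope_col = (
        design.pa_dev_col if spec.group_term == "family_intercept_and_slope" else None
    )
    if spec.group_term == "family_intercept_and_slope" and slope_col is None:
        raise FitError("random slope requires a paternal-age deviation term")
    if design.n_groups == 1:
        raise FitError("group term needs at least 2 families")

    if spec.family == "hurdle_poisson_log":
        y = design.y
        pos = y > 0
        # hurdle part: logit of clearing the hurdle, all observations, no RE
        d_h = DesignInfo(**{**vars(design), "y": pos.astype(float),
                            "groups": np.array([], dtype=np.int64), "n_groups": 0})
        part_h = fit_part("bernoulli_logit", d_h, prior, n_nodes,
                          compute_cov=compute_cov)
        # count part: zero-truncated Poisson on the positives, family RE
        sub_groups = design.groups[pos] if design.n_groups else np.array([], dtype=np.int64)
        if len(sub_groups):
            # re-factorize codes over the positive subset
            uniq, codes = np.unique(sub_groups, return_inverse=True)
            n_g = len(uniq)
        else:
            codes, n_g = np.array([], dtype=np.int64), 0
        d_c = DesignInfo(**{**vars(design), "X": design.X[pos], "y": y[pos],
                            "groups": codes, "n_groups": n_g,
                            "n_obs": int(pos.sum())})
        part_c = fit_part("ztpoisson_log", d_c, prior, n_nodes,
                          random_slope_col=slope_col, compute_cov=compute_cov)
        return FitResult(
            spec=spec,
            parts={"hurdle": part_h, "count": part_c},
            n_obs=design.n_obs,
            n_groups=design.n_groups,
            diagnostics={"converged": part_h.converged and part_c.converged},
        )

    part = fit_part(spec.family, design, prior, n_nodes,
                    random_slope_col=slope_col, compute_cov=compute_cov)
    return FitResult(
        spec=spec, parts={"mean": part}, n_obs=design.n_obs,
        n_groups=design.n_groups, diagnostics={"converged": part.converged},
    )


def fit_glmm(
    spec: ModelSpec,
    anchors,
    n_nodes: int = 21,
    compute_cov: bool = True,
) -> FitResult:
    """Fit a family-grouped model per the spec; MAP + Laplace intervals.

    Hurdle models return two parts ("hurdle": logit of clearing the hurdle,
    "count": zero-truncated Poisson with the family random intercept).  With
    flat priors and no group term, estimates coincide with an ordinary GLM.
    """
    if spec.family == "normal_identity":
        return _fit_normal(spec, anchors, spec.prior_set())
    design = build_design(anchors, spec)
    return fit_design(spec, design, n_nodes=n_nodes, compute_cov=compute_cov)
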