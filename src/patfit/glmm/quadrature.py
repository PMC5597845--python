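"""Adaptive Gauss-Hermite quadrature over family-level Gaussian effects.

The marginal likelihood of a mixed model integrates the per-family likelihood
over the family's random effect(s).  Each family's integrand is re-centered
at its posterior mode and re-scaled by the local curvature before applying
Gauss-Hermite nodes, so a modest node count reaches near machine accuracy.
Random intercepts (d = 1) and independent intercept + paternal-age-slope
effects (d = 2, product grid) are supported.

The gradient of the marginal log likelihood is the posterior expectation of
the complete-data score, which the same nodes evaluate at no extra modelling
cost; fitting uses it directly (see :mod:`patfit.glmm.fit`).
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp

from .families import get_family

_LOG2PI = np.log(2.0 * np.pi)


def _nodes(n_nodes: int, d: int):
    z, w = np.polynomial.hermite.hermgauss(n_nodes)
    logw = np.log(w)
    if d == 1:
        Z = z[:, None]
        LW = logw + z**2
    else:
        Z = np.column_stack([g.ravel() for g in np.meshgrid(z, z, indexing="ij")])
        LW = (logw[:, None] + logw[None, :]).ravel() + (Z**2).sum(axis=1)
    return Z, LW  # (Q,d), (Q,)


def _group_sums(codes, n_groups, vals):
    return np.bincount(codes, weights=vals, minlength=n_groups)


def _find_modes(fam, y, eta, codes, n_groups, Zre, sigmas, max_iter=60, tol=1e-10,
                u0=None):
    """Per-family posterior modes and curvatures, damped Newton, vectorized.

    Returns (u_hat (F,d), H (F,d,d)) with H the negative Hessian of the
    per-family log integrand at the mode (positive definite).
    """
    d = Zre.shape[1]
    F = n_groups
    u = np.zeros((F, d)) if u0 is None else u0.copy()
    inv_s2 = 1.0 / sigmas**2

    def penll(u):
        r = eta + (Zre * u[codes]).sum(axis=1)
        ll = _group_sums(codes, F, fam.loglik(y, r))
        return ll - 0.5 * (u**2 * inv_s2).sum(axis=1)

    cur = penll(u)
    for _ in range(max_iter):
        r = eta + (Zre * u[codes]).sum(axis=1)
        d1 = fam.d1(y, r)
        d2 = fam.d2(y, r)
        g = np.empty((F, d))
        H = np.empty((F, d, d))
        for a in range(d):
            g[:, a] = _group_sums(codes, F, d1 * Zre[:, a]) - u[:, a] * inv_s2[a]
            for b in range(a, d):
                hab = _group_sums(codes, F, d2 * Zre[:, a] * Zre[:, b])
                H[:, a, b] = H[:, b, a] = -hab
            H[:, a, a] += inv_s2[a]
        # guard indefinite curvature (possible for the cauchit link)
        for a in range(d):
            H[:, a, a] = np.maximum(H[:, a, a], 1e-8 + 0.5 * inv_s2[a])
        if d == 1:
            step = g[:, 0] / H[:, 0, 0]
            step = step[:, None]
        else:
            det = H[:, 0, 0] * H[:, 1, 1] - H[:, 0, 1] ** 2
            det = np.where(np.abs(det) < 1e-12, 1e-12, det)
            s0 = (H[:, 1, 1] * g[:, 0] - H[:, 0, 1] * g[:, 1]) / det
            s1 = (H[:, 0, 0] * g[:, 1] - H[:, 0, 1] * g[:, 0]) / det
            step = np.column_stack([s0, s1])
        # cap step length at 3 prior sd
        cap = 3.0 * sigmas
        step = np.clip(step, -cap, cap)
        if np.max(np.abs(g)) < tol:
            break
        new_u = u + step
        new_cur = penll(new_u)
        worse = new_cur < cur - 1e-12
        t = 1.0
        while np.any(worse) and t > 1e-3:
            t *= 0.5
            new_u[worse] = u[worse] + t * step[worse]
            new_cur[worse] = penll(new_u)[worse]
            worse = new_cur < cur - 1e-12
        u, cur = new_u, new_cur
    # final curvature at the mode
    r = eta + (Zre * u[codes]).sum(axis=1)
    d2 = fam.d2(y, r)
    H = np.empty((F, d, d))
    for a in range(d):
        for b in range(a, d):
            hab = _group_sums(codes, F, d2 * Zre[:, a] * Zre[:, b])
            H[:, a, b] = H[:, b, a] = -hab
        H[:, a, a] += inv_s2[a]
        H[:, a, a] = np.maximum(H[:, a, a], 1e-8 + 0.5 * inv_s2[a])
    return u, H


def _chol2(H):
    """Cholesky factors of the inverse of (F,d,d) SPD matrices."""
    F, d, _ = H.shape
    if d == 1:
        L = np.sqrt(1.0 / H)  # (F,1,1)
        logdet = np.log(L[:, 0, 0])
        return L, logdet
    # invert 2x2 then Cholesky analytically
    det = H[:, 0, 0] * H[:, 1, 1] - H[:, 0, 1] ** 2
    inv00 = H[:, 1, 1] / det
    inv01 = -H[:, 0, 1] / det
    inv11 = H[:, 0, 0] / det
    l00 = np.sqrt(inv00)
    l10 = inv01 / l00
    l11 = np.sqrt(np.maximum(inv11 - l10**2, 1e-14))
    L = np.zeros((F, 2, 2))
    L[:, 0, 0] = l00
    L[:, 1, 0] = l10
    L[:, 1, 1] = l11
    logdet = np.log(l00) + np.log(l11)
    return L, logdet


def group_marginal_core(fam, y, eta, codes, n_groups, Zre, sigmas, n_nodes,
                        want_grad=False, X=None, u0=None):
    """Per-family marginal log likelihoods (and optionally the score).

    ``Zre`` (n, d) holds the random-effect covariates (a column of ones for
    the intercept; the paternal-age deviation for a slope).  ``sigmas`` (d,)
    are the random-effect sds.  With ``want_grad`` the return includes the
    score with respect to the fixed effects (via ``X``) and each log sd.
    """
    d = Zre.shape[1]
    F = n_groups
    u_hat, H = _find_modes(fam, y, eta, codes, F, Zre, sigmas, u0=u0)
    L, logdetL = _chol2(H)
    # product grids grow quadratically; adaptive centering keeps 9 nodes per
    # dimension ample for two-dimensional effects
    Z, LW = _nodes(n_nodes if d == 1 else min(n_nodes, 9), d)
    Q = Z.shape[0]

    # node positions per family: u_fq = u_hat + sqrt(2) * L @ z_q
    # shape (Q, F, d)
    U = u_hat[None, :, :] + np.sqrt(2.0) * np.einsum("fab,qb->qfa", L, Z)
    LS = np.empty((Q, F))
    R = np.empty((Q, len(y)))
    for q in range(Q):
        r = eta + (Zre * U[q][codes]).sum(axis=1)
        R[q] = r
        ll = _group_sums(codes, F, fam.loglik(y, r))
        logprior = (
            -0.5 * (U[q] ** 2 / sigmas**2).sum(axis=1)
            - np.log(sigmas).sum()
            - 0.5 * d * _LOG2PI
        )
        LS[q] = LW[q] + ll + logprior
    ll_f = 0.5 * d * np.log(2.0) + logdetL + logsumexp(LS, axis=0)
    if not want_grad:
        return ll_f, {"u_hat": u_hat}

    P = np.exp(LS - ll_f[None, :] + 0.5 * d * np.log(2.0) + logdetL[None, :])
    # s_i = E_post[ d1_i ] per observation
    s = np.zeros(len(y))
    dlogsig = np.zeros(d)
    for q in range(Q):
        pq = P[q]
        s += pq[codes] * fam.d1(y, R[q])
        dlogsig += ((U[q] ** 2 / sigmas**2 - 1.0) * pq[:, None]).sum(axis=0)
    grad_beta = X.T @ s if X is not None else None
    return ll_f, {"grad_beta": grad_beta, "dlogsig": dlogsig, "score_obs": s,
                  "u_hat": u_hat}


def marginal_loglik(
    family: str,
    y,
    X,
    groups,
    beta,
    sigma,
    n_nodes: int = 21,
    Zre=None,
    X_hurdle=None,
    beta_hurdle=None,
    per_family: bool = False,
):
    """Marginal log likelihood with family effects integrated out.

    ``family`` is one of the model families; for ``hurdle_poisson_log`` the
    zero process is a logit regression (``X_hurdle @ beta_hurdle`` gives the
    linear predictor of *clearing* the hurdle, i.e. of a positive count) and
    the count process is a zero-truncated Poisson whose random intercept is
    integrated per family.  ``sigma`` may be a scalar (intercept) or length-2
    (intercept + slope, with ``Zre`` providing the slope covariate).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    beta = np.asarray(beta, dtype=float)
    groups = np.asarray(groups, dtype=np.int64)
    sig = np.atleast_1d(np.asarray(sigma, dtype=float))

    if family == "hurdle_poisson_log":
        from .families import BernoulliLogit

        pos = y > 0
        eta_h = np.asarray(X_hurdle, dtype=float) @ np.asarray(beta_hurdle, dtype=float)
        ll_h = BernoulliLogit.loglik(pos.astype(float), eta_h)
        n_groups = int(groups.max()) + 1 if len(groups) else 0
        out = np.bincount(groups, weights=ll_h, minlength=n_groups)
        if pos.any():
            sub_ll = marginal_loglik(
                "ztpoisson_log", y[pos], X[pos], groups[pos], beta, sig,
                n_nodes=n_nodes, Zre=None if Zre is None else np.asarray(Zre)[pos],
                per_family=True,
            )
            # sub_ll is indexed by original group codes (kept dense)
            out[: len(sub_ll)] += sub_ll
        return out if per_family else float(out.sum())

    fam = get_family(family)
    eta = X @ beta
    n_groups = int(groups.max()) + 1 if len(groups) else 0
    if n_groups == 0 or np.all(sig < 1e-8):
        ll = fam.loglik(y, eta)
        if per_family:
            return np.bincount(groups, weights=ll, minlength=max(n_groups, 1))
        return float(ll.sum())
    if Zre is None:
        Zre_arr = np.ones((len(y), 1))
    else:
        Zre_arr = np.asarray(Zre, dtype=float)
        if Zre_arr.ndim == 1:
            Zre_arr = np.column_stack([np.ones(len(y)), Zre_arr])
    ll_f, _ = group_marginal_core(fam, y, eta, groups, n_groups, Zre_arr, sig, n_nodes)
    return ll_f if per_family else float(ll_f.sum())
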