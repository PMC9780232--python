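"""Vectorised fitting primitives shared by the DE method implementations.

All genes share the same design matrix (cells x covariates); only the response
differs per gene.  That lets weighted least squares and logistic IRLS be
batched across genes with einsum-built normal equations, which is what keeps
the per-gene hurdle tests fast enough to run over benchmark grids.
"""

from __future__ import annotations

import numpy as np
import scipy.optimize
import scipy.stats

_EPS = 1e-12


def welch_t(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise Welch two-sample t-test.

    ``a``: (G, n1), ``b``: (G, n2).  Returns (t, p, effect) where effect is the
    difference of row means (a - b).  Zero-variance rows with equal means get
    p = 1 ("no evidence"); zero-variance rows with unequal means get p = 0.
    """
    n1, n2 = a.shape[1], b.shape[1]
    m1, m2 = a.mean(axis=1), b.mean(axis=1)
    v1 = a.var(axis=1, ddof=1)
    v2 = b.var(axis=1, ddof=1)
    se2 = v1 / n1 + v2 / n2
    effect = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect / np.sqrt(se2)
        df = se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        p = 2.0 * scipy.stats.t.sf(np.abs(t), df)
    degenerate = se2 <= 0
    p = np.where(degenerate & (effect == 0), 1.0, p)
    p = np.where(degenerate & (effect != 0), 0.0, p)
    t = np.where(degenerate, 0.0, t)
    return t, p, effect


def batched_wls(X: np.ndarray, Y: np.ndarray, W: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weighted least squares of each column of Y on shared design X.

    ``X``: (n, p), ``Y``: (n, G), ``W``: (n, G) non-negative weights.
    Returns (beta (G, p), rss (G,), ok (G,)); singular systems are flagged
    not-ok with NaN coefficients.
    """
    G = Y.shape[1]
    p = X.shape[1]
    XtWX = np.einsum("np,ng,nq->gpq", X, W, X, optimize=True)
    XtWy = np.einsum("np,ng->gp", X, W * Y, optimize=True)
    beta = np.full((G, p), np.nan)
    ok = np.zeros(G, dtype=bool)
    # batched solve; fall back per-gene on singular normal equations
    try:
        beta_all = np.linalg.solve(XtWX, XtWy[..., None])[..., 0]
        resid_ok = np.isfinite(beta_all).all(axis=1)
        beta[resid_ok] = beta_all[resid_ok]
        ok = resid_ok
    except np.linalg.LinAlgError:
        for g in range(G):
            try:
                beta[g] = np.linalg.solve(XtWX[g], XtWy[g])
                ok[g] = np.isfinite(beta[g]).all()
            except np.linalg.LinAlgError:
                ok[g] = False
    fitted = X @ np.nan_to_num(beta).T
    rss = np.einsum("ng,ng->g", W, (Y - fitted) ** 2)
    rss = np.where(ok, rss, np.nan)
    return beta, rss, ok


def batched_logistic_deviance(X: np.ndarray, Y: np.ndarray,
                              max_iter: int = 40, tol: float = 1e-9
                              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Logistic regression deviance of each column of Y (0/1) on shared X.

    IRLS batched over genes; linear predictors are clipped at +-30 so that
    separable genes converge to a (near-zero) finite deviance instead of
    diverging.  Returns (deviance (G,), beta (G, p), ok (G,)).
    """
    n, p = X.shape
    G = Y.shape[1]
    beta = np.zeros((G, p))
    ybar = np.clip(Y.mean(axis=0), 1e-6, 1 - 1e-6)
    beta[:, 0] = np.log(ybar / (1 - ybar))  # intercept-only start
    ok = np.ones(G, dtype=bool)
    for _ in range(max_iter):
        eta = np.clip(X @ beta.T, -30.0, 30.0)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1.0 - mu), _EPS, None)
        z = eta + (Y - mu) / w
        beta_new, _, ok_new = batched_wls(X, z, w)
        bad = ~ok_new
        beta_new[bad] = beta[bad]  # keep last good estimate for singular genes
        delta = np.nanmax(np.abs(beta_new - beta), axis=1)
        beta = beta_new
        if np.all(delta[np.isfinite(delta)] < tol):
            break
    eta = np.clip(X @ beta.T, -30.0, 30.0)
    mu = np.clip(1.0 / (1.0 + np.exp(-eta)), _EPS, 1 - _EPS)
    dev = -2.0 * np.sum(Y * np.log(mu) + (1 - Y) * np.log(1 - mu), axis=0)
    ok = np.isfinite(dev)
    return dev, beta, ok


def _tobit_nll_grad(theta: np.ndarray, X: np.ndarray, y: np.ndarray,
                    cens: np.ndarray) -> tuple[float, np.ndarray]:
    """Negative log-likelihood and gradient of a left-censored (at 0) Gaussian
    regression; theta = (coefficients..., log sigma)."""
    beta, log_s = theta[:-1], theta[-1]
    s = np.exp(log_s)
    xb = X @ beta
    nll = 0.0
    grad_b = np.zeros_like(beta)
    grad_ls = 0.0

    obs = ~cens
    if obs.any():
        r = (y[obs] - xb[obs]) / s
        nll += np.sum(0.5 * r ** 2 + log_s + 0.5 * np.log(2 * np.pi))
        grad_b += -(X[obs].T @ r) / s
        grad_ls += np.sum(1.0 - r ** 2)
    if cens.any():
        z = -xb[cens] / s  # P(y* <= 0) = Phi(z)
        log_cdf = scipy.stats.norm.logcdf(z)
        nll += -np.sum(log_cdf)
        # d/dz log Phi(z) = phi(z)/Phi(z), inverse Mills ratio
        mills = np.exp(scipy.stats.norm.logpdf(z) - log_cdf)
        grad_b += (X[cens].T @ mills) / s
        grad_ls += np.sum(mills * z)
    return nll, np.append(grad_b, grad_ls)


def _hessian_from_grad(theta: np.ndarray, X: np.ndarray, y: np.ndarray,
                       cens: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    """Central-difference Hessian of the analytic gradient (accurate, cheap)."""
    k = theta.size
    H = np.empty((k, k))
    for j in range(k):
        step = np.zeros(k)
        step[j] = eps
        _, g_hi = _tobit_nll_grad(theta + step, X, y, cens)
        _, g_lo = _tobit_nll_grad(theta - step, X, y, cens)
        H[:, j] = (g_hi - g_lo) / (2 * eps)
    return 0.5 * (H + H.T)


def tobit_fit(X: np.ndarray, y: np.ndarray) -> tuple[float, float, bool]:
    """Tobit (left-censored at 0) ML fit of y on X; Wald test on X[:, 1].

    Returns (p_value, coefficient, converged).  All-censored responses have a
    degenerate likelihood and are reported as failures.
    """
    cens = y <= 0
    if cens.all():
        return np.nan, np.nan, False
    # OLS warm start; sigma from residuals
    beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta0
    s0 = max(np.sqrt(np.mean(resid ** 2)), 1e-3)
    theta0 = np.append(beta0, np.log(s0))
    res = scipy.optimize.minimize(
        _tobit_nll_grad, theta0, args=(X, y, cens), jac=True, method="BFGS",
        options={"maxiter": 200, "gtol": 1e-8})
    if not np.isfinite(res.fun):
        return np.nan, np.nan, False
    theta = res.x
    H = _hessian_from_grad(theta, X, y, cens)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return np.nan, np.nan, False
    var = cov[1, 1]
    if not np.isfinite(var) or var <= 0:
        return np.nan, np.nan, False
    z = theta[1] / np.sqrt(var)
    p = 2.0 * scipy.stats.norm.sf(abs(z))
    return float(p), float(theta[1]), True
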