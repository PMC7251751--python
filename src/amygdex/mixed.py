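"""Random-intercept mixed models fitted by maximum likelihood.

Two building blocks used by the two-part (hurdle) expression model:

* a logistic mixed model — Bernoulli/binomial response, fixed covariates
  plus a Gaussian random intercept per group — whose marginal likelihood
  is evaluated by adaptive Gauss-Hermite quadrature (Laplace when
  ``n_quad=1``);
* a linear mixed model with one random intercept, fitted by profiling:
  for a fixed variance ratio the GLS estimates are closed-form, leaving
  a one-dimensional search over the ratio.

Both return genuine ML log-likelihoods, so nested fits from the same
family can be compared with a likelihood-ratio test.  Logistic
log-likelihoods omit the binomial coefficient: rows collapsed from
Bernoulli cells share the same kernel, and the constant cancels in any
LRT over the same response.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.special import expit

__all__ = [
    "MixedFit",
    "collapse_binomial",
    "fit_logistic_fixed",
    "fit_logistic_mixed",
    "fit_lmm",
    "fit_ols",
]

_SIGMA_FLOOR = 1e-6  # below this the random intercept is numerically zero


@dataclass
class MixedFit:
    """A fitted model: coefficients, random-intercept SD, ML log-likelihood."""

    beta: np.ndarray
    sigma_b: float | None  # None = fixed-effects-only model
    loglik: float
    converged: bool
    sigma2: float | None = None  # residual variance (Gaussian models)

    @property
    def mixed(self) -> bool:
        return self.sigma_b is not None


# ---------------------------------------------------------------------------
# logistic part
# ---------------------------------------------------------------------------


def collapse_binomial(
    X: np.ndarray, y: np.ndarray, groups: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Collapse Bernoulli rows sharing (group, covariate row) to binomial rows.

    Returns (X_rows, group_codes, successes, trials).  Exact: the
    Bernoulli likelihood kernel equals the collapsed binomial kernel.
    """
    X = np.asarray(X, float)
    stacked = np.column_stack([np.asarray(groups, float), X])
    uniq, inv = np.unique(stacked, axis=0, return_inverse=True)
    k = np.bincount(inv, weights=np.asarray(y, float))
    n = np.bincount(inv).astype(float)
    return uniq[:, 1:], uniq[:, 0].astype(int), k, n


def _binom_kernel(eta: np.ndarray, k: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Per-row binomial log-likelihood kernel k*eta - n*log(1+e^eta)."""
    return k * eta - n * np.logaddexp(0.0, eta)


def fit_logistic_fixed(
    Xr: np.ndarray,
    k: np.ndarray,
    n: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> MixedFit:
    """Binomial logistic regression by damped IRLS (no random effect)."""
    Xr = np.atleast_2d(np.asarray(Xr, float))
    p_dim = Xr.shape[1]
    beta = np.zeros(p_dim)
    converged = False
    for _ in range(max_iter):
        eta = Xr @ beta
        mu = expit(eta)
        grad = Xr.T @ (k - n * mu)
        w = n * mu * (1.0 - mu)
        hess = (Xr * w[:, None]).T @ Xr + 1e-10 * np.eye(p_dim)
        step = np.linalg.solve(hess, grad)
        # damp huge steps (quasi-separation)
        norm = np.max(np.abs(step))
        if norm > 10.0:
            step *= 10.0 / norm
        beta = beta + step
        if norm < tol:
            converged = True
            break
    loglik = float(np.sum(_binom_kernel(Xr @ beta, k, n)))
    return MixedFit(beta=beta, sigma_b=None, loglik=loglik, converged=converged)


def _logistic_group_modes(
    offset: np.ndarray,
    gr: np.ndarray,
    k: np.ndarray,
    n: np.ndarray,
    sigma: float,
    n_groups: int,
    iters: int = 40,
    tol: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-group posterior modes of the random intercept, by Newton.

    Maximizes g_i(b) = sum_rows[k*eta - n*log(1+e^eta)] - b^2/(2*sigma^2);
    strictly concave, so Newton with step damping is reliable.  Returns
    (modes, curvature h = -g'' at the mode).
    """
    inv_var = 1.0 / sigma**2
    b = np.zeros(n_groups)
    for _ in range(iters):
        mu = expit(offset + b[gr])
        grad = np.bincount(gr, weights=k - n * mu, minlength=n_groups) - b * inv_var
        h = np.bincount(gr, weights=n * mu * (1.0 - mu), minlength=n_groups) + inv_var
        step = np.clip(grad / h, -5.0, 5.0)
        b = b + step
        if np.max(np.abs(step)) < tol:
            break
    mu = expit(offset + b[gr])
    h = np.bincount(gr, weights=n * mu * (1.0 - mu), minlength=n_groups) + inv_var
    return b, h


def logistic_mixed_loglik(
    beta: np.ndarray,
    sigma: float,
    Xr: np.ndarray,
    gr: np.ndarray,
    k: np.ndarray,
    n: np.ndarray,
    n_groups: int,
    nodes: np.ndarray,
    log_weights: np.ndarray,
) -> float:
    """Marginal log-likelihood by adaptive Gauss-Hermite quadrature."""
    offset = Xr @ beta
    if sigma < _SIGMA_FLOOR:
        return float(np.sum(_binom_kernel(offset, k, n)))
    b_hat, h = _logistic_group_modes(offset, gr, k, n, sigma, n_groups)
    scale = np.sqrt(2.0 / h)  # per group
    # eta for every (row, node)
    b_nodes = b_hat[:, None] + scale[:, None] * nodes[None, :]  # (G, Q)
    eta = offset[:, None] + b_nodes[gr]
    ll_rows = _binom_kernel(eta, k[:, None], n[:, None])
    onehot = np.zeros((len(gr), n_groups))
    onehot[np.arange(len(gr)), gr] = 1.0
    ll_groups = onehot.T @ ll_rows  # (G, Q)
    g = ll_groups - b_nodes**2 / (2.0 * sigma**2) - 0.5 * np.log(2.0 * np.pi * sigma**2)
    arg = log_weights[None, :] + nodes[None, :] ** 2 + g
    top = arg.max(axis=1)
    lse = top + np.log(np.exp(arg - top[:, None]).sum(axis=1))
    return float(np.sum(0.5 * np.log(2.0 / h) + lse))


def fit_logistic_mixed(
    Xr: np.ndarray,
    gr: np.ndarray,
    k: np.ndarray,
    n: np.ndarray,
    n_quad: int = 9,
    start: np.ndarray | None = None,
) -> MixedFit:
    """ML fit of the logistic random-intercept model via AGQ.

    Parameters are (beta, log sigma_b); optimized with L-BFGS-B.  The
    fixed-effects solution provides starting values, and since sigma_b
    may go to its floor, the model nests the fixed fit.
    """
    Xr = np.atleast_2d(np.asarray(Xr, float))
    gr = np.asarray(gr, int)
    n_groups = int(gr.max()) + 1
    nodes, weights = np.polynomial.hermite.hermgauss(n_quad)
    log_weights = np.log(weights)

    fixed = fit_logistic_fixed(Xr, k, n)
    beta0 = start if start is not None else fixed.beta
    x0 = np.concatenate([beta0, [np.log(0.1)]])
    bounds = [(None, None)] * Xr.shape[1] + [(np.log(_SIGMA_FLOOR), np.log(20.0))]

    def neg(x: np.ndarray) -> float:
        return -logistic_mixed_loglik(
            x[:-1], np.exp(x[-1]), Xr, gr, k, n, n_groups, nodes, log_weights
        )

    res = minimize(neg, x0, method="L-BFGS-B", bounds=bounds)
    beta = res.x[:-1]
    sigma = float(np.exp(res.x[-1]))
    loglik = -float(res.fun)
    # the mixed family nests the fixed fit; never report a worse likelihood
    if fixed.loglik > loglik + 1e-8:
        beta, sigma, loglik = fixed.beta, _SIGMA_FLOOR / 2, fixed.loglik
    return MixedFit(beta=beta, sigma_b=sigma, loglik=loglik, converged=bool(res.success))


# ---------------------------------------------------------------------------
# Gaussian part
# ---------------------------------------------------------------------------


def _lmm_profile(
    lam: float,
    XtX: np.ndarray,
    Xty: np.ndarray,
    yty: float,
    S: np.ndarray,
    t: np.ndarray,
    n_i: np.ndarray,
    n_total: int,
) -> tuple[float, np.ndarray, float]:
    """Profiled ML log-likelihood at variance ratio lam = sigma_b^2/sigma^2.

    Uses the Woodbury form of V^-1 for a single random intercept, so the
    per-group sufficient statistics (S = X_i'1, t = 1'y_i) are all that
    is needed.  Returns (loglik, beta, sigma2).
    """
    c = lam / (1.0 + lam * n_i)  # per-group shrinkage
    xvx = XtX - (S * c[:, None]).T @ S
    xvy = Xty - S.T @ (c * t)
    yvy = yty - float(np.sum(c * t**2))
    try:
        beta = np.linalg.solve(xvx, xvy)
    except np.linalg.LinAlgError:
        beta = np.linalg.lstsq(xvx, xvy, rcond=None)[0]
    rss = yvy - float(beta @ xvy)
    rss = max(rss, 1e-12)
    sigma2 = rss / n_total
    loglik = (
        -0.5 * n_total * (np.log(2.0 * np.pi * sigma2) + 1.0)
        - 0.5 * float(np.sum(np.log1p(lam * n_i)))
    )
    return loglik, beta, sigma2


def _lmm_stats(
    X: np.ndarray, y: np.ndarray, groups: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray, np.ndarray, np.ndarray, int]:
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float)
    groups = np.asarray(groups, int)
    n_groups = int(groups.max()) + 1
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    S = np.zeros((n_groups, X.shape[1]))
    np.add.at(S, groups, X)
    t = np.bincount(groups, weights=y, minlength=n_groups)
    n_i = np.bincount(groups, minlength=n_groups).astype(float)
    return XtX, Xty, yty, S, t, n_i, len(y)


def fit_lmm(X: np.ndarray, y: np.ndarray, groups: np.ndarray) -> MixedFit:
    """ML fit of a linear model with one Gaussian random intercept.

    Profiles beta and sigma^2 out analytically and optimizes the
    remaining variance ratio on a log grid refined by bounded search;
    the boundary (ratio 0 = OLS) is always considered.
    """
    XtX, Xty, yty, S, t, n_i, n_total = _lmm_stats(X, y, groups)

    def ll_at(lam: float) -> float:
        return _lmm_profile(lam, XtX, Xty, yty, S, t, n_i, n_total)[0]

    # coarse log grid to bracket, then Brent refinement in log space
    grid = np.concatenate([[0.0], np.exp(np.linspace(np.log(1e-7), np.log(1e3), 41))])
    lls = np.array([ll_at(lam) for lam in grid])
    best = int(np.argmax(lls))
    lam_best = grid[best]
    if 0 < best < len(grid) - 1:
        res = minimize_scalar(
            lambda u: -ll_at(np.exp(u)),
            bounds=(np.log(grid[best - 1] + 1e-12), np.log(grid[best + 1])),
            method="bounded",
            options={"xatol": 1e-8},
        )
        if -res.fun >= lls[best]:
            lam_best = float(np.exp(res.x))
    loglik, beta, sigma2 = _lmm_profile(lam_best, XtX, Xty, yty, S, t, n_i, n_total)
    return MixedFit(
        beta=beta,
        sigma_b=float(np.sqrt(lam_best * sigma2)),
        loglik=loglik,
        converged=True,
        sigma2=sigma2,
    )


def fit_ols(X: np.ndarray, y: np.ndarray) -> MixedFit:
    """ML (not REML) ordinary least squares, for the fixed-effects fallback."""
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float)
    groups = np.zeros(len(y), dtype=int)
    XtX, Xty, yty, S, t, n_i, n_total = _lmm_stats(X, y, groups)
    loglik, beta, sigma2 = _lmm_profile(0.0, XtX, Xty, yty, S, t, n_i, n_total)
    return MixedFit(beta=beta, sigma_b=None, loglik=loglik, converged=True, sigma2=sigma2)
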