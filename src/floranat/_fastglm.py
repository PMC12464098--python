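"""Lightweight Newton/IRLS fitters for logistic and NB2 regression.

The mediation bootstrap refits a logistic outcome model and a negative
binomial mediator model in every replicate (hundreds of thousands of fits
across the property suite), so these fitters avoid any per-fit object
overhead. They are maximum-likelihood, match statsmodels to numerical
tolerance (asserted in the unit suite), and report observed-information
standard errors; for NB2 the dispersion is estimated jointly with the
coefficients and the beta covariance comes from the joint (beta, theta)
observed information.

Digamma/trigamma sums over integer counts use the telescoping identities
``psi(y + t) - psi(t) = sum_{k<y} 1/(t + k)`` aggregated through tail
counts, which turns each dispersion Newton step into an O(max y) vector
operation instead of n special-function evaluations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, gammaln

from .exceptions import ConvergenceError, SeparationError

_ETA_MAX = 500.0  # linear-predictor clamp before exponentiation
_THETA_MAX = 1e7  # beyond this the NB2 is numerically Poisson


@dataclass
class FastFit:
    beta: np.ndarray
    se: np.ndarray
    cov: np.ndarray
    llf: float
    llnull: float
    n_obs: int
    converged: bool
    n_iter: int
    theta: float | None = None
    theta_se: float | None = None
    poisson_limit: bool = False


def _logit_loglik(eta: np.ndarray, y: np.ndarray) -> float:
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logit(
    X: np.ndarray,
    y: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
    beta0: np.ndarray | None = None,
) -> FastFit:
    """Newton-Raphson logistic regression; ``X`` must include the intercept
    column. ``beta0`` warm-starts the iteration (bootstrap replicates start
    from the full-sample fit). Raises :class:`SeparationError` when the MLE
    diverges."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if np.all(y == y[0]):
        raise ConvergenceError("response is constant; logistic MLE undefined")

    beta = np.zeros(p) if beta0 is None else np.asarray(beta0, dtype=float).copy()
    ll = _logit_loglik(X @ beta, y)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = expit(eta)
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu)
        H = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            raise SeparationError(
                "singular information matrix (separation or collinearity)"
            ) from None
        # step-halving to guarantee ascent
        for _ in range(30):
            cand = beta + step
            ll_new = _logit_loglik(X @ cand, y)
            if ll_new >= ll - 1e-12:
                break
            step *= 0.5
        beta = beta + step
        ll = ll_new
        if np.max(np.abs(step)) < tol:
            converged = True
            break

    eta = X @ beta
    if not converged or np.max(np.abs(beta)) > 1e3:
        if np.max(np.abs(eta)) > 25.0:
            raise SeparationError("perfect separation: fitted log-odds diverge")
        if not converged:
            raise ConvergenceError(
                f"logistic fit did not converge in {max_iter} iterations "
                f"(last step {np.max(np.abs(step)):.2e})"
            )
    mu = expit(eta)
    w = mu * (1.0 - mu)
    H = (X * w[:, None]).T @ X
    cov = np.linalg.inv(H)
    pbar = float(np.mean(y))
    llnull = n * (pbar * np.log(pbar) + (1.0 - pbar) * np.log(1.0 - pbar))
    return FastFit(
        beta=beta,
        se=np.sqrt(np.diag(cov)),
        cov=cov,
        llf=ll,
        llnull=llnull,
        n_obs=n,
        converged=True,
        n_iter=it,
    )


def _tail_counts(y: np.ndarray) -> np.ndarray:
    """``N[k] = #{ y_i >= k + 1 }`` for k = 0 .. max(y) - 1."""
    yi = y.astype(np.int64)
    cnt = np.bincount(yi)
    return len(yi) - np.cumsum(cnt)[:-1]


def _digamma_sum(tail: np.ndarray, theta: float) -> float:
    """sum_i [psi(y_i + theta) - psi(theta)] via tail counts."""
    k = np.arange(len(tail), dtype=float)
    return float(np.sum(tail / (theta + k)))


def _trigamma_sum(tail: np.ndarray, theta: float) -> float:
    """sum_i [psi'(y_i + theta) - psi'(theta)] via tail counts."""
    k = np.arange(len(tail), dtype=float)
    return float(-np.sum(tail / (theta + k) ** 2))


def _gammaln_sum(tail: np.ndarray, theta: float) -> float:
    """sum_i [gammaln(y_i + theta) - gammaln(theta)] via tail counts."""
    k = np.arange(len(tail), dtype=float)
    return float(np.sum(tail * np.log(theta + k)))


def _nb2_loglik(
    y: np.ndarray, mu: np.ndarray, theta: float, tail: np.ndarray, c_y: float
) -> float:
    n = len(y)
    return (
        _gammaln_sum(tail, theta)
        - c_y
        + n * theta * np.log(theta)
        + float(np.sum(y * np.log(mu) - (y + theta) * np.log(theta + mu)))
    )


def _poisson_loglik(y: np.ndarray, mu: np.ndarray) -> float:
    return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1.0)))


def _irls_beta(
    X: np.ndarray,
    y: np.ndarray,
    beta: np.ndarray,
    theta: float,
    tol: float,
    max_iter: int = 50,
) -> np.ndarray:
    """IRLS for the NB2 mean model at fixed dispersion (log link).
    ``theta = inf`` gives the Poisson limit."""
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -_ETA_MAX, _ETA_MAX)
        mu = np.exp(eta)
        if np.isinf(theta):
            w = mu
        else:
            w = mu * theta / (mu + theta)
        z = eta + (y - mu) / mu
        Xw = X * w[:, None]
        try:
            beta_new = np.linalg.solve(Xw.T @ X, Xw.T @ z)
        except np.linalg.LinAlgError:
            raise ConvergenceError(
                "singular design in negative binomial IRLS"
            ) from None
        delta = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if delta < tol:
            break
    return beta


def _update_theta(
    y: np.ndarray, mu: np.ndarray, theta: float, tol: float, tail: np.ndarray
) -> float:
    """Newton steps on log(theta) maximizing the NB2 profile likelihood."""
    n = len(y)
    t = np.log(theta)
    for _ in range(50):
        th = np.exp(t)
        thmu = th + mu
        dl_dth = (
            _digamma_sum(tail, th)
            + n * (np.log(th) + 1.0)
            - float(np.sum(np.log(thmu) + (y + th) / thmu))
        )
        d2l_dth2 = (
            _trigamma_sum(tail, th)
            + n / th
            - float(np.sum(2.0 / thmu - (y + th) / thmu**2))
        )
        # chain rule to log-scale
        g = th * dl_dth
        h = th * th * d2l_dth2 + th * dl_dth
        if h >= 0:  # not locally concave: fall back to a damped gradient step
            step = np.sign(g) * min(abs(g), 1.0)
        else:
            step = -g / h
        step = float(np.clip(step, -2.0, 2.0))
        t_new = t + step
        if t_new > np.log(_THETA_MAX):
            return np.inf
        t = t_new
        if abs(step) < tol:
            break
    return float(np.exp(t))


def fit_negbin(
    X: np.ndarray,
    y: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
    beta0: np.ndarray | None = None,
    theta0: float | None = None,
) -> FastFit:
    """Joint ML fit of an NB2 regression (log link, variance mu + mu^2/theta)
    by alternating IRLS for beta and Newton for theta.

    ``beta0`` / ``theta0`` warm-start the iteration. Equidispersed data
    drives theta to its cap and the fit is flagged as the Poisson limit
    rather than erred.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if np.all(y == 0):
        raise ConvergenceError("all counts are zero; NB mean model undefined")
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ValueError("negative binomial response must be non-negative integers")

    tail = _tail_counts(y)
    c_y = float(np.sum(gammaln(y + 1.0)))

    if beta0 is not None:
        beta = np.asarray(beta0, dtype=float).copy()
    else:
        beta = np.linalg.lstsq(X, np.log(y + 0.5), rcond=None)[0]
    if theta0 is not None and np.isfinite(theta0):
        theta = float(theta0)
    else:
        ybar_, s2_ = float(np.mean(y)), float(np.var(y, ddof=1)) if n > 1 else 0.0
        theta = ybar_ * ybar_ / (s2_ - ybar_) if s2_ > ybar_ else 100.0
    theta = float(np.clip(theta, 1e-3, 1e4))
    ybar = float(np.mean(y))

    ll = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        beta = _irls_beta(X, y, beta, theta, tol=tol)
        mu = np.exp(np.clip(X @ beta, -_ETA_MAX, _ETA_MAX))
        theta = _update_theta(y, mu, theta, tol=tol, tail=tail)
        if np.isinf(theta):
            break
        ll_new = _nb2_loglik(y, mu, theta, tail, c_y)
        if abs(ll_new - ll) < tol:
            ll = ll_new
            converged = True
            break
        ll = ll_new

    poisson_limit = np.isinf(theta)
    if poisson_limit:
        beta = _irls_beta(X, y, beta, np.inf, tol=tol)
        mu = np.exp(np.clip(X @ beta, -_ETA_MAX, _ETA_MAX))
        H = (X * mu[:, None]).T @ X
        cov = np.linalg.inv(H)
        return FastFit(
            beta=beta,
            se=np.sqrt(np.diag(cov)),
            cov=cov,
            llf=_poisson_loglik(y, mu),
            llnull=_poisson_loglik(y, np.full(n, ybar)),
            n_obs=n,
            converged=True,
            n_iter=it,
            theta=np.inf,
            theta_se=np.nan,
            poisson_limit=True,
        )

    if not converged:
        raise ConvergenceError(
            f"negative binomial fit did not converge in {max_iter} rounds "
            f"(theta = {theta:.3g})"
        )

    # joint observed information in (beta, theta); the beta block of its
    # inverse is invariant to how the nuisance theta is parameterized
    mu = np.exp(np.clip(X @ beta, -_ETA_MAX, _ETA_MAX))
    denom = (theta + mu) ** 2
    w_bb = (y + theta) * theta * mu / denom
    I_bb = (X * w_bb[:, None]).T @ X
    cross = -(mu * (y - mu) / denom)  # -d2l/(dbeta dtheta) per obs
    I_bt = X.T @ cross
    d2l_dth2 = (
        _trigamma_sum(tail, theta)
        + n / theta
        - float(np.sum(2.0 / (theta + mu) - (y + theta) / denom))
    )
    I_tt = -d2l_dth2
    info = np.zeros((p + 1, p + 1))
    info[:p, :p] = I_bb
    info[:p, p] = I_bt
    info[p, :p] = I_bt
    info[p, p] = I_tt
    try:
        cov_full = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        raise ConvergenceError("singular joint information in NB fit") from None
    cov = cov_full[:p, :p]
    theta_se = float(np.sqrt(max(cov_full[p, p], 0.0)))

    # intercept-only fit for the null log-likelihood
    if p == 1:
        llnull = _nb2_loglik(y, mu, theta, tail, c_y)
    else:
        llnull = fit_negbin(np.ones((n, 1)), y, tol=tol, max_iter=max_iter).llf
    return FastFit(
        beta=beta,
        se=np.sqrt(np.diag(cov)),
        cov=cov,
        llf=_nb2_loglik(y, mu, theta, tail, c_y),
        llnull=llnull,
        n_obs=n,
        converged=True,
        n_iter=it,
        theta=float(theta),
        theta_se=theta_se,
        poisson_limit=False,
    )
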