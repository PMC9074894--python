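"""Maximum-likelihood fitters for the two regression families used throughout.

The screening cascade fits on the order of 10^5 small regressions (a few
hundred samples, ~5 columns), so both fitters work directly on ndarrays and
avoid any per-fit object construction beyond the result record.

Families
--------
* Gaussian, identity link: ordinary least squares with t-based Wald tests.
* Negative binomial (NB2), log link: variance ``mu + alpha * mu**2`` with the
  dispersion ``alpha`` (the reciprocal of the size ``theta``) estimated by
  profile maximum likelihood.  Coefficients for a fixed ``alpha`` are obtained
  by iteratively reweighted least squares; ``alpha`` and the coefficient block
  are information-orthogonal, so the two updates are alternated until the
  log-likelihood stabilises.

Degenerate designs (constant predictor next to the intercept, duplicated
columns) are reported through ``converged=False`` plus a flag rather than an
exception, because a screen must keep going when one candidate model fails.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

__all__ = ["FitResult", "ols_fit", "nb2_fit"]

# alpha is profiled on the log scale within these bounds; below the lower
# bound the model is numerically Poisson, above the upper the dispersion
# estimate is treated as divergent.
_LOG_ALPHA_LO = np.log(1e-8)
_LOG_ALPHA_HI = np.log(1e4)


@dataclass(frozen=True)
class FitResult:
    """One fitted model: coefficients, Wald inference and convergence state."""

    params: np.ndarray
    bse: np.ndarray
    pvalues: np.ndarray
    nobs: int
    converged: bool
    flags: tuple[str, ...] = ()
    dispersion: float | None = None  # NB2 alpha (1/theta); None for OLS
    loglike: float = np.nan

    def failed(self, *flags: str) -> bool:
        return not self.converged or any(f in self.flags for f in flags)


def _failure(k: int, nobs: int, *flags: str) -> FitResult:
    nan = np.full(k, np.nan)
    return FitResult(
        params=nan,
        bse=nan.copy(),
        pvalues=np.ones(k),
        nobs=nobs,
        converged=False,
        flags=tuple(flags),
    )


def ols_fit(X: np.ndarray, y: np.ndarray) -> FitResult:
    """Ordinary least squares with classical (homoskedastic) standard errors.

    ``X`` must already carry an intercept column.  Rank deficiency is detected
    through the Cholesky factorisation of the normal equations and reported as
    a failed fit flagged ``rank_deficient``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if n <= k:
        return _failure(k, n, "insufficient_n")
    xtx = X.T @ X
    try:
        chol = np.linalg.cholesky(xtx)
    except np.linalg.LinAlgError:
        return _failure(k, n, "rank_deficient")
    # guard against numerically singular designs that survive Cholesky
    diag = np.diag(chol)
    if np.min(diag) < 1e-7 * np.max(diag):
        return _failure(k, n, "rank_deficient")
    try:
        beta = np.linalg.solve(xtx, X.T @ y)
    except np.linalg.LinAlgError:
        return _failure(k, n, "rank_deficient")
    resid = y - X @ beta
    dof = n - k
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(xtx)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    pvals = 2.0 * stats.t.sf(np.abs(tstat), dof)
    ll = -0.5 * n * (np.log(2 * np.pi * max(sigma2 * dof / n, 1e-300)) + 1.0)
    return FitResult(
        params=beta,
        bse=se,
        pvalues=pvals,
        nobs=n,
        converged=True,
        loglike=ll,
    )


def _nb_loglike(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    if alpha < 1e-10:  # Poisson limit
        return float(np.sum(y * np.log(mu) - mu - special.gammaln(y + 1)))
    r = 1.0 / alpha
    return float(
        np.sum(
            special.gammaln(y + r)
            - special.gammaln(r)
            - special.gammaln(y + 1)
            + r * np.log(r / (r + mu))
            + y * np.log(mu / (r + mu))
        )
    )


def _nb_irls(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float,
    beta: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """IRLS for the log-link NB mean model at fixed dispersion.

    Returns (beta, mu, converged).  Weights are the unit expected
    information ``mu / (1 + alpha * mu)``.
    """
    eta = np.clip(X @ beta, -30.0, 30.0)
    mu = np.exp(eta)
    ll_old = _nb_loglike(y, mu, alpha)
    for _ in range(max_iter):
        w = mu / (1.0 + alpha * mu)
        z = eta + (y - mu) / mu
        xw = X * w[:, None]
        try:
            beta_new = np.linalg.solve(xw.T @ X, xw.T @ z)
        except np.linalg.LinAlgError:
            return beta, mu, False
        # step-halving keeps the likelihood monotone on awkward data
        step = 1.0
        for _ in range(8):
            cand = beta + step * (beta_new - beta)
            eta_c = np.clip(X @ cand, -30.0, 30.0)
            mu_c = np.exp(eta_c)
            ll_new = _nb_loglike(y, mu_c, alpha)
            if np.isfinite(ll_new) and ll_new >= ll_old - 1e-12:
                break
            step *= 0.5
        beta, eta, mu = cand, eta_c, mu_c
        if abs(ll_new - ll_old) < tol * (abs(ll_old) + 1.0):
            return beta, mu, True
        ll_old = ll_new
    return beta, mu, False


def _profile_alpha(y: np.ndarray, mu: np.ndarray, log_alpha0: float) -> float:
    """One-dimensional ML update of log(alpha) holding the mean fixed."""

    def nll(la: float) -> float:
        return -_nb_loglike(y, mu, np.exp(la))

    from scipy.optimize import minimize_scalar

    res = minimize_scalar(
        nll,
        bounds=(_LOG_ALPHA_LO, _LOG_ALPHA_HI),
        method="bounded",
        options={"xatol": 1e-6},
    )
    return float(res.x)


def nb2_fit(
    X: np.ndarray,
    y: np.ndarray,
    max_outer: int = 30,
    tol: float = 1e-9,
) -> FitResult:
    """NB2 regression with log link and ML dispersion.

    Standard errors come from the observed information of the coefficient
    block, ``sum_i mu_i (1 + alpha y_i) / (1 + alpha mu_i)^2 x_i x_i'``;
    the dispersion is information-orthogonal to the coefficients, so no
    correction for estimating ``alpha`` is needed asymptotically.  Wald
    p-values use the normal reference.  A dispersion estimate at the upper
    bound is flagged ``dispersion_diverged`` and the fit falls back to the
    Poisson special case; an estimate at the lower bound (no overdispersion)
    is flagged ``poisson_limit`` but is a perfectly valid fit.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if n <= k:
        return _failure(k, n, "insufficient_n")
    if np.any(y < 0) or not np.allclose(y, np.round(y)):
        return _failure(k, n, "non_count_response")
    xtx = X.T @ X
    try:
        chol = np.linalg.cholesky(xtx)
    except np.linalg.LinAlgError:
        return _failure(k, n, "rank_deficient")
    if np.min(np.diag(chol)) < 1e-7 * np.max(np.diag(chol)):
        return _failure(k, n, "rank_deficient")

    # starting values: regress log(y + 0.5) by OLS, then moment dispersion
    try:
        beta = np.linalg.solve(xtx, X.T @ np.log(y + 0.5))
    except np.linalg.LinAlgError:
        return _failure(k, n, "rank_deficient")
    beta, mu, ok = _nb_irls(X, y, 0.0, beta)  # Poisson pass
    if not ok:
        return _failure(k, n, "nonconvergence")
    mom = float(np.sum((y - mu) ** 2 - mu) / max(np.sum(mu**2), 1e-12))
    log_alpha = np.log(np.clip(mom, 1e-6, 1e3))

    flags: list[str] = []
    ll_old = -np.inf
    converged = False
    for _ in range(max_outer):
        log_alpha = _profile_alpha(y, mu, log_alpha)
        alpha = float(np.exp(log_alpha))
        beta, mu, ok = _nb_irls(X, y, alpha, beta)
        if not ok:
            return _failure(k, n, "nonconvergence")
        ll = _nb_loglike(y, mu, alpha)
        if abs(ll - ll_old) < tol * (abs(ll) + 1.0):
            converged = True
            break
        ll_old = ll
    if not converged:
        return _failure(k, n, "nonconvergence")

    alpha = float(np.exp(log_alpha))
    if log_alpha >= _LOG_ALPHA_HI - 1e-3:
        flags.append("dispersion_diverged")
    elif log_alpha <= _LOG_ALPHA_LO + 1e-3:
        flags.append("poisson_limit")
        alpha = 0.0

    w_obs = mu * (1.0 + alpha * y) / (1.0 + alpha * mu) ** 2
    info = (X * w_obs[:, None]).T @ X
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        return _failure(k, n, "singular_information")
    se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    return FitResult(
        params=beta,
        bse=se,
        pvalues=pvals,
        nobs=n,
        converged=True,
        flags=tuple(flags),
        dispersion=alpha,
        loglike=_nb_loglike(y, mu, alpha),
    )
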