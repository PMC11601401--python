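"""Random-intercept mixed models used across the analysis stages.

Two fitters live here, both specialised to a single grouping factor
(tissue section) with a scalar random intercept, which makes the
covariance block-diagonal and the likelihood cheap to profile:

* a Gaussian linear mixed model with the variance ratio profiled out and
  maximised by a one-dimensional search (maximum likelihood, so that
  likelihood-ratio tests between nested fixed-effect specifications are
  valid);
* a logistic mixed model estimated by penalised IRLS over the joint
  (fixed, random) coefficients and a Laplace approximation to the
  marginal likelihood, maximised over the random-intercept standard
  deviation.

Both report the maximised log-likelihood; when the variance estimate hits
zero the fits coincide with the corresponding fixed-effect models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

_LOG2PI = np.log(2.0 * np.pi)


def group_indices(groups: np.ndarray) -> list[np.ndarray]:
    codes, _ = _factorize(groups)
    return [np.flatnonzero(codes == c) for c in range(codes.max() + 1)]


def _factorize(groups: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    uniques, codes = np.unique(np.asarray(groups), return_inverse=True)
    return codes, uniques


@dataclass
class LMMFit:
    beta: np.ndarray
    cov_beta: np.ndarray
    sigma2: float
    tau2: float
    llf: float
    n: int
    converged: bool = True

    def wald(self, index: int) -> tuple[float, float]:
        """(z, two-sided p) for one coefficient."""
        from scipy import stats

        se = float(np.sqrt(self.cov_beta[index, index]))
        z = float(self.beta[index]) / se if se > 0 else np.nan
        return z, 2.0 * stats.norm.sf(abs(z))

    def se(self, index: int) -> float:
        return float(np.sqrt(self.cov_beta[index, index]))


def fit_lmm(y: np.ndarray, X: np.ndarray, groups: np.ndarray) -> LMMFit:
    """ML fit of y = X beta + u_group + e with scalar random intercepts.

    The variance ratio lambda = tau^2 / sigma^2 is profiled: for fixed
    lambda the GLS estimate and the error variance are closed-form via the
    Sherman-Morrison structure of each group block, leaving a bounded 1-D
    maximisation over log-lambda.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    idx = group_indices(groups)
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    s = np.vstack([X[g].sum(axis=0) for g in idx])  # G x p
    t = np.array([y[g].sum() for g in idx])
    ng = np.array([len(g) for g in idx], dtype=float)

    def profile(lam: float):
        c = lam / (1.0 + lam * ng)
        A = XtX - (s * c[:, None]).T @ s
        b = Xty - s.T @ (c * t)
        beta = np.linalg.solve(A, b)
        rss = yty - float(np.sum(c * t * t)) - float(beta @ b)
        rss = max(rss, 1e-12)
        sigma2 = rss / n
        llf = -0.5 * (
            n * (_LOG2PI + np.log(sigma2) + 1.0) + float(np.log1p(lam * ng).sum())
        )
        return llf, beta, sigma2, A

    def neg(loglam: float) -> float:
        return -profile(np.exp(loglam))[0]

    ll0, beta0, sig0, A0 = profile(0.0)
    res = minimize_scalar(neg, bounds=(-12.0, 8.0), method="bounded",
                          options={"xatol": 1e-6})
    if res.success and -res.fun > ll0 + 1e-10:
        lam = float(np.exp(res.x))
        llf, beta, sigma2, A = profile(lam)
    else:
        lam, llf, beta, sigma2, A = 0.0, ll0, beta0, sig0, A0
    cov_beta = sigma2 * np.linalg.inv(A)
    return LMMFit(
        beta=beta,
        cov_beta=cov_beta,
        sigma2=sigma2,
        tau2=lam * sigma2,
        llf=float(llf),
        n=n,
    )


def ols_llf(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, float]:
    """OLS coefficients and Gaussian ML log-likelihood."""
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    n = len(y)
    sigma2 = max(float(resid @ resid) / n, 1e-12)
    llf = -0.5 * n * (_LOG2PI + np.log(sigma2) + 1.0)
    return beta, llf


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * np.clip(eta, -30.0, 30.0)))


@dataclass
class LogisticFit:
    beta: np.ndarray
    sigma_u: float
    llf: float
    converged: bool
    separated: bool


def fit_logistic(y: np.ndarray, X: np.ndarray, ridge: float = 1e-8) -> LogisticFit:
    """Plain logistic regression by IRLS (tiny ridge for stability)."""
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    p_dim = X.shape[1]
    beta = np.zeros(p_dim)
    converged = False
    for _ in range(60):
        eta = X @ beta
        mu = _sigmoid(eta)
        w = np.maximum(mu * (1.0 - mu), 1e-10)
        z = eta + (y - mu) / w
        Xw = X * w[:, None]
        A = X.T @ Xw + ridge * np.eye(p_dim)
        new = np.linalg.solve(A, Xw.T @ z)
        if np.max(np.abs(new - beta)) < 1e-9:
            beta = new
            converged = True
            break
        beta = new
    eta = np.clip(X @ beta, -30, 30)
    llf = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    separated = bool(np.max(np.abs(beta)) > 50.0)
    return LogisticFit(beta=beta, sigma_u=0.0, llf=llf, converged=converged,
                       separated=separated)


def _pirls(
    y: np.ndarray,
    X: np.ndarray,
    idx: list[np.ndarray],
    codes: np.ndarray,
    sigma_u: float,
    beta0: np.ndarray,
    ridge: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """Joint penalised IRLS over (beta, u); returns the Laplace loglik."""
    n, p = X.shape
    G = len(idx)
    beta = beta0.copy()
    u = np.zeros(G)
    inv_s2 = 1.0 / (sigma_u**2)
    converged = False
    for _ in range(40):
        eta = X @ beta + u[codes]
        mu = _sigmoid(eta)
        w = np.maximum(mu * (1.0 - mu), 1e-10)
        z = eta + (y - mu) / w
        Xw = X * w[:, None]
        XtWX = X.T @ Xw + ridge * np.eye(p)
        XtWz = Xw.T @ z
        Wg = np.array([w[g].sum() for g in idx])
        D = Wg + inv_s2
        XtWZ = np.vstack([Xw[g].sum(axis=0) for g in idx]).T  # p x G
        ZtWz = np.array([(w[g] * z[g]).sum() for g in idx])
        S = XtWX - (XtWZ / D) @ XtWZ.T
        rhs = XtWz - XtWZ @ (ZtWz / D)
        new_beta = np.linalg.solve(S, rhs)
        new_u = (ZtWz - XtWZ.T @ new_beta) / D
        step = max(
            float(np.max(np.abs(new_beta - beta))), float(np.max(np.abs(new_u - u)))
        )
        beta, u = new_beta, new_u
        if step < 1e-8:
            converged = True
            break
    eta = np.clip(X @ beta + u[codes], -30, 30)
    mu = _sigmoid(eta)
    w = np.maximum(mu * (1.0 - mu), 1e-10)
    Wg = np.array([w[g].sum() for g in idx])
    ll_data = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    llf = (
        ll_data
        - 0.5 * float(np.sum(u**2)) * inv_s2
        - 0.5 * float(np.sum(np.log1p(sigma_u**2 * Wg)))
    )
    return beta, u, llf, converged


def fit_logistic_mixed(
    y: np.ndarray, X: np.ndarray, groups: np.ndarray
) -> LogisticFit:
    """Laplace-approximated logistic model with a section random intercept.

    The random-intercept standard deviation is maximised on a bounded log
    grid; the zero-variance boundary is checked explicitly, where the model
    reduces to plain logistic regression.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    codes, _ = _factorize(np.asarray(groups))
    idx = [np.flatnonzero(codes == c) for c in range(codes.max() + 1)]
    base = fit_logistic(y, X)

    def neg(log_sigma: float) -> float:
        return -_pirls(y, X, idx, codes, np.exp(log_sigma), base.beta)[2]

    res = minimize_scalar(
        neg, bounds=(np.log(1e-3), np.log(5.0)), method="bounded",
        options={"xatol": 1e-4},
    )
    if res.success and -res.fun > base.llf + 1e-8:
        sigma_u = float(np.exp(res.x))
        beta, _, llf, converged = _pirls(y, X, idx, codes, sigma_u, base.beta)
        separated = bool(np.max(np.abs(beta)) > 50.0)
        return LogisticFit(beta=beta, sigma_u=sigma_u, llf=float(llf),
                           converged=converged, separated=separated)
    return base
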