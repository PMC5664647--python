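"""Newton-Raphson maximum-likelihood engines for the inner fitting loops.

Both the logic-regression annealing score and the permutation re-fits of
the interaction models evaluate many thousands of small generalised
linear models; these solvers are written for that loop (dense normal
equations, step-halving, separation flagging).  Agreement with
statsmodels on shared problems is asserted in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GlmFit", "fit_binomial", "fit_logistic", "fit_exponential", "SEPARATION_BETA"]

# |beta| beyond this on the log-odds / log-rate scale is treated as a
# diverging (separated / boundary) estimate.
SEPARATION_BETA = 15.0


@dataclass
class GlmFit:
    """Result of a Newton ML fit."""

    beta: np.ndarray
    loglik: float
    cov: np.ndarray | None = None
    converged: bool = True
    separated: bool = False
    n_iter: int = 0
    message: str = ""
    flags: list[str] = field(default_factory=list)

    @property
    def se(self) -> np.ndarray:
        if self.cov is None:
            return np.full_like(self.beta, np.nan)
        return np.sqrt(np.clip(np.diag(self.cov), 0.0, np.inf))

    @property
    def deviance(self) -> float:
        return -2.0 * self.loglik


def _newton(loglik_grad_hess, p, max_iter, tol):
    beta = np.zeros(p)
    ll, g, H = loglik_grad_hess(beta)
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(-H, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(-H, g, rcond=None)[0]
        # step-halving on the log-likelihood
        t = 1.0
        for _ in range(30):
            cand = beta + t * step
            ll_new, g_new, H_new = loglik_grad_hess(cand)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            t *= 0.5
        else:
            return beta, ll, H, it, False
        improved = ll_new - ll
        beta, ll, g, H = cand, ll_new, g_new, H_new
        if abs(improved) < tol:
            return beta, ll, H, it, True
    return beta, ll, H, max_iter, False


def fit_binomial(
    X: np.ndarray,
    successes: np.ndarray,
    trials: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> GlmFit:
    """Binomial logistic ML fit on (possibly aggregated) rows.

    Rows with ``trials`` observations of which ``successes`` are events;
    subject-level data is the special case trials == 1.
    """
    X = np.asarray(X, dtype=float)
    k = np.asarray(successes, dtype=float)
    n = np.asarray(trials, dtype=float)
    p = X.shape[1]

    def llgh(beta):
        eta = X @ beta
        # log(1 + e^eta) stably
        log1p = np.where(eta > 30, eta, np.log1p(np.exp(np.minimum(eta, 30))))
        ll = float(k @ eta - n @ log1p)
        mu = 1.0 / (1.0 + np.exp(-eta))
        g = X.T @ (k - n * mu)
        w = n * mu * (1.0 - mu)
        H = -(X.T * w) @ X
        return ll, g, H

    beta, ll, H, n_iter, converged = _newton(llgh, p, max_iter, tol)
    separated = bool(np.any(np.abs(beta) > SEPARATION_BETA))
    cov = None
    try:
        cov = np.linalg.inv(-H)
    except np.linalg.LinAlgError:
        pass
    return GlmFit(beta, ll, cov, converged, separated, n_iter)


def fit_logistic(X, y, **kw) -> GlmFit:
    """Subject-level Bernoulli logistic fit (thin wrapper over fit_binomial)."""
    y = np.asarray(y, dtype=float)
    return fit_binomial(X, y, np.ones_like(y), **kw)


def fit_exponential(
    X: np.ndarray,
    events: np.ndarray,
    exposure_time: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> GlmFit:
    """Exponential (constant-hazard) survival regression, log link.

    Rate for row i is exp(x_i' beta); the log-likelihood is
    sum d_i * eta_i - t_i * exp(eta_i), which also covers aggregated rows
    with d = total events and t = total exposure time.
    """
    X = np.asarray(X, dtype=float)
    d = np.asarray(events, dtype=float)
    t = np.asarray(exposure_time, dtype=float)
    if np.any(t < 0):
        raise ValueError("negative exposure time")
    if d.sum() <= 0:
        raise ValueError("no events: exponential MLE does not exist")
    p = X.shape[1]

    def llgh(beta):
        eta = np.clip(X @ beta, -500, 500)
        lam_t = np.exp(eta) * t
        ll = float(d @ eta - lam_t.sum())
        g = X.T @ (d - lam_t)
        H = -(X.T * lam_t) @ X
        return ll, g, H

    beta, ll, H, n_iter, converged = _newton(llgh, p, max_iter, tol)
    separated = bool(np.any(np.abs(beta) > SEPARATION_BETA))
    cov = None
    try:
        cov = np.linalg.inv(-H)
    except np.linalg.LinAlgError:
        pass
    return GlmFit(beta, ll, cov, converged, separated, n_iter)
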