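"""Maximum-likelihood fitters for logistic and proportional-odds models.

Both fitters use full Newton iterations with analytic gradient and
Hessian and step-halving, converging on the relative change in the
(penalised) log-likelihood (tolerance 1e-8 by default).  They return
the parameter covariance (inverse observed information), which the
chained-equations imputer uses for approximate-posterior parameter
draws, and support an optional ridge penalty on the slope coefficients
to stabilise separable fits.

The proportional-odds model is parameterised as

    P(Y <= j | x) = expit(theta_j - x' beta),   theta_1 < ... < theta_{k-1}

so that beta has the same orientation as a logistic regression on a
high-vs-low split of Y.  With k = 2 the model *is* logistic regression
(theta_1 = -intercept), which the tests exploit as an analytic check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .errors import DataError, FitError

_DEFAULT_TOL = 1e-8
_MAX_ITER = 200
_SEPARATION_BOUND = 12.0
#: ridge penalties attempted in order when a fit fails or separates
RIDGE_SCHEDULE = (0.0, 1.0, 10.0)


@dataclass
class FitResult:
    """Outcome of one maximum-likelihood fit."""

    params: np.ndarray
    param_names: list[str]
    loglike: float
    loglike_null: float
    cov: np.ndarray
    n: int
    converged: bool
    separation: bool
    ridge: float
    family: str
    n_cutpoints: int = 0  # 0 for logistic

    @property
    def slopes(self) -> np.ndarray:
        """Covariate coefficients (excluding intercept / cutpoints)."""
        if self.family == "logistic":
            return self.params[1:]
        return self.params[self.n_cutpoints:]


def _solve(H: np.ndarray, g: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.solve(H, g)
    except np.linalg.LinAlgError:
        return np.linalg.lstsq(H, g, rcond=None)[0]


# ----------------------------------------------------------------------
# Logistic regression

def logistic_loglike(beta: np.ndarray, X1: np.ndarray, y: np.ndarray) -> float:
    eta = X1 @ beta
    # log(1+exp) computed stably
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def fit_logistic_mle(
    X: np.ndarray,
    y: np.ndarray,
    ridge: float = 0.0,
    tol: float = _DEFAULT_TOL,
    max_iter: int = _MAX_ITER,
    param_names: list[str] | None = None,
) -> FitResult:
    """Logistic MLE; ``X`` excludes the intercept (added internally).

    The ridge penalty (0.5 * ridge * ||slopes||^2) never touches the
    intercept.  ``loglike`` is always the unpenalised value.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if n == 0:
        raise DataError("empty design matrix")
    if not np.isin(y, (0.0, 1.0)).all():
        raise DataError("logistic outcome must be 0/1")
    if y.min() == y.max():
        raise DataError("logistic outcome has a single class")
    X1 = np.hstack([np.ones((n, 1)), X])
    pen_mask = np.r_[0.0, np.ones(p)]

    beta = np.zeros(p + 1)
    beta[0] = np.log(y.mean() / (1 - y.mean()))
    pll = logistic_loglike(beta, X1, y) - 0.5 * ridge * float((pen_mask * beta**2).sum())
    converged = False
    for _ in range(max_iter):
        mu = expit(X1 @ beta)
        w = mu * (1 - mu)
        grad = X1.T @ (y - mu) - ridge * pen_mask * beta
        H = X1.T @ (w[:, None] * X1) + ridge * np.diag(pen_mask)  # negative Hessian
        step = _solve(H, grad)
        new = beta + step
        new_pll = logistic_loglike(new, X1, y) - 0.5 * ridge * float((pen_mask * new**2).sum())
        halvings = 0
        while not np.isfinite(new_pll) or new_pll < pll - 1e-12:
            step *= 0.5
            new = beta + step
            new_pll = logistic_loglike(new, X1, y) - 0.5 * ridge * float((pen_mask * new**2).sum())
            halvings += 1
            if halvings > 30:
                break
        if halvings > 30:
            break
        beta, delta, pll = new, new_pll - pll, new_pll
        if abs(delta) <= tol * (1.0 + abs(pll)):
            converged = True
            break

    mu = expit(X1 @ beta)
    w = np.maximum(mu * (1 - mu), 1e-12)
    info = X1.T @ (w[:, None] * X1) + ridge * np.diag(pen_mask)
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
    ybar = y.mean()
    ll_null = float(n * (ybar * np.log(ybar) + (1 - ybar) * np.log(1 - ybar)))
    separation = (not converged) or bool(np.abs(beta[1:]).max(initial=0.0) > _SEPARATION_BOUND)
    names = ["intercept"] + (param_names or [f"x{i}" for i in range(p)])
    return FitResult(beta, names, logistic_loglike(beta, X1, y), ll_null, cov,
                     n, converged, separation, ridge, "logistic")


# ----------------------------------------------------------------------
# Proportional-odds (cumulative logit) regression

def _po_parts(theta: np.ndarray, beta: np.ndarray, X: np.ndarray, y: np.ndarray, k: int):
    """Per-observation probabilities and logistic densities at the two
    active thresholds (upper for category y, lower for y-1)."""
    eta = X @ beta
    up_ok = y < k - 1
    lo_ok = y > 0
    z_u = np.where(up_ok, theta[np.minimum(y, k - 2)] - eta, np.inf)
    z_l = np.where(lo_ok, theta[np.maximum(y - 1, 0)] - eta, -np.inf)
    F_u = np.where(up_ok, expit(z_u), 1.0)
    F_l = np.where(lo_ok, expit(z_l), 0.0)
    prob = np.maximum(F_u - F_l, 1e-300)
    f_u = np.where(up_ok, F_u * (1 - F_u), 0.0)
    f_l = np.where(lo_ok, F_l * (1 - F_l), 0.0)
    fp_u = np.where(up_ok, f_u * (1 - 2 * F_u), 0.0)
    fp_l = np.where(lo_ok, f_l * (1 - 2 * F_l), 0.0)
    return prob, f_u, f_l, fp_u, fp_l


def po_loglike(theta: np.ndarray, beta: np.ndarray, X: np.ndarray, y: np.ndarray, k: int) -> float:
    prob = _po_parts(theta, beta, X, y, k)[0]
    return float(np.log(prob).sum())


def po_category_probs(theta: np.ndarray, beta: np.ndarray, X: np.ndarray) -> np.ndarray:
    """(n, k) matrix of category probabilities."""
    eta = np.asarray(X, dtype=float) @ beta
    cum = expit(theta[None, :] - eta[:, None])
    cum = np.hstack([np.zeros((len(eta), 1)), cum, np.ones((len(eta), 1))])
    return np.maximum(np.diff(cum, axis=1), 0.0)


def fit_proportional_odds_mle(
    X: np.ndarray,
    y_codes: np.ndarray,
    n_categories: int,
    ridge: float = 0.0,
    tol: float = _DEFAULT_TOL,
    max_iter: int = _MAX_ITER,
    param_names: list[str] | None = None,
) -> FitResult:
    """Proportional-odds MLE on 0-based category codes.

    ``n_categories`` (k >= 2) counts the distinct, already collapsed
    categories; cutpoints are kept strictly increasing throughout (a
    Newton step that breaks monotonicity is halved).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y_codes)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    k = int(n_categories)
    if k < 2:
        raise DataError("proportional-odds outcome needs >= 2 categories")
    if y.min() < 0 or y.max() > k - 1:
        raise DataError("category codes outside range")
    counts = np.bincount(y, minlength=k).astype(float)
    if (counts == 0).any():
        raise DataError("empty outcome category; collapse categories first")

    cum = np.cumsum(counts)[:-1] / n
    theta = np.log(cum / (1 - cum))
    beta = np.zeros(p)

    def pll(th, be):
        return po_loglike(th, be, X, y, k) - 0.5 * ridge * float(be @ be)

    cur = pll(theta, beta)
    converged = False
    for _ in range(max_iter):
        prob, f_u, f_l, fp_u, fp_l = _po_parts(theta, beta, X, y, k)
        a = f_u / prob
        b = f_l / prob
        A = fp_u / prob - a**2
        C = -fp_l / prob - b**2
        B = a * b
        u_idx = np.minimum(y, k - 2)        # valid only where y < k-1
        l_idx = np.maximum(y - 1, 0)        # valid only where y > 0
        up_ok = y < k - 1
        lo_ok = y > 0

        grad_theta = (np.bincount(u_idx[up_ok], weights=a[up_ok], minlength=k - 1)
                      - np.bincount(l_idx[lo_ok], weights=b[lo_ok], minlength=k - 1))
        grad_beta = X.T @ (b - a) - ridge * beta
        grad = np.r_[grad_theta, grad_beta]

        H = np.zeros((k - 1 + p, k - 1 + p))
        d_tt = (np.bincount(u_idx[up_ok], weights=A[up_ok], minlength=k - 1)
                + np.bincount(l_idx[lo_ok], weights=C[lo_ok], minlength=k - 1))
        H[np.arange(k - 1), np.arange(k - 1)] = d_tt
        both = up_ok & lo_ok
        if both.any():
            off = np.bincount(l_idx[both], weights=B[both], minlength=k - 1)
            for j in range(k - 2):
                H[j, j + 1] = H[j + 1, j] = off[j]
        for j in range(k - 1):
            w = np.zeros(n)
            m_u = up_ok & (u_idx == j)
            m_l = lo_ok & (l_idx == j)
            w[m_u] -= (A + B)[m_u]
            w[m_l] -= (B + C)[m_l]
            row = X.T @ w
            H[j, k - 1:] = row
            H[k - 1:, j] = row
        H[k - 1:, k - 1:] = X.T @ ((A + 2 * B + C)[:, None] * X) - ridge * np.eye(p)

        step = _solve(-H, grad)
        scale = 1.0
        improved = False
        for _h in range(31):
            th_new = theta + scale * step[: k - 1]
            be_new = beta + scale * step[k - 1:]
            if np.all(np.diff(th_new) > 0) or k == 2:
                new = pll(th_new, be_new)
                if np.isfinite(new) and new >= cur - 1e-12:
                    improved = True
                    break
            scale *= 0.5
        if not improved:
            break
        delta = new - cur
        theta, beta, cur = th_new, be_new, new
        if abs(delta) <= tol * (1.0 + abs(cur)):
            converged = True
            break

    # observed information at the optimum for the covariance
    prob, f_u, f_l, fp_u, fp_l = _po_parts(theta, beta, X, y, k)
    a, b = f_u / prob, f_l / prob
    A = fp_u / prob - a**2
    C = -fp_l / prob - b**2
    B = a * b
    u_idx = np.minimum(y, k - 2)
    l_idx = np.maximum(y - 1, 0)
    up_ok, lo_ok = y < k - 1, y > 0
    H = np.zeros((k - 1 + p, k - 1 + p))
    d_tt = (np.bincount(u_idx[up_ok], weights=A[up_ok], minlength=k - 1)
            + np.bincount(l_idx[lo_ok], weights=C[lo_ok], minlength=k - 1))
    H[np.arange(k - 1), np.arange(k - 1)] = d_tt
    both = up_ok & lo_ok
    if both.any():
        off = np.bincount(l_idx[both], weights=B[both], minlength=k - 1)
        for j in range(k - 2):
            H[j, j + 1] = H[j + 1, j] = off[j]
    for j in range(k - 1):
        w = np.zeros(n)
        m_u = up_ok & (u_idx == j)
        m_l = lo_ok & (l_idx == j)
        w[m_u] -= (A + B)[m_u]
        w[m_l] -= (B + C)[m_l]
        row = X.T @ w
        H[j, k - 1:] = row
        H[k - 1:, j] = row
    H[k - 1:, k - 1:] = X.T @ ((A + 2 * B + C)[:, None] * X) - ridge * np.eye(p)
    try:
        cov = np.linalg.inv(-H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(-H)

    ll = po_loglike(theta, beta, X, y, k)
    ll_null = float((counts * np.log(counts / n)).sum())
    separation = (not converged) or bool(np.abs(beta).max(initial=0.0) > _SEPARATION_BOUND)
    names = [f"cut_{j + 1}" for j in range(k - 1)] + (param_names or [f"x{i}" for i in range(p)])
    return FitResult(np.r_[theta, beta], names, ll, ll_null, cov, n,
                     converged, separation, ridge, "proportional_odds", n_cutpoints=k - 1)


# ----------------------------------------------------------------------

def fit_with_retries(fit_fn, *args, ridges=RIDGE_SCHEDULE, **kwargs) -> FitResult:
    """Run a fitter through the ridge-stabilisation schedule.

    The unpenalised fit is attempted first; on failure, non-convergence
    or separation the fit is retried with each ridge penalty in turn.
    Raises :class:`FitError` after the schedule is exhausted.
    """
    last = None
    for ridge in ridges:
        try:
            res = fit_fn(*args, ridge=ridge, **kwargs)
        except DataError:
            raise
        except Exception as exc:  # numerical failure: retry stabilised
            last = exc
            continue
        if res.converged and not res.separation:
            return res
        last = res
    if isinstance(last, FitResult):
        if last.converged:
            return last  # converged but flagged; usable with its flag
        raise FitError("fit failed to converge after ridge retries")
    raise FitError(f"fit failed after ridge retries: {last}")
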