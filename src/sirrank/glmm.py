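"""Conditional (random-intercept) and marginal logistic models.

The conditional model is a logistic GLMM with a single hospital-level
random intercept:

    logit p_ij = a_i + x_ij' beta,   a_i ~ N(alpha, sigma_alpha^2),

fitted by maximum likelihood with adaptive Gauss-Hermite quadrature over
the scalar random effect.  The marginal (population-averaged) model is an
ordinary logistic regression logit p*_ij = alpha_s + x_ij' beta_s ignoring
clustering.  The two parameterizations are linked by the cumulative
Gaussian approximation to the logistic: every conditional coefficient is
attenuated by 1 / sqrt(c^2 sigma_alpha^2 + 1) with c = 16 sqrt(3) / (15 pi).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy.optimize import minimize
from scipy.special import expit, roots_hermite
from sklearn.base import BaseEstimator

__all__ = [
    "ConditionalParams",
    "MarginalParams",
    "ATTENUATION_C",
    "attenuate",
    "RandomInterceptLogit",
    "MarginalLogit",
    "fit_conditional",
    "fit_marginal",
    "random_intercept_loglik",
]

#: c in the logistic-probit bridge, 16*sqrt(3)/(15*pi) ~= 0.588.
ATTENUATION_C = 16.0 * np.sqrt(3.0) / (15.0 * np.pi)


class FitError(RuntimeError):
    """Model fit failed (separation, degeneracy or non-convergence).

    ``last_params`` carries the final iterate when one is available.
    """

    def __init__(self, message, last_params=None):
        super().__init__(message)
        self.last_params = last_params


@dataclass(frozen=True)
class ConditionalParams:
    """Parameters (alpha, beta, sigma_alpha^2) of the random-intercept model."""

    alpha: float
    beta: np.ndarray
    sigma_alpha_sq: float

    def __post_init__(self):
        object.__setattr__(self, "beta", np.asarray(self.beta, dtype=float))
        if self.sigma_alpha_sq < 0:
            raise ValueError("sigma_alpha_sq must be nonnegative")

    @property
    def sigma_alpha(self) -> float:
        return float(np.sqrt(self.sigma_alpha_sq))


@dataclass(frozen=True)
class MarginalParams:
    """Population-averaged intercept and coefficients (alpha_s, beta_s)."""

    alpha_s: float
    beta_s: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "beta_s", np.asarray(self.beta_s, dtype=float))


def attenuate(cond: ConditionalParams) -> MarginalParams:
    """Map conditional to marginal parameters.

    Every coefficient is divided by sqrt(c^2 sigma_alpha^2 + 1); the map is
    the identity at sigma_alpha^2 = 0 and shrinks strictly toward zero as
    the random-effect variance grows.
    """
    shrink = 1.0 / np.sqrt(ATTENUATION_C**2 * cond.sigma_alpha_sq + 1.0)
    return MarginalParams(alpha_s=cond.alpha * shrink, beta_s=cond.beta * shrink)


# ---------------------------------------------------------------------------
# likelihood machinery
# ---------------------------------------------------------------------------


def _group_modes(theta_a, eta_x, y, gidx, m, alpha, sigma_sq, tol=1e-10, max_iter=50):
    """Posterior mode of each hospital's random intercept, by Newton steps.

    ``theta_a`` is the warm-start vector (modified in place is avoided);
    ``eta_x`` = X @ beta per row.
    """
    a = theta_a.copy()
    ysum = np.bincount(gidx, weights=y, minlength=m)
    for _ in range(max_iter):
        p = expit(a[gidx] + eta_x)
        grad = ysum - np.bincount(gidx, weights=p, minlength=m) - (a - alpha) / sigma_sq
        hess = np.bincount(gidx, weights=p * (1.0 - p), minlength=m) + 1.0 / sigma_sq
        step = grad / hess
        np.clip(step, -2.0, 2.0, out=step)
        a += step
        if np.max(np.abs(step)) < tol:
            break
    p = expit(a[gidx] + eta_x)
    hess = np.bincount(gidx, weights=p * (1.0 - p), minlength=m) + 1.0 / sigma_sq
    return a, hess


def random_intercept_loglik(
    params: ConditionalParams, X, y, group_index, quad_points: int = 15, _mode_cache=None
) -> float:
    """Integrated log-likelihood of the random-intercept logistic model.

    Uses adaptive Gauss-Hermite quadrature: nodes are centered at each
    hospital's posterior mode and scaled by the local curvature, so a
    modest number of nodes (default 15) is accurate even for large
    hospitals.  For ``sigma_alpha_sq = 0`` the model collapses to ordinary
    logistic likelihood with intercept alpha.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    gidx = np.asarray(group_index, dtype=np.intp)
    m = int(gidx.max()) + 1
    eta_x = X @ params.beta
    if params.sigma_alpha_sq == 0.0:
        eta = params.alpha + eta_x
        return float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    sigma_sq = params.sigma_alpha_sq
    start = _mode_cache if _mode_cache is not None else np.full(m, params.alpha)
    a_hat, hess = _group_modes(start, eta_x, y, gidx, m, params.alpha, sigma_sq)
    if _mode_cache is not None:
        _mode_cache[:] = a_hat
    s = 1.0 / np.sqrt(hess)  # per-hospital quadrature scale
    z, w = roots_hermite(quad_points)
    logw = np.log(w)
    # log integrand at transformed nodes, per hospital x node
    log_f = np.empty((m, quad_points))
    for q in range(quad_points):
        a_q = a_hat + np.sqrt(2.0) * s * z[q]
        eta = a_q[gidx] + eta_x
        row_ll = y * eta - np.logaddexp(0.0, eta)
        ll_i = np.bincount(gidx, weights=row_ll, minlength=m)
        log_phi = -0.5 * np.log(2.0 * np.pi * sigma_sq) - 0.5 * (a_q - params.alpha) ** 2 / sigma_sq
        log_f[:, q] = logw[q] + z[q] ** 2 + ll_i + log_phi
    mx = log_f.max(axis=1)
    integral = mx + np.log(np.exp(log_f - mx[:, None]).sum(axis=1))
    return float(np.sum(integral + 0.5 * np.log(2.0) + np.log(s)))


class RandomInterceptLogit(BaseEstimator):
    """Maximum-likelihood logistic regression with a hospital random intercept.

    Parameters
    ----------
    quad_points : int, default 15
        Number of adaptive Gauss-Hermite nodes for the random-effect
        integral.
    tol : float, default 1e-8
        Relative convergence tolerance on the log-likelihood.
    max_iter : int, default 200
        Optimizer iteration budget.

    Attributes
    ----------
    intercept_ : float
        Estimated random-intercept mean alpha.
    coef_ : ndarray of shape (p,)
        Estimated covariate effects beta.
    sigma_alpha_ : float
        Estimated random-intercept standard deviation (0 at the boundary).
    loglik_ : float
        Maximized integrated log-likelihood.
    n_iter_ : int
    converged_ : bool
    """

    def __init__(self, quad_points: int = 15, tol: float = 1e-8, max_iter: int = 200):
        self.quad_points = quad_points
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y, groups):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        groups = np.asarray(groups)
        if X.ndim != 2 or len(y) != X.shape[0] or len(groups) != X.shape[0]:
            raise ValueError("X, y, groups must be row-aligned")
        _, gidx = np.unique(groups, return_inverse=True)
        gidx = gidx.astype(np.intp)
        m = int(gidx.max()) + 1
        if m < 2:
            raise ValueError("need at least two hospitals")
        if y.sum() == 0 or y.sum() == len(y):
            raise FitError("all outcomes identical: conditional model not identifiable")
        sd = X.std(axis=0)
        if np.any(sd == 0):
            cols = np.nonzero(sd == 0)[0].tolist()
            raise FitError(f"constant covariate column(s) {cols}; drop before fitting")

        p = X.shape[1]
        # start from the marginal fit, de-attenuated at a mid-range sigma
        start_m = _irls(np.column_stack([np.ones(len(y)), X]), y)
        sigma0 = 0.4
        infl = np.sqrt(ATTENUATION_C**2 * sigma0**2 + 1.0)
        theta0 = np.concatenate([start_m * infl, [np.log(sigma0)]])

        mode_cache = np.full(m, theta0[0])

        def negll(theta):
            params = ConditionalParams(
                alpha=theta[0], beta=theta[1 : 1 + p], sigma_alpha_sq=np.exp(2.0 * theta[-1])
            )
            return -random_intercept_loglik(
                params, X, y, gidx, self.quad_points, _mode_cache=mode_cache
            )

        bounds = [(None, None)] * (1 + p) + [(-7.0, 2.0)]
        res = minimize(
            negll,
            theta0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": self.tol, "maxiter": self.max_iter},
        )
        theta = res.x
        sigma = float(np.exp(theta[-1]))
        boundary = sigma < 1e-3
        if boundary:
            warnings.warn(
                "sigma_alpha estimate at the zero boundary; reporting 0", stacklevel=2
            )
            sigma = 0.0
        params = ConditionalParams(
            alpha=float(theta[0]), beta=theta[1 : 1 + p].copy(), sigma_alpha_sq=sigma**2
        )
        if not res.success and "MAXLS" not in str(res.message):
            raise FitError(f"GLMM fit did not converge: {res.message}", last_params=params)
        self.intercept_ = params.alpha
        self.coef_ = params.beta
        self.sigma_alpha_ = sigma
        self.loglik_ = float(-res.fun)
        self.n_iter_ = int(res.nit)
        self.converged_ = bool(res.success)
        self.n_hospitals_ = m
        return self

    def params_(self) -> ConditionalParams:
        return ConditionalParams(self.intercept_, self.coef_, self.sigma_alpha_**2)


# ---------------------------------------------------------------------------
# marginal model
# ---------------------------------------------------------------------------


def _irls(X1, y, start=None, max_iter=50, tol=1e-10):
    """Newton-Raphson logistic MLE on a design that already has the
    intercept column.  Lean path used inside hot simulation loops; the
    user-facing fit goes through statsmodels.  Raises FitError on
    divergence (separation) or degenerate outcomes."""
    n, p = X1.shape
    ybar = y.mean()
    if ybar == 0.0 or ybar == 1.0:
        raise FitError("degenerate outcomes: no events or all events")
    beta = np.zeros(p) if start is None else np.asarray(start, dtype=float).copy()
    if start is None:
        beta[0] = np.log(ybar / (1.0 - ybar))
    dev_old = np.inf
    for _ in range(max_iter):
        eta = X1 @ beta
        mu = expit(eta)
        w = mu * (1.0 - mu)
        # guard against complete separation driving weights to 0
        grad = X1.T @ (y - mu)
        H = (X1 * w[:, None]).T @ X1
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as e:
            raise FitError(f"singular information matrix: {e}") from e
        beta = beta + step
        if not np.all(np.isfinite(beta)) or np.max(np.abs(beta)) > 1e4:
            raise FitError("logistic fit diverged (likely separation)")
        dev = -2.0 * np.sum(y * eta - np.logaddexp(0.0, eta))
        if abs(dev_old - dev) < tol * (abs(dev) + 1.0):
            break
        dev_old = dev
    return beta


class MarginalLogit(BaseEstimator):
    """Ordinary logistic regression (population-averaged model).

    Fitted via statsmodels GLM with a binomial family; no clustering
    adjustment, exactly the model whose coefficients feed the SIR
    denominator.

    Attributes
    ----------
    intercept_ : float
    coef_ : ndarray of shape (p,)
    """

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if y.sum() == 0 or y.sum() == len(y):
            raise FitError("degenerate outcomes: no events or all events")
        if X.size:
            sd = X.std(axis=0)
            if np.any(sd == 0):
                cols = np.nonzero(sd == 0)[0].tolist()
                raise FitError(
                    f"constant covariate column(s) {cols}; drop before fitting"
                )
        X1 = sm.add_constant(X, has_constant="add")
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error", sm.tools.sm_exceptions.PerfectSeparationWarning)
                res = sm.GLM(y, X1, family=sm.families.Binomial()).fit()
        except Exception as e:  # separation or numeric failure
            raise FitError(f"marginal logistic fit failed: {e}") from e
        if not np.all(np.isfinite(res.params)) or np.max(np.abs(res.params)) > 1e4:
            raise FitError("marginal logistic fit diverged (likely separation)")
        self.intercept_ = float(res.params[0])
        self.coef_ = np.asarray(res.params[1:], dtype=float)
        self.loglik_ = float(res.llf)
        return self

    def params_(self) -> MarginalParams:
        return MarginalParams(self.intercept_, self.coef_)


# ---------------------------------------------------------------------------
# cohort-level wrappers
# ---------------------------------------------------------------------------


def fit_conditional(cohort, quad_points: int = 15, tol: float = 1e-8):
    """Fit the random-intercept model to a cohort.

    Returns ``(ConditionalParams, loglik)``.
    """
    est = RandomInterceptLogit(quad_points=quad_points, tol=tol)
    est.fit(cohort.covariates, cohort.outcomes, cohort.group_index)
    return est.params_(), est.loglik_


def fit_marginal(cohort) -> MarginalParams:
    """Fit the population-averaged logistic model to a cohort."""
    est = MarginalLogit().fit(cohort.covariates, cohort.outcomes)
    return est.params_()
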