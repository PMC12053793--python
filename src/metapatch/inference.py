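"""Generalised linear models and a spatial random-effect extension.

This module implements the statistical machinery the occupancy analysis rests
on, from scratch:

* :class:`GLM` -- binomial (logit link) and Gaussian (identity link) models
  fitted by iteratively reweighted least squares (IRLS), with a monotone
  log-likelihood path enforced by step-halving;
* :class:`SpatialGLMM` -- a binomial GLM plus one Gaussian random effect per
  plot with covariance ``sigma2 * exp(-h / rho)`` in inter-plot distance
  ``h``, fitted by maximising the Laplace-approximate marginal likelihood
  (inner Newton over the joint density with fixed effects profiled, outer
  Nelder--Mead over ``(log sigma2, log rho)``);
* type II analysis-of-deviance tests (likelihood ratio for plain GLMs, Wald
  for spatial models) and the small-sample AICc.

Estimators follow scikit-learn conventions (``fit`` / ``predict``,
``get_params`` / ``set_params``, trailing-underscore fitted attributes); a
lightweight :class:`ModelSpec` maps named data-frame columns, pairwise
interactions and a family onto a design matrix, and module-level functions
(:func:`fit_glm`, :func:`type2_tests`, ...) wrap the estimators for
spec-driven use.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg as sla
from scipy import optimize, stats
from scipy.special import expit
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

#: |coefficient| on the logit scale beyond which a fit is flagged as separated.
SEPARATION_BOUND = 30.0


# ---------------------------------------------------------------------------
# model specification and design matrices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """Names a response, main-effect columns, pairwise interactions, a family
    and whether a spatial random effect is included."""

    response: str
    terms: tuple = ()
    interactions: tuple = ()
    family: str = "binomial"
    spatial: bool = False

    def __post_init__(self):
        object.__setattr__(self, "terms", tuple(self.terms))
        object.__setattr__(self, "interactions", tuple(tuple(i) for i in self.interactions))
        if self.family not in ("binomial", "gaussian"):
            raise ValueError(f"unknown family {self.family!r}")
        for a, b in self.interactions:
            if a not in self.terms or b not in self.terms:
                raise ValueError(f"interaction {a}:{b} references undeclared main effect")

    @property
    def term_names(self) -> tuple:
        return self.terms + tuple(f"{a}:{b}" for a, b in self.interactions)

    def drop(self, term: str) -> "ModelSpec":
        """Spec without ``term`` (a main effect or an ``a:b`` interaction)."""
        if ":" in term:
            a, b = term.split(":")
            inter = tuple(i for i in self.interactions if set(i) != {a, b})
            return ModelSpec(self.response, self.terms, inter, self.family, self.spatial)
        terms = tuple(t for t in self.terms if t != term)
        inter = tuple(i for i in self.interactions if term not in i)
        return ModelSpec(self.response, terms, inter, self.family, self.spatial)


def build_design(spec: ModelSpec, data: pd.DataFrame, with_response: bool = True):
    """Design matrix (no intercept column; estimators add it) after
    complete-case filtering over the response and every term column.

    Returns ``(X, y, kept_index)``; ``y`` is None when ``with_response`` is
    False (prediction on new data keeps all rows, NaN predictors propagate).
    """
    cols = list(spec.terms) + ([spec.response] if with_response else [])
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise KeyError(f"data lacks column(s) {missing}")
    if with_response:
        mask = data[cols].notna().all(axis=1)
        sub = data.loc[mask]
    else:
        sub = data
    X = sub[list(spec.terms)].to_numpy(float)
    for a, b in spec.interactions:
        X = np.column_stack([X, sub[a].to_numpy(float) * sub[b].to_numpy(float)])
    y = sub[spec.response].to_numpy(float) if with_response else None
    return X, y, sub.index


# ---------------------------------------------------------------------------
# information criteria
# ---------------------------------------------------------------------------

def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample Akaike criterion: ``AIC + 2k(k+1)/(n-k-1)``.

    Requires ``n > k + 1``; the correction vanishes as ``n`` grows.
    """
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def _check_rank(X: np.ndarray, names) -> None:
    if X.shape[1] == 0:
        return
    _, R, piv = sla.qr(X, mode="economic", pivoting=True)
    d = np.abs(np.diag(R))
    tol = d[0] * max(X.shape) * np.finfo(float).eps if d[0] > 0 else 0.0
    bad = d <= tol
    if bad.any():
        culprits = [names[piv[i]] for i in np.flatnonzero(bad)]
        raise ValueError(f"design matrix is rank deficient; collinear term(s): {culprits}")


def _bin_loglik(y, eta):
    # sum y*eta - log(1 + exp(eta)), stable for large |eta|
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


# ---------------------------------------------------------------------------
# plain GLM
# ---------------------------------------------------------------------------

class GLM(BaseEstimator):
    """Binomial-logit or Gaussian-identity GLM fitted by IRLS.

    Parameters
    ----------
    family : {"binomial", "gaussian"}
    tol : float
        Relative log-likelihood convergence tolerance.
    max_iter : int
    add_intercept : bool
        Prepend an intercept column (the default; pass False only when the
        caller supplies one).

    Attributes
    ----------
    coef_ : ndarray, (p+1,) -- intercept first.
    se_, cov_ : observed-information standard errors / covariance.
    loglik_, loglik_path_, deviance_, null_deviance_
    aic_, aicc_, n_, df_model_ : ``df_model_`` counts estimated parameters
        (Gaussian includes the residual variance).
    converged_, separation_ : diagnostics; separation is flagged when any
        logit-scale coefficient exceeds ``SEPARATION_BOUND`` in magnitude.
    """

    def __init__(self, family="binomial", tol=1e-10, max_iter=100, add_intercept=True):
        self.family = family
        self.tol = tol
        self.max_iter = max_iter
        self.add_intercept = add_intercept

    # -- internals ---------------------------------------------------------
    def _design(self, X):
        X = np.asarray(X, float)
        if X.ndim == 1:
            X = X[:, None]
        if self.add_intercept:
            X = np.column_stack([np.ones(len(X)), X])
        return X

    def fit(self, X, y, feature_names=None):
        Xd = self._design(X)
        y = np.asarray(y, float).ravel()
        if len(y) != len(Xd):
            raise ValueError("X and y length mismatch")
        if len(y) == 0:
            raise ValueError("no rows to fit after complete-case filtering")
        names = list(feature_names) if feature_names is not None else [
            f"x{i}" for i in range(Xd.shape[1] - int(self.add_intercept))
        ]
        self.feature_names_in_ = names
        all_names = (["(Intercept)"] if self.add_intercept else []) + names
        _check_rank(Xd, all_names)

        if self.family == "gaussian":
            self._fit_gaussian(Xd, y)
        elif self.family == "binomial":
            if not np.isin(y, (0.0, 1.0)).all():
                raise ValueError("binomial response must be coded 0/1")
            self._fit_binomial(Xd, y)
        else:  # pragma: no cover - guarded by ModelSpec too
            raise ValueError(f"unknown family {self.family!r}")

        self.n_ = len(y)
        self.aic_ = -2.0 * self.loglik_ + 2.0 * self.df_model_
        self.aicc_ = aicc(self.loglik_, self.df_model_, self.n_) if self.n_ > self.df_model_ + 1 else np.nan
        return self

    def _fit_gaussian(self, X, y):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        n, p = X.shape
        rss = float(resid @ resid)
        sigma2_mle = rss / n
        ll = -0.5 * n * (np.log(2 * np.pi * max(sigma2_mle, 1e-300)) + 1.0)
        s2 = rss / (n - p) if n > p else np.nan
        XtX_inv = np.linalg.pinv(X.T @ X)
        self.coef_ = beta
        self.cov_ = XtX_inv * s2
        self.se_ = np.sqrt(np.diag(self.cov_))
        self.loglik_ = ll
        self.loglik_path_ = [ll]
        self.deviance_ = rss
        ybar = y.mean()
        self.null_deviance_ = float(((y - ybar) ** 2).sum())
        self.scale_ = s2
        self.df_model_ = p + 1  # + residual variance
        self.n_iter_ = 1
        self.converged_ = True
        self.separation_ = False

    def _fit_binomial(self, X, y):
        n, p = X.shape
        beta = np.zeros(p)
        ll = _bin_loglik(y, X @ beta)
        path = [ll]
        converged = False
        for it in range(1, self.max_iter + 1):
            eta = X @ beta
            mu = expit(eta)
            w = np.clip(mu * (1.0 - mu), 1e-10, None)
            z = eta + (y - mu) / w
            Xw = X * w[:, None]
            try:
                beta_new = sla.solve(X.T @ Xw, Xw.T @ z, assume_a="pos")
            except sla.LinAlgError:
                beta_new, *_ = np.linalg.lstsq(Xw * np.sqrt(w)[:, None] / w[:, None], z * np.sqrt(w), rcond=None)
            # step-halve until the log-likelihood does not decrease
            step = beta_new - beta
            ll_new = _bin_loglik(y, X @ (beta + step))
            halvings = 0
            while ll_new < ll - 1e-12 and halvings < 30:
                step *= 0.5
                ll_new = _bin_loglik(y, X @ (beta + step))
                halvings += 1
            beta = beta + step
            path.append(ll_new)
            if abs(ll_new - ll) < self.tol * (abs(ll) + 1.0):
                ll = ll_new
                converged = True
                break
            ll = ll_new
        self.coef_ = beta
        eta = X @ beta
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        info = X.T @ (X * w[:, None])
        self.cov_ = np.linalg.pinv(info)
        self.se_ = np.sqrt(np.diag(self.cov_))
        self.loglik_ = ll
        self.loglik_path_ = path
        self.deviance_ = -2.0 * ll  # saturated log-likelihood is 0 for 0/1 data
        p0 = np.clip(y.mean(), 1e-12, 1 - 1e-12)
        self.null_deviance_ = -2.0 * float(np.sum(y * np.log(p0) + (1 - y) * np.log1p(-p0)))
        self.df_model_ = p
        self.n_iter_ = len(path) - 1
        self.converged_ = converged
        # diverging coefficients, a perfectly fitted binary response (all
        # probabilities pinned at 0/1) or a stalled IRLS all indicate
        # (quasi-)separation / a boundary MLE
        self.separation_ = (bool(np.any(np.abs(beta) > SEPARATION_BOUND))
                            or self.deviance_ < 1e-6
                            or not converged)
        if self.separation_:
            logger.warning("possible separation: max |coef| = %.2f", np.abs(beta).max())

    # -- prediction --------------------------------------------------------
    def linear_predictor(self, X):
        return self._design(X) @ self.coef_

    def predict(self, X):
        """Expected response: probability (binomial) or mean (Gaussian)."""
        eta = self.linear_predictor(X)
        return expit(eta) if self.family == "binomial" else eta


# ---------------------------------------------------------------------------
# spatial GLMM (binomial only)
# ---------------------------------------------------------------------------

def _joint_newton(X, offset, y, Sigma_inv, beta0, u0, max_iter=50, tol=1e-9):
    """Maximise the joint binomial log-density over (beta, u).

    f(beta, u) = sum[y*eta - log(1+e^eta)] - u' Sigma_inv u / 2,
    eta = offset + X beta + u.  Returns (beta, u, f, W) at the mode.
    """
    n = len(y)
    p = X.shape[1]
    beta, u = beta0.copy(), u0.copy()

    def fval(beta, u):
        eta = offset + X @ beta + u
        return _bin_loglik(y, eta) - 0.5 * float(u @ (Sigma_inv @ u))

    f = fval(beta, u)
    for _ in range(max_iter):
        eta = offset + X @ beta + u
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        r = y - mu
        g = np.concatenate([X.T @ r, r - Sigma_inv @ u])
        H = np.empty((p + n, p + n))
        Xw = X * w[:, None]
        H[:p, :p] = X.T @ Xw
        H[:p, p:] = Xw.T
        H[p:, :p] = Xw
        H[p:, p:] = Sigma_inv + np.diag(w)
        try:
            step = sla.cho_solve(sla.cho_factor(H, lower=True), g)
        except sla.LinAlgError:
            step = np.linalg.lstsq(H, g, rcond=None)[0]
        db, du = step[:p], step[p:]
        f_new = fval(beta + db, u + du)
        halvings = 0
        while f_new < f - 1e-12 and halvings < 30:
            db *= 0.5
            du *= 0.5
            f_new = fval(beta + db, u + du)
            halvings += 1
        beta, u = beta + db, u + du
        if abs(f_new - f) < tol * (abs(f) + 1.0):
            f = f_new
            break
        f = f_new
    eta = offset + X @ beta + u
    mu = expit(eta)
    w = np.clip(mu * (1.0 - mu), 1e-12, None)
    return beta, u, f, w


def laplace_loglik(offset, y, Sigma):
    """Laplace-approximate log marginal likelihood of a binomial model with a
    fixed linear predictor ``offset`` plus one Gaussian random effect per
    observation with covariance ``Sigma``.

    Integrates over the random effects only (fixed effects held at
    ``offset``); used directly by the low-dimensional quadrature cross-check.
    """
    offset = np.asarray(offset, float)
    y = np.asarray(y, float)
    n = len(y)
    cf = sla.cho_factor(Sigma, lower=True)
    Sigma_inv = sla.cho_solve(cf, np.eye(n))
    logdet_Sigma = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    _, u, f, w = _joint_newton(np.empty((n, 0)), offset, y, Sigma_inv,
                               np.empty(0), np.zeros(n))
    H_uu = Sigma_inv + np.diag(w)
    sign, logdet_H = np.linalg.slogdet(H_uu)
    # the (2*pi)^{n/2} factors of prior and Laplace volume cancel
    return f - 0.5 * logdet_Sigma - 0.5 * logdet_H


class SpatialGLMM(BaseEstimator):
    """Binomial GLM with a spatially correlated Gaussian random effect.

    One random intercept per plot, covariance ``sigma2 * exp(-h / rho)`` for
    inter-plot planar distance ``h`` (metres).  The marginal likelihood is
    approximated by a Laplace expansion around the joint (beta, u) mode; the
    fixed effects are profiled by joint inner Newton optimisation and the
    outer search runs Nelder--Mead over ``(log sigma2, log rho)``.

    Parameters
    ----------
    nugget : float
        Diagonal jitter added to the correlation matrix for stability with
        near-coincident plots.
    fixed_sigma2, fixed_rho : float, optional
        Pin either variance parameter instead of estimating it.
    dense_cap : int
        Refuse fits beyond this size (dense covariance algebra).

    Attributes
    ----------
    coef_, se_ : fixed effects (intercept first) and their standard errors
        from the Schur complement of the joint Hessian.
    sigma2_, rho_ : estimated marginal variance and decay range (metres).
    loglik_ : Laplace-approximate marginal log-likelihood.
    aic_, aicc_ : counting the fixed effects plus 2 covariance parameters.
    boundary_ : True when sigma2 collapsed to ~0 (model reduces to a GLM).
    random_effects_ : posterior-mode random effects at the optimum.
    """

    def __init__(self, tol=1e-8, max_outer=250, nugget=1e-6,
                 fixed_sigma2=None, fixed_rho=None, dense_cap=4000,
                 add_intercept=True):
        self.tol = tol
        self.max_outer = max_outer
        self.nugget = nugget
        self.fixed_sigma2 = fixed_sigma2
        self.fixed_rho = fixed_rho
        self.dense_cap = dense_cap
        self.add_intercept = add_intercept

    def _design(self, X):
        X = np.asarray(X, float)
        if X.ndim == 1:
            X = X[:, None]
        if self.add_intercept:
            X = np.column_stack([np.ones(len(X)), X])
        return X

    def fit(self, X, y, coords, feature_names=None):
        Xd = self._design(X)
        y = np.asarray(y, float).ravel()
        coords = np.asarray(coords, float)
        n, p = Xd.shape
        if n > self.dense_cap:
            raise ValueError(f"n={n} exceeds dense-solver cap {self.dense_cap}")
        if coords.shape[0] != n:
            raise ValueError("coords and X length mismatch")
        self.feature_names_in_ = list(feature_names) if feature_names is not None else [
            f"x{i}" for i in range(p - int(self.add_intercept))
        ]

        D = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
        eye = np.eye(n)

        start = GLM(family="binomial", add_intercept=False).fit(Xd, y)
        beta0 = start.coef_.copy()
        self._glm_loglik_ = start.loglik_

        state = {"beta": beta0.copy(), "u": np.zeros(n)}

        def profile_nll(theta):
            s2, rho = np.exp(theta)
            C = np.exp(-D / rho)
            C[np.diag_indices_from(C)] += self.nugget
            try:
                cf = sla.cho_factor(C, lower=True)
            except sla.LinAlgError:
                return 1e10
            C_inv = sla.cho_solve(cf, eye)
            Sigma_inv = C_inv / s2
            logdet_Sigma = n * np.log(s2) + 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
            beta, u, f, w = _joint_newton(Xd, np.zeros(n), y, Sigma_inv,
                                          state["beta"], state["u"])
            state["beta"], state["u"] = beta, u
            H_uu = Sigma_inv + np.diag(w)
            sign, logdet_H = np.linalg.slogdet(H_uu)
            if sign <= 0:
                return 1e10
            state["cache"] = (beta, u, w, Sigma_inv)
            return -(f - 0.5 * logdet_Sigma - 0.5 * logdet_H)

        # outer search over the free covariance parameters
        nz = D[D > 0]
        rho0 = self.fixed_rho if self.fixed_rho is not None else max(np.median(nz) / 5.0, 1.0)
        s20 = self.fixed_sigma2 if self.fixed_sigma2 is not None else 0.5

        free = [self.fixed_sigma2 is None, self.fixed_rho is None]

        def wrap(theta_free):
            theta = np.log([s20, rho0])
            theta[np.flatnonzero(free)] = theta_free
            return profile_nll(theta)

        x0 = np.log([s20, rho0])[np.flatnonzero(free)]
        if len(x0):
            res = optimize.minimize(wrap, x0, method="Nelder-Mead",
                                    options={"maxiter": self.max_outer,
                                             "xatol": 1e-3, "fatol": 1e-6})
            theta = np.log([s20, rho0])
            theta[np.flatnonzero(free)] = res.x
            self.converged_ = bool(res.success)
            nll = profile_nll(theta)  # re-evaluate to refresh the cache
        else:
            theta = np.log([s20, rho0])
            nll = profile_nll(theta)
            self.converged_ = True
        if not self.converged_:
            logger.warning("spatial GLMM outer optimiser did not converge")

        s2, rho = np.exp(theta)
        beta, u, w, Sigma_inv = state["cache"]
        self.coef_ = beta
        self.random_effects_ = u
        self.sigma2_ = float(s2)
        self.rho_ = float(rho)
        self.loglik_ = float(-nll)
        self.boundary_ = s2 < 1e-6
        if self.boundary_:
            logger.info("sigma2 at boundary; spatial model reduces to plain GLM")

        # fixed-effect covariance: Schur complement of the joint Hessian
        Xw = Xd * w[:, None]
        H_uu = Sigma_inv + np.diag(w)
        sol = sla.cho_solve(sla.cho_factor(H_uu, lower=True), Xw)
        info_beta = Xd.T @ Xw - Xw.T @ sol
        self.cov_ = np.linalg.pinv(info_beta)
        self.se_ = np.sqrt(np.diag(self.cov_))
        self.n_ = n
        self.df_model_ = p + 2  # + (sigma2, rho)
        self.aic_ = -2.0 * self.loglik_ + 2.0 * self.df_model_
        self.aicc_ = aicc(self.loglik_, self.df_model_, n) if n > self.df_model_ + 1 else np.nan
        return self

    def linear_predictor(self, X):
        return self._design(X) @ self.coef_

    def predict(self, X):
        """Population-level prediction (random effect at its zero mean)."""
        return expit(self.linear_predictor(X))

    @property
    def family(self):
        return "binomial"


# ---------------------------------------------------------------------------
# spec-driven wrappers
# ---------------------------------------------------------------------------

def fit_glm(spec: ModelSpec, data: pd.DataFrame, coords_cols=("x_m", "y_m")):
    """Fit ``spec`` to ``data`` after complete-case filtering.

    Returns the fitted estimator (:class:`GLM` or :class:`SpatialGLMM`) with
    ``spec_``, ``n_dropped_`` and term names attached.
    """
    X, y, kept = build_design(spec, data)
    names = list(spec.term_names)
    if spec.spatial:
        if spec.family != "binomial":
            raise ValueError("spatial models implemented for the binomial family only")
        coords = data.loc[kept, list(coords_cols)].to_numpy(float)
        est = SpatialGLMM().fit(X, y, coords, feature_names=names)
    else:
        est = GLM(family=spec.family).fit(X, y, feature_names=names)
    est.spec_ = spec
    est.n_dropped_ = len(data) - len(kept)
    if est.n_dropped_:
        logger.info("fit_glm[%s]: %d row(s) dropped as incomplete; n=%d",
                    spec.response, est.n_dropped_, est.n_)
    return est


def predict_response(fit, newdata: pd.DataFrame):
    """Expected response on new data at the fixed effects (population level)."""
    spec = fit.spec_
    X, _, _ = build_design(spec, newdata, with_response=False)
    return fit.predict(X)


@dataclass(frozen=True)
class TermTest:
    """One type II test: the model with all marginality-respecting terms vs
    the model without this term."""

    term: str
    statistic: float
    df: int
    pvalue: float
    test: str  # "LR" or "Wald"
    note: str = ""


def _term_columns(spec: ModelSpec, term: str):
    names = list(spec.term_names)
    if ":" in term:
        a, b = term.split(":")
        idx = [i for i, nm in enumerate(names)
               if ":" in nm and set(nm.split(":")) == {a, b}]
    else:
        idx = [i for i, nm in enumerate(names) if nm == term]
    return [i + 1 for i in idx]  # +1 for the intercept column


def type2_tests(spec: ModelSpec, data: pd.DataFrame, fit=None) -> list:
    """Type II tests for every term of ``spec``.

    For plain GLMs each main effect is tested by a likelihood-ratio
    comparison of the model containing all other terms (excluding any
    interaction involving the tested effect, per marginality) against the
    model without it; interactions are tested against the full model.  A
    main effect whose interaction is retained in the full model is still
    tested this way (type II convention); spatial models use single-fit Wald
    chi-square tests instead of refits.
    """
    results = []
    if spec.spatial:
        full = fit if fit is not None else fit_glm(spec, data)
        for term in spec.term_names:
            cols = _term_columns(spec, term)
            b = full.coef_[cols]
            V = full.cov_[np.ix_(cols, cols)]
            stat = float(b @ np.linalg.solve(V, b))
            df = len(cols)
            results.append(TermTest(term, stat, df, float(stats.chi2.sf(stat, df)), "Wald"))
        return results

    for term in spec.term_names:
        if ":" not in term:
            # marginality: drop interactions involving this main effect from both models
            base = ModelSpec(spec.response, spec.terms,
                             tuple(i for i in spec.interactions if term not in i),
                             spec.family, spec.spatial)
        else:
            base = spec
        reduced = base.drop(term)
        # fit both models on the base model's complete cases
        _, _, kept = build_design(base, data)
        sub = data.loc[kept]
        full_fit = fit_glm(base, sub)
        red_fit = fit_glm(reduced, sub)
        stat = 2.0 * (full_fit.loglik_ - red_fit.loglik_)
        df = full_fit.df_model_ - red_fit.df_model_
        stat = max(stat, 0.0)
        results.append(TermTest(term, stat, df, float(stats.chi2.sf(stat, df)), "LR"))
    return results


def fit_gaussian_trend(variable: str, data: pd.DataFrame,
                       distance: str = "dist_km", log10p1: bool = False):
    """Gaussian GLM of a covariate on distance to the range limit.

    With ``log10p1`` the response is ``log10(x + 1)`` (zeros are common in
    abundance covariates).  A positive slope means the covariate increases
    toward the range core.
    """
    df = data[[variable, distance]].copy()
    if log10p1:
        df[variable] = np.log10(df[variable] + 1.0)
    spec = ModelSpec(response=variable, terms=(distance,), family="gaussian")
    return fit_glm(spec, df)


def fit_to_dict(fit) -> dict:
    """JSON-ready summary of a fitted model."""
    names = ["(Intercept)"] + list(getattr(fit, "feature_names_in_", []))
    out = {
        "family": fit.family,
        "coef": dict(zip(names, [float(c) for c in fit.coef_])),
        "se": dict(zip(names, [float(s) for s in fit.se_])),
        "loglik": float(fit.loglik_),
        "aic": float(fit.aic_),
        "aicc": float(fit.aicc_) if np.isfinite(fit.aicc_) else None,
        "n": int(fit.n_),
        "converged": bool(fit.converged_),
    }
    if isinstance(fit, SpatialGLMM):
        out.update(sigma2=float(fit.sigma2_), rho_m=float(fit.rho_),
                   boundary=bool(fit.boundary_))
    else:
        out["separation"] = bool(getattr(fit, "separation_", False))
    if hasattr(fit, "n_dropped_"):
        out["n_dropped"] = int(fit.n_dropped_)
    return out
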