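"""Fitting, standard errors and confidence intervals.

Maximization uses Nelder-Mead from an ordinary-least-squares start.  By
default the variance components are optimized on the log scale and the
latent cross-covariance through a bounded correlation (atanh) transform,
which keeps every iterate in the interior of the parameter space; a
raw-scale option mirrors unconstrained optimization over the natural
parameters.  Standard errors come from the finite-difference observed
information at the optimum, mapped back to the natural scale by the
delta method; the sandwich (robust) variance A^{-1} B A^{-1} combines
the summed per-study Hessians with the summed outer products of
per-study scores and is the recommended variance under the
pseudo-likelihood working independence assumption.

The naive (measurement-error-ignoring) analysis is a two-stage weighted
least-squares meta-regression: coefficients from WLS with fixed inverse
within-study-variance weights (or unweighted), residual heterogeneity
estimated as the mean squared raw residual, and lm-style
dispersion-scaled coefficient standard errors.
"""

from __future__ import annotations


from typing import Literal, Sequence

import numpy as np
from scipy import stats
from scipy.optimize import minimize
from statsmodels.tools import numdiff

from . import approx_likelihood as al
from .data_model import (ErrorModel, FitResult, Method, ModelParams,
                         ObservedTriple, stack_triples)

__all__ = ["ols_start", "fit", "fit_naive_wls", "hessian_se", "sandwich_se",
           "wald_ci"]

_VAR_FLOOR = 1e-8
_VARIANCE_PARAMS = ("tau2", "sigma_xi2", "sigma_zeta2")


def ols_start(
    obs: np.ndarray,
    gammas: np.ndarray,
    has_covariate: bool,
    zeta_offsets: np.ndarray | None = None,
) -> ModelParams:
    """Moment/least-squares starting values for the structural model.

    Regression coefficients from OLS of eta_hat on the observed
    regressors; latent means from sample means; variance components from
    observed variances minus mean sampling variances, floored at a small
    positive value.
    """
    eta = obs[:, 0]
    cols = [np.ones_like(eta), obs[:, 1]]
    if obs.shape[1] == 3:
        cols.append(obs[:, 2])
    elif zeta_offsets is not None:
        cols.append(np.asarray(zeta_offsets, dtype=float))
    x = np.column_stack(cols)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("collinear design in OLS start")
    beta, *_ = np.linalg.lstsq(x, eta, rcond=None)
    resid = eta - x @ beta
    tau2 = max(float(np.var(resid) - gammas[:, 0, 0].mean()), 1e-2)
    sigma_xi2 = max(float(np.var(obs[:, 1]) - gammas[:, 1, 1].mean()), 1e-2)
    p = ModelParams(
        beta0=float(beta[0]),
        beta1=float(beta[1]),
        beta2=float(beta[2]) if len(beta) == 3 else 0.0,
        mu_xi=float(obs[:, 1].mean()),
        tau2=tau2,
        sigma_xi2=sigma_xi2,
    )
    if obs.shape[1] == 3:
        p.mu_zeta = float(obs[:, 2].mean())
        p.sigma_zeta2 = max(float(np.var(obs[:, 2]) - gammas[:, 2, 2].mean()), 1e-2)
    return p


def _free_names(mode: str, has_obs_covariate: bool, has_offset: bool,
                estimate_sigma_xizeta: bool) -> tuple:
    if mode == "naive":
        names = ["beta0", "beta1"] + (["beta2"] if has_obs_covariate or has_offset else [])
        return tuple(names + ["tau2"])
    if mode == "classical":
        names = ["beta0", "beta1"] + (["beta2"] if has_offset else [])
        return tuple(names + ["mu_xi", "tau2", "sigma_xi2"])
    names = ["beta0", "beta1", "beta2", "mu_xi", "mu_zeta",
             "tau2", "sigma_xi2", "sigma_zeta2"]
    if estimate_sigma_xizeta:
        names.append("sigma_xizeta")
    return tuple(names)


class _Parametrization:
    """Map between natural-scale free parameters and optimizer coordinates."""

    def __init__(self, free_names: Sequence[str], scale: str = "log"):
        self.free_names = tuple(free_names)
        self.scale = scale
        self.has_corr = "sigma_xizeta" in self.free_names

    def to_opt(self, params: ModelParams) -> np.ndarray:
        phi = []
        for name in self.free_names:
            v = getattr(params, name)
            if self.scale == "log" and name in _VARIANCE_PARAMS:
                phi.append(np.log(max(v, _VAR_FLOOR)))
            elif self.scale == "log" and name == "sigma_xizeta":
                sx = max(params.sigma_xi2, _VAR_FLOOR)
                sz = max(params.sigma_zeta2, _VAR_FLOOR)
                rho = np.clip(v / np.sqrt(sx * sz), -0.999, 0.999)
                phi.append(np.arctanh(rho))
            else:
                phi.append(v)
        return np.array(phi)

    def to_params(self, phi: np.ndarray, template: ModelParams) -> ModelParams:
        d = template.to_dict()
        for name, v in zip(self.free_names, phi):
            if self.scale == "log" and name in _VARIANCE_PARAMS:
                d[name] = float(np.exp(v))
            else:
                d[name] = float(v)
        if self.scale == "log" and self.has_corr:
            i = self.free_names.index("sigma_xizeta")
            rho = np.tanh(phi[i])
            d["sigma_xizeta"] = float(
                rho * np.sqrt(d["sigma_xi2"] * d["sigma_zeta2"])
            )
        return al.unvalidated_params(**d)

    def jacobian_diag(self, phi: np.ndarray) -> np.ndarray:
        """d(theta)/d(phi) for the delta method (diagonal approximation).

        For the correlation coordinate the diagonal term holds the
        variances fixed; the full Jacobian cross-terms are ignored,
        which is exact when sigma_xizeta is not estimated.
        """
        jac = np.ones(len(phi))
        for j, name in enumerate(self.free_names):
            if self.scale != "log":
                continue
            if name in _VARIANCE_PARAMS:
                jac[j] = np.exp(phi[j])
            elif name == "sigma_xizeta":
                i_x = self.free_names.index("sigma_xi2")
                i_z = self.free_names.index("sigma_zeta2")
                sx, sz = np.exp(phi[i_x]), np.exp(phi[i_z])
                jac[j] = (1.0 - np.tanh(phi[j]) ** 2) * np.sqrt(sx * sz)
        return jac


def fit_naive_wls(
    obs: np.ndarray,
    gammas: np.ndarray,
    zeta_offsets: np.ndarray | None = None,
    weighting: Literal["inverse_variance", "unweighted"] = "inverse_variance",
) -> FitResult:
    """Two-stage naive meta-regression ignoring measurement error.

    Stage 1: (weighted) least squares of eta_hat on the observed
    regressors.  Stage 2: tau2_hat = mean squared raw residual.
    Coefficient SEs are the dispersion-scaled WLS ones; the tau2 SE uses
    the chi-square variance of the residual sum of squares.
    """
    eta = obs[:, 0]
    cols = [np.ones_like(eta), obs[:, 1]]
    if obs.shape[1] == 3:
        cols.append(obs[:, 2])
    elif zeta_offsets is not None:
        cols.append(np.asarray(zeta_offsets, dtype=float))
    x = np.column_stack(cols)
    n, p = x.shape
    w = 1.0 / gammas[:, 0, 0] if weighting == "inverse_variance" else np.ones(n)
    xtwx = x.T @ (x * w[:, None])
    beta = np.linalg.solve(xtwx, x.T @ (eta * w))
    resid = eta - x @ beta
    tau2 = float(np.mean(resid ** 2))
    dispersion = float(np.sum(w * resid ** 2) / (n - p))
    se_beta = np.sqrt(dispersion * np.diag(np.linalg.inv(xtwx)))
    se_tau2 = tau2 * np.sqrt(2.0 * (n - p)) / n
    params = ModelParams(
        beta0=float(beta[0]), beta1=float(beta[1]),
        beta2=float(beta[2]) if p == 3 else 0.0, tau2=tau2,
    )
    names = ["beta0", "beta1"] + (["beta2"] if p == 3 else []) + ["tau2"]
    ses = dict(zip(names, [*se_beta, se_tau2]))
    v = gammas[:, 0, 0] * 0 + tau2
    loglik = float(np.sum(stats.norm.logpdf(resid, scale=np.sqrt(v))))
    return FitResult(
        params=params, loglik=loglik, converged=True, n_studies=n,
        method=Method.NAIVE, error_model=ErrorModel.APPROXIMATE,
        se_hessian=ses, free_names=tuple(names),
    )


def fit(
    data: Sequence[ObservedTriple],
    mode: al.Mode = "classical",
    zeta_offsets: np.ndarray | None = None,
    start: ModelParams | None = None,
    estimate_sigma_xizeta: bool = False,
    naive_variant: Literal["wls", "ols", "ml"] = "wls",
    naive_include_s2: bool = True,
    param_scale: Literal["log", "raw"] = "log",
    xatol: float = 1e-8,
    fatol: float = 1e-8,
    compute_se: bool = True,
    compute_sandwich: bool = False,
    exact_objective=None,
    records=None,
) -> FitResult:
    """Maximize the selected (pseudo-)likelihood; never raises on
    optimizer failure (``converged`` is set instead).

    ``exact_objective``: optional callable ``f(params) -> float``
    (negative log-likelihood) replacing the approximate-model objective,
    e.g. a closure over one of the exact-likelihood functions; the
    observed triples are still used for starting values.
    """
    obs, gammas = stack_triples(data)
    has_obs_cov = obs.shape[1] == 3

    if mode == "naive" and naive_variant in ("wls", "ols"):
        weighting = "inverse_variance" if naive_variant == "wls" else "unweighted"
        return fit_naive_wls(obs, gammas, zeta_offsets, weighting)

    free = _free_names(mode, has_obs_cov, zeta_offsets is not None,
                       estimate_sigma_xizeta and mode in ("full", "pseudo"))
    if start is None:
        start = ols_start(obs, gammas, has_obs_cov, zeta_offsets)
    par = _Parametrization(free, scale=param_scale)
    phi0 = par.to_opt(start)

    include_s2 = naive_include_s2 if mode == "naive" else False

    def objective(phi):
        params = par.to_params(phi, start)
        if param_scale == "raw" and any(
            getattr(params, v) < 0 for v in _VARIANCE_PARAMS
        ):
            return np.inf
        if exact_objective is not None:
            try:
                val = exact_objective(params)
            except (ValueError, FloatingPointError):
                val = np.inf
        else:
            val = al.neg_loglik_arrays(params, obs, gammas, mode, zeta_offsets,
                                       naive_include_s2=include_s2)
        # large finite penalty keeps the simplex arithmetic warning-free
        return min(val, 1e30)

    opt = minimize(
        objective, phi0, method="Nelder-Mead",
        options=dict(xatol=xatol, fatol=fatol,
                     maxiter=5000 * len(phi0), maxfev=5000 * len(phi0)),
    )
    phi_hat = opt.x
    params_hat = par.to_params(phi_hat, start)
    converged = bool(opt.success) and np.isfinite(opt.fun)
    # a variance pinned at the floor is a boundary solution: the estimates
    # are still the (boundary) MLE, so the fit counts as convergent, but
    # the message records it
    at_floor = any(
        name in _VARIANCE_PARAMS and getattr(params_hat, name) < 10 * _VAR_FLOOR
        for name in free
    )

    method = Method.NAIVE if mode == "naive" else (
        Method.PSEUDO_LIKELIHOOD if mode == "pseudo" else Method.LIKELIHOOD
    )
    result = FitResult(
        params=_validated(params_hat), loglik=-float(opt.fun),
        converged=converged, n_studies=len(data),
        method=method,
        error_model=ErrorModel.EXACT if exact_objective is not None
        else ErrorModel.APPROXIMATE,
        free_names=free,
        message=(opt.message + "; variance at boundary floor") if at_floor
        else opt.message,
    )
    if compute_se and converged:
        try:
            cov_phi, hess_ok = _cov_from_hessian(objective, phi_hat)
            jac = par.jacobian_diag(phi_hat)
            result.se_hessian = dict(
                zip(free, np.sqrt(np.clip(np.diag(cov_phi), 0, None)) * np.abs(jac))
            )
            result.converged = result.converged and hess_ok
            if compute_sandwich and exact_objective is None:
                result.se_sandwich = _sandwich_from_parts(
                    params_hat, obs, gammas, mode, free, zeta_offsets,
                    include_s2, cov_phi, jac, phi_hat, par, start)
        except np.linalg.LinAlgError:
            result.converged = False
    return result


def _validated(params: ModelParams) -> ModelParams:
    d = params.to_dict()
    for v in _VARIANCE_PARAMS:
        d[v] = max(d[v], 0.0)
    try:
        return ModelParams(**d)
    except ValueError:
        return al.unvalidated_params(**d)


def _cov_from_hessian(objective, phi_hat):
    hess = numdiff.approx_hess(phi_hat, objective)
    if not np.all(np.isfinite(hess)):
        return np.full((len(phi_hat),) * 2, np.nan), False
    eigvals = np.linalg.eigvalsh(hess)
    # near-zero curvature (boundary solutions) makes the information
    # numerically singular: fall back to the pseudo-inverse
    if eigvals[0] <= 1e-10 * max(eigvals[-1], 1.0):
        return np.linalg.pinv(hess), False
    return np.linalg.inv(hess), True


def _sandwich_from_parts(params_hat, obs, gammas, mode, free, zeta_offsets,
                         include_s2, cov_phi, jac, phi_hat, par, template):
    """A^{-1} B A^{-1} on the optimizer scale, delta-mapped to natural."""
    scores_nat = al.score_per_study(params_hat, obs, gammas, mode, free,
                                    zeta_offsets, include_s2)
    scores_phi = scores_nat * jac  # chain rule, diagonal Jacobian
    b = scores_phi.T @ scores_phi
    a_inv = cov_phi  # inverse of the summed per-study Hessians
    cov_sand = a_inv @ b @ a_inv
    return dict(zip(free, np.sqrt(np.clip(np.diag(cov_sand), 0, None)) * np.abs(jac)))


def hessian_se(fit_result: FitResult, data: Sequence[ObservedTriple],
               mode: al.Mode | None = None,
               zeta_offsets: np.ndarray | None = None) -> dict:
    """Recompute observed-information SEs at the fitted parameters."""
    if not fit_result.converged:
        raise ValueError("Hessian SEs require a converged fit")
    if fit_result.se_hessian:
        return fit_result.se_hessian
    obs, gammas = stack_triples(data)
    free = fit_result.free_names
    par = _Parametrization(free, scale="log")
    phi_hat = par.to_opt(fit_result.params)

    def objective(phi):
        return al.neg_loglik_arrays(par.to_params(phi, fit_result.params),
                                    obs, gammas, mode or "classical", zeta_offsets)

    cov_phi, _ = _cov_from_hessian(objective, phi_hat)
    jac = par.jacobian_diag(phi_hat)
    return dict(zip(free, np.sqrt(np.clip(np.diag(cov_phi), 0, None)) * np.abs(jac)))


def sandwich_se(fit_result: FitResult, data: Sequence[ObservedTriple],
                mode: al.Mode, zeta_offsets: np.ndarray | None = None) -> dict:
    """Robust A^{-1} B A^{-1} SEs at the fitted parameters."""
    if not fit_result.converged:
        raise ValueError("sandwich SEs require a converged fit")
    obs, gammas = stack_triples(data)
    free = fit_result.free_names
    par = _Parametrization(free, scale="log")
    phi_hat = par.to_opt(fit_result.params)

    def objective(phi):
        return al.neg_loglik_arrays(par.to_params(phi, fit_result.params),
                                    obs, gammas, mode, zeta_offsets)

    cov_phi, _ = _cov_from_hessian(objective, phi_hat)
    jac = par.jacobian_diag(phi_hat)
    return _sandwich_from_parts(fit_result.params, obs, gammas, mode, free,
                                zeta_offsets, False, cov_phi, jac, phi_hat,
                                par, fit_result.params)


def wald_ci(estimate: float, se: float, level: float = 0.95):
    """Wald interval estimate +/- z_{(1+level)/2} * se."""
    if se < 0:
        raise ValueError("standard error must be nonnegative")
    z = stats.norm.ppf(0.5 * (1.0 + level))
    return estimate - z * se, estimate + z * se
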