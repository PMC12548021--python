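"""Closed-form (pseudo-)likelihoods under the approximate error model.

Under the structural model the latent treatment risk is linear in the
latent baseline risk and covariate,

    eta_i = beta0 + beta1 * xi_i + beta2 * zeta_i + eps_i,
    xi_i ~ N(mu_xi, sigma_xi2),  zeta_i ~ N(mu_zeta, sigma_zeta2),
    eps_i ~ N(0, tau2),

and the observed measures are the latent ones plus normal sampling error
with known within-study covariance Gamma_i.  The marginal law of
(eta_hat, xi_hat, zeta_hat) is then multivariate normal with mean mu and
covariance Sigma + Gamma_i, giving a closed-form likelihood.

Modes
-----
``classical``
    Bivariate model in (eta_hat, xi_hat); an error-free covariate, when
    present, enters only through the mean as a per-study offset
    beta2 * zeta_i.
``full``
    Trivariate model using the full Gamma_i (Taylor within-study
    covariances included).
``pseudo``
    Trivariate model under the working independence assumption: the
    off-diagonal entries of Gamma_i are set to zero.  Identical to
    ``full`` whenever those entries are zero to begin with.
``naive``
    Measurement error ignored: univariate normal likelihood for eta_hat
    with mean beta0 + beta1*xi_hat + beta2*zeta_hat and residual
    variance tau2 (optionally s_eta2 + tau2), the observed regressors
    treated as fixed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .data_model import ModelParams, ObservedTriple, stack_triples

__all__ = [
    "MarginalMoments",
    "marginal_moments",
    "neg_loglik",
    "neg_loglik_arrays",
    "per_study_loglik",
    "score_per_study",
]

Mode = Literal["classical", "full", "pseudo", "naive"]

_LOG2PI = np.log(2.0 * np.pi)


def unvalidated_params(**fields) -> ModelParams:
    """Build a ModelParams without invariant checks.

    Finite-difference probes may step a variance marginally below zero;
    the density evaluation itself guards against indefinite covariances.
    """
    p = object.__new__(ModelParams)
    defaults = dict(beta0=0.0, beta1=0.0, beta2=0.0, mu_xi=0.0, mu_zeta=0.0,
                    tau2=0.0, sigma_xi2=0.0, sigma_zeta2=0.0, sigma_xizeta=0.0)
    defaults.update(fields)
    p.__dict__.update(defaults)
    return p


@dataclass
class MarginalMoments:
    mean: np.ndarray  # (k,) marginal mean (classical: before the error-free offset)
    cov: np.ndarray   # (k, k) latent covariance Sigma; add Gamma_i per study


def marginal_moments(params: ModelParams, has_covariate: bool) -> MarginalMoments:
    """Marginal mean and latent covariance of the observed measures.

    The trivariate covariance uses the internally consistent general
    form with the latent cross-covariance sigma_xizeta propagated into
    every entry; it reduces to the familiar display when
    sigma_xizeta = 0.
    """
    p = params
    if has_covariate:
        mean = np.array([p.beta0 + p.beta1 * p.mu_xi + p.beta2 * p.mu_zeta,
                         p.mu_xi, p.mu_zeta])
        s11 = (p.beta1 ** 2 * p.sigma_xi2 + p.beta2 ** 2 * p.sigma_zeta2
               + 2.0 * p.beta1 * p.beta2 * p.sigma_xizeta + p.tau2)
        s12 = p.beta1 * p.sigma_xi2 + p.beta2 * p.sigma_xizeta
        s13 = p.beta2 * p.sigma_zeta2 + p.beta1 * p.sigma_xizeta
        cov = np.array([
            [s11, s12, s13],
            [s12, p.sigma_xi2, p.sigma_xizeta],
            [s13, p.sigma_xizeta, p.sigma_zeta2],
        ])
    else:
        mean = np.array([p.beta0 + p.beta1 * p.mu_xi, p.mu_xi])
        cov = np.array([
            [p.beta1 ** 2 * p.sigma_xi2 + p.tau2, p.beta1 * p.sigma_xi2],
            [p.beta1 * p.sigma_xi2, p.sigma_xi2],
        ])
    if np.linalg.eigvalsh(cov)[0] < -1e-10:
        raise ValueError("latent covariance matrix is not positive semidefinite")
    return MarginalMoments(mean=mean, cov=cov)


def _diag_only(gammas: np.ndarray) -> np.ndarray:
    out = np.zeros_like(gammas)
    idx = np.arange(gammas.shape[1])
    out[:, idx, idx] = gammas[:, idx, idx]
    return out


def per_study_loglik(
    params: ModelParams,
    obs: np.ndarray,
    gammas: np.ndarray,
    mode: Mode,
    zeta_offsets: np.ndarray | None = None,
    naive_include_s2: bool = False,
) -> np.ndarray:
    """Vector of per-study log-density contributions.

    ``obs`` is (n, 2) for classical/naive without observed covariate
    column, or (n, 3) with the covariate in the last column.  For
    ``classical`` mode with an error-free covariate, pass its values as
    ``zeta_offsets``.
    """
    p = params
    if mode == "naive":
        eta = obs[:, 0]
        pred = p.beta0 + p.beta1 * obs[:, 1]
        if obs.shape[1] == 3:
            pred = pred + p.beta2 * obs[:, 2]
        elif zeta_offsets is not None:
            pred = pred + p.beta2 * np.asarray(zeta_offsets)
        var = p.tau2 + (gammas[:, 0, 0] if naive_include_s2 else 0.0)
        if np.any(var <= 0):
            return np.full(len(eta), -np.inf)
        r = eta - pred
        return -0.5 * (_LOG2PI + np.log(var) + r * r / var)

    if mode == "classical":
        try:
            mm = marginal_moments(p, has_covariate=False)
        except ValueError:
            return np.full(len(obs), -np.inf)
        d = obs[:, :2] - mm.mean
        if zeta_offsets is not None:
            d = d.copy()
            d[:, 0] -= p.beta2 * np.asarray(zeta_offsets)
        cov = mm.cov + gammas[:, :2, :2]
    else:
        if obs.shape[1] != 3:
            raise ValueError(f"mode {mode!r} needs an observed covariate column")
        try:
            mm = marginal_moments(p, has_covariate=True)
        except ValueError:
            return np.full(len(obs), -np.inf)
        d = obs - mm.mean
        g = _diag_only(gammas) if mode == "pseudo" else gammas
        cov = mm.cov + g

    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        return np.full(len(obs), -np.inf)
    sol = np.linalg.solve(chol, d[:, :, None])[:, :, 0]
    k = d.shape[1]
    logdet = 2.0 * np.sum(np.log(np.diagonal(chol, axis1=1, axis2=2)), axis=1)
    return -0.5 * (k * _LOG2PI + logdet + np.sum(sol * sol, axis=1))


def neg_loglik_arrays(
    params: ModelParams,
    obs: np.ndarray,
    gammas: np.ndarray,
    mode: Mode,
    zeta_offsets: np.ndarray | None = None,
    naive_include_s2: bool = False,
) -> float:
    ll = per_study_loglik(params, obs, gammas, mode, zeta_offsets, naive_include_s2)
    total = float(np.sum(ll))
    return np.inf if not np.isfinite(total) else -total


def neg_loglik(
    params: ModelParams,
    data: Sequence[ObservedTriple],
    mode: Mode,
    zeta_offsets: np.ndarray | None = None,
    naive_include_s2: bool = False,
) -> float:
    """Negative log (pseudo-)likelihood over a list of observed triples."""
    obs, gammas = stack_triples(data)
    val = neg_loglik_arrays(params, obs, gammas, mode, zeta_offsets, naive_include_s2)
    if np.isinf(val):
        ll = per_study_loglik(params, obs, gammas, mode, zeta_offsets, naive_include_s2)
        bad = [data[i].study_id or str(i) for i in np.nonzero(~np.isfinite(ll))[0]]
        raise np.linalg.LinAlgError(
            f"singular or indefinite per-study covariance for studies {bad}"
        )
    return val


def score_per_study(
    params: ModelParams,
    obs: np.ndarray,
    gammas: np.ndarray,
    mode: Mode,
    free_names: Sequence[str],
    zeta_offsets: np.ndarray | None = None,
    naive_include_s2: bool = False,
    rel_step: float = 1e-6,
) -> np.ndarray:
    """Central-difference per-study score matrix (n, p) of the log-density.

    Differentiates with respect to the natural-scale parameters listed in
    ``free_names``.  The column sums vanish at an interior maximum.
    """
    theta = np.array([getattr(params, name) for name in free_names], dtype=float)
    variance_like = {"tau2", "sigma_xi2", "sigma_zeta2"}
    n = len(obs)
    scores = np.empty((n, len(theta)))

    def _ll_at(vec):
        trial = unvalidated_params(**{**params.to_dict(),
                                      **dict(zip(free_names, vec))})
        return per_study_loglik(trial, obs, gammas, mode, zeta_offsets,
                                naive_include_s2)

    for j, name in enumerate(free_names):
        h = rel_step * max(1.0, abs(theta[j]))
        if name in variance_like and theta[j] - h < 0:
            # one-sided step away from the boundary
            up = theta.copy(); up[j] += h
            mid = theta.copy()
            scores[:, j] = (_ll_at(up) - _ll_at(mid)) / h
            continue
        up = theta.copy(); up[j] += h
        dn = theta.copy(); dn[j] -= h
        scores[:, j] = (_ll_at(up) - _ll_at(dn)) / (2.0 * h)
    return scores
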