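"""Exact measurement-error likelihoods via Gauss-Hermite quadrature.

Instead of approximating the sampling law of the observed log-odds by a
normal with known variance, the exact model keeps the binomial (or
multinomial / bivariate-normal subgroup) observation distributions and
integrates the latent risks out numerically.  The integrals are
evaluated on tensor-product Gauss-Hermite grids after standardizing each
latent variable at its conditional mean and scale:

    xi   = mu_xi  + sigma_xi  * u,
    zeta = mu_zeta + sigma_zeta * w,
    eta  = beta0 + beta1*xi + beta2*zeta + tau * v,

so that each one-dimensional rule integrates against an exact standard
normal weight.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import numpy as np
from scipy import special
from scipy.stats import binom

from .data_model import ModelParams, StudyRecord

__all__ = [
    "QuadratureRule",
    "gauss_hermite_rule",
    "neg_loglik_exact_binomial",
    "neg_pseudo_loglik_exact_multinomial",
    "neg_pseudo_loglik_exact_meancov",
]


@dataclass
class QuadratureRule:
    """Normalized probabilists' Gauss-Hermite rule, optionally tensorized.

    ``nodes`` is (m, dims) and ``weights`` (m,), with sum(weights) = 1,
    so that ``sum(w_k f(nodes_k)) ~ E[f(U)]`` for U ~ N(0, I_dims).
    """

    nodes: np.ndarray
    weights: np.ndarray
    n_nodes: int
    dims: int


def gauss_hermite_rule(n_nodes: int, dims: int = 1) -> QuadratureRule:
    if n_nodes < 2:
        raise ValueError("need at least 2 quadrature nodes")
    if not 1 <= dims <= 3:
        raise ValueError("dims must be 1, 2 or 3")
    x, w = special.roots_hermitenorm(n_nodes)
    w = w / w.sum()  # normalize against the standard normal weight
    grids = np.meshgrid(*([x] * dims), indexing="ij")
    nodes = np.column_stack([g.ravel() for g in grids])
    wgrids = np.meshgrid(*([w] * dims), indexing="ij")
    weights = np.prod(np.column_stack([g.ravel() for g in wgrids]), axis=1)
    return QuadratureRule(nodes=nodes, weights=weights, n_nodes=n_nodes, dims=dims)


def _require_positive(params: ModelParams, names: Sequence[str]) -> None:
    for name in names:
        if getattr(params, name) <= 0:
            raise ValueError(f"{name} must be strictly positive for the exact model")


def neg_loglik_exact_binomial(
    params: ModelParams,
    records: Sequence[StudyRecord],
    n_nodes: int = 10,
) -> float:
    """Exact classical likelihood: binomial counts, latent (eta, xi).

    Per study a double integral of
    Binom(Y; nT, expit(eta)) * Binom(X; nC, expit(xi)) against the
    Gaussian laws of (eta | xi) and xi, evaluated on a 2-D grid.
    """
    _require_positive(params, ("tau2", "sigma_xi2"))
    p = params
    rule = gauss_hermite_rule(n_nodes, dims=2)
    u, v = rule.nodes[:, 0], rule.nodes[:, 1]
    xi = p.mu_xi + np.sqrt(p.sigma_xi2) * u
    eta = p.beta0 + p.beta1 * xi + np.sqrt(p.tau2) * v
    total = 0.0
    for r in records:
        like = (
            binom.pmf(r.y_events, r.n_treat, special.expit(eta))
            * binom.pmf(r.x_events, r.n_control, special.expit(xi))
        )
        val = float(np.dot(rule.weights, like))
        if val <= 0:
            return np.inf
        total += np.log(val)
    return -total


def _latent_grid(params: ModelParams, n_nodes: int):
    p = params
    rule = gauss_hermite_rule(n_nodes, dims=3)
    u, v, w = rule.nodes.T
    xi = p.mu_xi + np.sqrt(p.sigma_xi2) * u
    zeta = p.mu_zeta + np.sqrt(p.sigma_zeta2) * w
    eta = p.beta0 + p.beta1 * xi + p.beta2 * zeta + np.sqrt(p.tau2) * v
    return rule.weights, eta, xi, zeta


def _multinomial_cell_probs(p_event: np.ndarray, p_trait: np.ndarray,
                            coupling: Callable | None):
    """Cell probabilities (1M, 0M, 1F, 0F) given event and trait margins.

    ``coupling`` maps (p_event, p_trait) to the joint cell p_1M; the
    default is independence, clipped into the Frechet feasibility bounds.
    """
    if coupling is None:
        p1m = p_event * p_trait
    else:
        p1m = coupling(p_event, p_trait)
    lo = np.maximum(0.0, p_event + p_trait - 1.0)
    hi = np.minimum(p_event, p_trait)
    if np.any(p1m < lo - 1e-12) or np.any(p1m > hi + 1e-12):
        raise ValueError("cell probability outside the feasible (Frechet) bounds")
    p1m = np.clip(p1m, lo, hi)
    return np.stack([p1m, p_trait - p1m, p_event - p1m,
                     1.0 - p_event - p_trait + p1m])


def _log_multinomial(cells: Sequence[int], probs: np.ndarray) -> np.ndarray:
    cells_arr = np.asarray(cells, dtype=float)
    coeff = special.gammaln(cells_arr.sum() + 1) - special.gammaln(cells_arr + 1).sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        lp = np.where(cells_arr[:, None] > 0,
                      cells_arr[:, None] * np.log(np.clip(probs, 1e-300, None)),
                      0.0)
    return coeff + lp.sum(axis=0)


def neg_pseudo_loglik_exact_multinomial(
    params: ModelParams,
    records: Sequence[StudyRecord],
    n_nodes: int = 10,
    mode: Literal["pseudo", "full"] = "pseudo",
    coupling: Callable | None = None,
) -> float:
    """Exact-model (pseudo-)likelihood for a binary-trait covariate.

    ``pseudo``: the event counts and the trait count are treated as
    independent given the latents, each binomial; this is the working
    independence factorization.  ``full``: the two 4-cell multinomial
    subgroup vectors are used, with the joint cell probability p_1M
    supplied by ``coupling`` (default: independence of event and trait
    within each arm).
    """
    _require_positive(params, ("tau2", "sigma_xi2", "sigma_zeta2"))
    weights, eta, xi, zeta = _latent_grid(params, n_nodes)
    pe, px, pz = special.expit(eta), special.expit(xi), special.expit(zeta)
    total = 0.0
    for r in records:
        sg = r.subgroup
        if sg is None or not sg.is_binary:
            raise ValueError(
                f"study {r.study_id!r}: binary subgroup table required"
            )
        if mode == "pseudo":
            z = sg.male_total()
            loglike = (
                binom.logpmf(r.y_events, r.n_treat, pe)
                + binom.logpmf(r.x_events, r.n_control, px)
                + binom.logpmf(z, r.n_total, pz)
            )
        else:
            probs_t = _multinomial_cell_probs(pe, pz, coupling)
            probs_c = _multinomial_cell_probs(px, pz, coupling)
            loglike = (
                _log_multinomial([sg.zt1m, sg.zt0m, sg.zt1f, sg.zt0f], probs_t)
                + _log_multinomial([sg.zc1m, sg.zc0m, sg.zc1f, sg.zc0f], probs_c)
            )
        m = loglike.max()
        val = float(np.dot(weights, np.exp(loglike - m)))
        if val <= 0 or not np.isfinite(m):
            return np.inf
        total += m + np.log(val)
    return -total


def _log_bvn_pair(z1, z0, mean, v1, v0, rho):
    """Log density of a correlated pair of subgroup means at grid means."""
    if not -1.0 < rho < 1.0:
        raise ValueError("|rho| must be < 1")
    d1 = (z1 - mean) / np.sqrt(v1)
    d0 = (z0 - mean) / np.sqrt(v0)
    q = (d1 * d1 - 2.0 * rho * d1 * d0 + d0 * d0) / (1.0 - rho * rho)
    return -0.5 * (q + np.log((2.0 * np.pi) ** 2 * v1 * v0 * (1.0 - rho * rho)))


def neg_pseudo_loglik_exact_meancov(
    params: ModelParams,
    records: Sequence[StudyRecord],
    n_nodes: int = 10,
    rho_treat: Sequence[float] | None = None,
    rho_control: Sequence[float] | None = None,
) -> float:
    """Exact-model pseudo-likelihood for a mean-value covariate.

    Per study: binomial event counts times bivariate-normal densities of
    the subgroup means (ZT1, ZT0) and (ZC1, ZC0) around the latent
    covariate, integrated over (eta, xi, zeta) on a 3-D grid.  The
    within-arm correlations are inputs (default 0).
    """
    _require_positive(params, ("tau2", "sigma_xi2", "sigma_zeta2"))
    weights, eta, xi, zeta = _latent_grid(params, n_nodes)
    pe, px = special.expit(eta), special.expit(xi)
    n = len(records)
    rho_t = np.zeros(n) if rho_treat is None else np.asarray(rho_treat, float)
    rho_c = np.zeros(n) if rho_control is None else np.asarray(rho_control, float)
    total = 0.0
    for i, r in enumerate(records):
        sg = r.subgroup
        if sg is None or not sg.is_mean:
            raise ValueError(f"study {r.study_id!r}: mean subgroup table required")
        y, x = r.y_events, r.x_events
        if not (0 < y < r.n_treat and 0 < x < r.n_control):
            raise ValueError(
                f"study {r.study_id!r}: subgroup-mean variances undefined "
                "for boundary counts"
            )
        sd2 = sg.sd ** 2
        loglike = (
            binom.logpmf(y, r.n_treat, pe)
            + binom.logpmf(x, r.n_control, px)
            + _log_bvn_pair(sg.zt1, sg.zt0, zeta, sd2 / y, sd2 / (r.n_treat - y),
                            float(rho_t[i]))
            + _log_bvn_pair(sg.zc1, sg.zc0, zeta, sd2 / x, sd2 / (r.n_control - x),
                            float(rho_c[i]))
        )
        m = loglike.max()
        val = float(np.dot(weights, np.exp(loglike - m)))
        if val <= 0 or not np.isfinite(m):
            return np.inf
        total += m + np.log(val)
    return -total
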