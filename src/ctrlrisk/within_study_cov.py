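"""Within-study covariances between risk measures and the covariate.

The observed risk measures and the observed covariate summary share
subjects, so their sampling errors are correlated.  First-order Taylor
(delta-method) approximations of the covariances are available from
subgroup summary tables:

* binary trait (log-odds covariate), from the eight cell counts:
  s_eta,zeta ~ (1/Z)[Zt1m/Y - Zt0m/(nT-Y)] - (1/(n-Z))[Zt1f/Y - Zt0f/(nT-Y)]
  and analogously for the control arm;
* mean-value covariate, from the four subgroup means:
  s_eta,zeta ~ (Zt1 - Zt0)/n, s_xi,zeta ~ (Zc1 - Zc0)/n.

A Monte-Carlo oracle resamples the observation model at plug-in latent
values and reports the empirical covariances; it validates the Taylor
formulas on any concrete table.
"""

from __future__ import annotations

import logging
from typing import Tuple

import numpy as np

from .data_model import SubgroupTable

__all__ = [
    "taylor_cov_binary",
    "taylor_cov_mean",
    "monte_carlo_cov_oracle",
    "assemble_gamma",
]

log = logging.getLogger(__name__)


def taylor_cov_binary(table: SubgroupTable) -> Tuple[float, float]:
    """Delta-method covariances (s_eta_zeta, s_xi_zeta) from a binary table."""
    if not table.is_binary:
        raise ValueError("binary-layout subgroup table required")
    y = table.zt1m + table.zt1f
    nt = y + table.zt0m + table.zt0f
    x = table.zc1m + table.zc1f
    nc = x + table.zc0m + table.zc0f
    z = table.male_total()
    n = nt + nc
    for value, name in ((y, "Y"), (nt - y, "nT-Y"), (x, "X"), (nc - x, "nC-X"),
                        (z, "Z"), (n - z, "n-Z")):
        if value <= 0:
            raise ValueError(f"margin {name} is zero; Taylor covariance undefined")
    s_eta_zeta = (1.0 / z) * (table.zt1m / y - table.zt0m / (nt - y)) - (
        1.0 / (n - z)
    ) * (table.zt1f / y - table.zt0f / (nt - y))
    s_xi_zeta = (1.0 / z) * (table.zc1m / x - table.zc0m / (nc - x)) - (
        1.0 / (n - z)
    ) * (table.zc1f / x - table.zc0f / (nc - x))
    return float(s_eta_zeta), float(s_xi_zeta)


def taylor_cov_mean(
    table: SubgroupTable, y_events: int, n_treat: int, x_events: int, n_control: int
) -> Tuple[float, float]:
    """Delta-method covariances (s_eta_zeta, s_xi_zeta) from a mean table."""
    if not table.is_mean:
        raise ValueError("mean-layout subgroup table required")
    n = n_treat + n_control
    if n <= 0:
        raise ValueError("total sample size must be positive")
    return float((table.zt1 - table.zt0) / n), float((table.zc1 - table.zc0) / n)


def monte_carlo_cov_oracle(
    table: SubgroupTable,
    y_events: int,
    n_treat: int,
    x_events: int,
    n_control: int,
    reps: int = 100_000,
    seed: int | np.random.Generator = 0,
    continuity: float = 0.5,
) -> Tuple[float, float, float, float]:
    """Empirical covariances of (eta_hat, zeta_hat) and (xi_hat, zeta_hat).

    Resamples the observation model holding latent values at plug-in
    estimates: multinomial cell counts for the binary layout, normal
    subgroup means (zero within-arm correlation) for the mean layout.
    Returns ``(s_eta_zeta, s_xi_zeta, mc_se_eta, mc_se_xi)`` where the
    last two are Monte-Carlo standard errors of the covariance
    estimates.
    """
    if reps < 10_000:
        raise ValueError("need at least 10^4 replicates for a stable oracle")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = n_treat + n_control
    if table.is_binary:
        p_t = np.array([table.zt1m, table.zt1f, table.zt0m, table.zt0f]) / n_treat
        p_c = np.array([table.zc1m, table.zc1f, table.zc0m, table.zc0f]) / n_control
        zt = rng.multinomial(n_treat, p_t, size=reps).astype(float)
        zc = rng.multinomial(n_control, p_c, size=reps).astype(float)
        y = zt[:, 0] + zt[:, 1]
        x = zc[:, 0] + zc[:, 1]
        z = zt[:, 0] + zt[:, 2] + zc[:, 0] + zc[:, 2]
        c = continuity
        eta = np.log((y + c) / (n_treat - y + c))
        xi = np.log((x + c) / (n_control - x + c))
        zeta = np.log((z + c) / (n - z + c))
    else:
        sd = table.sd
        y, x = float(y_events), float(x_events)
        means = np.array([table.zt1, table.zt0, table.zc1, table.zc0])
        # the coupling between the risk measures and the pooled covariate
        # runs through the event counts, which weight the subgroup means:
        # resample counts and means jointly
        yy = rng.binomial(n_treat, y / n_treat, size=reps).astype(float)
        xx = rng.binomial(n_control, x / n_control, size=reps).astype(float)
        sizes = np.stack([yy, n_treat - yy, xx, n_control - xx], axis=1)
        scales = sd / np.sqrt(np.clip(sizes, 1.0, None))
        draws = means + scales * rng.standard_normal((reps, 4))
        zeta = np.sum(sizes * draws, axis=1) / n
        c = continuity
        eta = np.log((yy + c) / (n_treat - yy + c))
        xi = np.log((xx + c) / (n_control - xx + c))

    def _cov_with_se(a, b):
        prod = (a - a.mean()) * (b - b.mean())
        return float(prod.mean()), float(prod.std(ddof=1) / np.sqrt(reps))

    sez, se1 = _cov_with_se(eta, zeta)
    sxz, se2 = _cov_with_se(xi, zeta)
    return sez, sxz, se1, se2


def assemble_gamma(
    s_eta2: float,
    s_xi2: float,
    s_zeta2: float | None = None,
    s_eta_zeta: float = 0.0,
    s_xi_zeta: float = 0.0,
    study_id: str = "",
) -> np.ndarray:
    """Build the within-study covariance matrix Gamma_i.

    The (eta_hat, xi_hat) entry is structurally zero (disjoint arms).  If
    the Taylor off-diagonal entries make the matrix indefinite, they are
    shrunk toward zero by the smallest factor restoring positive
    semidefiniteness, and a warning is logged.
    """
    if s_zeta2 is None:
        return np.diag([s_eta2, s_xi2]).astype(float)
    g = np.array(
        [
            [s_eta2, 0.0, s_eta_zeta],
            [0.0, s_xi2, s_xi_zeta],
            [s_eta_zeta, s_xi_zeta, s_zeta2],
        ]
    )
    if np.linalg.eigvalsh(g)[0] < 0:
        lo, hi = 0.0, 1.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            trial = g.copy()
            trial[0, 2] = trial[2, 0] = mid * s_eta_zeta
            trial[1, 2] = trial[2, 1] = mid * s_xi_zeta
            if np.linalg.eigvalsh(trial)[0] >= 0:
                lo = mid
            else:
                hi = mid
        g[0, 2] = g[2, 0] = lo * s_eta_zeta
        g[1, 2] = g[2, 1] = lo * s_xi_zeta
        log.warning(
            "study %r: Taylor within-study covariances shrunk by factor %.3f "
            "to restore a PSD Gamma", study_id, lo,
        )
    return g
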