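"""Assemble observed measures and within-study covariances from records."""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np

from .data_model import CovariateKind, ObservedTriple, StudyRecord
from .transforms import (ContinuityPolicy, covariate_measure, log_odds_with_var,
                         standardize_covariate)
from .within_study_cov import assemble_gamma, taylor_cov_binary, taylor_cov_mean

__all__ = ["observed_from_records"]


def observed_from_records(
    records: Sequence[StudyRecord],
    continuity: float = 0.5,
    continuity_policy: ContinuityPolicy = "only_zero",
    standardize: bool = False,
    use_subgroup_cov: bool = True,
) -> Tuple[list, Optional[np.ndarray]]:
    """Build the observed triples for a meta-analysis.

    Returns ``(triples, zeta_offsets)``: for an error-free covariate the
    triples are bivariate and the covariate values are returned
    separately as fixed regression offsets; for error-prone covariates
    the triples carry zeta_hat and the 3x3 within-study covariance, with
    Taylor off-diagonal entries when subgroup tables are available (and
    ``use_subgroup_cov``), zero otherwise.

    ``standardize`` centers/scales an error-prone covariate by its
    unweighted sample moments (with the matching variance and covariance
    scaling), the usual treatment of a mean-age covariate.
    """
    if not records:
        raise ValueError("no study records")
    kinds = {r.covariate.kind if r.covariate else None for r in records}
    if len(kinds) > 1:
        raise ValueError("all studies must share one covariate kind")
    kind = kinds.pop()

    eta, s_eta2, xi, s_xi2 = [], [], [], []
    for r in records:
        e, ve = log_odds_with_var(r.y_events, r.n_treat, continuity,
                                  continuity_policy, label=f"{r.study_id} treatment")
        x, vx = log_odds_with_var(r.x_events, r.n_control, continuity,
                                  continuity_policy, label=f"{r.study_id} control")
        eta.append(e); s_eta2.append(ve); xi.append(x); s_xi2.append(vx)

    if kind is None:
        triples = [
            ObservedTriple(eta_hat=eta[i], xi_hat=xi[i],
                           gamma=assemble_gamma(s_eta2[i], s_xi2[i]),
                           study_id=records[i].study_id)
            for i in range(len(records))
        ]
        return triples, None

    if kind is CovariateKind.ERROR_FREE:
        offsets = np.array([r.covariate.value for r in records])
        if standardize:
            offsets, _, _, _ = standardize_covariate(offsets, np.zeros_like(offsets))
        triples = [
            ObservedTriple(eta_hat=eta[i], xi_hat=xi[i],
                           gamma=assemble_gamma(s_eta2[i], s_xi2[i]),
                           study_id=records[i].study_id)
            for i in range(len(records))
        ]
        return triples, offsets

    zeta, s_zeta2, covs = [], [], []
    for r in records:
        z, vz = covariate_measure(r, continuity, continuity_policy)
        zeta.append(z); s_zeta2.append(vz)
        sg = r.subgroup
        if use_subgroup_cov and sg is not None and sg.is_binary:
            try:
                covs.append(taylor_cov_binary(sg))
            except ValueError:
                # degenerate margin (empty cell); fall back to working
                # independence for this study
                covs.append((0.0, 0.0))
        elif use_subgroup_cov and sg is not None and sg.is_mean:
            covs.append(taylor_cov_mean(sg, r.y_events, r.n_treat,
                                        r.x_events, r.n_control))
        else:
            covs.append((0.0, 0.0))

    zeta_arr = np.asarray(zeta)
    s_zeta2_arr = np.asarray(s_zeta2)
    covs_arr = np.asarray(covs)
    if standardize:
        zeta_arr, s_zeta2_arr, _, scale = standardize_covariate(zeta_arr, s_zeta2_arr)
        covs_arr = covs_arr / scale

    triples = [
        ObservedTriple(
            eta_hat=eta[i], xi_hat=xi[i], zeta_hat=float(zeta_arr[i]),
            gamma=assemble_gamma(s_eta2[i], s_xi2[i], float(s_zeta2_arr[i]),
                                 float(covs_arr[i, 0]), float(covs_arr[i, 1]),
                                 study_id=records[i].study_id),
            study_id=records[i].study_id,
        )
        for i in range(len(records))
    ]
    return triples, None
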