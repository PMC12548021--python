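"""Observed risk and covariate measures with their sampling variances.

Counts are mapped to empirical log-odds with the usual large-sample
variance ``1/a + 1/b`` for a split ``(a, b)`` of the group total.  The
optional Haldane-Anscombe continuity correction adds ``c`` (default 0.5)
to both cells, either never, only when a cell is empty, or always; the
"always" convention is the one used by the synthetic-data generator so
that boundary counts never produce infinite log-odds.
"""

from __future__ import annotations

from typing import Literal, Sequence, Tuple

import numpy as np

from .data_model import CovariateKind, StudyRecord

__all__ = [
    "log_odds_with_var",
    "covariate_log_odds",
    "covariate_mean",
    "standardize_covariate",
    "ContinuityPolicy",
]

ContinuityPolicy = Literal["none", "only_zero", "always"]


def _apply_continuity(events, total, continuity: float, policy: ContinuityPolicy):
    events = np.asarray(events, dtype=float)
    total = np.asarray(total, dtype=float)
    if policy == "always":
        c = np.full_like(events, continuity)
    elif policy == "only_zero":
        c = np.where((events == 0) | (events == total), continuity, 0.0)
    else:
        c = np.zeros_like(events)
    return events + c, total - events + c


def log_odds_with_var(
    events,
    total,
    continuity: float = 0.5,
    policy: ContinuityPolicy = "only_zero",
    label: str = "",
) -> Tuple[np.ndarray, np.ndarray]:
    """Empirical log-odds and its sampling variance.

    Parameters are scalars or arrays of counts.  With ``policy="none"``
    (or ``continuity=0``) a zero cell raises, naming ``label``.
    """
    events_arr = np.asarray(events)
    total_arr = np.asarray(total)
    if np.any(events_arr < 0) or np.any(events_arr > total_arr):
        raise ValueError(f"{label or 'counts'}: events outside [0, total]")
    if np.any(total_arr <= 0):
        raise ValueError(f"{label or 'counts'}: nonpositive total")
    a, b = _apply_continuity(events_arr, total_arr, continuity, policy)
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError(
            f"{label or 'counts'}: log-odds undefined for an empty cell "
            "(set a positive continuity correction)"
        )
    est = np.log(a / b)
    var = 1.0 / a + 1.0 / b
    if np.isscalar(events) or events_arr.ndim == 0:
        return float(est), float(var)
    return est, var


def covariate_log_odds(
    z_count,
    n_total,
    continuity: float = 0.5,
    policy: ContinuityPolicy = "only_zero",
    label: str = "",
) -> Tuple[float, float]:
    """Observed log-odds covariate zeta_hat = log(Z/(n-Z)) with variance
    1/Z + 1/(n-Z)."""
    return log_odds_with_var(z_count, n_total, continuity, policy, label=label)


def covariate_mean(
    zt1: float,
    zt0: float,
    zc1: float,
    zc0: float,
    y_events: float,
    n_treat: float,
    x_events: float,
    n_control: float,
    sd: float,
) -> Tuple[float, float]:
    """Pool subgroup means into the study-level covariate mean.

    zeta_hat = [Y*Zt1 + (nT-Y)*Zt0 + X*Zc1 + (nC-X)*Zc0] / (nT + nC),
    with sampling variance SD^2 / (nT + nC).
    """
    if sd <= 0:
        raise ValueError("within-subject SD must be positive")
    n = n_treat + n_control
    if n <= 0:
        raise ValueError("total sample size must be positive")
    zeta_hat = (
        y_events * zt1
        + (n_treat - y_events) * zt0
        + x_events * zc1
        + (n_control - x_events) * zc0
    ) / n
    return float(zeta_hat), float(sd * sd / n)


def covariate_measure(
    record: StudyRecord,
    continuity: float = 0.5,
    policy: ContinuityPolicy = "only_zero",
) -> Tuple[float, float]:
    """Observed covariate value and variance for one study record.

    Dispatches on the covariate kind.  A mean-value covariate reported
    only as mean +/- SD (no subgroup means) uses the reported mean
    directly; when a mean-layout subgroup table is present the subgroup
    means are pooled instead.
    """
    cov = record.covariate
    if cov is None:
        raise ValueError(f"study {record.study_id!r} has no covariate")
    if cov.kind is CovariateKind.ERROR_FREE:
        return float(cov.value), 0.0
    if cov.kind is CovariateKind.LOG_ODDS:
        return covariate_log_odds(
            cov.z_count, cov.z_total, continuity, policy, label=record.study_id
        )
    sg = record.subgroup
    if sg is not None and sg.is_mean:
        return covariate_mean(
            sg.zt1, sg.zt0, sg.zc1, sg.zc0,
            record.y_events, record.n_treat, record.x_events, record.n_control,
            sg.sd,
        )
    if cov.sd <= 0:
        raise ValueError(f"study {record.study_id!r}: mean covariate needs SD > 0")
    return float(cov.value), float(cov.sd ** 2 / record.n_total)


def standardize_covariate(
    values: Sequence[float], variances: Sequence[float]
) -> Tuple[np.ndarray, np.ndarray, float, float]:
    """Center and scale covariate values by their unweighted sample moments.

    Returns ``(scaled_values, scaled_variances, center, scale)``.  The
    sampling variances are divided by the squared scale, as affine error
    propagation requires.
    """
    v = np.asarray(values, dtype=float)
    s2 = np.asarray(variances, dtype=float)
    center = float(v.mean())
    scale = float(v.std(ddof=1))
    if scale == 0:
        raise ValueError("cannot standardize a constant covariate")
    return (v - center) / scale, s2 / scale ** 2, center, scale
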