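"""Domain types for control-risk meta-regression.

A meta-analysis of ``n`` independent two-arm studies is represented as a
list of :class:`StudyRecord`.  Each study reports event counts for the
treatment and control arm and, optionally, one additional study-level
covariate: an error-free scalar, the count of a binary trait (log-odds
covariate), or a mean value with its within-study standard deviation
(mean-value covariate).  Optionally a study carries subgroup summary
information (counts or means cross-classified by arm and event status)
from which within-study covariances between the observed risk measures
and the observed covariate can be approximated.

Symbols follow the usual control-risk regression notation: eta_i is the
latent risk measure (log-odds) in the treatment arm, xi_i the latent
baseline risk in the control arm, zeta_i the latent covariate value, and
hats denote the observed error-prone versions.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "CovariateKind",
    "Method",
    "ErrorModel",
    "CovariateSummary",
    "SubgroupTable",
    "StudyRecord",
    "ObservedTriple",
    "ModelParams",
    "FitResult",
    "validate_study",
]


class CovariateKind(str, enum.Enum):
    ERROR_FREE = "error_free"
    LOG_ODDS = "log_odds"
    MEAN_VALUE = "mean_value"


class Method(str, enum.Enum):
    NAIVE = "naive"
    LIKELIHOOD = "likelihood"
    PSEUDO_LIKELIHOOD = "pseudo_likelihood"


class ErrorModel(str, enum.Enum):
    APPROXIMATE = "approximate"
    EXACT = "exact"


@dataclass
class CovariateSummary:
    """One study-level covariate in raw (as-reported) form.

    For ``kind == LOG_ODDS`` the raw input is the trait count ``z_count``
    out of ``z_total`` subjects; for ``kind == MEAN_VALUE`` it is the
    reported mean ``value`` with within-study standard deviation ``sd``;
    for ``kind == ERROR_FREE`` only ``value`` is used and the sampling
    variance is identically zero.
    """

    kind: CovariateKind
    value: float = float("nan")
    sd: float = float("nan")
    z_count: int = -1
    z_total: int = -1

    def __post_init__(self) -> None:
        self.kind = CovariateKind(self.kind)
        if self.kind is CovariateKind.LOG_ODDS:
            if self.z_total <= 0:
                raise ValueError("log-odds covariate needs a positive total")
            if not 0 <= self.z_count <= self.z_total:
                raise ValueError(
                    f"trait count {self.z_count} outside [0, {self.z_total}]"
                )
        elif self.kind is CovariateKind.MEAN_VALUE:
            if not np.isfinite(self.value):
                raise ValueError("mean-value covariate needs a finite mean")
            if not (np.isfinite(self.sd) and self.sd > 0):
                raise ValueError("mean-value covariate needs a positive SD")
        else:
            if not np.isfinite(self.value):
                raise ValueError("error-free covariate needs a finite value")


@dataclass
class SubgroupTable:
    """Subgroup summary information for the additional covariate.

    Binary layout: eight cell counts cross-classifying arm (T/C), event
    status (1/0) and the binary trait (M/F).  Mean layout: four subgroup
    means by arm and event status, plus the common within-subject SD.
    """

    # binary layout
    zt1m: int = -1
    zt1f: int = -1
    zt0m: int = -1
    zt0f: int = -1
    zc1m: int = -1
    zc1f: int = -1
    zc0m: int = -1
    zc0f: int = -1
    # mean layout
    zt1: float = float("nan")
    zt0: float = float("nan")
    zc1: float = float("nan")
    zc0: float = float("nan")
    sd: float = float("nan")

    _BINARY_CELLS = ("zt1m", "zt1f", "zt0m", "zt0f", "zc1m", "zc1f", "zc0m", "zc0f")
    _MEAN_CELLS = ("zt1", "zt0", "zc1", "zc0")

    @property
    def is_binary(self) -> bool:
        return all(getattr(self, c) >= 0 for c in self._BINARY_CELLS)

    @property
    def is_mean(self) -> bool:
        return all(np.isfinite(getattr(self, c)) for c in self._MEAN_CELLS)

    def __post_init__(self) -> None:
        if not (self.is_binary or self.is_mean):
            raise ValueError("subgroup table must fill the binary or the mean layout")
        if self.is_mean and not (np.isfinite(self.sd) and self.sd > 0):
            raise ValueError("mean-layout subgroup table needs a positive SD")

    def male_total(self) -> int:
        """Trait count Z_i = sum of the four male cells (binary layout)."""
        return self.zt1m + self.zt0m + self.zc1m + self.zc0m


@dataclass
class StudyRecord:
    study_id: str
    y_events: int
    n_treat: int
    x_events: int
    n_control: int
    covariate: Optional[CovariateSummary] = None
    subgroup: Optional[SubgroupTable] = None

    def __post_init__(self) -> None:
        validate_study(self)

    @property
    def n_total(self) -> int:
        return self.n_treat + self.n_control

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.covariate is not None:
            d["covariate"]["kind"] = self.covariate.kind.value
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyRecord":
        d = dict(d)
        if d.get("covariate") is not None:
            d["covariate"] = CovariateSummary(**d["covariate"])
        if d.get("subgroup") is not None:
            d["subgroup"] = SubgroupTable(**d["subgroup"])
        return cls(**d)


def validate_study(record: StudyRecord) -> StudyRecord:
    """Check count invariants; raise ``ValueError`` naming the study."""
    r = record
    if r.n_treat <= 0 or r.n_control <= 0:
        raise ValueError(f"study {r.study_id!r}: group sizes must be positive")
    if not 0 <= r.y_events <= r.n_treat:
        raise ValueError(
            f"study {r.study_id!r}: treatment events {r.y_events} "
            f"outside [0, {r.n_treat}]"
        )
    if not 0 <= r.x_events <= r.n_control:
        raise ValueError(
            f"study {r.study_id!r}: control events {r.x_events} "
            f"outside [0, {r.n_control}]"
        )
    sg = r.subgroup
    if sg is not None and sg.is_binary:
        cells = [getattr(sg, c) for c in sg._BINARY_CELLS]
        if any(c < 0 for c in cells):
            raise ValueError(f"study {r.study_id!r}: negative subgroup cell")
        if sg.zt1m + sg.zt1f != r.y_events:
            raise ValueError(
                f"study {r.study_id!r}: subgroup event cells "
                f"{sg.zt1m}+{sg.zt1f} != treatment events {r.y_events}"
            )
        if sg.zc1m + sg.zc1f != r.x_events:
            raise ValueError(
                f"study {r.study_id!r}: subgroup event cells "
                f"{sg.zc1m}+{sg.zc1f} != control events {r.x_events}"
            )
        if sg.zt1m + sg.zt1f + sg.zt0m + sg.zt0f != r.n_treat:
            raise ValueError(f"study {r.study_id!r}: treatment cells do not sum to n_treat")
        if sg.zc1m + sg.zc1f + sg.zc0m + sg.zc0f != r.n_control:
            raise ValueError(f"study {r.study_id!r}: control cells do not sum to n_control")
    return record


@dataclass
class ObservedTriple:
    """Observed (eta_hat, xi_hat[, zeta_hat]) with within-study covariance.

    ``gamma`` is the 2x2 (no covariate) or 3x3 symmetric within-study
    covariance matrix of the observed measures, ordered
    (eta_hat, xi_hat, zeta_hat).  The (1,2) entry is zero because the two
    arms involve disjoint subjects.
    """

    eta_hat: float
    xi_hat: float
    gamma: np.ndarray
    zeta_hat: Optional[float] = None
    study_id: str = ""

    def __post_init__(self) -> None:
        self.gamma = np.asarray(self.gamma, dtype=float)
        k = 3 if self.zeta_hat is not None else 2
        if self.gamma.shape != (k, k):
            raise ValueError(
                f"study {self.study_id!r}: gamma must be {k}x{k}, "
                f"got {self.gamma.shape}"
            )
        if not np.allclose(self.gamma, self.gamma.T):
            raise ValueError(f"study {self.study_id!r}: gamma must be symmetric")
        if np.any(np.diag(self.gamma)[:2] <= 0):
            raise ValueError(
                f"study {self.study_id!r}: risk-measure variances must be positive"
            )

    @property
    def has_covariate(self) -> bool:
        return self.zeta_hat is not None


def stack_triples(triples: Sequence[ObservedTriple]):
    """Stack a list of triples into dense arrays for vectorized likelihoods.

    Returns ``(obs, gammas)`` where ``obs`` is (n, k) and ``gammas`` is
    (n, k, k), k = 2 or 3 depending on the presence of a covariate.
    """
    if not triples:
        raise ValueError("empty data")
    has_cov = triples[0].has_covariate
    if any(t.has_covariate != has_cov for t in triples):
        raise ValueError("all studies must agree on covariate presence")
    if has_cov:
        obs = np.array([[t.eta_hat, t.xi_hat, t.zeta_hat] for t in triples])
    else:
        obs = np.array([[t.eta_hat, t.xi_hat] for t in triples])
    gammas = np.stack([t.gamma for t in triples])
    return obs, gammas


@dataclass
class ModelParams:
    """Full parameter vector theta of the structural model.

    beta0, beta1, beta2 are the regression coefficients of the treatment
    risk measure on the baseline risk and the covariate; mu_xi, mu_zeta
    and sigma_xi2, sigma_zeta2 are the means and variances of the latent
    Gaussian baseline risk and covariate; tau2 is the residual
    between-study variance; sigma_xizeta the latent covariance between
    baseline risk and covariate.
    """

    beta0: float = 0.0
    beta1: float = 0.0
    beta2: float = 0.0
    mu_xi: float = 0.0
    mu_zeta: float = 0.0
    tau2: float = 0.0
    sigma_xi2: float = 0.0
    sigma_zeta2: float = 0.0
    sigma_xizeta: float = 0.0

    def __post_init__(self) -> None:
        if self.tau2 < 0 or self.sigma_xi2 < 0 or self.sigma_zeta2 < 0:
            raise ValueError("variance components must be nonnegative")
        if self.sigma_xizeta ** 2 > self.sigma_xi2 * self.sigma_zeta2 + 1e-12:
            raise ValueError("latent (xi, zeta) covariance matrix not PSD")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class FitResult:
    params: ModelParams
    loglik: float
    converged: bool
    n_studies: int
    method: Method
    error_model: ErrorModel
    se_hessian: dict = field(default_factory=dict)
    se_sandwich: Optional[dict] = None
    free_names: tuple = ()
    message: str = ""

    def to_json(self, **kwargs) -> str:
        d = {
            "params": self.params.to_dict(),
            "loglik": self.loglik,
            "converged": bool(self.converged),
            "n_studies": self.n_studies,
            "method": self.method.value,
            "error_model": self.error_model.value,
            "se_hessian": self.se_hessian,
            "se_sandwich": self.se_sandwich,
            "message": self.message,
        }
        return json.dumps(d, **kwargs)
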