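"""Scenario generators and the simulation-study harness.

Three data-generating scenarios exercise the estimators:

1. error-free covariate: zeta_i ~ N(0,1) (or Bernoulli(0.5)) enters the
   linear model directly; event counts are binomial given the latent
   log-odds;
2. binary-trait covariate: per-arm 4-cell multinomial subgroup tables
   cross-classifying event status and the trait, with the joint cell
   probability drawn uniformly over its feasible (Frechet) range; the
   event and trait counts are the table margins;
3. mean-value covariate: binomial event counts plus subgroup means drawn
   from correlated bivariate normals around the latent covariate, with
   within-arm correlations uniform on (-1, 1) and unit within-subject SD.

Group sizes are integer-uniform on [15, 200] per arm.  The generator
applies the 0.5 continuity correction to every cell when forming the
observed log-odds, so boundary counts never produce infinite values.
The harness fits the requested methods to each replicate and aggregates
bias, mean estimated standard error (se), empirical standard deviation
(sd), the number of convergent replicates, and empirical coverage of
95% Wald intervals for the regression coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import inference
from .data_model import CovariateKind, CovariateSummary, StudyRecord, SubgroupTable
from .observed import observed_from_records

__all__ = ["SimConfig", "SimSummary", "draw_skew_normal", "generate_scenario",
           "run_study"]


@dataclass
class SimConfig:
    scenario: int = 1
    n_studies: int = 20
    tau2: float = 0.1
    betas: tuple = (0.0, 1.0, 0.8)
    xi_dist: str = "normal"          # "normal" | "skew_normal" (shape -5)
    zeta_dist: str = "normal"        # scenario 1: "normal" | "bernoulli"
    sd_subject: float = 1.0          # scenario 3 within-subject SD
    size_range: tuple = (15, 200)
    n_reps: int = 1000
    seed: int = 0
    skew_shape: float = -5.0

    def __post_init__(self) -> None:
        if self.scenario not in (1, 2, 3):
            raise ValueError("scenario must be 1, 2 or 3")
        if self.n_reps < 1:
            raise ValueError("n_reps must be at least 1")
        lo, hi = self.size_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid size range")


@dataclass
class SimSummary:
    method: str
    n_reps: int
    conv: int
    bias: dict = field(default_factory=dict)
    se: dict = field(default_factory=dict)
    sd: dict = field(default_factory=dict)
    coverage_hessian: dict = field(default_factory=dict)
    coverage_sandwich: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in self.bias:
            rows.append({
                "parameter": name, "method": self.method,
                "bias": self.bias[name],
                "se": self.se.get(name, np.nan),
                "sd": self.sd.get(name, np.nan),
                "conv": self.conv,
                "coverage_hessian": self.coverage_hessian.get(name, np.nan),
                "coverage_sandwich": self.coverage_sandwich.get(name, np.nan),
            })
        return pd.DataFrame(rows)


def draw_skew_normal(count: int, location: float, scale: float, shape: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Skew-normal draws via the |Z| representation.

    X = location + scale * (delta*|Z0| + sqrt(1-delta^2)*Z1) with
    delta = shape / sqrt(1 + shape^2) has the SN(location, scale, shape)
    law; shape = 0 recovers the normal.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    delta = shape / np.sqrt(1.0 + shape * shape)
    z0 = np.abs(rng.standard_normal(count))
    z1 = rng.standard_normal(count)
    return location + scale * (delta * z0 + np.sqrt(1.0 - delta * delta) * z1)


def _expit(t):
    return 1.0 / (1.0 + np.exp(-t))


def _draw_latents(config: SimConfig, rng: np.random.Generator):
    n = config.n_studies
    if config.xi_dist == "skew_normal":
        xi = draw_skew_normal(n, 0.0, 1.0, config.skew_shape, rng)
    else:
        xi = rng.standard_normal(n)
    if config.scenario == 1 and config.zeta_dist == "bernoulli":
        zeta = rng.integers(0, 2, n).astype(float)
    else:
        zeta = rng.standard_normal(n)
    b0, b1, b2 = config.betas
    eta = b0 + b1 * xi + b2 * zeta + np.sqrt(config.tau2) * rng.standard_normal(n)
    return eta, xi, zeta


def _feasible_joint_prob(p_event: float, p_trait: float,
                         rng: np.random.Generator) -> float:
    """Joint cell probability uniform on its feasible (Frechet) range."""
    lo = max(0.0, p_event + p_trait - 1.0)
    hi = min(p_event, p_trait)
    return rng.uniform(lo, hi)


def generate_scenario(config: SimConfig, rng: np.random.Generator):
    """One replicate: a list of StudyRecord plus the true latent values."""
    n = config.n_studies
    lo, hi = config.size_range
    n_treat = rng.integers(lo, hi + 1, n)
    n_control = rng.integers(lo, hi + 1, n)
    eta, xi, zeta = _draw_latents(config, rng)
    p_eta, p_xi, p_zeta = _expit(eta), _expit(xi), _expit(zeta)
    records = []

    if config.scenario == 1:
        y = rng.binomial(n_treat, p_eta)
        x = rng.binomial(n_control, p_xi)
        for i in range(n):
            records.append(StudyRecord(
                study_id=f"s{i}", y_events=int(y[i]), n_treat=int(n_treat[i]),
                x_events=int(x[i]), n_control=int(n_control[i]),
                covariate=CovariateSummary(kind=CovariateKind.ERROR_FREE,
                                           value=float(zeta[i])),
            ))
    elif config.scenario == 2:
        for i in range(n):
            cells = {}
            for arm, p_ev, ntot in (("t", p_eta[i], n_treat[i]),
                                    ("c", p_xi[i], n_control[i])):
                p1m = _feasible_joint_prob(p_ev, p_zeta[i], rng)
                probs = np.array([p1m, p_zeta[i] - p1m, p_ev - p1m,
                                  1.0 - p_ev - p_zeta[i] + p1m])
                probs = np.clip(probs, 0.0, None)
                draw = rng.multinomial(ntot, probs / probs.sum())
                cells[f"z{arm}1m"], cells[f"z{arm}0m"] = int(draw[0]), int(draw[1])
                cells[f"z{arm}1f"], cells[f"z{arm}0f"] = int(draw[2]), int(draw[3])
            table = SubgroupTable(**cells)
            y_i = table.zt1m + table.zt1f
            x_i = table.zc1m + table.zc1f
            records.append(StudyRecord(
                study_id=f"s{i}", y_events=y_i, n_treat=int(n_treat[i]),
                x_events=x_i, n_control=int(n_control[i]),
                covariate=CovariateSummary(
                    kind=CovariateKind.LOG_ODDS,
                    z_count=table.male_total(),
                    z_total=int(n_treat[i] + n_control[i]),
                ),
                subgroup=table,
            ))
    else:
        y = rng.binomial(n_treat, p_eta)
        x = rng.binomial(n_control, p_xi)
        sd = config.sd_subject
        rho_t = rng.uniform(-1.0, 1.0, n)
        rho_c = rng.uniform(-1.0, 1.0, n)
        for i in range(n):
            # guard degenerate subgroup sizes; a zero-size subgroup mean has
            # zero weight in the pooled covariate anyway
            yc = min(max(int(y[i]), 1), int(n_treat[i]) - 1)
            xc = min(max(int(x[i]), 1), int(n_control[i]) - 1)
            def _pair(m, n1, n0, rho):
                z1 = rng.standard_normal()
                z2 = rng.standard_normal()
                a = m + sd / np.sqrt(n1) * z1
                b = m + sd / np.sqrt(n0) * (rho * z1 + np.sqrt(1 - rho * rho) * z2)
                return float(a), float(b)
            zt1, zt0 = _pair(zeta[i], yc, n_treat[i] - yc, rho_t[i])
            zc1, zc0 = _pair(zeta[i], xc, n_control[i] - xc, rho_c[i])
            table = SubgroupTable(zt1=zt1, zt0=zt0, zc1=zc1, zc0=zc0, sd=sd)
            ni = int(n_treat[i] + n_control[i])
            pooled = (y[i] * zt1 + (n_treat[i] - y[i]) * zt0
                      + x[i] * zc1 + (n_control[i] - x[i]) * zc0) / ni
            records.append(StudyRecord(
                study_id=f"s{i}", y_events=int(y[i]), n_treat=int(n_treat[i]),
                x_events=int(x[i]), n_control=int(n_control[i]),
                covariate=CovariateSummary(kind=CovariateKind.MEAN_VALUE,
                                           value=float(pooled), sd=sd),
                subgroup=table,
            ))

    truth = {"eta": eta, "xi": xi, "zeta": zeta}
    return records, truth


_TRUE_BY_NAME = {"mu_xi": 0.0, "mu_zeta": 0.0, "sigma_xi2": 1.0,
                 "sigma_zeta2": 1.0, "sigma_xizeta": 0.0}


def _true_value(name: str, config: SimConfig) -> float:
    b0, b1, b2 = config.betas
    if name == "beta0":
        return b0
    if name == "beta1":
        return b1
    if name == "beta2":
        return b2
    if name == "tau2":
        return config.tau2
    if name == "sigma_zeta2" and config.scenario == 1 \
            and config.zeta_dist == "bernoulli":
        return 0.25
    return _TRUE_BY_NAME[name]


def _fit_one(method: str, config: SimConfig, triples, zeta_offsets,
             compute_se: bool):
    if method == "naive":
        return inference.fit(triples, mode="naive", zeta_offsets=zeta_offsets,
                             naive_variant="ols", compute_se=compute_se)
    if config.scenario == 1:
        mode = "classical"
    else:
        mode = "pseudo" if method == "pseudo_likelihood" else "full"
    return inference.fit(triples, mode=mode, zeta_offsets=zeta_offsets,
                         compute_se=compute_se,
                         compute_sandwich=compute_se and mode in ("full", "pseudo"))


def run_study(
    config: SimConfig,
    methods: Sequence[str] = ("likelihood", "naive"),
    compute_se: bool = True,
) -> dict:
    """Run the full simulation study; returns {method: SimSummary}."""
    seed_seq = np.random.SeedSequence(config.seed)
    child_seeds = seed_seq.spawn(config.n_reps)
    estimates = {m: [] for m in methods}
    ses = {m: [] for m in methods}
    for rep in range(config.n_reps):
        rng = np.random.default_rng(child_seeds[rep])
        records, _ = generate_scenario(config, rng)
        triples, zeta_offsets = observed_from_records(
            records, continuity_policy="always")
        for m in methods:
            try:
                res = _fit_one(m, config, triples, zeta_offsets, compute_se)
            except (ValueError, np.linalg.LinAlgError):
                estimates[m].append(None)
                ses[m].append(None)
                continue
            if res.converged:
                estimates[m].append(res.params)
                ses[m].append((res.se_hessian, res.se_sandwich))
            else:
                estimates[m].append(None)
                ses[m].append(None)

    summaries = {}
    z95 = 1.959963984540054
    for m in methods:
        fitted = [p for p in estimates[m] if p is not None]
        se_pairs = [s for s in ses[m] if s is not None]
        conv = len(fitted)
        if conv == 0:
            summaries[m] = SimSummary(method=m, n_reps=config.n_reps, conv=0)
            continue
        names = ["beta0", "beta1", "beta2", "mu_xi", "mu_zeta",
                 "tau2", "sigma_xi2", "sigma_zeta2"]
        if m == "naive":
            names = ["beta0", "beta1", "beta2", "tau2"]
        elif config.scenario == 1:
            names = ["beta0", "beta1", "beta2", "mu_xi", "tau2", "sigma_xi2"]
        summary = SimSummary(method=m, n_reps=config.n_reps, conv=conv)
        for name in names:
            vals = np.array([getattr(p, name) for p in fitted])
            truth = _true_value(name, config)
            summary.bias[name] = float(vals.mean() - truth)
            summary.sd[name] = float(vals.std(ddof=1)) if conv > 1 else np.nan
            if compute_se:
                se_h = np.array([pair[0].get(name, np.nan) for pair in se_pairs])
                summary.se[name] = float(np.nanmean(se_h))
                if name.startswith("beta"):
                    cover = np.abs(vals - truth) <= z95 * se_h
                    summary.coverage_hessian[name] = float(
                        np.mean(cover[np.isfinite(se_h)]))
                    se_s = np.array([
                        pair[1].get(name, np.nan) if pair[1] else np.nan
                        for pair in se_pairs])
                    if np.any(np.isfinite(se_s)):
                        cover_s = np.abs(vals - truth) <= z95 * se_s
                        summary.coverage_sandwich[name] = float(
                            np.nanmean(np.where(np.isfinite(se_s), cover_s, np.nan)))
        summaries[m] = summary
    return summaries
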