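# ctrlrisk

Meta-regression of a treatment-arm risk measure on the baseline (control)
risk and additional study-level covariates, with likelihood-based
correction for the measurement error that study-level summaries carry.

## The problem

In a meta-analysis of `n` two-arm studies, let `eta_i` and `xi_i` be the
latent log-odds of the outcome in the treatment and control arm of study
`i`.  Regressing the treatment risk on the baseline risk,

    eta_i = beta0 + beta1 * xi_i + beta2 * zeta_i + eps_i,
    eps_i ~ N(0, tau2),

explains between-study heterogeneity by how sick the control population
is (`xi_i`) and by a study-level covariate `zeta_i` (mean age, % male,
...).  Neither `xi_i` nor `zeta_i` is observed: only the empirical
log-odds `xi_hat_i` and the covariate summary `zeta_hat_i`, both of
which vary around the truth with known sampling (co)variance.  Ignoring
that error attenuates `beta1` toward zero and inflates `tau2`; this
package implements the structural correction: latent Gaussian laws
`xi_i ~ N(mu_xi, sigma_xi2)`, `zeta_i ~ N(mu_zeta, sigma_zeta2)` make
the marginal law of the observed triple multivariate normal with mean

    mu = (beta0 + beta1*mu_xi + beta2*mu_zeta, mu_xi, mu_zeta)

and covariance `Sigma + Gamma_i`, where `Gamma_i` is the within-study
covariance of the observed measures.  The likelihood is maximized by
Nelder-Mead from an OLS start.  Variants:

* **likelihood** — full `Gamma_i`, with the within-study covariances
  between risk measures and covariate approximated by first-order Taylor
  expansions from subgroup summary tables;
* **pseudo-likelihood** — working independence (`Gamma_i` diagonal),
  for when subgroup tables are unavailable; robust (sandwich) standard
  errors `A^-1 B A^-1` restore valid inference;
* **exact error model** — binomial/multinomial observation laws instead
  of the normal approximation, integrated over the latents by
  Gauss-Hermite quadrature;
* **naive** — measurement error ignored (weighted or ordinary
  least-squares meta-regression), as the comparison baseline.

A simulation engine generates the three covariate scenarios (error-free
scalar, binary-trait log-odds, subgroup mean value) and summarizes bias,
standard errors, empirical SD, convergence and Wald coverage.

## Worked example

The package ships a ten-study meta-analysis of COVID-19 mortality in
patients with versus without schizophrenia (events/totals per arm plus
mean age, % male, % diabetes per study).  Fitting the classical
two-variable model by maximum likelihood:

```sh
$ ctrlrisk fit --method lik
method: likelihood  error model: approximate  studies: 10
log-likelihood: -24.6266  converged: True
  beta0          0.146 (0.329)
  beta1          0.761 (0.091) *
  mu_xi         -2.568 (0.500)
  tau2           0.028 (0.049)
  sigma_xi2      2.459 (1.112)
```

The slope 0.761 (SE 0.091) says mortality among schizophrenia patients
rises significantly with the background mortality of the study
population; the residual heterogeneity `tau2 = 0.028` is small once the
baseline risk is accounted for.  The naive analysis on the same data,

```sh
$ ctrlrisk fit --method naive
  beta0         -0.080 (0.140)
  beta1          0.709 (0.056) *
  tau2           0.527 (0.211)
```

shows the two classic symptoms of uncorrected measurement error: an
attenuated slope (0.709 < 0.761) and a greatly inflated residual
variance (0.527 vs 0.028).  Adding standardized mean age as an
error-prone covariate through the pseudo-likelihood,

```sh
$ ctrlrisk fit --model covariate --covariate age --method pseudo --standardize
  beta1          1.071 (0.185) *
  beta2         -0.560 (0.269) *
  ...
```

identifies age as a significant moderator (younger cohorts carry lower
mortality risk) and drives `tau2` essentially to zero.

Simulation studies run from the same CLI, e.g.

```sh
ctrlrisk simulate --scenario 1 --n 20 --tau2 0.1 --reps 1000 --seed 7
```

writes a tidy CSV of per-parameter bias/se/sd/convergence for the
corrected and naive estimators.

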