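# Methods

## Model

For study `i` with `Y_i` events among `n_iT` treated and `X_i` events
among `n_iC` controls, the observed log-odds are

    eta_hat_i = log(Y_i / (n_iT - Y_i)),   s_eta_i^2 = 1/Y_i + 1/(n_iT - Y_i),

and analogously for `xi_hat_i` in the control arm.  The structural model
couples a linear regression of the latent treatment risk on the latent
baseline risk and covariate with Gaussian laws for the latents:

    eta_i  = beta0 + beta1 * xi_i + beta2 * zeta_i + eps_i,
    xi_i   ~ N(mu_xi, sigma_xi2),
    zeta_i ~ N(mu_zeta, sigma_zeta2),   eps_i ~ N(0, tau2).

Under the approximate (normal) error model the observed triple
`(eta_hat, xi_hat, zeta_hat)` given the latents is normal with known
within-study covariance `Gamma_i`; marginally it is trivariate normal
with covariance `Sigma + Gamma_i`, so the likelihood is closed-form.
The `(1,2)` entry of `Gamma_i` is structurally zero (the two arms share
no subjects); the `(1,3)` and `(2,3)` entries are the within-study
covariances between risk measures and covariate summary induced by
shared subjects.

We implement `Sigma` in the internally consistent general form that
propagates a latent cross-covariance `sigma_xizeta` into every entry
(row 1 gains `2*beta1*beta2*sigma_xizeta`, etc.).  It reduces to the
familiar display when `sigma_xizeta = 0`, which is also the default:
the cross-covariance is held at zero unless explicitly freed, because
freeing it is rarely identifiable with typical numbers of studies and
the published analyses we reproduce hold it fixed.

### Within-study covariances

When a study reports subgroup summaries the covariances in `Gamma_i`
come from first-order Taylor (delta-method) expansions:

* binary trait (eight-cell table by arm x event x trait):
  `s_eta,zeta ~ (1/Z)[Zt1m/Y - Zt0m/(nT-Y)] - (1/(n-Z))[Zt1f/Y - Zt0f/(nT-Y)]`,
  and the control-arm analogue;
* mean-value covariate (four subgroup means, common within-subject SD):
  `s_eta,zeta ~ (Zt1 - Zt0)/n`, `s_xi,zeta ~ (Zc1 - Zc0)/n`.

A Monte-Carlo oracle (multinomial resampling of the table, or joint
resampling of counts and subgroup means) validates both formulas in the
test-suite.  First-order accuracy degrades for sparse margins (relative
error of order 1/margin); if an assembled `Gamma_i` is indefinite the
off-diagonal entries are shrunk toward zero by the smallest factor
restoring positive semidefiniteness and a warning is logged.  Degenerate
margins (an empty cell) fall back to zero covariance for that study.

### Pseudo-likelihood and sandwich variance

Without subgroup tables the covariances are unknown; the
pseudo-likelihood sets the off-diagonal entries of `Gamma_i` to zero
(working independence).  The point estimates remain consistent; their
covariance is estimated by the sandwich `A^-1 B A^-1`, with `A` the
finite-difference Hessian of the negative log pseudo-likelihood and `B`
the sum of outer products of per-study scores (central differences),
both evaluated at the optimum on the optimizer scale and mapped back to
the natural scale by the delta method.

### Exact error models

Instead of the normal approximation, the exact observation laws are
`Y_i ~ Binomial(n_iT, expit(eta_i))`, `X_i ~ Binomial(n_iC, expit(xi_i))`,
with the trait count binomial in `expit(zeta_i)` (binary covariate) or
the subgroup means bivariate normal around `zeta_i` with per-subgroup
variances `SD_i^2/count` and within-arm correlations supplied as inputs
(mean covariate; the correlations default to zero because no reporting
convention pins them down).  The latent integrals are evaluated on
tensor-product probabilists' Gauss-Hermite grids after standardizing
each latent at its conditional mean and scale (`xi = mu_xi + sigma_xi*u`,
`eta = beta0 + beta1*xi + beta2*zeta + tau*v`, ...).  The default is 10
nodes per dimension; the grids are centered at the prior, not adapted to
the data, so accuracy improves slowly with node count when the counts
are large and the integrand concentrates — the oracle tests use 80-150
nodes.  For the binary covariate the pseudo factorization treats the
event counts and the trait count as independent binomials given the
latents; the full multinomial mode additionally needs the joint cell
probability `p_1M`, which is not a function of the margins alone — the
default coupling is within-arm independence (`p_1M = p_event * p_trait`)
clipped into the Frechet bounds, and a user-supplied coupling can
replace it.

### Naive analyses

Two naive (error-ignoring) estimators are provided, because published
practice uses both:

* `wls` (default for data analysis): weighted least squares of
  `eta_hat` on the observed regressors with fixed weights
  `1/s_eta_i^2`; `tau2_hat` is the mean squared raw residual;
  coefficient SEs are dispersion-scaled (`Q/(n-p)`) as in a weighted
  linear model, and `SE(tau2_hat) = tau2_hat * sqrt(2(n-p))/n`;
* `ols` (default in the simulation harness): the unweighted,
  homoscedastic-ML fit (coefficients = OLS, `tau2_hat` = mean squared
  residual);
* `ml`: joint Nelder-Mead maximization of the heteroscedastic normal
  likelihood with variance `s_eta_i^2 + tau2` (set
  `naive_include_s2=False` for the homoscedastic version).

## Estimation and inference

Nelder-Mead from an ordinary-least-squares start (`beta` from OLS of
`eta_hat` on the regressors, latent means/variances from sample moments
minus mean sampling variances, floored at 0.01), with
`xatol = fatol = 1e-8` and `maxiter = 5000 p`.  By default variances are
optimized on the log scale and `sigma_xizeta` (when freed) through an
atanh-bounded correlation, keeping all iterates interior; a raw-scale
option exists and reaches the same optimum on regular datasets.  A
variance driven to the numerical floor (1e-8) is a boundary solution:
the fit still counts as converged (the estimates are the boundary MLE)
and the condition is recorded in the fit message.  Hessian standard
errors come from the finite-difference observed information on the
optimizer scale, delta-mapped to natural scale; a numerically singular
information (typical exactly at boundary solutions) falls back to the
pseudo-inverse and flags the fit as not cleanly converged.  Wald
intervals use the exact normal quantile (1.959964 at 95%).

## Synthetic-data generator

The generator emulates aggregated two-arm studies: per-arm sizes
integer-uniform on [15, 200]; latent baseline risk standard normal (or
skew-normal with shape -5, via the |Z| representation, to probe
misspecification); covariate standard normal (or Bernoulli(0.5));
regression coefficients (0, 1, 0.8); `tau2` in {0.1, 0.5, 1.0};
`mu_xi = mu_zeta = 0`.  Three observation designs:

1. binomial event counts, error-free covariate;
2. per-arm four-cell multinomial tables for a binary trait, with the
   joint cell probability drawn uniformly over its feasible (Frechet)
   range — the naive uniform-on-`[0, min(margins)]` draw can produce a
   negative fourth cell, so the lower Frechet bound is enforced — and
   event/trait counts taken as the margins;
3. binomial counts plus subgroup means from correlated bivariate
   normals around the latent covariate (correlations uniform on (-1, 1),
   within-subject SD 1 by default).

Observed log-odds in the generator always carry the 0.5
continuity correction in every cell (not only empty ones), so boundary
counts never produce infinite values; real-data analysis defaults to
correcting only empty cells.  One master seed drives a
`SeedSequence`-spawned substream per replicate, so studies are
reproducible and order-independent.

What the generator does not emulate: real covariate distributions are
rarely Gaussian, study sizes are not uniform, within-study correlations
of subgroup means are unknown rather than uniform, and the latent risks
of the two arms may be dependent beyond the regression structure.
Passing simulation checks therefore demonstrates internal consistency of
estimator and generator, not field calibration.

## Numerical choices and limitations

* The uniform continuity correction in the generator slightly shrinks
  all observed log-odds; with arm sizes 15-200 this leaves a small
  systematic attenuation (~0.03) in the covariate coefficient of the
  corrected estimators that does not vanish as the number of studies
  grows.  It is a property of the study conditions, not of the
  estimator.
* Monte-Carlo summaries (bias, se, sd, coverage) aggregate over
  convergent replicates only; convergence means optimizer success, and,
  where standard errors are requested, a numerically positive-definite
  observed information.
* The acceptance checks compare two Monte-Carlo means (ours and a
  reference value that is itself a 1000-replicate average) through their
  combined standard error `sqrt(sd_a^2/n_a + sd_b^2/n_b)`.
* Problem sizes: the simulation checks use 1000 replicates per scenario
  at n = 20 studies (the reference setting), 500 replicates for the
  n = 50 coverage check, and 30 replicates at n = 200 for parameter
  recovery — enough for the 3-combined-SE comparisons to be
  informative while keeping a full run in minutes on one core.
* Likelihood-ratio or bootstrap intervals, REML variants, multi-start
  optimization, and adaptive or sparse-grid quadrature are out of
  scope; the plain tensor Gauss-Hermite grid needs large node counts
  for sharply concentrated integrands (large counts, small subgroup
  SDs).
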