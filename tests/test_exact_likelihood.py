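import numpy as np
import pytest
from scipy import integrate, special, stats

from ctrlrisk.data_model import ModelParams, StudyRecord, SubgroupTable
from ctrlrisk.exact_likelihood import (gauss_hermite_rule,
                                       neg_loglik_exact_binomial,
                                       neg_pseudo_loglik_exact_meancov,
                                       neg_pseudo_loglik_exact_multinomial)


class TestGaussHermiteRule:
    def test_weights_normalized_and_positive(self):
        r = gauss_hermite_rule(10, dims=2)
        assert r.weights.sum() == pytest.approx(1.0, rel=1e-12)
        assert np.all(r.weights > 0)
        assert r.nodes.shape == (100, 2)

    def test_degree_three_exactness_with_two_nodes(self):
        r = gauss_hermite_rule(2)
        assert np.dot(r.weights, r.nodes[:, 0] ** 2) == pytest.approx(1.0)
        assert np.dot(r.weights, r.nodes[:, 0] ** 3) == pytest.approx(0.0, abs=1e-12)

    def test_gaussian_eighth_moment(self):
        # E[X^8] = 7!! = 105 for X ~ N(0,1); exact for a 10-node rule
        r = gauss_hermite_rule(10)
        assert np.dot(r.weights, r.nodes[:, 0] ** 8) == pytest.approx(105.0,
                                                                      rel=1e-10)

    def test_rejects_degenerate_rule(self):
        with pytest.raises(ValueError):
            gauss_hermite_rule(1)


class TestExactBinomial:
    def test_degenerate_latent_limit(self):
        # tiny latent variances, large arms: likelihood approaches the
        # product of binomial pmfs at the latent means
        p = ModelParams(beta0=0.4, beta1=0.0, mu_xi=-0.3, tau2=1e-10,
                        sigma_xi2=1e-10)
        rec = StudyRecord("s", 300, 500, 190, 500)
        got = neg_loglik_exact_binomial(p, [rec], n_nodes=10)
        expected = -(
            stats.binom.logpmf(300, 500, special.expit(0.4))
            + stats.binom.logpmf(190, 500, special.expit(-0.3))
        )
        assert got == pytest.approx(expected, rel=1e-6)

    def test_matches_adaptive_quadrature_oracle(self, small_exact_records,
                                                classical_params):
        p = classical_params
        got = neg_loglik_exact_binomial(p, small_exact_records, n_nodes=150)
        total = 0.0
        for rec in small_exact_records:
            def f(eta, xi):
                return (stats.binom.pmf(rec.y_events, rec.n_treat,
                                        special.expit(eta))
                        * stats.binom.pmf(rec.x_events, rec.n_control,
                                          special.expit(xi))
                        * stats.norm.pdf(eta, p.beta0 + p.beta1 * xi,
                                         np.sqrt(p.tau2))
                        * stats.norm.pdf(xi, p.mu_xi, np.sqrt(p.sigma_xi2)))
            val, _ = integrate.dblquad(f, -6, 6, -8, 8,
                                       epsabs=1e-12, epsrel=1e-10)
            total -= np.log(val)
        assert got == pytest.approx(total, rel=1e-4)

    def test_refinement_approaches_oracle(self, small_exact_records,
                                          classical_params):
        vals = {n: neg_loglik_exact_binomial(classical_params,
                                             small_exact_records, n)
                for n in (10, 40, 150)}
        ref = neg_loglik_exact_binomial(classical_params, small_exact_records,
                                        300)
        assert abs(vals[150] - ref) < abs(vals[40] - ref) < abs(vals[10] - ref)

    def test_requires_positive_variances(self, small_exact_records):
        p = ModelParams(beta0=0.1, beta1=1.0, tau2=0.0, sigma_xi2=1.0)
        with pytest.raises(ValueError):
            neg_loglik_exact_binomial(p, small_exact_records)


def _binary_records(rng, n=3):
    records = []
    for i in range(n):
        nt, nc = rng.integers(40, 120, 2)
        zt = rng.multinomial(nt, [0.25, 0.3, 0.25, 0.2])
        zc = rng.multinomial(nc, [0.2, 0.3, 0.3, 0.2])
        table = SubgroupTable(zt1m=int(zt[0]), zt0m=int(zt[1]),
                              zt1f=int(zt[2]), zt0f=int(zt[3]),
                              zc1m=int(zc[0]), zc0m=int(zc[1]),
                              zc1f=int(zc[2]), zc0f=int(zc[3]))
        records.append(StudyRecord(
            f"s{i}", int(zt[0] + zt[2]), int(nt), int(zc[0] + zc[2]), int(nc),
            subgroup=table))
    return records


FULL_PARAMS = ModelParams(beta0=0.1, beta1=0.9, beta2=0.5, mu_xi=-0.2,
                          mu_zeta=0.1, tau2=0.3, sigma_xi2=0.8,
                          sigma_zeta2=0.6)


class TestExactMultinomial:
    def test_nests_binomial_when_covariate_effect_absent(self, rng):
        records = _binary_records(rng)
        p = ModelParams(beta0=0.1, beta1=0.9, beta2=0.0, mu_xi=-0.2,
                        mu_zeta=0.1, tau2=0.3, sigma_xi2=0.8, sigma_zeta2=0.6)
        got = neg_pseudo_loglik_exact_multinomial(p, records, n_nodes=12)
        # with beta2 = 0 the integrand separates: event-count part times
        # an independent trait-count integral
        binom_part = neg_loglik_exact_binomial(p, records, n_nodes=12)
        rule = gauss_hermite_rule(12)
        zeta = p.mu_zeta + np.sqrt(p.sigma_zeta2) * rule.nodes[:, 0]
        trait_part = 0.0
        for r in records:
            z = r.subgroup.male_total()
            like = stats.binom.pmf(z, r.n_total, special.expit(zeta))
            trait_part -= np.log(np.dot(rule.weights, like))
        assert got == pytest.approx(binom_part + trait_part, rel=1e-10)

    def test_pseudo_matches_brute_force_oracle(self, rng):
        records = _binary_records(rng, n=1)
        p = FULL_PARAMS
        got = neg_pseudo_loglik_exact_multinomial(p, records, n_nodes=80)
        r = records[0]
        z = r.subgroup.male_total()
        # independent trapezoid quadrature on a wide fixed grid
        eta = np.linspace(-7, 7, 241)
        xi = np.linspace(-7, 7, 241)
        zeta = np.linspace(-7, 7, 241)
        inner_eta = np.empty((len(xi), len(zeta)))
        py = stats.binom.pmf(r.y_events, r.n_treat, special.expit(eta))
        for i, xv in enumerate(xi):
            mean = p.beta0 + p.beta1 * xv + p.beta2 * zeta
            dens = stats.norm.pdf(eta[None, :], mean[:, None], np.sqrt(p.tau2))
            inner_eta[i] = np.trapezoid(py[None, :] * dens, eta, axis=1)
        px = stats.binom.pmf(r.x_events, r.n_control, special.expit(xi))
        pz = stats.binom.pmf(z, r.n_total, special.expit(zeta))
        fx = stats.norm.pdf(xi, p.mu_xi, np.sqrt(p.sigma_xi2))
        fz = stats.norm.pdf(zeta, p.mu_zeta, np.sqrt(p.sigma_zeta2))
        grid = inner_eta * (px * fx)[:, None] * (pz * fz)[None, :]
        val = np.trapezoid(np.trapezoid(grid, zeta, axis=1), xi)
        assert got == pytest.approx(-np.log(val), rel=1e-3)

    def test_full_mode_relabeling_invariance(self, rng):
        records = _binary_records(rng)
        swapped = []
        for r in records:
            t = r.subgroup
            table = SubgroupTable(zt1m=t.zt1f, zt1f=t.zt1m, zt0m=t.zt0f,
                                  zt0f=t.zt0m, zc1m=t.zc1f, zc1f=t.zc1m,
                                  zc0m=t.zc0f, zc0f=t.zc0m)
            swapped.append(StudyRecord(r.study_id, r.y_events, r.n_treat,
                                       r.x_events, r.n_control, subgroup=table))
        p = FULL_PARAMS
        flipped = ModelParams(**{**p.to_dict(), "beta2": -p.beta2,
                                 "mu_zeta": -p.mu_zeta})
        for mode in ("pseudo", "full"):
            a = neg_pseudo_loglik_exact_multinomial(p, records, 15, mode=mode)
            b = neg_pseudo_loglik_exact_multinomial(flipped, swapped, 15,
                                                    mode=mode)
            assert a == pytest.approx(b, rel=1e-9)


def _mean_records(rng, n=2, sd=1.0):
    records = []
    for i in range(n):
        nt, nc = (int(v) for v in rng.integers(40, 120, 2))
        y = int(rng.integers(5, nt - 5))
        x = int(rng.integers(5, nc - 5))
        table = SubgroupTable(zt1=float(rng.normal(0, 1)),
                              zt0=float(rng.normal(0, 1)),
                              zc1=float(rng.normal(0, 1)),
                              zc0=float(rng.normal(0, 1)), sd=sd)
        records.append(StudyRecord(f"s{i}", y, nt, x, nc, subgroup=table))
    return records


class TestExactMeanCovariate:
    def test_zero_correlation_factorizes(self, rng):
        records = _mean_records(rng, n=1)
        p = FULL_PARAMS
        got = neg_pseudo_loglik_exact_meancov(p, records, n_nodes=15)
        # with rho = 0 the bivariate subgroup densities are products of
        # univariate normals; recompute the integrand that way
        rule = gauss_hermite_rule(15, dims=3)
        u, v, w = rule.nodes.T
        xi = p.mu_xi + np.sqrt(p.sigma_xi2) * u
        zeta = p.mu_zeta + np.sqrt(p.sigma_zeta2) * w
        eta = p.beta0 + p.beta1 * xi + p.beta2 * zeta + np.sqrt(p.tau2) * v
        r = records[0]
        t = r.subgroup
        y, x = r.y_events, r.x_events
        like = (stats.binom.pmf(y, r.n_treat, special.expit(eta))
                * stats.binom.pmf(x, r.n_control, special.expit(xi))
                * stats.norm.pdf(t.zt1, zeta, t.sd / np.sqrt(y))
                * stats.norm.pdf(t.zt0, zeta, t.sd / np.sqrt(r.n_treat - y))
                * stats.norm.pdf(t.zc1, zeta, t.sd / np.sqrt(x))
                * stats.norm.pdf(t.zc0, zeta, t.sd / np.sqrt(r.n_control - x)))
        expected = -np.log(np.dot(rule.weights, like))
        assert got == pytest.approx(expected, rel=1e-10)

    def test_matches_brute_force_oracle(self, rng):
        # a wide within-subject SD keeps the zeta-integrand resolvable by
        # the plain tensor-product grid
        records = _mean_records(rng, n=1, sd=4.0)
        p = FULL_PARAMS
        rho_t, rho_c = [0.4], [-0.3]
        got = neg_pseudo_loglik_exact_meancov(p, records, n_nodes=80,
                                              rho_treat=rho_t,
                                              rho_control=rho_c)
        r = records[0]
        t = r.subgroup
        y, x = r.y_events, r.x_events
        sd2 = t.sd ** 2

        def bvn_pdf(z1, z0, m, v1, v0, rho):
            cov = np.array([[v1, rho * np.sqrt(v1 * v0)],
                            [rho * np.sqrt(v1 * v0), v0]])
            return stats.multivariate_normal.pdf([z1, z0], mean=[m, m],
                                                 cov=cov)

        eta = np.linspace(-7, 7, 401)
        xi = np.linspace(-7, 7, 401)
        zeta = np.linspace(-5, 5, 801)
        py = stats.binom.pmf(y, r.n_treat, special.expit(eta))
        inner = np.empty((len(xi), len(zeta)))
        for i, xv in enumerate(xi):
            mean = p.beta0 + p.beta1 * xv + p.beta2 * zeta
            dens = stats.norm.pdf(eta[None, :], mean[:, None], np.sqrt(p.tau2))
            inner[i] = np.trapezoid(py[None, :] * dens, eta, axis=1)
        sub = np.array([
            bvn_pdf(t.zt1, t.zt0, zv, sd2 / y, sd2 / (r.n_treat - y), 0.4)
            * bvn_pdf(t.zc1, t.zc0, zv, sd2 / x, sd2 / (r.n_control - x), -0.3)
            for zv in zeta])
        px = stats.binom.pmf(x, r.n_control, special.expit(xi))
        fx = stats.norm.pdf(xi, p.mu_xi, np.sqrt(p.sigma_xi2))
        fz = stats.norm.pdf(zeta, p.mu_zeta, np.sqrt(p.sigma_zeta2))
        grid = inner * (px * fx)[:, None] * (sub * fz)[None, :]
        val = np.trapezoid(np.trapezoid(grid, zeta, axis=1), xi)
        assert got == pytest.approx(-np.log(val), rel=1e-3)

    def test_invalid_correlation_rejected(self, rng):
        records = _mean_records(rng, n=1)
        with pytest.raises(ValueError):
            neg_pseudo_loglik_exact_meancov(FULL_PARAMS, records,
                                            rho_treat=[1.0], rho_control=[0.0])
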