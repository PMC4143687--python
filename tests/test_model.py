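"""Density and container tests for the model module (closed-form oracles)."""

import numpy as np
import pytest
from scipy import stats
from scipy.integrate import quad

from pleiolvm import (
    FitData,
    LatentState,
    ModelSpec,
    PriorSpec,
    ThetaState,
    loglik_complete,
    loglik_family_pointwise,
    loglik_observed_pointwise,
    loglik_marginal_u_pointwise,
    loglik_subject_pointwise,
    logprior,
)
from pleiolvm.model import folded_t_logpdf

STD_LOGPDF_0 = -0.5 * np.log(2 * np.pi)  # -0.9189385


def single_record_fit(y=0.0):
    """One family, one individual, one visit, one continuous phenotype."""
    spec = ModelSpec(("y",))
    return FitData(
        spec=spec,
        y_cont=np.array([[y]]),
        cont_mask=np.array([[True]]),
        y_bin=np.zeros((1, 0)),
        bin_mask=np.zeros((1, 0), dtype=bool),
        W=np.zeros((1, 0)),
        X=np.zeros((1, 0)),
        fam_idx=np.array([0]),
        ind_idx=np.array([0]),
        ind_fam=np.array([0]),
    )


def unit_theta(J=1, J1=None, p1=0, p2=0):
    J1 = J if J1 is None else J1
    return ThetaState(
        beta0=np.zeros(J), beta=np.zeros((J, p1)), alpha=np.zeros(p2),
        lam=np.zeros(J), tau2=np.ones(J), sigma2=np.ones(J1),
        sigma_a2=1.0, sigma_d2=1.0,
    )


def zero_latent(fit):
    spec = fit.spec
    return LatentState(
        U=np.zeros(fit.n), a=np.zeros(fit.C), d=np.zeros(fit.M),
        b=np.zeros((fit.M, spec.J)), eta_bin=np.zeros((fit.n, spec.J2)),
    )


class TestLoglikComplete:
    def test_single_standard_record_closed_form(self):
        fit = single_record_fit(y=0.0)
        theta = unit_theta()
        latent = zero_latent(fit)
        # y-term, U-term, a, d, b are each a standard normal at 0
        assert loglik_complete(theta, latent, fit) == pytest.approx(5 * STD_LOGPDF_0, abs=1e-12)

    def test_doubling_sigma2_at_mean_costs_half_log2(self):
        fit = single_record_fit(y=0.0)
        latent = zero_latent(fit)
        t1 = unit_theta()
        t2 = unit_theta()
        t2.sigma2 = np.array([2.0])
        diff = loglik_complete(t2, latent, fit) - loglik_complete(t1, latent, fit)
        assert diff == pytest.approx(-0.5 * np.log(2.0), abs=1e-12)

    def test_matches_brute_force_oracle(self):
        # 2 families x 2 individuals x 1 visit, J = 2 (one continuous, one binary)
        rng = np.random.default_rng(8)
        spec = ModelSpec(("y1",), ("z1",), ("w1",), ("x1",))
        n, C, M = 4, 2, 4
        fit = FitData(
            spec=spec,
            y_cont=rng.normal(size=(n, 1)),
            cont_mask=np.ones((n, 1), dtype=bool),
            y_bin=(rng.random((n, 1)) < 0.5).astype(float),
            bin_mask=np.ones((n, 1), dtype=bool),
            W=rng.normal(size=(n, 1)),
            X=rng.normal(size=(n, 1)),
            fam_idx=np.array([0, 0, 1, 1]),
            ind_idx=np.array([0, 1, 2, 3]),
            ind_fam=np.array([0, 0, 1, 1]),
        )
        theta = ThetaState(
            beta0=rng.normal(size=2), beta=rng.normal(size=(2, 1)),
            alpha=rng.normal(size=1), lam=rng.normal(size=2),
            tau2=rng.uniform(0.5, 2.0, 2), sigma2=rng.uniform(0.5, 2.0, 1),
            sigma_a2=0.7, sigma_d2=1.3,
        )
        eta = rng.normal(size=(n, 1))
        eta = np.where(fit.y_bin == 1, np.abs(eta), -np.abs(eta))
        latent = LatentState(
            U=rng.normal(size=n), a=rng.normal(size=C), d=rng.normal(size=M),
            b=rng.normal(size=(M, 2)), eta_bin=eta,
        )
        # independent sum-of-log-densities oracle
        total = 0.0
        for r in range(n):
            mu_y = (theta.beta0[0] + fit.W[r, 0] * theta.beta[0, 0]
                    + theta.lam[0] * latent.U[r] + latent.b[fit.ind_idx[r], 0])
            total += stats.norm.logpdf(fit.y_cont[r, 0], mu_y, np.sqrt(theta.sigma2[0]))
            mu_e = (theta.beta0[1] + fit.W[r, 0] * theta.beta[1, 0]
                    + theta.lam[1] * latent.U[r] + latent.b[fit.ind_idx[r], 1])
            total += stats.norm.logpdf(latent.eta_bin[r, 0], mu_e, 1.0)
            mu_u = (fit.X[r, 0] * theta.alpha[0] + latent.a[fit.fam_idx[r]]
                    + latent.d[fit.ind_idx[r]])
            total += stats.norm.logpdf(latent.U[r], mu_u, 1.0)
        total += stats.norm.logpdf(latent.a, 0, np.sqrt(theta.sigma_a2)).sum()
        total += stats.norm.logpdf(latent.d, 0, np.sqrt(theta.sigma_d2)).sum()
        for j in range(2):
            total += stats.norm.logpdf(latent.b[:, j], 0, np.sqrt(theta.tau2[j])).sum()
        assert loglik_complete(theta, latent, fit) == pytest.approx(total, abs=1e-10)

    def test_maximized_over_u_at_precision_weighted_mean(self):
        rng = np.random.default_rng(3)
        fit = single_record_fit(y=2.0)
        theta = unit_theta()
        theta.lam = np.array([1.5])
        theta.sigma2 = np.array([0.8])
        latent = zero_latent(fit)
        latent.a[:] = 0.4
        latent.d[:] = -0.2
        latent.b[:] = 0.1

        def ll(u):
            latent.U[0] = u
            return loglik_complete(theta, latent, fit)

        # the log density is quadratic in U, so parabolic interpolation through
        # three points finds the maximizer exactly
        f_m, f_0, f_p = ll(-1.0), ll(0.0), ll(1.0)
        u_star = 0.5 * (f_p - f_m) / (2 * f_0 - f_m - f_p)
        prec = 1.0 + theta.lam[0] ** 2 / theta.sigma2[0]
        resid = fit.y_cont[0, 0] - theta.beta0[0] - latent.b[0, 0]
        mean = (latent.a[0] + latent.d[0] + theta.lam[0] * resid / theta.sigma2[0]) / prec
        assert u_star == pytest.approx(mean, abs=1e-8)

    def test_nonpositive_variance_rejected_by_name(self):
        fit = single_record_fit()
        theta = unit_theta()
        theta.sigma2 = np.array([-1.0])
        with pytest.raises(ValueError, match="sigma2"):
            theta.validate(fit.spec)

    def test_dimension_mismatch_rejected_by_name(self):
        fit = single_record_fit()
        theta = unit_theta(J=2, J1=2)
        with pytest.raises(ValueError, match="beta0"):
            theta.validate(fit.spec)


class TestLogprior:
    def test_alpha_block_bivariate_origin(self):
        spec = ModelSpec(("y",), indirect_covariates=("x1", "x2"))
        theta = unit_theta(p2=2)
        _, blocks = logprior(theta, PriorSpec(), spec, return_blocks=True)
        assert blocks["alpha"] == pytest.approx(-np.log(2 * np.pi), abs=1e-12)

    def test_folded_t3_at_zero(self):
        # folded-t_3(0) = 2 * t_3(0) = 2 * 0.36755... = 0.73510...
        val = np.exp(folded_t_logpdf(0.0, 3.0, 1.0))
        assert val == pytest.approx(2 * stats.t.pdf(0.0, 3), abs=1e-12)
        assert val == pytest.approx(0.7351, abs=1e-4)

    def test_extra_zero_loading_adds_folded_t_density(self):
        t1 = unit_theta(J=1)
        t2 = unit_theta(J=2, J1=2)
        _, b1 = logprior(t1, PriorSpec(), return_blocks=True)
        _, b2 = logprior(t2, PriorSpec(), return_blocks=True)
        assert b2["lam"] - b1["lam"] == pytest.approx(
            float(folded_t_logpdf(0.0, 3.0, 1.0)), abs=1e-12)

    def test_invariant_to_phenotype_reordering(self):
        spec1 = ModelSpec(("y1", "y2"))
        spec2 = ModelSpec(("y2", "y1"))
        rng = np.random.default_rng(0)
        theta = ThetaState(
            beta0=rng.normal(size=2), beta=np.zeros((2, 0)), alpha=np.zeros(0),
            lam=rng.normal(size=2), tau2=rng.uniform(0.5, 2, 2),
            sigma2=rng.uniform(0.5, 2, 2), sigma_a2=1.0, sigma_d2=1.0,
        )
        swapped = theta.copy()
        for name in ("beta0", "lam", "tau2", "sigma2"):
            setattr(swapped, name, getattr(theta, name)[::-1].copy())
        assert logprior(theta, PriorSpec(), spec1) == pytest.approx(
            logprior(swapped, PriorSpec(), spec2), abs=1e-12)

    def test_finite_on_support(self):
        theta = unit_theta()
        theta.lam = np.array([5.0])
        assert np.isfinite(logprior(theta, PriorSpec()))


def mixed_toy_fit(eta_mean=0.0, y=1.0):
    """One record with a single binary phenotype."""
    spec = ModelSpec((), ("z",))
    fit = FitData(
        spec=spec,
        y_cont=np.zeros((1, 0)),
        cont_mask=np.zeros((1, 0), dtype=bool),
        y_bin=np.array([[y]]),
        bin_mask=np.array([[True]]),
        W=np.zeros((1, 0)),
        X=np.zeros((1, 0)),
        fam_idx=np.array([0]),
        ind_idx=np.array([0]),
        ind_fam=np.array([0]),
    )
    theta = ThetaState(
        beta0=np.array([eta_mean]), beta=np.zeros((1, 0)), alpha=np.zeros(0),
        lam=np.zeros(1), tau2=np.ones(1), sigma2=np.zeros(0),
        sigma_a2=1.0, sigma_d2=1.0,
    )
    return fit, theta


class TestLoglikObservedPointwise:
    def test_binary_zero_predictor(self):
        fit, theta = mixed_toy_fit(eta_mean=0.0, y=1.0)
        out = loglik_observed_pointwise(theta, zero_latent(fit), fit)
        assert out[0] == pytest.approx(np.log(0.5), abs=1e-12)

    def test_binary_196_predictor(self):
        fit, theta = mixed_toy_fit(eta_mean=1.96, y=1.0)
        out = loglik_observed_pointwise(theta, zero_latent(fit), fit)
        assert out[0] == pytest.approx(np.log(0.975), abs=1e-3)

    def test_binary_y0_complements(self):
        fit, theta = mixed_toy_fit(eta_mean=0.7, y=0.0)
        out = loglik_observed_pointwise(theta, zero_latent(fit), fit)
        assert out[0] == pytest.approx(np.log(stats.norm.sf(0.7)), abs=1e-10)

    def test_matches_quadrature_of_augmented_representation(self):
        # P(y=1 | U, b) = integral over eta > 0 of N(eta; mean, 1)
        fit, theta = mixed_toy_fit(eta_mean=0.83, y=1.0)
        out = loglik_observed_pointwise(theta, zero_latent(fit), fit)
        val, _ = quad(lambda e: stats.norm.pdf(e, 0.83, 1.0), 0, np.inf)
        assert out[0] == pytest.approx(np.log(val), abs=1e-6)

    def test_continuous_cells_match_normal_density(self, tiny_fit, tiny_dataset):
        theta = tiny_dataset.truth["theta"]
        latent = tiny_dataset.truth["latent"]
        out = loglik_observed_pointwise(theta, latent, tiny_fit)
        mu = (theta.beta0[None, :] + tiny_fit.W @ theta.beta.T
              + theta.lam[None, :] * latent.U[:, None]
              + latent.b[tiny_fit.ind_idx, :])
        ref = stats.norm.logpdf(tiny_fit.y_cont, mu,
                                np.sqrt(theta.sigma2)[None, :]).sum(axis=1)
        np.testing.assert_allclose(out, ref, atol=1e-10)


class TestMarginalAndFamilyLikelihoods:
    def test_marginal_u_quadrature_matches_1d_quad(self):
        fit = single_record_fit(y=1.2)
        theta = unit_theta()
        theta.lam = np.array([0.9])
        latent = zero_latent(fit)
        latent.a[:] = 0.3
        out = loglik_marginal_u_pointwise(theta, latent, fit)

        def integrand(u):
            return (stats.norm.pdf(fit.y_cont[0, 0], theta.lam[0] * u, 1.0)
                    * stats.norm.pdf(u, 0.3, 1.0))

        val, _ = quad(integrand, -12, 12)
        assert out[0] == pytest.approx(np.log(val), abs=1e-8)

    def test_subject_matches_scipy_mvn(self, tiny_fit, tiny_dataset):
        theta = tiny_dataset.truth["theta"]
        latent = tiny_dataset.truth["latent"]
        out = loglik_subject_pointwise(theta, latent, tiny_fit)
        lam, tau2, sig2 = theta.lam, theta.tau2, theta.sigma2
        m_u = (tiny_fit.X @ theta.alpha + latent.a[tiny_fit.fam_idx]
               + latent.d[tiny_fit.ind_idx])
        mu = (theta.beta0[None, :] + tiny_fit.W @ theta.beta.T
              + lam[None, :] * m_u[:, None])
        for m in range(tiny_fit.M):
            rec = np.flatnonzero(tiny_fit.ind_idx == m)
            T = len(rec)
            cov = (np.kron(np.eye(T), np.outer(lam, lam) + np.diag(sig2))
                   + np.kron(np.ones((T, T)), np.diag(tau2)))
            ref = stats.multivariate_normal(mu[rec].ravel(), cov).logpdf(
                tiny_fit.y_cont[rec].ravel())
            assert out[m] == pytest.approx(ref, abs=1e-9)

    def test_family_matches_linear_map_oracle(self, tiny_fit, tiny_dataset):
        # independent construction: y = mean + Z g, g diagonal-Gaussian,
        # where g = (a_c, d_i..., eps_rec..., b_ij..., e_cells...)
        theta = tiny_dataset.truth["theta"]
        out = loglik_family_pointwise(theta, tiny_fit)
        spec = tiny_fit.spec
        J = spec.J1
        mu_all = (theta.beta0[None, :] + tiny_fit.W @ theta.beta.T
                  + theta.lam[None, :] * (tiny_fit.X @ theta.alpha)[:, None])
        for c in range(tiny_fit.C):
            rec = np.flatnonzero(tiny_fit.fam_idx == c)
            inds = np.unique(tiny_fit.ind_idx[rec])
            n_c = len(rec)
            dim = n_c * J
            n_g = 1 + len(inds) + n_c + len(inds) * J + dim
            Z = np.zeros((dim, n_g))
            var_g = np.zeros(n_g)
            var_g[0] = theta.sigma_a2
            var_g[1:1 + len(inds)] = theta.sigma_d2
            var_g[1 + len(inds):1 + len(inds) + n_c] = 1.0
            off_b = 1 + len(inds) + n_c
            var_g[off_b:off_b + len(inds) * J] = np.tile(theta.tau2, len(inds))
            off_e = off_b + len(inds) * J
            var_g[off_e:] = np.tile(theta.sigma2, n_c)
            for r_loc, r in enumerate(rec):
                i_loc = int(np.flatnonzero(inds == tiny_fit.ind_idx[r])[0])
                for j in range(J):
                    row = r_loc * J + j
                    Z[row, 0] = theta.lam[j]                      # a_c through U
                    Z[row, 1 + i_loc] = theta.lam[j]              # d_ci through U
                    Z[row, 1 + len(inds) + r_loc] = theta.lam[j]  # eps through U
                    Z[row, off_b + i_loc * J + j] = 1.0           # b_cij
                    Z[row, off_e + r_loc * J + j] = 1.0           # e_citj
            cov = Z @ np.diag(var_g) @ Z.T
            ref = stats.multivariate_normal(
                mu_all[rec].ravel(), cov).logpdf(tiny_fit.y_cont[rec].ravel())
            assert out[c] == pytest.approx(ref, abs=1e-8)

    def test_family_and_subject_reject_binary_specs(self, mixed_fit, mixed_dataset):
        theta = mixed_dataset.truth["theta"]
        latent = mixed_dataset.truth["latent"]
        with pytest.raises(ValueError, match="continuous"):
            loglik_family_pointwise(theta, mixed_fit)
        with pytest.raises(ValueError, match="continuous"):
            loglik_subject_pointwise(theta, latent, mixed_fit)


class TestModelSpec:
    def test_disjointness_enforced(self):
        with pytest.raises(ValueError, match="disjoint"):
            ModelSpec(("y",), direct_covariates=("age",), indirect_covariates=("age",))

    def test_pleiotropy_needs_two_phenotypes(self):
        spec = ModelSpec(("y",), indirect_covariates=("snp",), snp_name="snp")
        with pytest.raises(ValueError, match="J >= 2"):
            spec.validate_for_pleiotropy()

    def test_pleiotropy_needs_indirect_snp(self):
        spec = ModelSpec(("y1", "y2"), direct_covariates=("snp",), snp_name=None)
        with pytest.raises(ValueError, match="snp_name"):
            spec.validate_for_pleiotropy()

    def test_roundtrip_dict(self):
        spec = ModelSpec(("sbp", "dbp"), (), ("sex",), ("age", "snp"), "snp")
        assert ModelSpec.from_dict(spec.to_dict()) == spec
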