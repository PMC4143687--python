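"""Full-conditional and chain tests for the Gibbs sampler (hand oracles)."""

import numpy as np
import pytest
from scipy import stats

from pleiolvm import (
    FitData,
    LatentState,
    MCMCConfig,
    ModelSpec,
    PriorSpec,
    ThetaState,
    run_chain,
)
from pleiolvm.mcmc import (
    GibbsState,
    augment_binary,
    draw_theta_from_prior,
    initial_state,
    scale_group_move,
    update_latent_U,
    update_loadings_px,
    update_random_effects,
    update_regression_blocks,
    update_variances,
)


def make_fit(n, J1=1, J2=0, p1=0, p2=0, families=1, y_cont=None, y_bin=None,
             W=None, X=None, ind_idx=None, fam_idx=None):
    """Hand-built FitData: by default every record is its own individual."""
    spec = ModelSpec(
        tuple(f"y{j}" for j in range(J1)),
        tuple(f"z{j}" for j in range(J2)),
        tuple(f"w{k}" for k in range(p1)),
        tuple(f"x{k}" for k in range(p2)),
    )
    ind_idx = np.arange(n) if ind_idx is None else np.asarray(ind_idx)
    M = int(ind_idx.max()) + 1
    if fam_idx is None:
        fam_idx = ind_idx * families // M
    fam_idx = np.asarray(fam_idx)
    ind_fam = np.zeros(M, dtype=int)
    ind_fam[ind_idx] = fam_idx
    y_cont = np.zeros((n, J1)) if y_cont is None else np.asarray(y_cont, float)
    y_bin = np.zeros((n, J2)) if y_bin is None else np.asarray(y_bin, float)
    return FitData(
        spec=spec, y_cont=y_cont, cont_mask=~np.isnan(y_cont),
        y_bin=y_bin, bin_mask=~np.isnan(y_bin),
        W=np.zeros((n, p1)) if W is None else np.asarray(W, float),
        X=np.zeros((n, p2)) if X is None else np.asarray(X, float),
        fam_idx=fam_idx, ind_idx=ind_idx, ind_fam=ind_fam,
    )


def zero_state(fit, **theta_kw):
    spec = fit.spec
    kw = dict(
        beta0=np.zeros(spec.J), beta=np.zeros((spec.J, spec.p1)),
        alpha=np.zeros(spec.p2), lam=np.ones(spec.J), tau2=np.ones(spec.J),
        sigma2=np.ones(spec.J1), sigma_a2=1.0, sigma_d2=1.0,
    )
    kw.update(theta_kw)
    theta = ThetaState(**kw)
    latent = LatentState(
        U=np.zeros(fit.n), a=np.zeros(fit.C), d=np.zeros(fit.M),
        b=np.zeros((fit.M, spec.J)), eta_bin=np.zeros((fit.n, spec.J2)),
    )
    return GibbsState(theta, latent, np.ones(spec.J))


class TestAugmentBinary:
    def test_half_normal_mean_at_zero_predictor(self):
        n = 100_000
        fit = make_fit(n, J1=0, J2=1, y_bin=np.ones((n, 1)))
        state = zero_state(fit, lam=np.zeros(1))
        augment_binary(state, fit, np.random.default_rng(0))
        assert state.latent.eta_bin.mean() == pytest.approx(np.sqrt(2 / np.pi), abs=0.01)

    def test_strong_predictor_untruncated(self):
        n = 20_000
        fit = make_fit(n, J1=0, J2=1, y_bin=np.ones((n, 1)))
        state = zero_state(fit, lam=np.zeros(1), beta0=np.array([10.0]))
        augment_binary(state, fit, np.random.default_rng(1))
        assert state.latent.eta_bin.mean() == pytest.approx(10.0, abs=0.02)
        assert state.latent.eta_bin.std() == pytest.approx(1.0, abs=0.03)

    def test_truncation_side_y0(self):
        n = 5_000
        fit = make_fit(n, J1=0, J2=1, y_bin=np.zeros((n, 1)))
        state = zero_state(fit, lam=np.zeros(1), beta0=np.array([0.7]))
        augment_binary(state, fit, np.random.default_rng(2))
        assert np.all(state.latent.eta_bin <= 0)

    def test_missing_cells_untouched(self):
        y = np.ones((4, 1))
        y[2, 0] = np.nan
        fit = make_fit(4, J1=0, J2=1, y_bin=y)
        state = zero_state(fit, lam=np.zeros(1))
        state.latent.eta_bin[:] = -9.0
        augment_binary(state, fit, np.random.default_rng(3))
        assert state.latent.eta_bin[2, 0] == -9.0
        assert np.all(state.latent.eta_bin[[0, 1, 3], 0] > 0)


class TestUpdateLatentU:
    def test_zero_loading_reduces_to_structural(self):
        n = 50_000
        fit = make_fit(n)
        state = zero_state(fit, lam=np.zeros(1))
        state.latent.a[:] = 0.0
        update_latent_U(state, fit, np.random.default_rng(4))
        assert state.latent.U.mean() == pytest.approx(0.0, abs=0.02)
        assert state.latent.U.var() == pytest.approx(1.0, rel=0.02)

    def test_hand_precision_weighting(self):
        # one continuous phenotype, lam=1, sigma2=1, zero structural mean,
        # y-residual = 2  =>  U | rest ~ Normal(1, 1/2)
        n = 50_000
        fit = make_fit(n, y_cont=np.full((n, 1), 2.0))
        state = zero_state(fit)
        update_latent_U(state, fit, np.random.default_rng(5))
        assert state.latent.U.mean() == pytest.approx(1.0, abs=0.02)
        assert state.latent.U.var() == pytest.approx(0.5, rel=0.03)


class TestUpdateRandomEffects:
    def test_prior_dominates_small_sigma_a2(self):
        fit = make_fit(20, families=4)
        state = zero_state(fit, sigma_a2=1e-8)
        state.latent.U[:] = 3.0  # data pull that the prior must override
        update_random_effects(state, fit, np.random.default_rng(6),
                              hierarchical_centering=False)
        assert np.all(np.abs(state.latent.a) < 1e-3)

    def test_single_visit_d_conditional_variance_half(self):
        n = 50_000  # one visit per individual
        fit = make_fit(n)
        state = zero_state(fit)
        state.latent.U[:] = 0.0
        update_random_effects(state, fit, np.random.default_rng(7),
                              hierarchical_centering=False)
        assert state.latent.d.var() == pytest.approx(0.5, rel=0.03)

    def test_b_shrinks_with_small_tau2(self):
        fit = make_fit(10)
        state = zero_state(fit, tau2=np.array([1e-8]))
        state.latent.U[:] = 0.0
        fit.y_cont[:] = 5.0
        fit.y_cont_filled[:] = 5.0
        update_random_effects(state, fit, np.random.default_rng(8),
                              hierarchical_centering=False)
        assert np.all(np.abs(state.latent.b) < 1e-3)


class TestUpdateLoadings:
    def test_strong_signal_regression_through_origin(self):
        rng = np.random.default_rng(9)
        n = 5_000
        U = rng.standard_normal(n)
        y = 5.0 * U + rng.normal(0, 0.1, n)
        fit = make_fit(n, y_cont=y[:, None])
        state = zero_state(fit, sigma2=np.array([0.01]))
        state.latent.U = U
        draws = []
        for _ in range(400):
            update_loadings_px(state, fit, PriorSpec(), rng)
            draws.append(state.theta.lam[0])
        assert np.mean(draws[100:]) == pytest.approx(5.0, rel=0.02)

    @pytest.mark.parametrize("parameter_expansion,n_draws,ks_bound",
                             [(True, 100_000, 0.01), (False, 15_000, 0.03)])
    def test_prior_sampling_reproduces_folded_t(self, parameter_expansion,
                                                n_draws, ks_bound):
        # no data: repeated loading updates must traverse the folded-t_3 prior
        # (the non-expanded update is slower per call, hence fewer draws)
        y = np.full((1, 1), np.nan)
        fit = make_fit(1, y_cont=y)
        state = zero_state(fit)
        rng = np.random.default_rng(10)
        draws = np.empty(n_draws)
        for i in range(draws.size):
            update_loadings_px(state, fit, PriorSpec(), rng,
                               parameter_expansion=parameter_expansion)
            draws[i] = state.theta.lam[0]
        # lam_1 is sign-folded, so compare against the folded-t CDF
        ks = stats.kstest(draws, lambda x: 2 * stats.t.cdf(x, 3) - 1).statistic
        assert ks < ks_bound

    def test_sign_fold_keeps_lam1_positive(self):
        rng = np.random.default_rng(11)
        fit = make_fit(50, y_cont=rng.normal(size=(50, 1)))
        state = zero_state(fit)
        state.latent.U = rng.standard_normal(50)
        for _ in range(200):
            update_loadings_px(state, fit, PriorSpec(), rng)
            assert state.theta.lam[0] > 0


class TestUpdateRegression:
    def test_no_data_limit_draws_from_prior(self):
        y = np.full((1, 1), np.nan)
        fit = make_fit(1, y_cont=y)
        priors = PriorSpec(beta0_scale=2.5)
        rng = np.random.default_rng(12)
        draws = np.empty(20_000)
        state = zero_state(fit)
        for i in range(draws.size):
            update_regression_blocks(state, fit, priors, rng)
            draws[i] = state.theta.beta0[0]
        assert draws.mean() == pytest.approx(0.0, abs=0.06)
        assert draws.std() == pytest.approx(2.5, rel=0.02)

    def test_hand_linear_algebra_exact(self):
        # 3 records, p1 = 1: reproduce the draw arithmetic independently
        W = np.array([[1.0], [2.0], [-1.0]])
        y = np.array([[0.5], [1.5], [-0.3]])
        fit = make_fit(3, p1=1, W=W, y_cont=y)
        priors = PriorSpec(beta0_scale=10.0)
        state = zero_state(fit, lam=np.zeros(1))
        seed = 13
        update_regression_blocks(state, fit, priors, np.random.default_rng(seed))

        D = np.hstack([np.ones((3, 1)), W])
        P = np.diag([1 / 10.0**2, 1.0]) + D.T @ D
        rhs = D.T @ y[:, 0]
        L = np.linalg.cholesky(P)
        mean = np.linalg.solve(P, rhs)
        z = np.random.default_rng(seed).standard_normal(2)
        draw = mean + np.linalg.solve(L.T, z)
        assert state.theta.beta0[0] == pytest.approx(draw[0], abs=1e-12)
        assert state.theta.beta[0, 0] == pytest.approx(draw[1], abs=1e-12)

    def test_alpha_recovery_large_n(self):
        rng = np.random.default_rng(14)
        n = 10_000
        X = rng.normal(50, 10, size=(n, 1))
        U = 0.043 * X[:, 0] + rng.standard_normal(n)
        fit = make_fit(n, p2=1, X=X, y_cont=np.zeros((n, 1)))
        state = zero_state(fit, lam=np.zeros(1))
        state.latent.U = U
        draws = []
        for _ in range(200):
            update_regression_blocks(state, fit, PriorSpec(), rng)
            draws.append(state.theta.alpha[0])
        assert np.mean(draws) == pytest.approx(0.043, rel=0.10)


class TestUpdateVariances:
    def test_zero_residual_concentration(self):
        fit = make_fit(100)  # 100 individuals
        rng = np.random.default_rng(15)
        draws = []
        state = zero_state(fit, lam=np.zeros(1))
        state.latent.b[:] = 0.0
        for _ in range(500):
            update_variances(state, fit, PriorSpec(), rng)
            draws.append(state.theta.tau2[0])
            state.latent.b[:] = 0.0
        assert np.median(draws) < 1e-3

    def test_ig_concentration_rate(self):
        # at fixed mean square, quadrupling the effect count roughly halves
        # the conditional coefficient of variation
        rng = np.random.default_rng(16)
        cvs = []
        for M in (100, 400):
            fit = make_fit(M)
            state = zero_state(fit, lam=np.zeros(1))
            draws = []
            for _ in range(4_000):
                state.latent.b[:, 0] = 1.0  # mean square fixed at 1
                update_variances(state, fit, PriorSpec(), rng)
                draws.append(state.theta.tau2[0])
            cvs.append(np.std(draws) / np.mean(draws))
        assert cvs[0] / cvs[1] == pytest.approx(2.0, rel=0.15)


class TestScaleGroupMove:
    def test_posterior_functions_of_invariants_unchanged(self):
        # the move rescales (U, a, d, alpha, lam, variances) jointly; the
        # measurement-space quantities lam*U and lam*a must be invariant
        rng = np.random.default_rng(17)
        fit = make_fit(30, p2=1, X=rng.normal(size=(30, 1)),
                       y_cont=rng.normal(size=(30, 1)))
        state = zero_state(fit)
        state.latent.U = rng.standard_normal(30)
        state.latent.a = rng.standard_normal(fit.C)
        before = state.theta.lam[0] * state.latent.U.copy()
        scale_group_move(state, fit, PriorSpec(), rng)
        after = state.theta.lam[0] * state.latent.U
        np.testing.assert_allclose(after, before, rtol=1e-12)


class TestRunChain:
    def test_zero_iteration_guard(self, tiny_dataset, tiny_config):
        cfg = MCMCConfig(n_iter=50, burn_in=49, thin=1, seed=0,
                         store_deviance=False, compute_diagnostics=False)
        samples = run_chain(tiny_dataset, tiny_config.model_spec(), PriorSpec(), cfg)
        assert samples.n_draws == 1

    def test_seed_determinism(self, tiny_dataset, tiny_config):
        cfg = MCMCConfig(n_iter=120, burn_in=40, thin=2, seed=5,
                         store_deviance=False, compute_diagnostics=False)
        s1 = run_chain(tiny_dataset, tiny_config.model_spec(), PriorSpec(), cfg)
        s2 = run_chain(tiny_dataset, tiny_config.model_spec(), PriorSpec(), cfg)
        for name in s1.draws:
            np.testing.assert_array_equal(s1.draws[name], s2.draws[name])

    def test_lam1_positive_every_draw(self, small_samples):
        assert np.all(small_samples.get("lam[sbp]") > 0)

    def test_draw_count_and_diagnostics(self, small_samples):
        assert small_samples.n_draws == (900 - 300) // 2
        diag = small_samples.diagnostics
        assert diag is not None and {"ess", "rhat"} <= set(diag.columns)

    def test_theta_mean_roundtrip(self, small_samples, tiny_config):
        theta = small_samples.theta_mean()
        theta.validate(tiny_config.model_spec())

    def test_save_roundtrip(self, small_samples, tmp_path):
        path = tmp_path / "draws.npz"
        small_samples.save(path)
        archive = np.load(path)
        np.testing.assert_array_equal(
            archive["draw_lam[sbp]"], small_samples.get("lam[sbp]"))

    def test_config_validation(self):
        with pytest.raises(ValueError, match="burn_in"):
            MCMCConfig(n_iter=10, burn_in=10)
        with pytest.raises(ValueError, match="thin"):
            MCMCConfig(n_iter=10, burn_in=1, thin=0)
        with pytest.raises(ValueError, match="init"):
            MCMCConfig(n_iter=10, burn_in=1, init="bogus")

    def test_baseline_sampler_without_acceleration(self, tiny_dataset, tiny_config):
        cfg = MCMCConfig(n_iter=150, burn_in=50, thin=1, seed=2,
                         hierarchical_centering=False, parameter_expansion=False,
                         store_deviance=False, compute_diagnostics=False)
        samples = run_chain(tiny_dataset, tiny_config.model_spec(), PriorSpec(), cfg)
        assert samples.n_draws == 100
        assert np.all(samples.get("lam[sbp]") > 0)

    def test_initial_state_heuristic_uses_phenotype_means(self, tiny_fit):
        state = initial_state(tiny_fit, PriorSpec(),
                              MCMCConfig(n_iter=10, burn_in=1),
                              np.random.default_rng(0))
        means = np.nanmean(tiny_fit.y_cont, axis=0)
        np.testing.assert_allclose(state.theta.beta0[:2], means, rtol=1e-8)

    def test_prior_draw_shapes(self, tiny_config):
        spec = tiny_config.model_spec()
        theta, phi = draw_theta_from_prior(spec, PriorSpec(), np.random.default_rng(1))
        theta.validate(spec)
        assert phi.shape == (spec.J,)
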