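import numpy as np
import pytest

from bammi import (
    GibbsConfig,
    PriorSpec,
    build_designs,
    log_likelihood,
    planted_rank_trial,
    run_gibbs,
    simulate_trial,
    svd_truth,
)
from bammi.data import theta_vector
from bammi.gibbs import (
    initial_state,
    sample_bilinear_axis,
    sample_block_conditional,
    sample_genotype_conditional,
    sample_linear_effects,
    sample_mu,
    sample_variances,
)


@pytest.fixture(scope="module")
def toy():
    data, _ = simulate_trial(2, g=3, e=2, r=2, var_unstable=0, var_stable=0,
                             n_unstable_pos=0, n_unstable_neg=0)
    return data, build_designs(data)


class TestLogLikelihood:
    def test_zero_residual_value(self, rng):
        data, _ = simulate_trial(1, g=2, e=2, r=1, var_unstable=0, var_stable=0,
                                 n_unstable_pos=0, n_unstable_neg=0)
        designs = build_designs(data)
        state = initial_state(data, designs, 0, PriorSpec("bammi"))
        state.sigma2_e = 1.0
        data.y[:] = theta_vector(state, designs)  # n = 4 records, zero residual
        assert log_likelihood(state, data, designs) == pytest.approx(-2.0 * np.log(2 * np.pi))

    def test_matches_scalar_density_sum(self, toy):
        data, designs = toy
        state = initial_state(data, designs, 1, PriorSpec("bammi"))
        from scipy.stats import norm

        theta = theta_vector(state, designs)
        oracle = norm.logpdf(data.y, loc=theta, scale=np.sqrt(state.sigma2_e)).sum()
        assert log_likelihood(state, data, designs) == pytest.approx(oracle, abs=1e-10)

    def test_variance_doubling_identity(self, toy):
        data, designs = toy
        state = initial_state(data, designs, 0, PriorSpec("bammi"))
        rss = np.sum((data.y - theta_vector(state, designs)) ** 2)
        ll1 = log_likelihood(state, data, designs)
        state2 = state.copy()
        state2.sigma2_e = 2.0 * state.sigma2_e
        # delta = -n/2 log2 + RSS/2 (1/s - 1/(2s)) = -n/2 log2 + RSS/(4s)
        expected_delta = -0.5 * data.n * np.log(2.0) + rss / (4.0 * state.sigma2_e)
        assert log_likelihood(state2, data, designs) - ll1 == pytest.approx(expected_delta, abs=1e-10)

    def test_nonpositive_variance_rejected(self, toy):
        data, designs = toy
        state = initial_state(data, designs, 0, PriorSpec("bammi"))
        state.sigma2_e = 0.0
        with pytest.raises(ValueError):
            log_likelihood(state, data, designs)


class TestLinearConditionals:
    def test_block_conditional_mean_is_cell_mean(self, toy, rng):
        data, designs = toy
        state = initial_state(data, designs, 0, PriorSpec("bammi"))
        state.gvec[:] = 0.0
        draws = np.array([sample_block_conditional(state, data, designs, rng).beta for _ in range(3000)])
        cell_means = np.bincount(designs.cell_idx, weights=data.y) / designs.count_cell
        se = np.sqrt(state.sigma2_e / designs.count_cell / 3000)
        assert np.allclose(draws.mean(axis=0), cell_means, atol=4 * se.max())

    def test_genotype_conditional_matches_ridge_closed_form(self, toy, rng):
        data, designs = toy
        state = initial_state(data, designs, 0, PriorSpec("bammi"))
        state.sigma2_e, state.sigma2_g = 1.5, 3.0
        a2 = data.y - state.beta[designs.cell_idx]
        prec = designs.count_geno + state.sigma2_e / state.sigma2_g
        mean_oracle = np.bincount(designs.geno_idx, weights=a2, minlength=designs.g) / prec
        draws = np.array([sample_genotype_conditional(state, data, designs, rng).gvec for _ in range(4000)])
        se = np.sqrt(state.sigma2_e / prec / 4000)
        assert np.allclose(draws.mean(axis=0), mean_oracle, atol=4 * se.max())
        assert np.allclose(draws.var(axis=0), state.sigma2_e / prec, rtol=0.15)

    def test_flat_prior_limit_matches_gls(self, toy, rng):
        data, designs = toy
        state = initial_state(data, designs, 0, PriorSpec("bammi"))
        state.sigma2_g = 1e10
        a2 = data.y - state.beta[designs.cell_idx]
        gls = np.bincount(designs.geno_idx, weights=a2, minlength=designs.g) / designs.count_geno
        draws = np.array([sample_genotype_conditional(state, data, designs, rng).gvec for _ in range(3000)])
        assert np.allclose(draws.mean(axis=0), gls, atol=0.1)

    def test_joint_draw_matches_closed_form_gaussian(self, toy, rng):
        data, designs = toy
        state = initial_state(data, designs, 0, PriorSpec("bammi"))
        state.sigma2_e, state.sigma2_g = 1.0, 4.0
        S = np.array([
            np.concatenate([(s := sample_linear_effects(state, data, designs, rng)).beta, s.gvec])
            for _ in range(4000)
        ])
        X = np.hstack([designs.X1, designs.Z])
        A = X.T @ X + np.diag([0.0] * designs.n_cells + [state.sigma2_e / state.sigma2_g] * designs.g)
        mean = np.linalg.solve(A, X.T @ data.y)
        cov = np.linalg.inv(A) * state.sigma2_e
        assert np.allclose(S.mean(axis=0), mean, atol=4 * np.sqrt(np.diag(cov) / 4000))
        assert np.allclose(np.cov(S.T), cov, atol=0.15)


class TestBilinearAxis:
    def test_balanced_precision_identity(self, default_trial, default_designs, rng):
        data, _ = default_trial
        state = initial_state(data, default_designs, 2, PriorSpec("bammi"))
        phi = state.alphas[default_designs.geno_idx, 0] * state.gammas[default_designs.env_idx, 0]
        assert phi @ phi == pytest.approx(3.0, abs=1e-8)  # r replicates, unit vectors

    def test_order_constraint_never_violated(self, default_trial, default_designs, rng):
        data, _ = default_trial
        state = initial_state(data, default_designs, 2, PriorSpec("bammi"))
        for _ in range(200):
            state = sample_bilinear_axis(state, data, default_designs, PriorSpec("bammi"), 1, rng)
            state = sample_bilinear_axis(state, data, default_designs, PriorSpec("bammi"), 2, rng)
            assert state.lambdas[1] <= state.lambdas[0]

    def test_axis_constraints_after_update(self, default_trial, default_designs, rng):
        data, _ = default_trial
        state = initial_state(data, default_designs, 3, PriorSpec("bammie"))
        state = sample_bilinear_axis(state, data, default_designs, PriorSpec("bammie"), 2, rng)
        state.check(atol=1e-6)

    def test_planted_direction_recovery(self, rng):
        data, eff = planted_rank_trial(9, lambdas=(25.0,), sigma2_e=0.5)
        designs = build_designs(data)
        u_true = np.linalg.svd(eff.ge_true.values)[0][:, 0]
        state = initial_state(data, designs, 1, PriorSpec("bammi"))
        state.sigma2_e = eff.sigma2_e_true  # fix the noise level at truth
        for _ in range(50):
            state = sample_bilinear_axis(state, data, designs, PriorSpec("bammi"), 1, rng)
        assert abs(state.alphas[:, 0] @ u_true) > 0.99

    def test_axis_index_validation(self, default_trial, default_designs, rng):
        data, _ = default_trial
        state = initial_state(data, default_designs, 2, PriorSpec("bammi"))
        with pytest.raises(ValueError):
            sample_bilinear_axis(state, data, default_designs, PriorSpec("bammi"), 3, rng)


class TestVariancesAndMu:
    def test_sigma2_e_invgamma_mean(self, toy, rng):
        data, designs = toy
        state = initial_state(data, designs, 0, PriorSpec("bammi"))
        rss = np.sum((data.y - theta_vector(state, designs)) ** 2)
        draws = np.array([sample_variances(state, data, designs, rng).sigma2_e for _ in range(8000)])
        oracle = (rss / 2.0) / (data.n / 2.0 - 1.0)
        se = draws.std(ddof=1) / np.sqrt(len(draws))
        assert draws.mean() == pytest.approx(oracle, abs=4 * se)
        assert np.all(draws > 0)

    def test_sigma2_g_collapses_for_zero_effects(self, toy, rng):
        data, designs = toy
        state = initial_state(data, designs, 0, PriorSpec("bammi"))
        state.gvec[:] = 0.0
        draws = np.array([sample_variances(state, data, designs, rng).sigma2_g for _ in range(200)])
        assert np.median(draws) < 1e-6

    def test_mu_conjugate_mean(self, toy, rng):
        data, designs = toy
        state = initial_state(data, designs, 0, PriorSpec("bammi"))
        spec = PriorSpec("bammi")  # tau = upsilon = 1
        draws = np.array([sample_mu(state, spec, rng).mu for _ in range(8000)])
        se = draws.std(ddof=1) / np.sqrt(len(draws))
        assert draws.mean() == pytest.approx(0.5, abs=4 * se)
        assert np.all(draws > 0)

    def test_mu_mean_grows_with_t(self, default_trial, default_designs, rng):
        data, _ = default_trial
        spec = PriorSpec("bammi")
        means = []
        for t in (0, 3, 6):
            state = initial_state(data, default_designs, t, spec)
            means.append(np.mean([sample_mu(state, spec, rng).mu for _ in range(2000)]))
        assert means[0] < means[1] < means[2]


class TestRunGibbs:
    def test_additive_recovery_at_t0(self, additive_trial):
        data, eff = additive_trial
        designs = build_designs(data)
        cfg = GibbsConfig(iterations=1500, burn_in=300, seed=5, t_fixed=0)
        draws = run_gibbs(data, designs, PriorSpec("bammi"), cfg)
        post_g = draws.gvec.mean(axis=0)
        assert np.corrcoef(post_g, eff.g_true)[0, 1] > 0.95

    def test_planted_lambda_recovery_at_t2(self, planted2_trial):
        data, eff = planted2_trial
        designs = build_designs(data)
        truth = svd_truth(eff)
        cfg = GibbsConfig(iterations=1500, burn_in=400, seed=6, t_fixed=2)
        draws = run_gibbs(data, designs, PriorSpec("bammi"), cfg)
        lam = draws.lambda_matrix().mean(axis=0)
        assert lam[0] == pytest.approx(truth.true_lambdas[0], rel=0.15)
        assert lam[1] == pytest.approx(truth.true_lambdas[1], rel=0.15)

    def test_dimension_guard(self, default_trial, default_designs):
        data, _ = default_trial
        with pytest.raises(ValueError, match="t_max"):
            run_gibbs(data, default_designs, PriorSpec("bammi"),
                      GibbsConfig(iterations=10, burn_in=1, t_fixed=9))

    def test_stationarity_on_default_fit(self, default_gibbs_fit):
        from bammi import heidelberger_welch

        for trace in (default_gibbs_fit.loglik, default_gibbs_fit.sigma2_e):
            assert heidelberger_welch(trace).stationary
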