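import numpy as np
import pytest
from scipy import stats

from bammi import (
    GibbsConfig,
    PriorSpec,
    align_signs,
    biplot_regions,
    build_designs,
    classify_stability,
    hpd,
    orthonormalize_uv,
    run_rjmcmc,
    split_draws,
    visit_table,
)


class TestSplitDraws:
    def test_conditional_subset_of_marginal(self, default_gibbs_fit):
        cond, marg = split_draws(default_gibbs_fit, 2)
        assert cond.n_draws <= marg.n_draws
        assert np.all(cond.t == 2)
        assert np.all(marg.t == 2)  # fixed-t fit: both sets identical
        assert cond.n_draws == default_gibbs_fit.n_draws

    def test_missing_dimension_rejected(self, default_gibbs_fit):
        with pytest.raises(ValueError):
            split_draws(default_gibbs_fit, 5)

    def test_marginal_truncates_axes(self, default_trial, default_designs):
        data, _ = default_trial
        cfg = GibbsConfig(iterations=800, burn_in=300, seed=8, t_fixed=1, check_fraction=0.0)
        draws = run_rjmcmc(data, default_designs, PriorSpec("bammie"), cfg)
        _, modal = visit_table(draws)
        t_star = max(modal, 1)
        cond, marg = split_draws(draws, t_star)
        assert all(len(lam) == t_star for lam in marg.lambdas)

    def test_conditional_marginal_lambda_agreement(self, default_trial, default_designs):
        # point estimates from the two response definitions stay within one
        # posterior standard deviation of each other
        data, _ = default_trial
        cfg = GibbsConfig(iterations=1500, burn_in=500, seed=9, t_fixed=1, check_fraction=0.0)
        draws = run_rjmcmc(data, default_designs, PriorSpec("bammie"), cfg)
        _, modal = visit_table(draws)
        t_star = max(modal, 1)
        cond, marg = split_draws(draws, t_star)
        lam_c = np.array([lam[0] for lam in cond.lambdas])
        lam_m = np.array([lam[0] for lam in marg.lambdas])
        assert abs(lam_c.mean() - lam_m.mean()) < max(lam_c.std(), 1e-3)


class TestAlignSigns:
    def test_idempotence_and_flip_invariance(self, default_gibbs_fit):
        a1 = align_signs(default_gibbs_fit, 2)
        a2 = align_signs(a1, 2)
        for A, B in zip(a1.alphas, a2.alphas):
            assert np.allclose(A, B)
        flipped = default_gibbs_fit.select(np.ones(default_gibbs_fit.n_draws, dtype=bool))
        flipped.alphas = [-A for A in flipped.alphas]
        flipped.gammas = [-G for G in flipped.gammas]
        a3 = align_signs(flipped, 2, reference=a1.alphas[0])
        for A, B in zip(a1.alphas, a3.alphas):
            assert np.allclose(A, B)

    def test_alignment_increases_mean_norm(self, rng):
        # symmetric sign-mixed draws average to ~0 before alignment
        base = default = rng.standard_normal(6)
        base /= np.linalg.norm(base)
        from bammi.gibbs import PosteriorDraws

        m = 40
        signs = np.where(np.arange(m) % 2 == 0, 1.0, -1.0)
        draws = PosteriorDraws(
            beta=np.zeros((m, 1)), gvec=np.zeros((m, 6)),
            sigma2_g=np.ones(m), sigma2_e=np.ones(m), mu=np.ones(m),
            loglik=np.zeros(m), t=np.ones(m, dtype=int),
            lambdas=[np.array([1.0])] * m,
            alphas=[(s * base)[:, None] for s in signs],
            gammas=[(s * base)[:, None] for s in signs],
        )
        before = np.linalg.norm(np.mean([A for A in draws.alphas], axis=0))
        aligned = align_signs(draws, 1)
        after = np.linalg.norm(np.mean([A for A in aligned.alphas], axis=0))
        assert after > before + 0.5


class TestOrthonormalize:
    def test_orthonormal_input_unchanged(self, rng):
        Q = np.linalg.qr(rng.standard_normal((8, 2)))[0]
        Q *= np.sign(np.sum(Q, axis=0))  # fix an arbitrary sign for comparison
        U, V = orthonormalize_uv(Q, Q.copy())
        assert np.allclose(np.abs(U.T @ Q), np.eye(2), atol=1e-10)

    def test_output_exactly_orthonormal(self, rng):
        M = rng.standard_normal((10, 2))
        U, V = orthonormalize_uv(M, rng.standard_normal((5, 2)))
        assert np.allclose(U.T @ U, np.eye(2), atol=1e-12)
        assert np.allclose(V.T @ V, np.eye(2), atol=1e-12)

    def test_stability_under_perturbation(self, rng):
        Q = np.linalg.qr(rng.standard_normal((9, 2)))[0]
        eps = 1e-6
        U, _ = orthonormalize_uv(Q + eps * rng.standard_normal((9, 2)), Q)
        assert np.abs(np.abs(U.T @ Q) - np.eye(2)).max() < 100 * eps

    def test_rank_deficient_rejected(self):
        M = np.ones((5, 2))
        with pytest.raises(ValueError):
            orthonormalize_uv(M, M)


class TestHpd:
    def test_standard_normal_interval(self, rng):
        samples = rng.standard_normal(100000)
        iv = hpd(samples, 0.95)
        assert iv.lower == pytest.approx(-1.96, abs=0.06)
        assert iv.upper == pytest.approx(1.96, abs=0.06)

    def test_constant_samples_degenerate(self):
        iv = hpd(np.full(100, 3.3), 0.9)
        assert iv.lower == iv.upper == 3.3

    def test_exponential_narrower_than_equal_tail(self, rng):
        samples = rng.exponential(size=50000)
        iv = hpd(samples, 0.95)
        et = np.quantile(samples, [0.025, 0.975])
        assert (iv.upper - iv.lower) < (et[1] - et[0])

    def test_invalid_inputs(self, rng):
        with pytest.raises(ValueError):
            hpd(rng.standard_normal(10), 0.95)
        with pytest.raises(ValueError):
            hpd(rng.standard_normal(100), 1.5)


class TestBiplotRegions:
    def _synthetic_draws(self, centers_g, centers_e, spread, m, rng):
        from bammi.gibbs import PosteriorDraws

        g, e = centers_g.shape[0], centers_e.shape[0]
        alphas, gammas = [], []
        for _ in range(m):
            alphas.append(centers_g + spread * rng.standard_normal((g, 2)))
            gammas.append(centers_e + spread * rng.standard_normal((e, 2)))
        return PosteriorDraws(
            beta=np.zeros((m, 1)), gvec=np.zeros((m, g)),
            sigma2_g=np.ones(m), sigma2_e=np.ones(m), mu=np.ones(m),
            loglik=np.zeros(m), t=np.full(m, 2, dtype=int),
            lambdas=[np.array([2.0, 1.0])] * m,
            alphas=alphas, gammas=gammas,
        )

    def test_offset_scores_exclude_origin(self, rng):
        cg = np.tile([[0.3, 0.3]], (6, 1)) + 0.001 * rng.standard_normal((6, 2))
        ce = np.tile([[0.3, 0.3]], (4, 1))
        draws = self._synthetic_draws(cg, ce, 0.01, 200, rng)
        summary = biplot_regions(draws, 2)
        assert not summary.origin_inclusion.any()

    def test_centered_scores_include_origin(self, rng):
        cg = np.zeros((6, 2))
        ce = np.zeros((4, 2))
        draws = self._synthetic_draws(cg, ce, 0.05, 200, rng)
        summary = biplot_regions(draws, 2)
        assert summary.origin_inclusion.all()

    def test_ellipse_coverage_calibration(self, rng):
        # fresh points from the generating bivariate normal fall inside the
        # 90% region about 90% of the time
        center = np.array([[0.2, -0.1]])
        draws = self._synthetic_draws(center, center, 0.05, 500, rng)
        summary = biplot_regions(draws, 2, prob=0.90)
        row = summary.ellipses.iloc[0]
        cov = np.array([[row.v11, row.v12], [row.v12, row.v22]])
        mean = np.array([row.c1, row.c2])
        fresh = center[0] + 0.05 * rng.standard_normal((5000, 2))
        d2 = np.einsum("ij,jk,ik->i", fresh - mean, np.linalg.inv(cov), fresh - mean)
        cover = np.mean(d2 <= stats.chi2.ppf(0.90, 2))
        assert cover == pytest.approx(0.90, abs=0.03)

    def test_univariate_case_rejected(self, default_gibbs_fit):
        with pytest.raises(ValueError, match="t_star >= 2"):
            biplot_regions(default_gibbs_fit, 1)


class TestStability:
    def test_sign_flip_invariance(self, rng):
        cg = rng.standard_normal((5, 2)) * 0.3
        ce = rng.standard_normal((3, 2)) * 0.3
        maker = TestBiplotRegions()
        d1 = maker._synthetic_draws(cg, ce, 0.02, 150, np.random.default_rng(1))
        d2 = maker._synthetic_draws(-cg, -ce, 0.02, 150, np.random.default_rng(1))
        s1 = classify_stability(biplot_regions(d1, 2))
        s2 = classify_stability(biplot_regions(d2, 2))
        assert (s1["stable"] == s2["stable"]).all()

    def test_default_simulation_recovers_subgroups(self, default_trial, default_designs):
        # genotypes 1-10 carry the planted crossover interaction; 11-20 are
        # stable; classification from a t=2 fit must broadly agree
        data, eff = default_trial
        cfg = GibbsConfig(iterations=1200, burn_in=400, seed=31, t_fixed=2, check_fraction=0.0)
        from bammi import run_gibbs

        draws = run_gibbs(data, default_designs, PriorSpec("bammi"), cfg)
        summary = biplot_regions(draws, 2, genotype_labels=data.genotypes,
                                 environment_labels=data.environments)
        labels = classify_stability(summary)
        geno = labels[labels["kind"] == "genotype"]
        predicted_stable = geno["stable"].to_numpy()
        agreement = np.mean(predicted_stable == eff.stable)
        assert agreement >= 0.8
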