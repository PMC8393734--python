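import dataclasses

import numpy as np
import pytest
from scipy.special import expit

from splicevb import (
    FeatureMatrices,
    FitConfig,
    ModelParams,
    SimConfig,
    ValidationError,
    VariationalPosterior,
    elbo_estimate,
    fit,
    intercept_features,
    kl_gaussian,
    prior_params,
    psi_summarise,
    simulate_dataset,
)

import oracles

UNIT_L = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])


class TestKLGaussian:
    def test_identical_is_zero(self):
        assert kl_gaussian(1.3, 0.7, 1.3, 0.7) == pytest.approx(0.0, abs=1e-15)

    def test_mean_shift_closed_form(self):
        assert kl_gaussian(1.0, 1.0, 0.0, 1.0) == pytest.approx(0.5)

    def test_scale_mismatch_closed_form(self):
        assert kl_gaussian(0.0, 1.0, 0.0, 2.0) == pytest.approx(np.log(2) - 3 / 8)

    def test_matches_numerical_quadrature(self, rng):
        for _ in range(10):
            mu_q, mu_p = rng.normal(size=2)
            dq, sp = rng.uniform(0.3, 2.5, size=2)
            closed = kl_gaussian(mu_q, dq, mu_p, sp)
            quad = oracles.kl_by_quadrature(mu_q, dq, mu_p, sp)
            assert closed == pytest.approx(quad, abs=1e-6)

    def test_matrix_sum(self):
        mu_q = np.array([[1.0, 0.0]])
        total = kl_gaussian(mu_q, np.ones((1, 2)), np.zeros((1, 2)), np.ones((1, 2)))
        assert total == pytest.approx(0.5)

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValidationError):
            kl_gaussian(0.0, 0.0, 0.0, 1.0)

    def test_nonnegative_random(self, rng):
        for _ in range(50):
            val = kl_gaussian(rng.normal(), rng.uniform(0.1, 3),
                              rng.normal(), rng.uniform(0.1, 3))
            assert val >= -1e-12


class TestPriorParams:
    def test_intercept_only(self):
        params = ModelParams(A=np.zeros((3, 0)), B=np.array([[2.0]]), sigma=[1.0])
        mean, sigma = prior_params(None, np.ones((3, 1)), params)
        np.testing.assert_allclose(mean, 2.0)
        np.testing.assert_allclose(sigma, [1.0])

    def test_zero_gene_features(self, rng):
        X = np.zeros((4, 2))
        A = rng.normal(size=(3, 2))
        params = ModelParams(A=A, B=np.zeros((4, 0)), sigma=np.ones(4))
        mean, _ = prior_params(X, None, params)
        np.testing.assert_allclose(mean, 0.0)

    def test_shape_mismatch(self):
        params = ModelParams(A=np.zeros((3, 0)), B=np.array([[2.0]]), sigma=[1.0])
        with pytest.raises(ValidationError):
            prior_params(None, np.ones((5, 1)), params)


class TestElboEstimate:
    def test_zero_counts_posterior_equals_prior_is_exactly_zero(self, data_factory, rng):
        data = data_factory(np.zeros((3, 2, 3), dtype=int))
        params = ModelParams(A=np.zeros((3, 0)), B=np.zeros((2, 1)), sigma=[3.0, 3.0])
        post = VariationalPosterior(mu=np.zeros((3, 2)), delta=np.full((3, 2), 3.0))
        val = elbo_estimate(data, None, np.ones((3, 1)), params, post, R=5, rng=rng)
        assert val == 0.0

    def test_mean_matches_quadrature(self, data_factory):
        # single cell/event, s = [5, 5, 0]: MC average over 1e5 draws agrees
        # with -KL + Gauss-Hermite E_q[log-lik] within 3 MC standard errors
        s = np.array([[[5, 5, 0]]])
        data = data_factory(s)
        mu_q, delta_q, m_p, sig_p = 0.4, 0.8, 0.0, 1.5
        params = ModelParams(A=np.zeros((1, 0)), B=np.array([[m_p]]), sigma=[sig_p])
        post = VariationalPosterior(mu=np.array([[mu_q]]), delta=np.array([[delta_q]]))
        exact = -kl_gaussian(mu_q, delta_q, m_p, sig_p) + oracles.gh_expected_loglik(
            mu_q, delta_q, s[0, 0], UNIT_L
        )
        rng = np.random.default_rng(0)
        R = 100_000
        draws = mu_q + delta_q * rng.standard_normal(R)
        from splicevb.likelihood import loglik_from_z

        ll = loglik_from_z(draws[:, None, None], data.counts, data.lengths).ravel()
        mc = ll.mean() - kl_gaussian(mu_q, delta_q, m_p, sig_p)
        se = ll.std(ddof=1) / np.sqrt(R)
        assert abs(mc - exact) < 3 * se

    def test_elbo_below_evidence(self, data_factory, rng):
        # ELBO <= log p(S) (same constant convention) up to MC error
        L = np.array([[2.0, 0.0, 1.0], [0.0, 2.0, 1.0]])
        for i in range(10):
            s = rng.integers(0, 12, size=(1, 1, 3))
            data = data_factory(s, lengths=L[None])
            m_p, sig_p = rng.normal(0, 1), rng.uniform(0.5, 2.0)
            params = ModelParams(A=np.zeros((1, 0)), B=np.array([[m_p]]), sigma=[sig_p])
            post = VariationalPosterior(
                mu=np.array([[rng.normal(0, 1)]]), delta=np.array([[rng.uniform(0.3, 1.5)]])
            )
            vals = [
                elbo_estimate(data, None, np.ones((1, 1)), params, post, R=50,
                              rng=np.random.default_rng([i, k]))
                for k in range(40)
            ]
            mc = np.mean(vals)
            se = np.std(vals, ddof=1) / np.sqrt(len(vals))
            evidence = oracles.log_evidence(s[0, 0], L, m_p, sig_p)
            assert mc <= evidence + 3 * se + 1e-9

    def test_r_validation(self, data_factory, rng):
        data = data_factory(np.zeros((1, 1, 3), dtype=int))
        params = ModelParams(A=np.zeros((1, 0)), B=np.zeros((1, 1)), sigma=[1.0])
        post = VariationalPosterior(mu=np.zeros((1, 1)), delta=np.ones((1, 1)))
        with pytest.raises(ValidationError):
            elbo_estimate(data, None, np.ones((1, 1)), params, post, R=0, rng=rng)


class TestFit:
    def test_mode0_all_zero_counts_exact(self, data_factory):
        data = data_factory(np.zeros((4, 3, 3), dtype=int))
        res = fit(data, config=FitConfig(mode="mode0", seed=7))
        assert res.final_elbo == 0.0
        np.testing.assert_array_equal(psi_summarise(res).psi_median, 0.5)
        np.testing.assert_allclose(res.posterior.delta, 3.0, rtol=1e-9)

    def test_single_cell_strong_signal(self, data_factory):
        data = data_factory(np.array([[[90, 10, 0]]]))
        res = fit(data, config=FitConfig(mode="mode2_quant", seed=1))
        psi = psi_summarise(res).psi_median[0, 0]
        assert abs(psi - 0.90) < 0.03

    def test_matches_quadrature_posterior_median(self, se_lengths):
        # joint mode2_quant fit over independent events vs per-(cell,event)
        # grid quadrature under the fitted prior
        cfg = SimConfig(n_cells=8, n_events=6, n_das=0, eta=0.0, seed=3,
                        total_mean=40, total_dispersion=0.05)
        data, _ = simulate_dataset(cfg)
        res = fit(data, config=FitConfig(mode="mode2_quant", seed=2))
        m_prior = res.params.B[:, 0]
        for g in range(data.n_events):
            for c in range(data.n_cells):
                oracle = oracles.posterior_median_psi(
                    data.counts[c, g], data.lengths[g], m_prior[g], res.params.sigma[g]
                )
                ours = expit(res.posterior.mu[c, g])
                assert abs(ours - oracle) < 0.05

    def test_seed_determinism(self, data_factory, rng):
        counts = rng.integers(0, 25, size=(6, 5, 3))
        L = np.broadcast_to(np.array([[2.0, 0, 1], [0, 2.0, 1]]), (5, 2, 3)).copy()
        data = data_factory(counts, lengths=L)
        r1 = fit(data, config=FitConfig(mode="mode2_quant", seed=42))
        r2 = fit(data, config=FitConfig(mode="mode2_quant", seed=42))
        np.testing.assert_array_equal(r1.posterior.mu, r2.posterior.mu)
        np.testing.assert_array_equal(r1.posterior.delta, r2.posterior.delta)
        assert r1.final_elbo == r2.final_elbo
        r3 = fit(data, config=FitConfig(mode="mode2_quant", seed=43))
        assert not np.array_equal(r1.posterior.mu, r3.posterior.mu)

    def test_monotone_in_group1_count(self, data_factory):
        s1 = np.array([0, 10, 20, 30, 40])
        counts = np.zeros((1, 5, 3), dtype=int)
        counts[0, :, 0] = s1
        counts[0, :, 1] = 40 - s1
        data = data_factory(counts)
        res = fit(data, config=FitConfig(mode="mode0", seed=0))
        psi = psi_summarise(res).psi_median[0]
        assert np.all(np.diff(psi) > 0)

    def test_more_data_narrower_posterior(self, data_factory):
        base = np.array([[[12, 6, 2]]])
        d1 = data_factory(np.broadcast_to(base, (1, 1, 3)).copy(),
                          lengths=np.array([[[2.0, 0, 1], [0, 2.0, 1]]]))
        d10 = data_factory(10 * np.broadcast_to(base, (1, 1, 3)).copy(),
                           lengths=np.array([[[2.0, 0, 1], [0, 2.0, 1]]]))
        r1 = fit(d1, config=FitConfig(mode="mode2_quant", seed=5))
        r10 = fit(d10, config=FitConfig(mode="mode2_quant", seed=5))
        assert r10.posterior.delta[0, 0] < r1.posterior.delta[0, 0]

    def test_quant_equals_diff_with_intercept_only(self, data_factory, rng):
        counts = rng.integers(0, 20, size=(8, 4, 3))
        L = np.broadcast_to(np.array([[2.0, 0, 1], [0, 2.0, 1]]), (4, 2, 3)).copy()
        data = data_factory(counts, lengths=L)
        feats = intercept_features(data.cell_ids, data.n_events)
        rq = fit(data, config=FitConfig(mode="mode2_quant", seed=9))
        rd = fit(data, feats, config=FitConfig(mode="mode2_diff", seed=9))
        assert abs(rq.final_elbo - rd.final_elbo) <= 3 * np.hypot(
            rq.final_elbo_se, rd.final_elbo_se
        ) + 1e-9

    def test_smoothed_trace_nondecreasing(self, se_lengths):
        cfg = SimConfig(n_cells=20, n_events=15, n_das=0, eta=0.0, seed=8)
        data, _ = simulate_dataset(cfg)
        res = fit(data, config=FitConfig(mode="mode2_quant", seed=4, rel_tol=0.0,
                                         max_iter=1500))
        trace = res.elbo_trace
        w = 100
        smooth = np.convolve(trace, np.ones(w) / w, mode="valid")
        start = int(0.2 * smooth.size)
        mc_se = trace[-3 * w:].std(ddof=1) / np.sqrt(w)
        drops = np.diff(smooth[start:])
        assert drops.min() > -2 * mc_se

    def test_mode_feature_validation(self, data_factory, rng):
        data = data_factory(rng.integers(0, 5, size=(3, 2, 3)))
        with pytest.raises(ValidationError, match="mode1"):
            fit(data, config=FitConfig(mode="mode1"))
        with pytest.raises(ValidationError, match="mode2_diff"):
            fit(data, config=FitConfig(mode="mode2_diff"))

    def test_mode1_gene_features_run(self, data_factory, rng):
        counts = rng.integers(0, 15, size=(5, 4, 3))
        L = np.broadcast_to(np.array([[2.0, 0, 1], [0, 2.0, 1]]), (4, 2, 3)).copy()
        data = data_factory(counts, lengths=L)
        feats = FeatureMatrices(
            X=rng.normal(size=(4, 2)), Y=np.zeros((5, 0)),
            x_names=["f1", "f2"], y_names=[],
        )
        res = fit(data, feats, FitConfig(mode="mode1", seed=2, max_iter=600))
        assert res.params.A.shape == (5, 2)
        assert np.isfinite(res.final_elbo)

    def test_config_validation(self):
        with pytest.raises(ValidationError):
            FitConfig(mode="bogus")
        with pytest.raises(ValidationError):
            FitConfig(R=5, R_eval=2)
        with pytest.raises(ValidationError):
            FitConfig(learning_rate=0.0)

    def test_default_mc_samples_is_three(self):
        assert FitConfig().R == 3


class TestPsiSummarise:
    def _result(self, mu, delta):
        mu = np.atleast_2d(mu)
        delta = np.atleast_2d(delta)
        M, N = mu.shape
        from splicevb.inference import FitResult

        return FitResult(
            params=ModelParams(A=np.zeros((M, 0)), B=np.zeros((N, 0)), sigma=np.ones(N)),
            posterior=VariationalPosterior(mu=mu, delta=delta),
            elbo_trace=np.zeros(1), final_elbo=0.0, final_elbo_se=0.0,
            per_event_elbo=np.zeros(N), per_event_elbo_se=np.zeros(N),
            converged=True, n_iter=1, config=FitConfig(),
        )

    def test_median_at_zero(self):
        s = psi_summarise(self._result([[0.0]], [[1.0]]))
        assert s.psi_median[0, 0] == 0.5

    def test_degenerate_mean(self):
        s = psi_summarise(self._result([[2.0]], [[1e-8]]), n_samples=200)
        assert s.psi_mean[0, 0] == pytest.approx(expit(2.0), abs=1e-6)

    def test_mean_matches_quadrature(self):
        n = 40_000
        s = psi_summarise(self._result([[0.0]], [[2.0]]), n_samples=n,
                          rng=np.random.default_rng(3))
        exact = oracles.gh_expected_expit(0.0, 2.0)
        # var of expit(z) is bounded by 1/4
        se = 0.5 / np.sqrt(n)
        assert abs(s.psi_mean[0, 0] - exact) < 3 * se

    def test_median_inside_ci(self, rng):
        mu = rng.normal(size=(3, 4))
        delta = rng.uniform(0.2, 2.0, size=(3, 4))
        s = psi_summarise(self._result(mu, delta), n_samples=50)
        assert np.all(s.psi_ci_low <= s.psi_median)
        assert np.all(s.psi_median <= s.psi_ci_high)
        assert np.all((s.psi_mean >= 0) & (s.psi_mean <= 1))
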