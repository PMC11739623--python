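import numpy as np
import pytest
from scipy import stats

from frugijam import gjam, io, synth
from frugijam.gjam import (
    build_censor_map,
    consumption_indices,
    dic_from_deviance,
    ess,
    hpd,
    posterior_predict,
    ppc_summaries,
    psrf,
    rescale_to_correlation,
    sample_coefficients,
    sample_covariance,
    sample_latent,
    sensitivity,
    shannon_diversity,
    truncated_standard_normal,
)
from frugijam.io import AnalysisConfig, DietMatrix, ValidationError


def fc(values, simplex=True):
    values = np.asarray(values, float)
    return DietMatrix(values, io.FRACTIONAL_COMPOSITION,
                      [f"p{j}" for j in range(values.shape[1])], simplex=simplex)


def pa(values):
    values = np.asarray(values, float)
    return DietMatrix(values, io.PRESENCE_ABSENCE,
                      [f"p{j}" for j in range(values.shape[1])])


class TestCensorMap:
    def test_pa_intervals(self):
        cm = build_censor_map(pa([[0, 1]]))
        assert cm.censored.all()
        assert (cm.lo[0, 0], cm.hi[0, 0]) == (-np.inf, 0.0)
        assert (cm.lo[0, 1], cm.hi[0, 1]) == (0.0, np.inf)

    def test_fc_exact_and_censored(self):
        cm = build_censor_map(fc([[0.0, 0.25, 0.75]]))
        assert cm.censored[0, 0] and not cm.censored[0, 1]
        assert cm.hi[0, 0] == 0.0
        assert cm.y[0, 1] == 0.25

    def test_fc_one_censored_above(self):
        cm = build_censor_map(fc([[1.0, 0.0, 0.0]]))
        assert cm.censored[0, 0]
        assert (cm.lo[0, 0], cm.hi[0, 0]) == (1.0, np.inf)

    def test_out_of_range_errors(self):
        with pytest.raises(ValidationError):
            build_censor_map(fc([[1.5, 0.0]], simplex=False))

    def test_initial_latent_admissible(self, rng):
        Y = fc([[0.0, 0.4, 0.6], [1.0, 0.0, 0.0]], simplex=True)
        cm = build_censor_map(Y)
        assert cm.admits(cm.initial_latent())


class TestTruncatedNormal:
    def test_matches_scipy_truncnorm(self, rng):
        for a, b in [(-np.inf, 0.0), (0.0, np.inf), (1.0, 2.0), (-8.0, -6.0), (5.0, np.inf)]:
            ours = truncated_standard_normal(np.full(20000, a), np.full(20000, b), rng)
            ref = stats.truncnorm.rvs(a, b, size=20000,
                                      random_state=np.random.default_rng(1))
            ks = stats.ks_2samp(ours, ref).statistic
            assert ks < 0.025, (a, b, ks)
            assert (ours >= a).all() and (ours <= b).all()

    def test_half_normal_mean_vs_rejection_oracle(self, rng):
        # oracle: brute-force rejection sampling of N(0,1) restricted to w <= 0
        raw = rng.standard_normal(400_000)
        oracle = raw[raw <= 0][:100_000]
        draws = truncated_standard_normal(
            np.full(100_000, -np.inf), np.zeros(100_000), rng)
        assert draws.mean() == pytest.approx(oracle.mean(), abs=0.01)
        assert draws.mean() == pytest.approx(-np.sqrt(2 / np.pi), abs=0.01)


class TestSampleLatent:
    def test_half_normal_mean(self, rng):
        n = 100_000
        Y = pa(np.zeros((n, 1)))
        cm = build_censor_map(Y)
        W = sample_latent(np.full((n, 1), -0.5), np.zeros((1, 1)), np.eye(1),
                          np.ones((n, 1)) * 0.0, cm, rng)
        assert W.mean() == pytest.approx(-0.7979, abs=0.01)

    def test_exact_cells_untouched(self, rng):
        Y = fc([[0.0, 0.4, 0.6], [0.2, 0.3, 0.5]])
        cm = build_censor_map(Y)
        X = np.zeros((2, 1))
        B = np.zeros((1, 3))
        W = cm.initial_latent()
        for _ in range(100):
            W = sample_latent(W, B, np.eye(3), X, cm, rng)
        np.testing.assert_array_equal(W[~cm.censored], cm.y[~cm.censored])
        assert cm.admits(W)

    def test_conditional_slope_recovered(self, rng):
        # P=2, corr 0.9: censored column drawn given exact column should show
        # conditional mean slope 0.9
        n = 40_000
        Sigma = np.array([[1.0, 0.9], [0.9, 1.0]])
        w2 = rng.standard_normal(n)
        vals = np.column_stack([np.full(n, 0.5), np.clip(w2, 0.01, 0.99)])
        Y = fc(vals, simplex=False)
        cm = build_censor_map(Y)
        cm.censored[:, 0] = True  # treat col 0 as fully censored on (-inf, inf)
        cm.lo[:, 0], cm.hi[:, 0] = -np.inf, np.inf
        W = np.column_stack([np.zeros(n), np.clip(w2, 0.01, 0.99)])
        W = sample_latent(W, np.zeros((1, 2)), Sigma, np.zeros((n, 1)), cm, rng)
        slope = np.polyfit(W[:, 1], W[:, 0], 1)[0]
        assert slope == pytest.approx(0.9, abs=0.02)

    def test_non_pd_sigma_errors(self, rng):
        Y = pa([[0, 1]])
        cm = build_censor_map(Y)
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValidationError, match="positive definite"):
            sample_latent(cm.initial_latent(), np.zeros((1, 2)), bad,
                          np.zeros((1, 1)), cm, rng)


class TestSampleCoefficients:
    def test_posterior_mean_is_ols(self, rng):
        n, K, P = 200, 3, 2
        X = np.column_stack([np.ones(n), rng.standard_normal((n, K - 1))])
        W = rng.standard_normal((n, P))
        ols = np.linalg.lstsq(X, W, rcond=None)[0]
        draws = np.array([sample_coefficients(W, np.eye(P), X, 0.0, rng)
                          for _ in range(3000)])
        np.testing.assert_allclose(draws.mean(axis=0), ols, atol=0.02)

    def test_sd_shrinks_with_n(self, rng):
        P = 1
        sds = []
        for n in (200, 3200):
            X = rng.standard_normal((n, 1))
            W = X @ np.array([[0.5]]) + rng.standard_normal((n, 1))
            draws = np.array([sample_coefficients(W, np.eye(P), X, 0.0, rng)[0, 0]
                              for _ in range(1500)])
            sds.append(draws.std())
        assert sds[0] / sds[1] == pytest.approx(4.0, rel=0.25)  # sqrt(16)

    def test_prior_dominates_for_unidentified(self, rng):
        # strong ridge pulls coefficients of a zero-variance response to 0
        n = 50
        X = np.column_stack([np.ones(n)])
        W = np.zeros((n, 1))
        draws = np.array([sample_coefficients(W, np.eye(1), X, 1e-6, rng)[0, 0]
                          for _ in range(500)])
        assert abs(draws.mean()) < 0.05


class TestSampleCovariance:
    def test_iid_residuals_give_identity(self, rng):
        R = rng.standard_normal((10_000, 3))
        draws = np.array([sample_covariance(R, rng) for _ in range(200)])
        E = np.array([rescale_to_correlation(S, np.zeros((1, 3)))[0] for S in draws])
        off = E.mean(axis=0)[~np.eye(3, dtype=bool)]
        assert np.abs(off).max() < 0.05

    def test_rescale_unit_diagonal_exact(self, rng):
        S = sample_covariance(rng.standard_normal((500, 4)), rng)
        E, Bc, D = rescale_to_correlation(S, rng.standard_normal((2, 4)))
        np.testing.assert_array_equal(np.diag(E), np.ones(4))
        np.testing.assert_array_equal(E, E.T)

    def test_known_correlation_recovered(self, rng):
        L = np.linalg.cholesky(np.array([[1.0, 0.7], [0.7, 1.0]]))
        R = rng.standard_normal((5000, 2)) @ L.T
        draws = np.array([sample_covariance(R, rng) for _ in range(200)])
        E = np.array([rescale_to_correlation(S, np.zeros((1, 2)))[0] for S in draws])
        assert E.mean(axis=0)[0, 1] == pytest.approx(0.7, abs=0.05)

    def test_n_le_p_errors(self, rng):
        with pytest.raises(ValidationError, match="more samples"):
            sample_covariance(rng.standard_normal((3, 3)), rng)


class TestHpd:
    def test_constant_vector(self):
        lo, hi = hpd(np.full(500, 3.25))
        assert (lo, hi) == (3.25, 3.25)

    def test_exponential_starts_at_zero(self, rng):
        lo, hi = hpd(rng.exponential(1.0, 100_000))
        assert lo < 0.02

    def test_matches_arviz(self, rng):
        arviz = pytest.importorskip("arviz")
        draws = rng.gamma(2.0, 1.0, 20_000)
        lo, hi = hpd(draws)
        ref = arviz.hdi(draws, hdi_prob=0.95)
        assert lo == pytest.approx(ref[0], abs=0.02)
        assert hi == pytest.approx(ref[1], abs=0.02)

    def test_too_few_draws(self):
        with pytest.raises(ValidationError):
            hpd(np.arange(50))


class TestSensitivity:
    def _samples(self, b_cor, e):
        S, K, P = b_cor.shape
        return gjam.PosteriorSamples(
            b=b_cor, b_cor=b_cor, e=e, sigma=e, deviance=np.zeros(S),
            chain_ids=np.zeros(S, int), draw_ids=np.arange(S),
            covariate_labels=[f"c{k}" for k in range(K)],
            plant_labels=[f"p{p}" for p in range(P)],
            mode=io.PRESENCE_ABSENCE, seed=0, dev_at_mean=0.0)

    def test_zero_row_and_unit_vector(self):
        S, K, P = 150, 2, 3
        b = np.zeros((S, K, P))
        b[:, 1, 0] = 1.0  # unit vector row
        e = np.tile(np.eye(P), (S, 1, 1))
        out = sensitivity(self._samples(b, e))
        f = dict(zip(out.covariate, out["mean"]))
        assert f["c0"] == 0.0
        assert f["c1"] == pytest.approx(1.0)

    def test_matches_brute_force(self, rng):
        S, K, P = 120, 3, 4
        b = rng.standard_normal((S, K, P))
        A = rng.standard_normal((P, P)) * 0.2
        E = np.tile(rescale_to_correlation(A @ A.T + np.eye(P), np.zeros((1, P)))[0],
                    (S, 1, 1))
        out = sensitivity(self._samples(b, E))
        # brute force, one draw/covariate at a time
        expect = np.zeros(K)
        for s in range(S):
            Ei = np.linalg.inv(E[s])
            for k in range(K):
                expect[k] += b[s, k] @ Ei @ b[s, k] / S
        got = out.set_index("covariate")["mean"]
        for k in range(K):
            assert got[f"c{k}"] == pytest.approx(expect[k], rel=1e-8)


class TestDic:
    def test_degenerate_posterior_pd_zero(self):
        out = dic_from_deviance(np.full(100, 42.0), 42.0)
        assert out["pD"] == 0.0
        assert out["dic"] == 42.0

    def test_normal_mean_model_pd(self, rng):
        # oracle: y_i ~ N(mu, 1) with flat prior -> mu | y ~ N(ybar, 1/n);
        # pD = E[D] - D(mu_bar) = n * E[(mu - mu_bar)^2] = 1 per mean
        P = 8
        n = 50
        y = rng.standard_normal((n, P))
        mus = y.mean(axis=0) + rng.standard_normal((40_000, P)) / np.sqrt(n)
        dev = ((y[None, :, :] - mus[:, None, :]) ** 2).sum(axis=(1, 2))
        dev_at_mean = ((y - mus.mean(axis=0)) ** 2).sum()
        out = dic_from_deviance(dev, dev_at_mean)
        assert out["pD"] == pytest.approx(P, rel=0.05)


class TestPpc:
    def test_shannon_of_even_split(self):
        assert shannon_diversity(np.array([0.5, 0.5])) == pytest.approx(np.log(2))

    def test_all_absent_row(self):
        assert shannon_diversity(np.zeros(4)) == 0.0

    def test_self_consistency_band(self, tiny_fc_samples, rng):
        samples, X, Y, _ = tiny_fc_samples
        ysim = posterior_predict(samples, X, rng, n_sims=150)
        df, summary = ppc_summaries(ysim, Y)
        assert len(df) == Y.n
        assert summary["richness_band_coverage"] >= 0.9


class TestDiagnostics:
    def test_psrf_iid_chains(self, rng):
        chains = rng.standard_normal((4, 5000))
        assert 0.999 <= psrf(chains) <= 1.01

    def test_psrf_disjoint_chains(self, rng):
        chains = np.vstack([rng.standard_normal(500) - 10,
                            rng.standard_normal(500) + 10])
        assert psrf(chains) > 3

    def test_psrf_matches_arviz(self, rng):
        # near-converged stationary chains with slightly offset means: the
        # classical split-Rhat and arviz's rank-normalized version agree closely
        arviz = pytest.importorskip("arviz")
        chains = rng.standard_normal((4, 3000)) + np.array([[0.0], [0.05], [-0.05], [0.02]])
        ref = float(np.asarray(
            arviz.rhat(arviz.convert_to_dataset(chains)).to_array()).squeeze())
        assert psrf(chains) == pytest.approx(ref, abs=0.01)

    def test_ess_iid(self, rng):
        x = rng.standard_normal(20_000)
        assert ess(x) == pytest.approx(20_000, rel=0.15)

    def test_ess_ar1(self, rng):
        rho, n = 0.9, 50_000
        x = np.empty(n)
        x[0] = rng.standard_normal()
        eps = rng.standard_normal(n) * np.sqrt(1 - rho**2)
        for i in range(1, n):
            x[i] = rho * x[i - 1] + eps[i]
        expect = n * (1 - rho) / (1 + rho)
        assert ess(x) == pytest.approx(expect, rel=0.25)


class TestFit:
    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        n, P = 60, 3
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        Y = pa((rng.random((n, P)) < 0.4).astype(float))
        cfg = AnalysisConfig(mode=io.PRESENCE_ABSENCE, n_iterations=200,
                             n_burnin=50, thin=2, n_chains=2, rng_seed=17)
        a = gjam.fit(X, Y, cfg)
        b = gjam.fit(X, Y, cfg)
        np.testing.assert_array_equal(a.b_cor, b.b_cor)
        np.testing.assert_array_equal(a.deviance, b.deviance)

    def test_e_draw_invariants(self, tiny_fc_samples):
        samples, _, _, _ = tiny_fc_samples
        for E in samples.e:
            np.testing.assert_array_equal(np.diag(E), np.ones(E.shape[0]))
            np.testing.assert_array_equal(E, E.T)
            assert np.linalg.eigvalsh(E).min() > -1e-8

    def test_no_censoring_limit_matches_ols(self, tiny_fc_samples):
        samples, X, Y, _ = tiny_fc_samples
        ols = np.linalg.lstsq(np.asarray(X), Y.values, rcond=None)[0]
        np.testing.assert_allclose(samples.b.mean(axis=0), ols, atol=0.02)

    def test_mode_mismatch_errors(self):
        Y = pa(np.zeros((30, 2)) + np.eye(30, 2))
        cfg = AnalysisConfig(mode=io.FRACTIONAL_COMPOSITION, n_iterations=50,
                             n_burnin=10)
        with pytest.raises(ValidationError, match="mode"):
            gjam.fit(np.ones((30, 1)), Y, cfg)

    def test_small_pa_recovery(self):
        # one-replicate smoke version of the coverage simulation
        rng = np.random.default_rng(8)
        n, P, K = 600, 4, 3
        X = np.column_stack([np.ones(n), rng.standard_normal((n, K - 1))])
        B = np.array([[-0.4, 0.2, 0.0, 0.6],
                      [0.8, 0.0, -0.5, 0.0],
                      [0.0, 0.7, 0.0, -0.6]])
        E = synth.exchangeable_correlation(P, 0.3)
        Y = synth.simulate_diet(X, B, E, io.PRESENCE_ABSENCE, rng)
        cfg = AnalysisConfig(mode=io.PRESENCE_ABSENCE, n_iterations=1500,
                             n_burnin=500, thin=1, n_chains=1, rng_seed=4)
        s = gjam.fit(X, Y, cfg)
        rmse = np.sqrt(((s.b_cor.mean(axis=0) - B) ** 2).mean())
        assert rmse < 0.15


class TestConsumptionIndices:
    def test_flags_and_signs(self, rng):
        S = 400
        b = np.zeros((S, 1, 2))
        b[:, 0, 0] = rng.normal(1.0, 0.1, S)      # all positive -> strong +
        b[:, 0, 1] = rng.normal(0.0, 1.0, S)      # symmetric about 0 -> weak
        e = np.tile(np.eye(2), (S, 1, 1))
        samples = gjam.PosteriorSamples(
            b=b, b_cor=b, e=e, sigma=e, deviance=np.zeros(S),
            chain_ids=np.zeros(S, int), draw_ids=np.arange(S),
            covariate_labels=["cov"], plant_labels=["pa", "pb"],
            mode=io.PRESENCE_ABSENCE, seed=0, dev_at_mean=0.0)
        out = consumption_indices(samples)
        strong = out.set_index("plant")["strong"]
        assert bool(strong["pa"]) is True
        assert bool(strong["pb"]) is False
        assert out.set_index("plant")["sign"]["pa"] == "+"

    def test_ordering_invariant_to_thinning(self):
        rng = np.random.default_rng(10)
        n, P = 150, 4
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        B = np.array([[0.0, -0.3, 0.3, 0.0], [0.5, 0.0, -0.5, 0.2]])
        Y = synth.simulate_diet(X, B, np.eye(P), io.PRESENCE_ABSENCE, rng)
        meds = {}
        for thin in (2, 4):
            cfg = AnalysisConfig(mode=io.PRESENCE_ABSENCE, n_iterations=1200,
                                 n_burnin=400, thin=thin, n_chains=1, rng_seed=3)
            s = gjam.fit(X, Y, cfg)
            t = consumption_indices(s)
            meds[thin] = t[t.covariate == "x1"].set_index("plant")["median"]
        # same median ordering across plant species within MC error
        order2 = meds[2].sort_values().index.tolist()
        order4 = meds[4].sort_values().index.tolist()
        assert order2 == order4
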