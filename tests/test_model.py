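"""Posterior mean, edge significance, correlation conversion, sparsification."""

import numpy as np
import pytest
from scipy.stats import invgamma, norm

from bonobonet import (
    Bonobo,
    BonobonetError,
    DegenerateGeneError,
    DegreesOfFreedomError,
    ExpressionMatrix,
    PriorSpec,
    SampleNetwork,
    StateError,
    bonobo_all_samples,
    compute_loo_stats,
    cov_to_corr,
    edge_pvalues,
    fixed_delta_prior,
    loo_covariance,
    posterior_edge_sd,
    posterior_mean,
    sparsify,
)

from conftest import make_expr


def _prior(delta: float, g: int) -> PriorSpec:
    return fixed_delta_prior(delta, g)


class TestPosteriorMean:
    def test_hand_oracle(self):
        # dev = (1,2), S = I, delta = 0.5 -> 0.5*[[1,2],[2,4]] + 0.5*I
        sigma = posterior_mean(
            np.array([1.0, 2.0]), np.zeros(2), _prior(0.5, 2), np.eye(2)
        )
        np.testing.assert_allclose(sigma, [[1.0, 1.0], [1.0, 2.5]])

    def test_delta_one_is_pure_outer_product(self):
        x, xbar = np.array([2.0, -1.0, 0.5]), np.array([1.0, 0.0, 0.0])
        sigma = posterior_mean(x, xbar, _prior(1.0, 3), np.eye(3))
        dev = x - xbar
        np.testing.assert_allclose(sigma, np.outer(dev, dev))

    def test_sample_at_grand_mean_shrinks_fully(self):
        s = np.array([[2.0, 0.3], [0.3, 1.0]])
        sigma = posterior_mean(np.ones(2), np.ones(2), _prior(0.25, 2), s)
        np.testing.assert_allclose(sigma, 0.75 * s)

    def test_dimension_mismatch(self):
        with pytest.raises(BonobonetError):
            posterior_mean(np.ones(3), np.ones(2), _prior(0.5, 2), np.eye(2))

    def test_ratio_form_identity_on_random_fixtures(self):
        """Sigma via the convex combination equals the scale-ratio form
        [(x-xbar)(x-xbar)^T + (nu-g-1) S_i] / (nu-g)."""
        expr = make_expr(4, 9, seed=7)
        stats = compute_loo_stats(expr)
        res = Bonobo(expr).fit()
        g = expr.n_genes
        for i in range(expr.n_samples):
            p = res.priors[i]
            s_i = loo_covariance(expr, i, stats=stats)
            dev = expr.values[:, i] - stats.grand_mean
            via_delta = posterior_mean(expr.values[:, i], stats.grand_mean, p, s_i)
            via_ratio = (np.outer(dev, dev) + (p.nu - g - 1) * s_i) / (p.nu - g)
            np.testing.assert_allclose(via_delta, via_ratio, atol=1e-12)


class TestEdgeVariance:
    @pytest.mark.parametrize(
        "s_entries,m,expected_var",
        [
            ((1.0, 1.0, 0.0), 5.0, 0.4),   # (4*1)/(5*2)
            ((1.0, 1.0, 1.0), 5.0, 1.0),   # (6+4)/10
        ],
    )
    def test_direct_substitution(self, s_entries, m, expected_var):
        g = 3
        prior = fixed_delta_prior(1.0 / m, g)
        psi = posterior_edge_sd(prior, s_entries)
        assert psi == pytest.approx(np.sqrt(expected_var))

    def test_dof_too_small_errors(self):
        prior = fixed_delta_prior(1.0, g=2)  # nu - g = 1
        with pytest.raises(DegreesOfFreedomError):
            posterior_edge_sd(prior, (1.0, 1.0, 0.0))

    def test_monte_carlo_oracle(self):
        """Empirical entry variances of InvWishart((nu-g-1)S, nu) draws match
        the closed form within 3 Monte-Carlo standard errors."""
        from scipy.stats import invwishart

        g, m = 2, 10
        nu = g + m
        s = np.array([[1.0, 0.4], [0.4, 2.0]])
        draws = invwishart.rvs(
            df=nu, scale=(nu - g - 1) * s, size=50_000,
            random_state=np.random.default_rng(7),
        )
        emp = draws.var(axis=0)
        formula = ((m + 1) * s**2 + (m - 1) * np.outer(np.diag(s), np.diag(s))) / (
            m * (m - 3)
        )
        centered = draws - draws.mean(axis=0)
        mc_se = np.sqrt(((centered**4).mean(axis=0) - emp**2) / draws.shape[0])
        assert np.all(np.abs(emp - formula) <= 3 * mc_se)
        prior = fixed_delta_prior(1.0 / m, g)
        for (j, k) in [(0, 0), (0, 1), (1, 1)]:
            psi = posterior_edge_sd(prior, (s[j, j], s[k, k], s[j, k]))
            assert psi == pytest.approx(np.sqrt(formula[j, k]))


class TestEdgePvalues:
    def _setup(self, g=3, m=8.0):
        rng = np.random.default_rng(3)
        a = rng.standard_normal((g, 2 * g))
        s = a @ a.T / (2 * g)
        prior = fixed_delta_prior(1.0 / m, g)
        return prior, s

    def test_zero_estimate_gives_p_one(self):
        prior, s = self._setup()
        pv = edge_pvalues(np.zeros((3, 3)), prior, s)
        np.testing.assert_allclose(pv, 1.0)

    def test_critical_z_gives_p_005(self):
        prior, s = self._setup(g=2, m=6.0)
        psi = posterior_edge_sd(prior, (s[0, 0], s[1, 1], s[0, 1]))
        post = np.zeros((2, 2))
        post[0, 1] = post[1, 0] = 1.959964 * psi
        pv = edge_pvalues(post, prior, s)
        assert pv[0, 1] == pytest.approx(0.05, abs=5e-5)

    def test_sign_flip_invariance(self):
        prior, s = self._setup()
        post = np.array([[1.0, 0.3, -0.2], [0.3, 1.0, 0.1], [-0.2, 0.1, 1.0]])
        pv_pos = edge_pvalues(post, prior, s)
        pv_neg = edge_pvalues(-post, prior, s)
        np.testing.assert_allclose(pv_pos, pv_neg, atol=1e-15)

    def test_posterior_params_variant_is_more_conservative_scale(self):
        # same formula evaluated at (nu+1, Sigma): still a valid p in [0,1]
        prior, s = self._setup()
        post = s.copy()
        pv = edge_pvalues(post, prior, s, edge_var="posterior-params")
        assert np.all((pv >= 0) & (pv <= 1))
        np.testing.assert_allclose(pv, pv.T)


class TestCovToCorr:
    def test_diagonal_input_gives_identity(self):
        np.testing.assert_allclose(cov_to_corr(np.diag([4.0, 9.0, 2.5])), np.eye(3))

    def test_hand_arithmetic(self):
        corr = cov_to_corr(np.array([[4.0, 2.0], [2.0, 9.0]]))
        assert corr[0, 1] == pytest.approx(1.0 / 3.0)
        np.testing.assert_allclose(np.diagonal(corr), 1.0)

    def test_nonpositive_diagonal_rejected(self):
        with pytest.raises(DegenerateGeneError):
            cov_to_corr(np.array([[0.0, 0.0], [0.0, 1.0]]))

    def test_psd_preserved_under_normalisation(self):
        expr = make_expr(8, 12, seed=13)
        for net in bonobo_all_samples(expr, pvalues=False):
            eig = np.linalg.eigvalsh(net.correlation)
            assert eig.min() >= -1e-8 * max(eig.max(), 1.0)


class TestSparsify:
    def _net(self, pvals, corr=None):
        g = pvals.shape[0]
        if corr is None:
            corr = np.eye(g)
        return SampleNetwork(
            sample_id="s", gene_ids=tuple(f"g{i}" for i in range(g)),
            post_mean_cov=corr, correlation=corr, nu=20.0, delta=0.05,
            pvalues=pvals,
        )

    def test_all_p_one_gives_empty_set(self):
        pv = np.ones((4, 4))
        assert sparsify(self._net(pv), alpha=0.05).edges == []

    def test_bh_hand_oracle(self):
        # three edges with p {0.01, 0.02, 0.04}: BH adjusted {0.03, 0.03, 0.04}
        pv = np.ones((3, 3))
        pv[0, 1] = pv[1, 0] = 0.01
        pv[0, 2] = pv[2, 0] = 0.02
        pv[1, 2] = pv[2, 1] = 0.04
        sp = sparsify(self._net(pv), alpha=0.05, correction="benjamini_hochberg")
        adj = {(a, b): p for a, b, _, p in sp.edges}
        assert adj[("g0", "g1")] == pytest.approx(0.03)
        assert adj[("g0", "g2")] == pytest.approx(0.03)
        assert adj[("g1", "g2")] == pytest.approx(0.04)
        assert len(sp.edges) == 3

    def test_boundary_p_equal_alpha_is_retained(self):
        pv = np.ones((2, 2))
        pv[0, 1] = pv[1, 0] = 0.05
        sp = sparsify(self._net(pv), alpha=0.05, correction="none")
        assert len(sp.edges) == 1

    def test_missing_pvalues_is_state_error(self):
        net = self._net(np.ones((2, 2)))
        net.pvalues = None
        with pytest.raises(StateError):
            sparsify(net, alpha=0.05)

    def test_weights_come_from_correlation(self):
        corr = np.array([[1.0, -0.7], [-0.7, 1.0]])
        pv = np.full((2, 2), 0.001)
        sp = sparsify(self._net(pv, corr), alpha=0.05)
        assert sp.edges[0][2] == pytest.approx(-0.7)


class TestModelResults:
    def test_determinism_bit_identical(self):
        expr = make_expr(10, 8, seed=2)
        nets_a = list(bonobo_all_samples(expr))
        nets_b = list(bonobo_all_samples(expr))
        for a, b in zip(nets_a, nets_b):
            assert np.array_equal(a.correlation, b.correlation)
            assert np.array_equal(a.pvalues, b.pvalues)

    def test_shrinkage_limit_delta_to_zero(self):
        """As a fixed delta shrinks to zero, the posterior mean converges
        monotonically onto the leave-one-out covariance."""
        expr = make_expr(5, 10, seed=8)
        stats = compute_loo_stats(expr)
        prev = None
        for delta in (0.3, 0.1, 0.03, 0.01, 0.003):
            res = Bonobo(expr, delta=delta).fit(pvalues=False)
            gap = max(
                np.linalg.norm(
                    net.post_mean_cov - loo_covariance(expr, i, stats=stats)
                )
                for i, net in enumerate(res.sample_networks())
            )
            if prev is not None:
                assert gap < prev
            prev = gap
        assert prev < 0.1

    def test_single_gene_reduces_to_inverse_gamma_update(self):
        """At g=1 the posterior mean is [(x-xbar)^2 + (nu-2) s^2]/(nu-1)."""
        vals = np.array([[0.3, -1.2, 0.7, 2.1, -0.5]])
        expr = ExpressionMatrix(vals, ("g0",), tuple(f"s{i}" for i in range(5)))
        res = Bonobo(expr, delta=0.25).fit(pvalues=False)
        nu = 1 + 1.0 / 0.25
        xbar = vals.mean()
        for i, net in enumerate(res.sample_networks()):
            keep = np.arange(5) != i
            s2 = vals[0, keep].var(ddof=1)
            expected = ((vals[0, i] - xbar) ** 2 + (nu - 2) * s2) / (nu - 1)
            assert net.post_mean_cov[0, 0] == pytest.approx(expected, rel=1e-12)

    def test_conjugacy_density_oracle_g1(self):
        """Prior x likelihood renormalized equals the closed-form posterior
        (the matching inverse-gamma) pointwise on a variance grid."""
        from scipy.integrate import quad

        nu, s2, dev = 7.0, 1.3, 0.8
        prior = invgamma(a=nu / 2, scale=(nu - 2) * s2 / 2)

        def unnorm(v):
            return prior.pdf(v) * norm.pdf(dev, scale=np.sqrt(v))

        z, _ = quad(unnorm, 0, np.inf, limit=200)
        sigma = (dev**2 + (nu - 2) * s2) / (nu - 1)
        post = invgamma(a=(nu + 1) / 2, scale=(nu - 1) * sigma / 2)
        grid = np.linspace(0.05, 12.0, 200)
        assert np.abs(unnorm(grid) / z - post.pdf(grid)).max() < 1e-6

    def test_summary_contains_priors(self, small_expr):
        res = Bonobo(small_expr).fit(pvalues=False)
        text = res.summary()
        assert "delta" in text and "s0" in text
        assert res.prior_table().shape == (8, 3)

    def test_network_lookup_by_id_and_index(self, small_expr):
        res = Bonobo(small_expr).fit(pvalues=False)
        np.testing.assert_array_equal(
            res.network("s3").correlation, res.network(3).correlation
        )
        with pytest.raises(KeyError):
            res.network("nope")
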