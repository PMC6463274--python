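import math

import numpy as np
import pytest
from scipy.special import betaln
from scipy.stats import beta as beta_dist

import providervar as pv

from conftest import make_counts


def _bb_log_marginal(ys, ns, a1=1.0, b1=1.0):
    """Exact log marginal likelihood of a cluster (binomial coefficients
    dropped consistently, as they cancel in partition comparisons)."""
    y, n = sum(ys), sum(ns)
    return betaln(a1 + y, b1 + n - y) - betaln(a1, b1)


def _partition_posterior(y, n, alpha):
    """Exact posterior over set partitions of a tiny cohort (fixed alpha)."""
    idx = range(len(y))
    partitions = []
    if len(y) == 2:
        partitions = [[(0, 1)], [(0,), (1,)]]
    elif len(y) == 3:
        partitions = [
            [(0, 1, 2)],
            [(0, 1), (2,)], [(0, 2), (1,)], [(1, 2), (0,)],
            [(0,), (1,), (2,)],
        ]
    logps = []
    for part in partitions:
        lp = len(part) * np.log(alpha)
        for block in part:
            lp += np.log(math.factorial(len(block) - 1))
            lp += _bb_log_marginal([y[i] for i in block], [n[i] for i in block])
        logps.append(lp)
    logps = np.array(logps)
    probs = np.exp(logps - logps.max())
    return partitions, probs / probs.sum()


class TestDPConfig:
    def test_exactly_one_alpha_mode(self):
        with pytest.raises(pv.ValidationError):
            pv.DPConfig(alpha=1.0, alpha_prior=(4, 4))
        with pytest.raises(pv.ValidationError):
            pv.DPConfig(alpha=None, alpha_prior=None)

    def test_presets(self):
        assert pv.dp_preset("dp1").alpha_prior == (4.0, 4.0)
        assert pv.dp_preset("dp2").alpha_prior == (10.0, 0.10)
        assert pv.dp_preset("dp3").alpha == 20.0


class TestDPFit:
    def test_single_provider_single_cluster(self):
        c = make_counts([5], [10])
        cfg = pv.DPConfig(alpha=2.0, alpha_prior=None, n_iter=200, burn_in=50,
                          thin=1, seed=0)
        res = pv.dp_fit(c, cfg)
        assert np.all(res.cluster_counts == 1)

    def test_two_provider_exact_enumeration(self):
        y, n = [4, 9], [20, 20]
        c = make_counts(y, n)
        cfg = pv.DPConfig(alpha=1.0, alpha_prior=None, n_iter=6000,
                          burn_in=500, thin=2, seed=3)
        res = pv.dp_fit(c, cfg)
        parts, probs = _partition_posterior(y, n, 1.0)
        p_same_exact = probs[0]
        p_same_mc = float((res.cluster_counts == 1).mean())
        se = np.sqrt(p_same_exact * (1 - p_same_exact) / res.n_draws)
        assert abs(p_same_mc - p_same_exact) < 4 * se  # mild autocorrelation

    def test_three_provider_exact_enumeration(self):
        y, n = [2, 5, 14], [20, 20, 20]
        c = make_counts(y, n)
        cfg = pv.DPConfig(alpha=1.5, alpha_prior=None, n_iter=8000,
                          burn_in=500, thin=2, seed=4)
        res = pv.dp_fit(c, cfg)
        parts, probs = _partition_posterior(y, n, 1.5)
        # compare the posterior distribution of the cluster count
        k_exact = {k: 0.0 for k in (1, 2, 3)}
        for part, pr in zip(parts, probs):
            k_exact[len(part)] += pr
        for k in (1, 2, 3):
            p_mc = float((res.cluster_counts == k).mean())
            se = np.sqrt(max(k_exact[k] * (1 - k_exact[k]), 1e-6) / res.n_draws)
            assert abs(p_mc - k_exact[k]) < 4 * se

    def test_small_alpha_all_one_cluster(self):
        c = make_counts([4, 6, 5], [20, 20, 20])
        cfg = pv.DPConfig(alpha=1e-6, alpha_prior=None, n_iter=1200,
                          burn_in=200, thin=1, seed=1)
        res = pv.dp_fit(c, cfg)
        assert (res.cluster_counts == 1).mean() >= 0.999

    def test_reproducibility(self):
        c = make_counts([4, 9, 2], [20, 20, 20])
        cfg = pv.dp_preset("dp1", n_iter=500, burn_in=100, thin=2, seed=7)
        r1 = pv.dp_fit(c, cfg)
        r2 = pv.dp_fit(c, cfg)
        np.testing.assert_array_equal(r1.cluster_counts, r2.cluster_counts)
        np.testing.assert_array_equal(r1.labels, r2.labels)
        np.testing.assert_allclose(r1.alphas, r2.alphas)

    def test_prior_only_sampler_recovers_crp_prior(self):
        """With the likelihood switched off, the Gibbs sampler's marginal
        distribution of the cluster count matches direct CRP simulation."""
        N = 30
        c = make_counts(np.full(N, 5), np.full(N, 20))
        cfg = pv.DPConfig(alpha_prior=(4.0, 4.0), n_iter=4000, burn_in=500,
                          thin=2, seed=9)
        res = pv.dp_fit(c, cfg, _prior_only=True)
        direct = pv.prior_cluster_distribution(N, pv.DPConfig(alpha_prior=(4.0, 4.0)),
                                               n_draws=40_000, seed=10)
        gibbs_mean = res.cluster_counts.mean()
        # generous band: Gibbs draws are autocorrelated
        se = res.cluster_counts.std(ddof=1) / np.sqrt(res.n_draws / 10)
        assert abs(gibbs_mean - direct["mean"]) < 4 * se


class TestDPDensity:
    def test_single_provider_closed_form(self):
        c = make_counts([5], [10])
        alpha = 2.5
        cfg = pv.DPConfig(alpha=alpha, alpha_prior=None, n_iter=300,
                          burn_in=100, thin=1, seed=0)
        res = pv.dp_fit(c, cfg)
        est = pv.dp_density(res, c)
        w = alpha / (alpha + 1)
        expected = w * beta_dist.pdf(est.grid, 1, 1) + (1 - w) * beta_dist.pdf(
            est.grid, 6, 6)
        np.testing.assert_allclose(est.pdf, expected, atol=1e-10)

    def test_pdf_integrates_to_one(self):
        c = make_counts([4, 9, 2], [20, 20, 20])
        cfg = pv.dp_preset("dp1", n_iter=400, burn_in=100, thin=2, seed=5)
        est = pv.dp_density(pv.dp_fit(c, cfg), c)
        total = np.trapezoid(est.pdf, est.grid)
        assert total == pytest.approx(1.0, abs=1e-4)
        assert est.cdf(np.array([1.0]))[0] == pytest.approx(1.0, abs=1e-9)

    def test_variance_bounded(self):
        c = make_counts([4, 16], [20, 20])
        cfg = pv.dp_preset("dp3", n_iter=400, burn_in=100, thin=2, seed=6)
        est = pv.dp_density(pv.dp_fit(c, cfg), c)
        assert 0 <= est.variance <= 0.25


class TestPriorClusterDistribution:
    def test_crp_mean_matches_analytic(self):
        for alpha in (0.5, 5.0, 20.0):
            cfg = pv.DPConfig(alpha=alpha, alpha_prior=None)
            dist = pv.prior_cluster_distribution(100, cfg, n_draws=20_000, seed=2)
            analytic = np.sum(alpha / (alpha + np.arange(100)))
            se = dist["samples"].std(ddof=1) / np.sqrt(20_000)
            assert abs(dist["mean"] - analytic) < 3 * se

    def test_tiny_alpha_single_cluster(self):
        cfg = pv.DPConfig(alpha=1e-9, alpha_prior=None)
        dist = pv.prior_cluster_distribution(50, cfg, n_draws=2000, seed=0)
        assert np.all(dist["samples"] == 1)

    def test_pmf_sums_to_one(self):
        cfg = pv.DPConfig(alpha_prior=(10.0, 0.10))
        dist = pv.prior_cluster_distribution(100, cfg, n_draws=5000, seed=1)
        assert dist["probability"].sum() == pytest.approx(1.0)
        assert dist["quantiles"][97.5] <= 100
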