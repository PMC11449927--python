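"""Sampler correctness and MCMC diagnostics against constructed references."""

from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

from moodhrv.cohort import apply_inclusion_filters, build_table
from moodhrv.errors import InsufficientDataError
from moodhrv.inference import (
    SamplerConfig,
    bfmi,
    ess,
    fit,
    kl_divergence,
    prior_predictive_quantiles,
    rhat,
)
from moodhrv.models import build_model
from moodhrv.sampling import sample_nuts_chain
from moodhrv.synthetic import CohortConfig, TrueParams, generate_cohort

from conftest import FAST_SAMPLER


class TestNutsOnKnownTargets:
    def test_standard_normal_moments(self):
        def logp_grad(x):
            return -0.5 * float(x @ x), -x

        rng = np.random.default_rng(0)
        ch = sample_nuts_chain(logp_grad, np.zeros(4), 500, 2000, 0.9, rng)
        assert np.abs(ch.draws.mean(axis=0)).max() < 0.1
        assert np.allclose(ch.draws.std(axis=0), 1.0, atol=0.1)
        assert not ch.divergent.any()

    def test_conjugate_posterior_mean_recovered(self):
        """Normal likelihood, known sigma, Normal prior: closed-form posterior."""
        y = np.array([2.1, 1.4, 2.8, 1.9, 2.3])
        sigma, mu0, tau0 = 0.5, 0.0, 2.0
        post_var = 1.0 / (1 / tau0**2 + len(y) / sigma**2)
        post_mean = post_var * (mu0 / tau0**2 + y.sum() / sigma**2)

        def logp_grad(x):
            m = x[0]
            lp = -0.5 * ((m - mu0) / tau0) ** 2 - 0.5 * np.sum(((y - m) / sigma) ** 2)
            g = -(m - mu0) / tau0**2 + np.sum(y - m) / sigma**2
            return float(lp), np.array([g])

        rng = np.random.default_rng(1)
        ch = sample_nuts_chain(logp_grad, np.zeros(1), 500, 4000, 0.9, rng)
        mcse = ch.draws.std() / np.sqrt(400)  # conservative effective size
        assert ch.draws.mean() == pytest.approx(post_mean, abs=3 * mcse)
        assert ch.draws.std() == pytest.approx(np.sqrt(post_var), rel=0.1)


class TestFit:
    def test_ground_truth_slope_recovery(self):
        tp = TrueParams(gamma_mania=0.2, gamma_depression=0.2)
        subjects, truth = generate_cohort(CohortConfig(true_params=tp, seed=77))
        table = build_table(apply_inclusion_filters(subjects)[0])
        spec = build_model(table, "one_disease")
        post = fit(spec, table, FAST_SAMPLER)
        pooled = post.stacked("beta1").ravel()
        assert pooled.mean() == pytest.approx(0.2, abs=0.1)

    def test_same_seed_reproduces_summaries(self, default_table):
        spec = build_model(default_table, "one_disease")
        cfg = SamplerConfig(n_chains=2, n_tune=150, n_draws=150, target_accept=0.9, seed=5)
        a = fit(spec, default_table, cfg)
        b = fit(spec, default_table, cfg)
        np.testing.assert_array_equal(a.posterior["beta1"], b.posterior["beta1"])
        np.testing.assert_array_equal(a.energy, b.energy)

    def test_posterior_shapes(self, small_fit):
        post = small_fit
        n = post.spec.n_subjects
        assert post.posterior["beta1"].shape == (2, 400, n)
        assert post.log_likelihood.shape == (2, 400, post.spec.n_obs)
        assert post.energy.shape == (2, 400)


class TestCalibration:
    def test_gamma_rank_statistic_is_uniform(self):
        """Scaled simulation-based calibration of the polarity slope centre.

        Each replicate draws a true gamma pair from its uniform prior,
        generates a small cohort from it, fits the two-polarities model,
        and ranks the truth within thinned posterior draws; ranks must be
        consistent with uniformity (chi-squared, alpha = 0.01).
        """
        n_reps, n_thin, n_bins = 24, 16, 4
        rng = np.random.default_rng(314)
        cfg = SamplerConfig(
            n_chains=2, n_tune=150, n_draws=150, target_accept=0.8,
            max_treedepth=7, dense_metric=False, seed=0,
        )
        counts = np.zeros(n_bins)
        for rep in range(n_reps):
            gm, gd = rng.uniform(-1, 1, 2)
            subjects, _ = generate_cohort(
                CohortConfig(
                    n_mania=4,
                    n_depression=4,
                    n_assessments_distribution={3: 8},
                    true_params=TrueParams(gamma_mania=gm, gamma_depression=gd),
                    seed=int(rng.integers(2**31)),
                )
            )
            table = build_table(apply_inclusion_filters(subjects)[0])
            spec = build_model(table, "two_polarities")
            post = fit(spec, table, replace(cfg, seed=rep))
            draws = post.stacked("gamma")[:, 0]
            thinned = draws[:: max(1, draws.size // n_thin)][:n_thin]
            rank = int(np.sum(thinned < gm))
            counts[min(rank * n_bins // (n_thin + 1), n_bins - 1)] += 1
        expected = n_reps / n_bins
        chi2 = float(np.sum((counts - expected) ** 2 / expected))
        critical = stats.chi2(n_bins - 1).ppf(0.99)
        assert chi2 < critical, f"rank histogram {counts} too far from uniform"


def _independent_ess(x):
    """Plain (non-rank-normalized) multi-chain autocorrelation ESS."""
    m, n = x.shape
    mean_c = x.mean(axis=1, keepdims=True)
    w = np.mean(x.var(axis=1, ddof=1))
    b = n * x.mean(axis=1).var(ddof=1) if m > 1 else 0.0
    var_plus = (n - 1) / n * w + b / n
    rho_sum = 0.0
    for lag in range(1, n // 2):
        acov = np.mean(
            [np.mean((x[c, :-lag] - mean_c[c]) * (x[c, lag:] - mean_c[c])) for c in range(m)]
        )
        rho = 1.0 - (w - acov) / var_plus
        if rho < 0.05:
            break
        rho_sum += rho
    return m * n / (1 + 2 * rho_sum)


class TestDiagnostics:
    def test_white_noise_ess_near_total(self):
        rng = np.random.default_rng(0)
        draws = rng.normal(size=(4, 2000))
        assert 0.8 * 8000 <= ess(draws) <= 1.2 * 8000

    def test_constant_chain_flagged_not_raised(self):
        draws = np.ones((4, 100))
        assert np.isnan(ess(draws))

    def test_ar1_ess_matches_analytic_limit(self):
        rho = 0.9
        rng = np.random.default_rng(1)
        draws = np.empty((4, 5000))
        for c in range(4):
            e = rng.normal(size=5000)
            x = np.zeros(5000)
            for t in range(1, 5000):
                x[t] = rho * x[t - 1] + e[t] * np.sqrt(1 - rho**2)
            draws[c] = x
        expected = 20000 * (1 - rho) / (1 + rho)
        assert ess(draws) == pytest.approx(expected, rel=0.3)

    def test_ess_agrees_with_independent_estimator(self):
        rng = np.random.default_rng(3)
        draws = rng.normal(size=(4, 3000))
        draws = draws + 0.5 * np.roll(draws, 1, axis=1)  # mild autocorrelation
        assert ess(draws) == pytest.approx(_independent_ess(draws), rel=0.15)

    def test_identical_chains_rhat_one(self):
        rng = np.random.default_rng(2)
        one = rng.normal(size=2000)
        draws = np.tile(one, (4, 1))
        assert rhat(draws) == pytest.approx(1.0, abs=2e-3)

    def test_disjoint_chains_rhat_large(self):
        rng = np.random.default_rng(4)
        draws = rng.normal(size=(2, 1000)) + np.array([[10.0], [-10.0]])
        assert rhat(draws) > 1.5

    def test_iid_chains_rhat_near_one(self):
        rng = np.random.default_rng(5)
        assert rhat(rng.normal(size=(4, 2000))) < 1.01

    def test_single_chain_rhat_raises(self):
        with pytest.raises(InsufficientDataError):
            rhat(np.random.default_rng(0).normal(size=(1, 100)))

    def test_bfmi_iid_energy_near_two(self):
        rng = np.random.default_rng(6)
        vals = bfmi(rng.normal(size=(4, 2000)))
        assert (vals > 0.75).all()
        assert vals == pytest.approx(2.0, rel=0.15)

    def test_bfmi_random_walk_energy_small(self):
        rng = np.random.default_rng(7)
        energy = np.cumsum(rng.normal(size=(2, 2000)), axis=1)
        assert (bfmi(energy) < 0.1).all()

    def test_bfmi_zero_variance_flagged(self):
        assert np.isnan(bfmi(np.array([[1.0, 1.0]]))).all()

    def test_bfmi_formula_direct(self):
        e = np.array([[1.0, 3.0, 2.0, 5.0]])
        expected = np.mean(np.diff(e[0]) ** 2) / np.var(e[0])
        assert bfmi(e)[0] == pytest.approx(expected)


class TestPriorPredictiveSummaries:
    def test_midpoint_quantile_convention(self):
        draws = np.arange(1, 101, dtype=float)
        q = prior_predictive_quantiles(draws, (0.05, 0.5, 0.95))
        assert q[1] == pytest.approx(50.5)

    def test_constant_draws(self):
        q = prior_predictive_quantiles(np.full(50, 3.3))
        assert np.allclose(q, 3.3)

    def test_quantiles_monotone(self):
        rng = np.random.default_rng(8)
        q = prior_predictive_quantiles(rng.normal(size=5000))
        assert q[0] <= q[1] <= q[2]


class TestKLDivergence:
    def test_self_divergence_near_zero(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=20000)
        assert kl_divergence(x, x) < 0.01

    def test_gaussian_shift_matches_closed_form(self):
        rng = np.random.default_rng(10)
        p = rng.normal(0, 1, 100000)
        q = rng.normal(1, 1, 100000)
        assert kl_divergence(p, q) == pytest.approx(0.5, abs=0.05)

    def test_nonnegative_even_with_disjoint_support(self):
        rng = np.random.default_rng(11)
        assert kl_divergence(rng.normal(0, 1, 5000), rng.normal(30, 1, 5000)) >= 0.0
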