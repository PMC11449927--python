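"""Joint densities of the two hierarchical models against independent oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.optimize import approx_fprime

from moodhrv.errors import EmptyInputError, ModelStructureError
from moodhrv.inference import kl_divergence, prior_predictive_quantiles
from moodhrv.models import (
    ModelParameters,
    ModelSpec,
    build_model,
    log_joint,
    prior_predictive,
    sample_prior,
    unconstrained_posterior,
)


def oracle_log_joint(spec, params, table):
    """Term-by-term scipy evaluation, one density call per parameter/observation."""
    total = stats.norm.logpdf(
        params.alpha0, spec.alpha0_prior_mean, spec.alpha0_prior_sd
    )
    for coef in (params.alpha1, params.alpha2, params.alpha3, params.beta2):
        total += stats.norm.logpdf(coef, spec.coef_prior_mean, spec.coef_prior_sd)
    for i in range(spec.n_subjects):
        mu0 = (
            params.alpha0
            + params.alpha1 * spec.age_std[i]
            + params.alpha2 * spec.sex[i]
            + params.alpha3 * spec.baseline_sev[i]
        )
        total += stats.norm.logpdf(params.beta0[i], mu0, spec.sd_beta0)
        total += stats.invgamma.logpdf(
            params.sigma[i], spec.sigma_shape, scale=spec.sigma_scale
        )
        if spec.variant == "two_polarities":
            total += stats.norm.logpdf(
                params.beta1[i], params.gamma[spec.polarity_idx[i]], spec.sd_beta1
            )
        else:
            total += stats.uniform.logpdf(params.beta1[i], -1, 2)
    if spec.variant == "two_polarities":
        for g in params.gamma:
            total += stats.uniform.logpdf(g, -1, 2)
    for _, row in table.iterrows():
        i = int(row["subject_index"])
        mu = (
            params.beta0[i]
            + params.beta1[i] * row["I"]
            + params.beta2 * row["M"]
        )
        total += stats.norm.logpdf(row["ln_rmssd"], mu, params.sigma[i])
    return float(total)


def random_params(spec, rng, variant):
    n = spec.n_subjects
    return ModelParameters(
        alpha0=float(rng.normal(3.6, 0.3)),
        alpha1=float(rng.normal(-0.1, 0.2)),
        alpha2=float(rng.normal(-0.1, 0.2)),
        alpha3=float(rng.normal(-0.1, 0.2)),
        beta2=float(rng.normal(-0.05, 0.1)),
        beta0=rng.normal(3.6, 0.5, n),
        beta1=rng.uniform(-0.9, 0.9, n),
        sigma=rng.uniform(0.05, 1.0, n),
        gamma=rng.uniform(-0.9, 0.9, 2) if variant == "two_polarities" else None,
    )


@pytest.fixture(scope="module", params=["one_disease", "two_polarities"])
def spec_and_table(request, default_table):
    return build_model(default_table, request.param), default_table


class TestBuildModel:
    def test_alpha0_centred_at_sample_mean(self, default_table):
        spec = build_model(default_table, "one_disease")
        assert spec.alpha0_prior_mean == pytest.approx(default_table["ln_rmssd"].mean())

    def test_constant_outcome_centres_prior_at_it(self, default_table):
        t = default_table.copy()
        t["ln_rmssd"] = 3.14
        assert build_model(t, "one_disease").alpha0_prior_mean == pytest.approx(3.14)

    def test_one_polarity_table_valid_for_one_disease_only(self, default_table):
        mania = default_table[default_table["polarity_index"] == 0].copy()
        mania["subject_index"] = pd.factorize(mania["subject_id"])[0]
        assert build_model(mania, "one_disease").variant == "one_disease"
        with pytest.raises(ModelStructureError):
            build_model(mania, "two_polarities")

    def test_empty_table_rejected(self):
        with pytest.raises(EmptyInputError):
            build_model(pd.DataFrame(), "one_disease")


class TestLogJoint:
    def test_matches_term_by_term_oracle(self, spec_and_table):
        spec, table = spec_and_table
        rng = np.random.default_rng(17)
        for _ in range(100):
            p = random_params(spec, rng, spec.variant)
            mine = log_joint(spec, p, table)
            theirs = oracle_log_joint(spec, p, table)
            assert mine == pytest.approx(theirs, rel=1e-8)

    def test_outside_support_is_minus_inf(self, default_table):
        spec = build_model(default_table, "two_polarities")
        p = random_params(spec, np.random.default_rng(0), "two_polarities")
        p.gamma = np.array([1.5, 0.0])
        assert log_joint(spec, p, default_table) == -np.inf
        spec1 = build_model(default_table, "one_disease")
        p1 = random_params(spec1, np.random.default_rng(0), "one_disease")
        p1.beta1[0] = 1.2
        assert log_joint(spec1, p1, default_table) == -np.inf
        p2 = random_params(spec1, np.random.default_rng(1), "one_disease")
        p2.sigma[0] = -0.1
        assert log_joint(spec1, p2, default_table) == -np.inf

    def test_observation_at_mode_adds_gaussian_peak_density(self, default_table):
        spec = build_model(default_table, "one_disease")
        rng = np.random.default_rng(3)
        p = random_params(spec, rng, "one_disease")
        base = log_joint(spec, p, default_table)
        extra = default_table.iloc[[0]].copy()
        i = int(extra["subject_index"].iloc[0])
        extra["ln_rmssd"] = p.beta0[i] + p.beta1[i] * extra["I"] + p.beta2 * extra["M"]
        bigger = pd.concat([default_table, extra], ignore_index=True)
        spec2 = build_model(bigger, "one_disease")
        # keep the data-dependent alpha0 centring identical for the comparison
        spec2.alpha0_prior_mean = spec.alpha0_prior_mean
        delta = log_joint(spec2, p, bigger) - base
        assert delta == pytest.approx(-math.log(p.sigma[i] * math.sqrt(2 * math.pi)))

    def test_polarity_label_symmetry(self, default_table):
        """Swapping polarity labels together with gamma components is a no-op."""
        spec = build_model(default_table, "two_polarities")
        flipped = default_table.copy()
        flipped["polarity_index"] = 1 - flipped["polarity_index"]
        spec_f = build_model(flipped, "two_polarities")
        rng = np.random.default_rng(5)
        for _ in range(10):
            p = random_params(spec, rng, "two_polarities")
            p_f = ModelParameters(**{**p.__dict__, "gamma": p.gamma[::-1].copy()})
            assert log_joint(spec, p, default_table) == pytest.approx(
                log_joint(spec_f, p_f, flipped), rel=1e-12
            )


class TestGradient:
    def test_analytic_gradient_matches_finite_differences(self, spec_and_table):
        spec, table = spec_and_table
        logp_grad, initial, _ = unconstrained_posterior(spec, table)
        rng = np.random.default_rng(11)
        for _ in range(5):
            x = initial(rng) + rng.normal(0, 0.3, size=initial(rng).size)
            _, g = logp_grad(x)
            g_num = approx_fprime(x, lambda v: logp_grad(v)[0], 1e-6)
            np.testing.assert_allclose(g, g_num, rtol=2e-4, atol=2e-4)

    def test_unconstrained_density_consistent_with_log_joint(self, spec_and_table):
        """logp minus the log-Jacobian equals the constrained joint density."""
        spec, table = spec_and_table
        logp_grad, initial, constrain = unconstrained_posterior(spec, table)
        rng = np.random.default_rng(2)
        x = initial(rng) + rng.normal(0, 0.2, size=initial(rng).size)
        lp, _ = logp_grad(x)
        v = constrain(x)
        params = ModelParameters(
            alpha0=float(v["alpha0"]), alpha1=float(v["alpha1"]),
            alpha2=float(v["alpha2"]), alpha3=float(v["alpha3"]),
            beta2=float(v["beta2"]), beta0=v["beta0"], beta1=v["beta1"],
            sigma=v["sigma"], gamma=v.get("gamma"),
        )
        n = spec.n_subjects
        log_jac = float(np.sum(np.log(v["sigma"])))
        if spec.variant == "one_disease":
            b = (v["beta1"] + 1) / 2
            log_jac += float(np.sum(np.log(2 * b * (1 - b))))
        else:
            g = (v["gamma"] + 1) / 2
            log_jac += float(np.sum(np.log(2 * g * (1 - g))))
        assert lp - log_jac == pytest.approx(log_joint(spec, params, table), rel=1e-10)


class TestSpecSerialization:
    def test_yaml_round_trip_preserves_density(self, default_table, tmp_path):
        from moodhrv.models import spec_from_yaml, spec_to_yaml

        spec = build_model(default_table, "two_polarities")
        spec_to_yaml(spec, tmp_path / "spec.yaml")
        back = spec_from_yaml(tmp_path / "spec.yaml")
        p = random_params(spec, np.random.default_rng(0), "two_polarities")
        assert log_joint(back, p, default_table) == pytest.approx(
            log_joint(spec, p, default_table), rel=1e-12
        )


class TestPriorSampling:
    def test_prior_moments(self, default_table):
        spec = build_model(default_table, "two_polarities")
        draws = sample_prior(spec, 20000, seed=1)
        assert abs(draws["gamma"].mean()) < 3 * math.sqrt(1 / 3) / math.sqrt(
            draws["gamma"].size
        )
        assert draws["alpha1"].std() == pytest.approx(0.1, rel=0.05)
        assert (draws["sigma"] > 0).all()
        # beta1 centred on its polarity's gamma draw
        resid = draws["beta1"] - draws["gamma"][:, spec.polarity_idx]
        assert resid.std() == pytest.approx(spec.sd_beta1, rel=0.05)

    def test_prior_predictive_bulk_in_physiological_range(self, default_table):
        spec = build_model(default_table, "one_disease")
        y = prior_predictive(spec, 4000, seed=2)
        q05, q50, q95 = prior_predictive_quantiles(y)
        assert 1.0 <= q05 <= q50 <= q95 <= 5.5

    def test_collapsed_prior_yields_deterministic_predictor(self, default_table):
        spec = build_model(default_table, "two_polarities")
        spec.alpha0_prior_sd = 0.0
        spec.coef_prior_sd = 0.0
        spec.sd_beta0 = 0.0
        spec.sd_beta1 = 0.0
        spec.sigma_scale = 0.0  # sigma draws collapse to zero noise
        spec.gamma_bounds = (0.2, 0.2)
        y = prior_predictive(spec, 3, seed=9)
        mu0 = (
            spec.alpha0_prior_mean
            + spec.coef_prior_mean
            * (spec.age_std + spec.sex + spec.baseline_sev)
        )
        expected = mu0[spec.subj_idx] + 0.2 * spec.improvement + (
            spec.coef_prior_mean * spec.medications
        )
        np.testing.assert_allclose(y, np.tile(expected, (3, 1)), atol=1e-12)

    def test_two_variants_have_similar_prior_predictives(self, default_table):
        a = prior_predictive(build_model(default_table, "two_polarities"), 5000, seed=3)
        b = prior_predictive(build_model(default_table, "one_disease"), 5000, seed=4)
        assert kl_divergence(a, b) < 0.05
        qa, qb = np.quantile(a, [0.05, 0.5, 0.95]), np.quantile(b, [0.05, 0.5, 0.95])
        np.testing.assert_allclose(qa, qb, atol=0.15)

    def test_prior_predictive_matches_independent_ancestral_sampler(self, default_table):
        """Distributional check against a brute-force re-derivation of the chain."""
        spec = build_model(default_table, "one_disease")
        mine = prior_predictive(spec, 4000, seed=5).ravel()
        rng = np.random.default_rng(123)
        rows = default_table.reset_index(drop=True)
        brute = []
        for _ in range(300):
            a0 = rng.normal(spec.alpha0_prior_mean, spec.alpha0_prior_sd)
            a1, a2, a3, b2 = rng.normal(-0.1, 0.1, 4)
            beta0 = rng.normal(
                a0
                + a1 * spec.age_std
                + a2 * spec.sex
                + a3 * spec.baseline_sev,
                spec.sd_beta0,
            )
            beta1 = rng.uniform(-1, 1, spec.n_subjects)
            sigma = 1.0 / rng.gamma(spec.sigma_shape, 1.0 / spec.sigma_scale, spec.n_subjects)
            for _, row in rows.iterrows():
                i = int(row["subject_index"])
                brute.append(
                    rng.normal(beta0[i] + beta1[i] * row["I"] + b2 * row["M"], sigma[i])
                )
        res = stats.ks_2samp(mine, np.asarray(brute))
        assert res.pvalue > 0.01
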