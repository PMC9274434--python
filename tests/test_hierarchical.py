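"""Hierarchical logistic model: structure, gradients, sampling, summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import approx_fprime

from dotlattice import DesignSpec, PopulationParams, simulate_cohort, to_binary_trials
from dotlattice.hierarchical import (
    ModelSpec,
    PriorConfig,
    SamplerConfig,
    build_model,
    fit,
    fixed_effect_summary,
    hdci,
    individual_effect_summaries,
)


def _main1(binary):
    return binary[(binary["task"] == "main") & (binary["session"] == 1)]


class TestModelStructure:
    def test_full_model_parameter_count(self, micro_binary):
        model = build_model(ModelSpec(), _main1(micro_binary))
        P = model.P
        # 3 fixed + 3 SDs + 3 correlation parameters + 3 deviations/participant
        assert model.n_params == 3 + 3 + 3 + 3 * P

    def test_random_not_subset_of_fixed_rejected(self):
        with pytest.raises(ValueError, match="random terms"):
            ModelSpec(fixed_terms=("intercept",), random_terms=("intercept", "r1"))

    def test_sign_constraint_on_absent_term_rejected(self):
        with pytest.raises(ValueError, match="absent term"):
            ModelSpec(fixed_terms=("intercept", "r1"), random_terms=("intercept",),
                      sign_constraint={"centered_ar": "positive"})

    def test_fully_correlated_shares_deviations(self, micro_binary):
        main = micro_binary[micro_binary["task"] == "main"]
        model = build_model(ModelSpec(sessions="joint_fully_correlated"), main)
        rng = np.random.default_rng(0)
        theta = rng.standard_normal(model.n_params)
        named = model.unpack(theta)
        # shared deviations: both sessions' individual effects differ only by
        # session-specific fixed effect and SD scaling; with equal raw SD
        # parameters, correlation across sessions is exactly one
        d1 = named["individual_r1_s1"] - named["beta_r1_s1"][..., None]
        d2 = named["individual_r1_s2"] - named["beta_r1_s2"][..., None]
        sd1, sd2 = named["sd_r1_s1"], named["sd_r1_s2"]
        np.testing.assert_allclose(d1 / sd1[..., None], d2 / sd2[..., None], rtol=1e-10)


class TestDensityAndGradient:
    @pytest.mark.parametrize(
        "spec",
        [
            ModelSpec(),
            ModelSpec(fixed_terms=("intercept", "centered_ar", "r1", "ar_by_r1"),
                      random_terms=("intercept", "centered_ar", "r1", "ar_by_r1")),
            ModelSpec(sign_constraint={"r1": "positive", "centered_ar": "positive"}),
            ModelSpec(random_terms=("intercept", "centered_ar")),
        ],
        ids=["full", "interaction", "positive", "common_hyst"],
    )
    def test_gradient_matches_finite_differences(self, micro_binary, spec):
        model = build_model(spec, _main1(micro_binary))
        rng = np.random.default_rng(1)
        theta = model.initial_value(rng)
        num = approx_fprime(theta, lambda t: model.logpost(t), 1e-6)
        ana = model.grad(theta)
        np.testing.assert_allclose(ana, num, rtol=1e-3, atol=1e-3)

    @pytest.mark.parametrize("mode", ["joint_uncorrelated", "joint_correlated",
                                      "joint_fully_correlated"])
    def test_joint_model_gradient(self, micro_binary, mode):
        main = micro_binary[micro_binary["task"] == "main"]
        model = build_model(ModelSpec(sessions=mode, session_effect="r1"), main)
        rng = np.random.default_rng(2)
        theta = model.initial_value(rng)
        num = approx_fprime(theta, lambda t: model.logpost(t), 1e-6)
        np.testing.assert_allclose(model.grad(theta), num, rtol=1e-3, atol=1e-3)

    def test_likelihood_symmetry_under_outcome_relabeling(self, micro_binary):
        """Relabeling y2 -> 1 - y2 while negating all linear-predictor terms
        leaves the log-likelihood unchanged."""
        data = _main1(micro_binary)
        flipped = data.assign(y2=1 - data["y2"])
        m1 = build_model(ModelSpec(), data)
        m2 = build_model(ModelSpec(), flipped)
        rng = np.random.default_rng(3)
        theta = rng.standard_normal(m1.n_params)
        theta2 = theta.copy()
        theta2[m1._slices["beta"]] *= -1.0
        theta2[m1._slices["u"]] *= -1.0
        assert m1.loglik(theta) == pytest.approx(m2.loglik(theta2), rel=1e-12)

    def test_sign_constrained_beta_has_the_sign(self, micro_binary):
        spec = ModelSpec(sign_constraint={"r1": "positive"})
        model = build_model(spec, _main1(micro_binary))
        rng = np.random.default_rng(4)
        theta = rng.standard_normal((50, model.n_params))
        named = model.unpack(theta)
        assert (named["beta_r1"] > 0).all()

    def test_prior_predictive_centered(self, micro_binary):
        model = build_model(ModelSpec(), _main1(micro_binary))
        rng = np.random.default_rng(5)
        p = model.prior_predictive_p(2000, rng)
        assert np.median(p) == pytest.approx(0.5, abs=0.05)

    def test_missing_session_named_in_error(self, micro_binary):
        main = micro_binary[micro_binary["task"] == "main"]
        drop = main[
            ~((main["participant"] == "p001") & (main["session"] == 2))
        ]
        with pytest.raises(ValueError, match="p001"):
            build_model(ModelSpec(sessions="joint_correlated", session_effect="r1"), drop)


class TestSampling:
    def test_same_seed_identical_draws(self, micro_binary):
        data = _main1(micro_binary)
        model = build_model(ModelSpec(), data)
        cfg = SamplerConfig(chains=1, iterations=120, seed=7)
        d1 = fit(model, cfg)
        d2 = fit(model, cfg)
        np.testing.assert_array_equal(d1.theta, d2.theta)

    def test_null_cohort_recovery(self, quick_sampler):
        """Population effects of zero are recovered within +-0.15."""
        pop = PopulationParams(mu_intercept=0.0, mu_hysteresis=0.0, mu_adaptation=0.0,
                               sd_intercept=0.1, sd_hysteresis=0.1, sd_adaptation=0.1,
                               rho_hyst_adapt=0.0, lapse_rate=0.0)
        spec = DesignSpec(n_participants=12, n_blocks=9, trials_per_block=70,
                          orientation_blocks=1, control_trials=0, seed=77, sessions=(1,))
        trials, _ = simulate_cohort(pop, spec)
        data = _main1(to_binary_trials(trials))
        draws = fit(build_model(ModelSpec(), data), quick_sampler)
        for term in ("intercept", "centered_ar", "r1"):
            assert abs(draws.flat(f"beta_{term}").mean()) < 0.15

    def test_no_pooling_limit_matches_single_level_fit(self, micro_binary):
        """With SD priors pinned near zero the fixed effects agree with an
        ordinary (single-level) logistic regression."""
        import statsmodels.api as sm

        data = _main1(micro_binary)
        spec = ModelSpec(prior_config=PriorConfig(fixed_scale=5.0, sd_scale=0.01))
        draws = fit(build_model(spec, data), SamplerConfig(chains=2, iterations=500, seed=8))
        X = sm.add_constant(np.column_stack([data["centered_ar"], data["r1"]]))
        glm = sm.GLM(data["y2"].to_numpy(float), X,
                     family=sm.families.Binomial()).fit()
        assert draws.flat("beta_intercept").mean() == pytest.approx(glm.params[0], abs=0.1)
        assert draws.flat("beta_centered_ar").mean() == pytest.approx(glm.params[1], abs=0.15)
        assert draws.flat("beta_r1").mean() == pytest.approx(glm.params[2], abs=0.1)


class TestSummaries:
    def test_hdci_matches_normal_quantiles(self):
        rng = np.random.default_rng(9)
        lo, hi = hdci(rng.normal(2.0, 0.1, size=1000), 0.95)
        assert lo == pytest.approx(1.804, abs=0.03)
        assert hi == pytest.approx(2.196, abs=0.03)

    def test_individual_summaries_shapes_and_errors(self, micro_fit):
        model, draws = micro_fit
        summ = individual_effect_summaries(draws, "r1")
        assert list(summ["participant"]) == model.participants
        assert (summ["hdci_low"] <= summ["mean"]).all()
        assert (summ["mean"] <= summ["hdci_high"]).all()
        with pytest.raises(ValueError, match="absent"):
            individual_effect_summaries(draws, "ar_by_r1")

    def test_common_effects_model_shares_summary(self, micro_binary):
        data = _main1(micro_binary)
        spec = ModelSpec(random_terms=("intercept", "centered_ar"))
        draws = fit(build_model(spec, data), SamplerConfig(chains=1, iterations=150, seed=10))
        summ = individual_effect_summaries(draws, "r1")
        assert summ["mean"].nunique() == 1
        fx = fixed_effect_summary(draws, "r1")
        assert summ["mean"].iloc[0] == pytest.approx(fx["mean"])

    def test_diagnostics_present(self, micro_fit):
        _, draws = micro_fit
        d = draws.diagnostics
        assert {"rhat_max", "ess_bulk_min", "divergence_fraction", "reliable"} <= set(d)
        assert d["rhat_max"] < 1.2  # short chains, loose sanity bound
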