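"""Bayes-factor estimators: analytic oracles, counting arithmetic, and the
sequential stopping rule."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

from dotlattice.comparison import (
    BetaBinomialToy,
    ConjugateRegression,
    NormalMeanToy,
    bridge_log_ml,
    correlation_bf,
    encompassing_bf,
    linear_vs_quadratic_bf,
    savage_dickey_onesided,
    sequential_rule,
)


class TestBridgeOracles:
    def test_normal_mean_toy_against_numeric_integration(self):
        rng = np.random.default_rng(20)
        y = rng.normal(0.3, 1.0, size=25)
        toy = NormalMeanToy(y, sigma0=1.0, tau=1.5)
        # independent oracle: brute-force quadrature over the mean
        # (narrow window around the posterior so quad resolves the peak)
        integrand = lambda mu: np.exp(toy.logpost(np.array([mu])))
        sd = math.sqrt(toy.post_var)
        evidence, _ = integrate.quad(
            integrand, toy.post_mean - 10 * sd, toy.post_mean + 10 * sd
        )
        assert toy.log_ml() == pytest.approx(math.log(evidence), abs=1e-6)
        ml, err = bridge_log_ml(toy.sample_posterior(4000, rng), toy.logpost, seed=1)
        assert ml == pytest.approx(toy.log_ml(), abs=0.05)

    def test_beta_binomial_toy(self):
        rng = np.random.default_rng(21)
        toy = BetaBinomialToy(k=13, n=20, a=2.0, b=1.0)
        integrand = lambda t: np.exp(toy.logpost(np.array([t])))
        evidence, _ = integrate.quad(integrand, -15, 15, limit=200)
        assert toy.log_ml() == pytest.approx(math.log(evidence), abs=1e-6)
        ml, _ = bridge_log_ml(toy.sample_posterior(4000, rng), toy.logpost, seed=2)
        assert ml == pytest.approx(toy.log_ml(), abs=0.05)

    def test_conjugate_regression_bridge_matches_closed_form(self):
        rng = np.random.default_rng(22)
        X = np.column_stack([np.ones(40), rng.normal(size=40)])
        y = X @ np.array([0.5, -1.0]) + rng.normal(0, 0.8, size=40)
        model = ConjugateRegression(X, y)
        ml, _ = bridge_log_ml(model.sample_posterior(4000, rng), model.logpost, seed=3)
        assert ml == pytest.approx(model.log_ml(), abs=0.05)

    def test_seed_consistency_within_mc_error(self):
        rng = np.random.default_rng(23)
        toy = NormalMeanToy(rng.normal(size=40), tau=2.0)
        draws = toy.sample_posterior(3000, rng)
        ml1, e1 = bridge_log_ml(draws, toy.logpost, seed=4)
        ml2, e2 = bridge_log_ml(draws, toy.logpost, seed=5)
        assert abs(ml1 - ml2) < 3.0 * math.hypot(max(e1, 1e-6), max(e2, 1e-6)) + 1e-4


class TestEncompassing:
    def _draws(self, n, n_ok, sign=1.0, seed=0):
        rng = np.random.default_rng(seed)
        out = -sign * np.abs(rng.normal(size=(n, 3))) - 0.1
        out[:n_ok] = sign * (np.abs(out[:n_ok]) + 0.1)
        return out

    def test_counting_arithmetic(self):
        post = self._draws(10_000, 200, seed=1)
        prior = self._draws(10_000, 5_000, seed=2)
        res = encompassing_bf(post, prior, "positive")
        assert math.exp(res.log_bf) == pytest.approx(0.04, rel=1e-9)
        assert res.favored == "unconstrained"

    def test_equals_independent_recount(self):
        rng = np.random.default_rng(3)
        post = rng.normal(0.5, 1.0, size=(5000, 4))
        prior = rng.normal(0.0, 1.0, size=(5000, 4))
        res = encompassing_bf(post, prior, "positive")
        # brute-force recount, written independently of the implementation
        p_post = sum(1 for row in post if min(row) > 0) / len(post)
        p_prior = sum(1 for row in prior if min(row) > 0) / len(prior)
        assert res.log_bf == pytest.approx(math.log(p_post / p_prior), abs=1e-12)

    def test_two_participant_prior_proportion_quarter(self):
        """Independent standard-normal effects: P(both positive) = 1/4, and
        using the prior as its own posterior gives BF = 1."""
        rng = np.random.default_rng(4)
        prior = rng.standard_normal((200_000, 2))
        p = (prior > 0).all(axis=1).mean()
        exact = stats.norm.sf(0) ** 2
        assert p == pytest.approx(exact, abs=0.005)
        res = encompassing_bf(prior[:100_000], prior[100_000:], "positive")
        assert res.log_bf == pytest.approx(0.0, abs=0.05)

    def test_all_positive_posterior_hits_upper_bound_region(self):
        rng = np.random.default_rng(5)
        post = np.abs(rng.standard_normal((2000, 2))) + 0.01
        prior = rng.standard_normal((20_000, 2))
        res = encompassing_bf(post, prior, "positive")
        assert math.exp(res.log_bf) == pytest.approx(4.0, rel=0.1)

    def test_zero_posterior_count_reports_bound(self):
        post = -np.ones((1000, 2))
        prior = np.random.default_rng(6).standard_normal((1000, 2))
        res = encompassing_bf(post, prior, "positive")
        assert res.is_bound
        assert res.log_bf < 0

    def test_zero_prior_count_raises(self):
        post = np.ones((100, 2))
        prior = -np.ones((100, 2))
        with pytest.raises(ValueError, match="prior"):
            encompassing_bf(post, prior, "positive")

    def test_negative_constraint(self):
        rng = np.random.default_rng(7)
        post = -np.abs(rng.standard_normal((4000, 2))) - 0.01
        prior = rng.standard_normal((4000, 2))
        res = encompassing_bf(post, prior, "negative")
        assert res.favored == "constrained"


class TestSavageDickey:
    def test_posterior_odds_arithmetic(self):
        draws = np.concatenate([np.ones(999), -np.ones(1)])
        res = savage_dickey_onesided(draws, direction="positive")
        assert math.exp(res.log_bf) == pytest.approx(999.0, rel=1e-9)

    def test_indifference(self):
        draws = np.concatenate([np.ones(500), -np.ones(500)])
        res = savage_dickey_onesided(draws, direction="positive")
        assert res.log_bf == pytest.approx(0.0, abs=1e-12)

    def test_one_sided_bound_not_infinite(self):
        res = savage_dickey_onesided(np.ones(2000), direction="positive")
        assert res.is_bound and math.isfinite(res.log_bf)
        assert math.exp(res.log_bf) == pytest.approx(2000.0)

    def test_asymmetric_prior_mass(self):
        draws = np.concatenate([np.ones(750), -np.ones(250)])
        res = savage_dickey_onesided(draws, prior_mass_positive=0.75, direction="positive")
        assert res.log_bf == pytest.approx(0.0, abs=1e-12)


class TestCorrelationBF:
    def test_strong_positive_correlation(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal(70)
        y = 0.7 * x + math.sqrt(1 - 0.49) * rng.standard_normal(70)
        res, summ = correlation_bf(x, y, "positive")
        assert math.exp(res.log_bf) > 100.0
        assert summ["hdci_low"] < summ["r_mean"] < summ["hdci_high"]

    def test_null_near_indifference(self):
        rng = np.random.default_rng(9)
        bfs = []
        for _ in range(20):
            x, y = rng.standard_normal((2, 40))
            res, _ = correlation_bf(x, y, "positive")
            bfs.append(res.log_bf)
        assert abs(np.mean(bfs)) < 1.0  # centered near log BF = 0 over replicates

    def test_direction_mirror(self):
        rng = np.random.default_rng(10)
        x = rng.standard_normal(30)
        y = -0.5 * x + rng.standard_normal(30)
        pos, _ = correlation_bf(x, y, "positive")
        neg, _ = correlation_bf(x, y, "negative")
        assert pos.log_bf == pytest.approx(-neg.log_bf, abs=1e-9)

    def test_identical_vectors_at_bound(self):
        x = np.arange(20.0)
        res, _ = correlation_bf(x, x + 0.0, "positive")
        assert res.is_bound


class TestLinearVsQuadratic:
    def test_detects_curvature(self):
        rng = np.random.default_rng(11)
        x = rng.uniform(-2, 2, size=80)
        y_quad = 1.0 + 0.2 * x + 1.5 * x**2 + rng.normal(0, 0.5, size=80)
        res = linear_vs_quadratic_bf(x, y_quad, seed=1)
        assert res.favored == "quadratic"
        y_lin = 1.0 + 1.2 * x + rng.normal(0, 0.5, size=80)
        res2 = linear_vs_quadratic_bf(x, y_lin, seed=1)
        assert res2.favored == "linear"


class TestSequentialRule:
    def _stream(self, values_by_n):
        return [(n, bfs) for n, bfs in values_by_n]

    def test_immediate_stop(self):
        d = sequential_rule([(30, (7.0, 8.0, 9.0, 10.0))])
        assert d.decision == "stop_threshold" and d.n == 30

    def test_runs_to_max_n(self):
        stream = [(n, (7.0, 2.0, 8.0, 0.1)) for n in range(30, 80, 5)]
        d = sequential_rule(stream)
        assert d.decision == "stop_max_n" and d.n == 75

    def test_stops_when_first_decisive(self):
        # straddling until 50, decisive at 55 (the study's stopping point)
        stream = [(n, (8.0, 3.0, 0.1, 6.5)) for n in range(30, 55, 5)]
        stream += [(55, (9.0, 6.2, 0.08, 7.0)), (60, (9.0, 6.2, 0.08, 7.0))]
        d = sequential_rule(stream)
        assert d.decision == "stop_threshold" and d.n == 55

    def test_lower_threshold_counts_as_decisive(self):
        d = sequential_rule([(30, (1 / 7.0, 0.1, 6.1, 12.0))])
        assert d.decision == "stop_threshold"

    def test_unordered_stream_rejected(self):
        with pytest.raises(ValueError, match="unordered"):
            sequential_rule([(30, (1.0,)), (40, (1.0,))])
        with pytest.raises(ValueError, match="start"):
            sequential_rule([(35, (1.0,))])


class TestBayesFactorAlgebra:
    def test_antisymmetry_and_transitivity(self):
        """log BF(a,b) = -log BF(b,a) and log BF(a,c) = log BF(a,b) +
        log BF(b,c) hold exactly for bridge-estimated marginal likelihoods."""
        rng = np.random.default_rng(12)
        mls = []
        for tau in (0.5, 1.0, 2.0):
            toy = NormalMeanToy(rng.normal(size=30), tau=tau)
            ml, _ = bridge_log_ml(toy.sample_posterior(2000, rng), toy.logpost, seed=6)
            mls.append(ml)
        ab, bc, ac = mls[0] - mls[1], mls[1] - mls[2], mls[0] - mls[2]
        assert ab == pytest.approx(-(mls[1] - mls[0]), abs=1e-12)
        assert ac == pytest.approx(ab + bc, abs=1e-12)
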