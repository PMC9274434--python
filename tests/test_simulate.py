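"""Synthetic-observer generator: design balance, determinism, response rules,
and recovery of its own parameters."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from dotlattice import DesignSpec, PopulationParams, simulate_cohort
from dotlattice.circular import orientation_vector
from dotlattice.simulate import (
    draw_participants,
    l1_probability,
    l2_probability,
    make_design,
    simulate_l1,
    simulate_l2,
    simulate_orientation_task,
)


class TestDesign:
    def test_default_block_balance(self):
        spec = DesignSpec(n_participants=2, seed=1)
        design = make_design(spec)
        per = design.groupby(["participant", "aspect_ratio"]).size()
        assert (per == 90).all()  # 10 per block x 9 blocks
        per_block = design.groupby(["participant", "block", "aspect_ratio"]).size()
        assert (per_block == 10).all()
        assert design["base_orientation"].between(0, 89).all()

    def test_one_trial_per_ar(self):
        spec = DesignSpec(n_participants=1, n_blocks=1, trials_per_block=7, seed=2)
        design = make_design(spec)
        assert design.groupby("aspect_ratio").size().eq(1).all()

    def test_indivisible_trials_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            DesignSpec(trials_per_block=71)

    def test_same_seed_same_design(self):
        a = make_design(DesignSpec(n_participants=2, seed=9))
        b = make_design(DesignSpec(n_participants=2, seed=9))
        pd.testing.assert_frame_equal(a, b)


class TestParticipantDraws:
    def test_zero_sds_collapse_to_means(self):
        pop = PopulationParams(sd_intercept=0, sd_hysteresis=0, sd_adaptation=0,
                               sd_proximity=0, rho_hyst_adapt=0, rho_session=0)
        eff = draw_participants(pop, DesignSpec(n_participants=5, seed=3))
        assert np.allclose(eff["hysteresis"], pop.mu_hysteresis)
        assert np.allclose(eff["adaptation"], pop.mu_adaptation)

    def test_full_session_correlation_shares_effects(self):
        pop = PopulationParams(rho_session=1.0)
        eff = draw_participants(pop, DesignSpec(n_participants=6, seed=4))
        wide = eff.pivot(index="participant", columns="session", values="adaptation")
        assert np.allclose(wide[1], wide[2])

    def test_hysteresis_adaptation_correlation_recovered(self):
        pop = PopulationParams(rho_hyst_adapt=0.7)
        eff = draw_participants(pop, DesignSpec(n_participants=10_000, seed=5))
        s1 = eff[eff["session"] == 1]
        r = np.corrcoef(s1["hysteresis"], s1["adaptation"])[0, 1]
        assert r == pytest.approx(0.7, abs=0.03)

    def test_invalid_correlation_matrix_rejected(self):
        pop = PopulationParams(rho_hyst_adapt=0.99,
                               rho_session={"hysteresis": 0.99, "adaptation": -0.99,
                                            "intercept": 0, "proximity": 0})
        with pytest.raises(ValueError, match="positive semidefinite"):
            draw_participants(pop, DesignSpec(n_participants=2, seed=6))


class TestResponseRules:
    def test_l1_probability_formula(self):
        # strong proximity at the flattest aspect ratio
        assert l1_probability(1 / 1.3 - 1, 0.0, -8.0) == pytest.approx(
            expit(-8.0 * (1 / 1.3 - 1)), abs=1e-12
        )
        assert l1_probability(0.0, 0.0, -8.0) == pytest.approx(0.5)

    def test_l2_probability_formula(self):
        p = l2_probability(0.0, 1.0, intercept=-1.0, hysteresis=2.3, adaptation=2.0)
        assert p == pytest.approx(expit(1.3), abs=1e-12)
        # flipping the previous percept moves the log odds by exactly the
        # hysteresis coefficient
        p0 = l2_probability(0.2, 0.0, -1.0, 2.3, 2.0)
        p1 = l2_probability(0.2, 1.0, -1.0, 2.3, 2.0)
        assert np.log(p1 / (1 - p1)) - np.log(p0 / (1 - p0)) == pytest.approx(2.3)

    def test_null_observer_is_indifferent(self):
        p = l2_probability(0.37, 1.0, 0.0, 0.0, 0.0)
        assert p == pytest.approx(0.5)

    def test_lapse_boundaries(self):
        rng = np.random.default_rng(0)
        eff = {"proximity": -8.0, "hysteresis": 2.0, "adaptation": 2.0, "intercept": 0.0}
        all_lapse = PopulationParams(lapse_rate=1.0)
        out = simulate_l1(np.zeros(200), eff, all_lapse, rng)
        assert set(out) <= {"diag1", "diag2"}
        out2 = simulate_l2(np.zeros(200), np.ones(200), eff, all_lapse, rng)
        assert set(out2) <= {"deg60", "deg120", "deg90"}
        no_lapse = PopulationParams(lapse_rate=0.0)
        out3 = simulate_l1(np.zeros(200), eff, no_lapse, rng)
        assert set(out3) <= {"deg0", "deg90"}

    def test_determinism(self):
        pop = PopulationParams()
        spec = DesignSpec(n_participants=2, n_blocks=1, trials_per_block=14, seed=7)
        a, ea = simulate_cohort(pop, spec)
        b, eb = simulate_cohort(pop, spec)
        pd.testing.assert_frame_equal(a, b)
        pd.testing.assert_frame_equal(ea, eb)


class TestOrientationTask:
    def _effects(self, kappa, direction):
        return pd.DataFrame(
            [{"participant": "p001", "session": 1, "intercept": 0.0, "hysteresis": 0.0,
              "adaptation": 0.0, "proximity": 0.0, "bias_concentration": kappa,
              "bias_direction": direction}]
        )

    def test_flat_bias_equiprobable(self):
        spec = DesignSpec(n_participants=1, orientation_blocks=50, seed=8)
        pop = PopulationParams(lapse_rate=0.0)
        out = simulate_orientation_task(self._effects(0.0, 0.0), pop, spec, seed=8)
        props = out["l2_response"].value_counts(normalize=True)
        assert props.max() < 0.36 and props.min() > 0.30  # 3000 trials

    def test_strong_bias_recovers_direction(self):
        spec = DesignSpec(n_participants=1, orientation_blocks=170, seed=9)  # ~10,200 trials
        pop = PopulationParams(lapse_rate=0.0)
        out = simulate_orientation_task(self._effects(1.5, 0.0), pop, spec, seed=9)
        offsets = out["l2_response"].map({"deg0": 0, "deg60": 60, "deg120": 120})
        thetas = (out["base_orientation"] + offsets) % 180
        L, direction = orientation_vector(thetas.to_numpy())
        dist = min(direction, 180 - direction)  # axial distance from 0
        assert dist < 3.0
        assert L > 20.0

    def test_infinite_concentration_always_nearest(self):
        spec = DesignSpec(n_participants=1, orientation_blocks=2, seed=10)
        pop = PopulationParams(lapse_rate=0.0)
        out = simulate_orientation_task(self._effects(200.0, 90.0), pop, spec, seed=10)
        offsets = out["l2_response"].map({"deg0": 0, "deg60": 60, "deg120": 120})
        chosen = (out["base_orientation"] + offsets) % 180
        # chosen axis must be the candidate closest (axially) to 90 degrees
        for base, c in zip(out["base_orientation"], chosen):
            cands = (base + np.array([0, 60, 120])) % 180
            d = np.abs(((cands - 90 + 90) % 180) - 90)
            d_chosen = d[list(cands).index(c)]
            assert d_chosen == pytest.approx(d.min())  # ties allowed


class TestSingleLevelRecovery:
    def test_glm_crosscheck_on_one_participant(self):
        """An off-the-shelf logistic fit on >=50k simulated trials recovers the
        generating hysteresis and adaptation within 0.05 logits."""
        import statsmodels.api as sm

        rng = np.random.default_rng(11)
        n = 60_000
        car = rng.choice(np.asarray(DesignSpec().aspect_ratios) - 1.0, size=n)
        eff = {"intercept": -1.0, "hysteresis": 2.3, "adaptation": 2.0, "proximity": -8.0}
        pop = PopulationParams(lapse_rate=0.0)
        l1 = simulate_l1(car, eff, pop, rng)
        r1 = (l1 == "deg0").astype(float)
        l2 = simulate_l2(car, r1, eff, pop, rng)
        y = (l2 == "deg0").astype(float)
        X = sm.add_constant(np.column_stack([car, r1]))
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        assert res.params[1] == pytest.approx(2.0, abs=0.05)  # adaptation
        assert res.params[2] == pytest.approx(2.3, abs=0.05)  # hysteresis
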