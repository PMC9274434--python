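# dotlattice

Analysis pipeline for **individual differences in hysteresis and adaptation
in multistable dot-lattice perception**, for psychophysicists and
computational cognition researchers studying serial dependence.

## The problem

An ambiguous dot lattice can be perceived as organized along several
orientations. When lattices are shown in sequence, the current percept is
pulled in two opposite directions by temporal context:

* **Hysteresis** (attraction): the orientation *perceived* in the previous
  lattice is more likely to be perceived again.
* **Adaptation** (repulsion): the orientation *supported by the previous
  stimulus* (its aspect ratio |a|/|b|) is less likely to be perceived.

Because both effects act on the same response, they can only be separated
by modeling them jointly at the trial level. The paradigm shows a
rectangular lattice L1 whose aspect ratio AR biases its percept (0° vs.
90°), then an ambiguous hexagonal lattice L2 (0°/60°/120°); each is
reported with a 4-AFC response. Restricting analysis to the alternatives
that are equally likely at AR = 1 gives a binary percept per lattice.

## The model

The percept of the second lattice is a Bernoulli multilevel logistic
regression with random intercepts and random slopes per participant *i*:

```
Y_ijkl ~ Bernoulli(p_ijkl)
logit(p_ijkl) = beta_0 + beta_AR * AR_c + beta_R1 * R1_0
              + b_i0   + b_iAR  * AR_c + b_iR1  * R1_0
```

where `AR_c` is the centered aspect ratio of L1 (0 at AR = 1), `R1_0`
indicates that L1 was perceived at 0°, `beta_R1` is the population
hysteresis effect, `beta_AR` the population adaptation effect, and the
`b_i` are individual deviations with estimated SDs and a full correlation
matrix. Hypotheses are compared with Bayes factors: bridge-sampled
marginal likelihoods for non-nested variants (no-effect, common-effects,
interaction, session-correlation families), the encompassing approach for
"everyone shows the effect" order constraints, and Savage–Dickey ratios
for one-sided correlation tests. Absolute orientation biases are
summarized by the axial mean resultant vector (magnitude `L` in percent,
direction in degrees, computed on doubled angles).

Inference is Hamiltonian Monte Carlo on the unconstrained parameter space,
written in-package with analytic gradients over binomial cell aggregates
(see `docs/methods.md` for priors, transforms and numerical choices).

## Worked example

Simulate a small cohort with the canonical generative parameters
(population hysteresis 2.3, adaptation 2.0 logits, individual SDs 1.0,
hysteresis–adaptation correlation 0.7), fit the full model, and summarize:

```python
import numpy as np
from dotlattice import (DesignSpec, ModelSpec, PopulationParams, SamplerConfig,
                        build_model, fit, simulate_cohort, to_binary_trials,
                        fixed_effect_summary, savage_dickey_onesided)

pop = PopulationParams()                      # hysteresis 2.3, adaptation 2.0 (logits)
spec = DesignSpec(n_participants=12, n_blocks=3, trials_per_block=35, seed=7)
trials, effects = simulate_cohort(pop, spec)
print(f"simulated {len(trials)} trials for {spec.n_participants} participants")

binary = to_binary_trials(trials)
main1 = binary.query("task == 'main' and session == 1")
print(f"{len(main1)} binary main-task trials kept in session 1")

draws = fit(build_model(ModelSpec(), main1), SamplerConfig(chains=2, iterations=700, seed=7))
for label, term in (("hysteresis", "r1"), ("adaptation", "centered_ar")):
    s = fixed_effect_summary(draws, term)
    print(f"{label:<11} mean {s['mean']:.2f}  95% HDCI [{s['hdci_low']:.2f}, {s['hdci_high']:.2f}]")
corr = draws.flat("corr_centered_ar_r1")
bf = savage_dickey_onesided(corr, direction="positive")
print(f"hysteresis-adaptation correlation: mean {corr.mean():.2f}, "
      f"BF(r>0) = {np.exp(bf.log_bf):.0f}")
```

Output:

```
simulated 9360 trials for 12 participants
1076 binary main-task trials kept in session 1
hysteresis  mean 1.93  95% HDCI [1.40, 2.30]
adaptation  mean 1.41  95% HDCI [0.43, 2.29]
hysteresis-adaptation correlation: mean 0.13, BF(r>0) = 1
```

Both context effects are recovered with the expected sign (the generating
values 2.3 and 2.0 lie inside or near the wide small-sample intervals);
twelve participants are far too few to resolve the individual-effect
correlation, so its Bayes factor is indifferent — the full-scale design
uses 75 participants with 630 trials each.

The complete hypothesis battery (H1–H10 plus exploratory proximity
analyses) runs as a pipeline:

```sh
dotlattice replica --seed 1 --out-dir out/
```

which writes `report.json`, `manifest.json` and the figure families
(logit-vs-aspect-ratio lines split by previous percept, individual-effect
forest plots, effect–effect scatters with HDCI bars, orientation-bias
polar plots, cross-session scatters).

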