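"""Shared fixtures: small simulated cohorts and scaled-down sampler settings."""

import numpy as np
import pytest

from dotlattice import (
    DesignSpec,
    ModelSpec,
    PopulationParams,
    SamplerConfig,
    build_model,
    fit,
    simulate_cohort,
    to_binary_trials,
)


@pytest.fixture(scope="session")
def micro_cohort():
    """Lapse-free 8-participant cohort, 105 main trials per session."""
    pop = PopulationParams(lapse_rate=0.0)
    spec = DesignSpec(n_participants=8, n_blocks=3, trials_per_block=35,
                      orientation_blocks=2, control_trials=60, seed=101)
    trials, effects = simulate_cohort(pop, spec)
    return {"pop": pop, "spec": spec, "trials": trials, "effects": effects}


@pytest.fixture(scope="session")
def micro_binary(micro_cohort):
    binary = to_binary_trials(micro_cohort["trials"])
    return binary


@pytest.fixture(scope="session")
def quick_sampler():
    return SamplerConfig(chains=2, iterations=500, seed=42)


@pytest.fixture(scope="session")
def micro_fit(micro_binary, quick_sampler):
    """Full L2 model fitted once on the micro cohort (session 1)."""
    main1 = micro_binary[(micro_binary["task"] == "main") & (micro_binary["session"] == 1)]
    model = build_model(ModelSpec(), main1)
    return model, fit(model, quick_sampler)
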