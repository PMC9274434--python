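"""Synthetic observers for the dot-lattice serial-dependence paradigm.

Generates the full experimental design (main, control, and
absolute-orientation-bias tasks over two sessions) and simulates 4-AFC
responses with the statistical structure the downstream analysis assumes:

* L1 percept: Bernoulli on {0°, 90°} with logit ``P(0°) = intercept_l1 +
  proximity * centered_ar`` — proximity is negative for the canonical
  observer (closer dots along an orientation favor grouping along it).
* L2 percept: Bernoulli on {0°, not-0°} with logit ``P(0°) = intercept +
  adaptation * centered_ar + hysteresis * r1``; hysteresis attracts toward
  the previous percept, adaptation repels from the previous stimulus
  evidence.
* Lapses: with probability ``lapse_rate`` the response is drawn uniformly
  from the non-dominant options (the two diagonals for L1; 60°/120°/90°
  for L2), emulating occasional random responding.
* Absolute orientation bias: hexagonal-lattice responses weighted by an
  axial von-Mises-type kernel ``exp(kappa * cos(2*(theta - mu)))``.

Individual effects are drawn from a multivariate normal whose correlation
structure couples hysteresis with adaptation within a session and each
effect with itself across sessions.  The generator's defaults are the
replica study conditions: 75 participants, 9 blocks x 70 main trials with
7 aspect ratios, a 90-trial control task, and a 240-trial orientation task
per session.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .trial_io import CSV_COLUMNS, DESIGN_ASPECT_RATIOS

__all__ = [
    "PopulationParams",
    "DesignSpec",
    "EFFECT_NAMES",
    "make_design",
    "draw_participants",
    "simulate_l1",
    "simulate_l2",
    "simulate_main_task",
    "simulate_control_task",
    "simulate_orientation_task",
    "simulate_cohort",
    "l1_probability",
    "l2_probability",
    "write_truth",
]

EFFECT_NAMES = ("intercept", "hysteresis", "adaptation", "proximity")


def _logistic(x):
    return 0.5 * (1.0 + np.tanh(0.5 * np.asarray(x, dtype=float)))


def l1_probability(centered_ar, intercept_l1: float, proximity: float):
    """P(L1 perceived at 0° | no lapse) = logistic(intercept_l1 + proximity * centered_ar)."""
    return _logistic(intercept_l1 + proximity * np.asarray(centered_ar, dtype=float))


def l2_probability(centered_ar, r1, intercept: float, hysteresis: float, adaptation: float):
    """P(L2 perceived at 0° | no lapse) = logistic(intercept + adaptation*AR_c + hysteresis*r1)."""
    eta = (
        intercept
        + adaptation * np.asarray(centered_ar, dtype=float)
        + hysteresis * np.asarray(r1, dtype=float)
    )
    return _logistic(eta)


@dataclass(frozen=True)
class PopulationParams:
    """Generative population for individual context effects (logit units).

    Means/SDs parameterize the multivariate-normal distribution of
    individual total effects.  ``rho_hyst_adapt`` correlates hysteresis and
    adaptation within a session; ``rho_session`` (scalar or per-effect map)
    correlates each effect with itself across sessions.  The hysteresis and
    adaptation means sit inside the ranges estimated for human observers in
    this paradigm; proximity is strongly negative (logit per unit aspect
    ratio); the lapse rate matches the observed share of non-dominant
    responses.
    """

    mu_intercept: float = -1.1
    mu_hysteresis: float = 2.3
    mu_adaptation: float = 2.0
    mu_proximity: float = -8.0
    sd_intercept: float = 0.7
    sd_hysteresis: float = 1.0
    sd_adaptation: float = 1.0
    sd_proximity: float = 2.0
    rho_hyst_adapt: float = 0.7
    rho_session: float | Mapping[str, float] = 0.8
    lapse_rate: float = 0.1
    intercept_l1: float = 0.0
    bias_concentration: float = 1.5
    bias_direction: float = 90.0
    bias_direction_spread: float = 30.0  # axial SD (deg) of individual preferred orientations
    sd_log_bias: float = 0.6  # lognormal spread of individual bias concentrations
    rho_bias_hysteresis: float = 0.0  # couples log-concentration to the hysteresis latent
    control_carryover: float = 0.95  # decisional hysteresis in the control task (logits)

    def rho_session_map(self) -> dict[str, float]:
        if isinstance(self.rho_session, Mapping):
            out = {e: float(self.rho_session.get(e, 0.0)) for e in EFFECT_NAMES}
        else:
            out = {e: float(self.rho_session) for e in EFFECT_NAMES}
        return out

    def mean(self, effect: str) -> float:
        return getattr(self, f"mu_{effect}")

    def sd(self, effect: str) -> float:
        return getattr(self, f"sd_{effect}")


@dataclass(frozen=True)
class DesignSpec:
    """Counts and levels of the replica experimental design."""

    n_participants: int = 75
    n_blocks: int = 9
    trials_per_block: int = 70
    aspect_ratios: tuple[float, ...] = DESIGN_ASPECT_RATIOS
    orientation_range: tuple[int, int] = (1, 60)
    seed: int = 0
    control_trials: int = 90
    orientation_blocks: int = 4
    sessions: tuple[int, ...] = (1, 2)

    def __post_init__(self):
        if self.trials_per_block % len(self.aspect_ratios) != 0:
            raise ValueError(
                f"trials_per_block={self.trials_per_block} not divisible by "
                f"{len(self.aspect_ratios)} aspect ratios"
            )

    @property
    def main_trials_per_session(self) -> int:
        return self.n_blocks * self.trials_per_block

    @property
    def orientation_trials_per_session(self) -> int:
        lo, hi = self.orientation_range
        return self.orientation_blocks * (hi - lo + 1)


def _participant_ids(n: int) -> list[str]:
    return [f"p{i + 1:03d}" for i in range(n)]


def make_design(spec: DesignSpec, session: int = 1) -> pd.DataFrame:
    """Main-task trial skeletons for every participant in one session.

    Within each block every aspect ratio occurs ``trials_per_block /
    n_aspect_ratios`` times in a seeded-shuffled order; the base (0°-)
    orientation of each trial is drawn uniformly over 0-89° in 1° steps.
    Response columns are left empty.  Deterministic for a fixed spec seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 11, session]))
    reps = spec.trials_per_block // len(spec.aspect_ratios)
    block_template = np.repeat(np.asarray(spec.aspect_ratios, dtype=float), reps)
    rows = []
    for pid in _participant_ids(spec.n_participants):
        for block in range(1, spec.n_blocks + 1):
            ars = rng.permutation(block_template)
            bases = rng.integers(0, 90, size=spec.trials_per_block)
            for t, (ar, base) in enumerate(zip(ars, bases), start=1):
                rows.append((pid, session, "main", block, t, ar, int(base), "", "", ""))
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def _session_correlation_matrix(pop: PopulationParams) -> np.ndarray:
    """8x8 correlation of (4 effects) x (2 sessions).

    Within-session: hysteresis-adaptation = rho_hyst_adapt, others
    uncorrelated.  Across sessions: each effect with itself at its own
    rho_session; cross terms filled by the product path
    rho_hyst_adapt * sqrt(rho_hyst * rho_adapt).
    """
    rho_s = pop.rho_session_map()
    k = len(EFFECT_NAMES)
    corr = np.eye(2 * k)
    ih, ia = EFFECT_NAMES.index("hysteresis"), EFFECT_NAMES.index("adaptation")
    for s in range(2):
        o = s * k
        corr[o + ih, o + ia] = corr[o + ia, o + ih] = pop.rho_hyst_adapt
    for e, name in enumerate(EFFECT_NAMES):
        corr[e, k + e] = corr[k + e, e] = rho_s[name]
    cross = pop.rho_hyst_adapt * np.sqrt(
        max(rho_s["hysteresis"], 0.0) * max(rho_s["adaptation"], 0.0)
    )
    corr[ih, k + ia] = corr[k + ia, ih] = cross
    corr[ia, k + ih] = corr[k + ih, ia] = cross
    return corr


def draw_participants(
    pop: PopulationParams, spec: DesignSpec, seed: int | None = None
) -> pd.DataFrame:
    """Draw individual true effects for every participant x session.

    Multivariate normal with the population means, SDs and correlations;
    raises on a non-positive-semidefinite implied covariance.  Also draws
    each individual's orientation-bias concentration (lognormal around the
    population value, optionally coupled to the hysteresis latent) and
    preferred direction (axial normal spread around the population
    direction).
    """
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([seed, 23]))
    corr = _session_correlation_matrix(pop)
    sds = np.array([pop.sd(e) for e in EFFECT_NAMES] * 2, dtype=float)
    cov = corr * np.outer(sds, sds)
    eig = np.linalg.eigvalsh(corr)
    if eig.min() < -1e-9:
        raise ValueError(
            f"implied effect correlation matrix is not positive semidefinite "
            f"(min eigenvalue {eig.min():.3g}); check rho_hyst_adapt / rho_session"
        )
    means = np.array([pop.mean(e) for e in EFFECT_NAMES] * 2, dtype=float)
    n = spec.n_participants
    draws = rng.multivariate_normal(means, cov, size=n, method="eigh")
    pids = _participant_ids(n)

    # orientation-bias individual parameters (session-stable)
    sd_h = pop.sd_hysteresis
    hyst_latent = (
        (draws[:, EFFECT_NAMES.index("hysteresis")] - pop.mu_hysteresis) / sd_h
        if sd_h > 0
        else np.zeros(n)
    )
    z_indep = rng.standard_normal(n)
    r = float(np.clip(pop.rho_bias_hysteresis, -1.0, 1.0))
    z_bias = r * hyst_latent + np.sqrt(max(1.0 - r * r, 0.0)) * z_indep
    kappa = pop.bias_concentration * np.exp(pop.sd_log_bias * z_bias)
    directions = (
        pop.bias_direction + pop.bias_direction_spread * rng.standard_normal(n)
    ) % 180.0

    rows = []
    for i, pid in enumerate(pids):
        for s_idx, session in enumerate(spec.sessions):
            o = s_idx * len(EFFECT_NAMES)
            rows.append(
                {
                    "participant": pid,
                    "session": session,
                    **{e: draws[i, o + j] for j, e in enumerate(EFFECT_NAMES)},
                    "bias_concentration": float(kappa[i]),
                    "bias_direction": float(directions[i]),
                }
            )
    return pd.DataFrame(rows)


def simulate_l1(centered_ar, effects_row, pop: PopulationParams, rng) -> np.ndarray:
    """L1 responses for main-task trials of one participant x session.

    With probability ``lapse_rate`` the response is a uniform diagonal;
    otherwise Bernoulli on {deg0, deg90} with
    ``logit P(deg0) = intercept_l1 + proximity * centered_ar``.
    """
    car = np.asarray(centered_ar, dtype=float)
    p0 = l1_probability(car, pop.intercept_l1, float(effects_row["proximity"]))
    resp = np.where(rng.random(car.shape) < p0, "deg0", "deg90").astype(object)
    lapse = rng.random(car.shape) < pop.lapse_rate
    diag = np.where(rng.random(car.shape) < 0.5, "diag1", "diag2")
    resp[lapse] = diag[lapse]
    return resp


def simulate_l2(
    centered_ar, r1, effects_row, pop: PopulationParams, rng, hysteresis: float | None = None
) -> np.ndarray:
    """L2 responses given the binary L1 percepts ``r1``.

    With probability ``lapse_rate`` the response is uniform over
    {deg60, deg120, deg90}; otherwise ``y2 ~ Bernoulli(logistic(intercept +
    adaptation*AR_c + hysteresis*r1))`` and a 0 outcome maps to deg60 or
    deg120 with equal probability.  ``hysteresis`` can be overridden (the
    control task uses the decisional carryover instead).
    """
    car = np.asarray(centered_ar, dtype=float)
    h = float(effects_row["hysteresis"]) if hysteresis is None else float(hysteresis)
    p0 = l2_probability(
        car, np.asarray(r1, dtype=float), float(effects_row["intercept"]), h,
        float(effects_row["adaptation"]),
    )
    y2 = rng.random(car.shape) < p0
    alt = np.where(rng.random(car.shape) < 0.5, "deg60", "deg120")
    resp = np.where(y2, "deg0", alt).astype(object)
    lapse = rng.random(car.shape) < pop.lapse_rate
    lapse_resp = np.asarray(["deg60", "deg120", "deg90"], dtype=object)[
        rng.integers(0, 3, size=car.shape)
    ]
    resp[lapse] = lapse_resp[lapse]
    return resp


def _with_hands(frame: pd.DataFrame, rng) -> pd.DataFrame:
    # response-option positions are randomized, so the L2 hand is a coin flip
    frame["response_hand"] = np.where(rng.random(len(frame)) < 0.5, "left", "right")
    return frame


def simulate_main_task(
    design: pd.DataFrame, effects: pd.DataFrame, pop: PopulationParams, seed: int
) -> pd.DataFrame:
    """Fill a main-task design skeleton with simulated responses."""
    out = design.copy()
    eff = effects.set_index(["participant", "session"])
    rng = np.random.default_rng(np.random.SeedSequence([seed, 31]))
    for (pid, session), idx in out.groupby(["participant", "session"], sort=True).groups.items():
        row = eff.loc[(pid, session)]
        car = out.loc[idx, "aspect_ratio"].to_numpy(float) - 1.0
        l1 = simulate_l1(car, row, pop, rng)
        r1 = (l1 == "deg0").astype(float)
        l2 = simulate_l2(car, r1, row, pop, rng)
        out.loc[idx, "l1_response"] = l1
        out.loc[idx, "l2_response"] = l2
    return _with_hands(out, rng)


def simulate_control_task(
    effects: pd.DataFrame, pop: PopulationParams, spec: DesignSpec, seed: int, session: int = 1
) -> pd.DataFrame:
    """Control task: random first lattice, so L1 carries no stimulus support.

    The first response is simulated with proximity = 0 (responses deg0 /
    deg90 / deg45 / deg135); the second-lattice model replaces the
    perceptual hysteresis coefficient with the decisional
    ``control_carryover``, emulating the reduced first-response carryover
    observed without a percept-inducing first stimulus.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 37, session]))
    eff = effects.set_index(["participant", "session"])
    rows = []
    nt = spec.control_trials
    for pid in _participant_ids(spec.n_participants):
        row = eff.loc[(pid, session)]
        bases = rng.integers(0, 90, size=nt)
        car = np.zeros(nt)
        p0 = _logistic(np.full(nt, pop.intercept_l1))
        l1 = np.where(rng.random(nt) < p0, "deg0", "deg90").astype(object)
        lapse = rng.random(nt) < pop.lapse_rate
        diag = np.where(rng.random(nt) < 0.5, "deg45", "deg135")
        l1[lapse] = diag[lapse]
        r1 = (l1 == "deg0").astype(float)
        l2 = simulate_l2(car, r1, row, pop, rng, hysteresis=pop.control_carryover)
        for t in range(nt):
            rows.append((pid, session, "control", 1, t + 1, np.nan, int(bases[t]), l1[t], l2[t], ""))
    frame = pd.DataFrame(rows, columns=CSV_COLUMNS)
    return _with_hands(frame, rng)


def simulate_orientation_task(
    effects: pd.DataFrame, pop: PopulationParams, spec: DesignSpec, seed: int, session: int = 1
) -> pd.DataFrame:
    """Absolute-orientation-bias task: hexagonal lattices at 1°-60°.

    Each block shows every base orientation once in shuffled order.  The
    response is drawn over the three plausible axes {theta, theta+60,
    theta+120} with axial von-Mises weights
    ``exp(kappa * cos(2*(candidate - preferred)))``; with probability
    ``lapse_rate`` the (implausible) 90° option is chosen instead.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 41, session]))
    eff = effects.set_index(["participant", "session"])
    lo, hi = spec.orientation_range
    base_set = np.arange(lo, hi + 1)
    offsets = np.array([0.0, 60.0, 120.0])
    labels = np.array(["deg0", "deg60", "deg120"], dtype=object)
    rows = []
    for pid in _participant_ids(spec.n_participants):
        row = eff.loc[(pid, session)]
        kappa = float(row["bias_concentration"])
        mu = float(row["bias_direction"])
        for block in range(1, spec.orientation_blocks + 1):
            bases = rng.permutation(base_set)
            cand = bases[:, None] + offsets[None, :]
            w = np.exp(kappa * (np.cos(np.deg2rad(2.0 * (cand - mu))) - 1.0))
            w /= w.sum(axis=1, keepdims=True)
            cum = np.cumsum(w, axis=1)
            u = rng.random(len(bases))[:, None]
            choice = (u > cum).sum(axis=1)
            resp = labels[choice]
            lapse = rng.random(len(bases)) < pop.lapse_rate
            resp = resp.copy()
            resp[lapse] = "deg90"
            for t, (base, r) in enumerate(zip(bases, resp), start=1):
                rows.append((pid, session, "orientation", block, t, np.nan, int(base), "", r, ""))
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def simulate_cohort(
    pop: PopulationParams | None = None,
    spec: DesignSpec | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the full replica study: all tasks, all sessions.

    Returns ``(trials, effects)``: the trial table in the package CSV schema
    and the per-participant true effects (the recovery ground truth).  The
    control task runs in session 1 only, matching the study procedure.
    Fully deterministic given the seed.
    """
    pop = pop or PopulationParams()
    spec = spec or DesignSpec()
    seed = spec.seed if seed is None else seed
    effects = draw_participants(pop, spec, seed=seed)
    parts = []
    for session in spec.sessions:
        design = make_design(spec, session=session)
        parts.append(simulate_main_task(design, effects, pop, seed=seed + session))
        parts.append(simulate_orientation_task(effects, pop, spec, seed=seed, session=session))
    parts.append(simulate_control_task(effects, pop, spec, seed=seed, session=spec.sessions[0]))
    parts = [p.astype({"aspect_ratio": float}) for p in parts]
    trials = pd.concat(parts, ignore_index=True)
    return trials, effects


def write_truth(path: str | Path, pop: PopulationParams, effects: pd.DataFrame) -> None:
    """Sidecar YAML with the true population parameters and individual effects."""
    payload = {
        "population": asdict(pop),
        "participants": effects.to_dict(orient="records"),
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False), encoding="utf-8")
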