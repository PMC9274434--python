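"""End-to-end replica pipeline: simulate -> preprocess -> fit -> compare -> report.

``run_replica`` executes the full hypothesis battery on either a trial CSV
or a freshly simulated cohort: average hysteresis/adaptation Bayes factors
(bridge sampling), the interaction test, individual-differences tests
(unconstrained vs. common-effects), everyone-shows-the-effect tests
(encompassing approach), the hysteresis-adaptation correlation, the
control-task carryover, orientation-bias relations, session-stability
model comparisons, and the exploratory proximity analyses.  Every stage is
seeded from one top-level seed and logged into a run manifest; the report
body is deterministic for a fixed config (timings live only in the
manifest).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import circular, comparison, trial_io
from .hierarchical import (
    ModelSpec,
    PriorConfig,
    SamplerConfig,
    build_model,
    fit,
    fixed_effect_summary,
    individual_effect_summaries,
)
from .simulate import DesignSpec, PopulationParams, simulate_cohort

__all__ = ["default_config", "run_replica", "plot_suite"]

log = logging.getLogger("dotlattice")

ALL_HYPOTHESES = ("H1", "H2", "H3", "H4", "H5", "H6", "H7", "H8", "H9", "H10",
                  "exploratory")


def default_config(scale: str = "desk") -> dict:
    """Pipeline configuration.

    ``scale="paper"`` uses the replica design (75 participants, 9 x 70 main
    trials, 4-chain 20,000-iteration sampler); ``scale="desk"`` shrinks the
    cohort and sampler to run a full hypothesis battery in minutes on one
    CPU.
    """
    if scale == "paper":
        design = {"n_participants": 75, "n_blocks": 9, "trials_per_block": 70,
                  "orientation_blocks": 4, "control_trials": 90}
        sampler = {"chains": 4, "iterations": 20000, "target_accept": 0.8,
                   "max_treedepth": 10}
    elif scale == "desk":
        design = {"n_participants": 12, "n_blocks": 3, "trials_per_block": 35,
                  "orientation_blocks": 2, "control_trials": 60}
        sampler = {"chains": 2, "iterations": 700, "target_accept": 0.8,
                   "max_treedepth": 10}
    else:
        raise ValueError(f"unknown scale {scale!r}")
    return {
        "seed": 1,
        "data_csv": None,
        "design": design,
        "population": {},
        "sampler": sampler,
        "priors": {"fixed_scale": 2.0, "sd_scale": 1.0, "lkj_eta": 1.0},
        "hypotheses": list(ALL_HYPOTHESES),
    }


def _bfr(res: comparison.BayesFactorResult) -> dict:
    return {
        "log_bf": res.log_bf,
        "bf": float(np.exp(np.clip(res.log_bf, -700, 700))),
        "favored": res.favored,
        "estimator": res.estimator,
        "mc_error": res.mc_error,
        "n_draws_used": res.n_draws_used,
        "is_bound": res.is_bound,
    }


def _corr_or_skip(x, y, direction):
    """Directed correlation BF, or a skip record when too few pairs remain."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        log.warning("correlation skipped: only %d complete pairs", int(ok.sum()))
        return None, {"skipped": f"only {int(ok.sum())} complete pairs"}
    if ok.sum() < 10:
        log.warning("small sample: %d pairs, correlation estimate unstable", int(ok.sum()))
    return comparison.correlation_bf(x[ok], y[ok], direction)


def _round_floats(obj, ndigits=6):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def run_replica(config: dict | None = None, out_dir: str | Path | None = None) -> dict:
    """Run the full analysis battery; returns a bundle with ``report``,
    ``manifest`` and in-memory artifacts (draws, tables).

    The report carries one entry per hypothesis key with the Bayes factors
    (log scale), effect summaries and correlation summaries the analysis
    produced; the manifest records the config snapshot, seeds, per-stage
    timings and sampler diagnostics.  Any stage failure aborts with the
    manifest accumulated so far attached to the exception.
    """
    config = config or default_config()
    seed = int(config.get("seed", 1))
    hyps = set(config.get("hypotheses", ALL_HYPOTHESES))
    priors = PriorConfig(**config.get("priors", {}))
    sampler = SamplerConfig(seed=seed, **config.get("sampler", {}))
    manifest: dict = {"config": config, "seed": seed, "stages": {}, "diagnostics": {}}
    report: dict = {}
    bundle: dict = {"report": report, "manifest": manifest}
    t_start = time.perf_counter()

    def stage(name):
        manifest["stages"][name] = {"t_start": time.perf_counter() - t_start}
        log.info("stage %s started", name)

    def stage_done(name):
        st = manifest["stages"][name]
        st["seconds"] = time.perf_counter() - t_start - st["t_start"]
        log.info("stage %s finished in %.1fs", name, st["seconds"])

    # ---- data ------------------------------------------------------------
    stage("data")
    if config.get("data_csv"):
        trials = trial_io.read_trials(config["data_csv"])
        effects = None
    else:
        design_kwargs = dict(config.get("design", {}))
        pop = PopulationParams(**config.get("population", {}))
        spec = DesignSpec(seed=seed, **design_kwargs)
        trials, effects = simulate_cohort(pop, spec, seed=seed)
        bundle["effects"] = effects
    bundle["trials"] = trials
    stage_done("data")

    # ---- preprocessing ---------------------------------------------------
    stage("preprocess")
    n_main = int(
        trials[(trials["task"] == "main") & (trials["session"] == 1)]
        .groupby("participant")
        .size()
        .max()
    )
    excl1 = trial_io.apply_participant_exclusions(
        trials, sessions_required=(1,), expected_main_trials=n_main
    )
    excl12 = trial_io.apply_participant_exclusions(
        trials, sessions_required=(1, 2), expected_main_trials=n_main
    )
    keep1 = set(excl1.loc[~excl1["excluded"], "participant"])
    keep12 = set(excl12.loc[~excl12["excluded"], "participant"])
    binary = trial_io.to_binary_trials(trials)
    main1 = binary[
        (binary["task"] == "main")
        & (binary["session"] == 1)
        & binary["participant"].isin(keep1)
    ]
    control1 = binary[
        (binary["task"] == "control") & binary["participant"].isin(keep1)
    ]
    main12 = binary[(binary["task"] == "main") & binary["participant"].isin(keep12)]
    bundle["binary"] = binary
    bundle["exclusions"] = excl12
    report["preprocessing"] = {
        "n_participants_session1": len(keep1),
        "n_participants_both_sessions": len(keep12),
        "n_binary_main_session1": int(len(main1)),
        "n_binary_control": int(len(control1)),
    }
    stage_done("preprocess")

    draws_cache: dict = {}
    bundle["draws"] = draws_cache

    def fit_l2(name, fixed, random, data, **spec_kwargs):
        if name not in draws_cache:
            spec = ModelSpec(
                outcome="l2_percept", fixed_terms=fixed, random_terms=random,
                prior_config=priors, **spec_kwargs,
            )
            model = build_model(spec, data)
            draws_cache[name] = fit(model, sampler)
            manifest["diagnostics"][name] = {
                k: v for k, v in draws_cache[name].diagnostics.items()
                if k not in ("step_sizes",)
            }
        return draws_cache[name]

    needs_full = hyps & {"H1", "H2", "H3", "H4", "H5", "H6", "H8", "exploratory"}
    if needs_full:
        stage("fit_full_model")
        full = fit_l2("l2_full", ("intercept", "centered_ar", "r1"),
                      ("intercept", "centered_ar", "r1"), main1)
        ml_full = comparison.bridge_log_ml(full, seed=seed)
        report["full_model"] = {
            "hysteresis": fixed_effect_summary(full, "r1"),
            "adaptation": fixed_effect_summary(full, "centered_ar"),
            "intercept": fixed_effect_summary(full, "intercept"),
        }
        stage_done("fit_full_model")

    # ---- H1/H2: average effects ------------------------------------------
    if "H1" in hyps:
        stage("H1")
        reduced = fit_l2("l2_no_hyst", ("intercept", "centered_ar"),
                         ("intercept", "centered_ar"), main1)
        ml_red = comparison.bridge_log_ml(reduced, seed=seed + 1)
        log_bf = ml_full[0] - ml_red[0]
        report["H1"] = {
            "question": "average hysteresis effect (model with vs without L1 percept)",
            **_bfr(comparison.BayesFactorResult(
                log_bf, "with_hysteresis" if log_bf > 0 else "without",
                "bridge", float(np.hypot(ml_full[1], ml_red[1])), full.n_draws)),
            "effect": report["full_model"]["hysteresis"],
        }
        stage_done("H1")
    if "H2" in hyps:
        stage("H2")
        reduced = fit_l2("l2_no_adapt", ("intercept", "r1"), ("intercept", "r1"), main1)
        ml_red = comparison.bridge_log_ml(reduced, seed=seed + 2)
        log_bf = ml_full[0] - ml_red[0]
        report["H2"] = {
            "question": "average adaptation effect (model with vs without L1 aspect ratio)",
            **_bfr(comparison.BayesFactorResult(
                log_bf, "with_adaptation" if log_bf > 0 else "without",
                "bridge", float(np.hypot(ml_full[1], ml_red[1])), full.n_draws)),
            "effect": report["full_model"]["adaptation"],
        }
        stage_done("H2")

    # ---- H3: interaction --------------------------------------------------
    if "H3" in hyps:
        stage("H3")
        no_inter = full
        inter = fit_l2("l2_interaction",
                       ("intercept", "centered_ar", "r1", "ar_by_r1"),
                       ("intercept", "centered_ar", "r1", "ar_by_r1"), main1)
        ml_no = comparison.bridge_log_ml(no_inter, seed=seed + 3)
        ml_in = comparison.bridge_log_ml(inter, seed=seed + 4)
        log_bf = ml_no[0] - ml_in[0]  # in favor of NO interaction
        report["H3"] = {
            "question": "independence of hysteresis and adaptation (no-interaction vs interaction)",
            **_bfr(comparison.BayesFactorResult(
                log_bf, "no_interaction" if log_bf > 0 else "interaction",
                "bridge", float(np.hypot(ml_no[1], ml_in[1])), no_inter.n_draws)),
            "interaction_effect": fixed_effect_summary(inter, "ar_by_r1"),
        }
        stage_done("H3")

    # ---- H4: individual differences ---------------------------------------
    if "H4" in hyps:
        stage("H4")
        out = {}
        for effect, term in (("hysteresis", "r1"), ("adaptation", "centered_ar")):
            randoms = tuple(t for t in ("intercept", "centered_ar", "r1") if t != term)
            common = fit_l2(f"l2_common_{effect}", ("intercept", "centered_ar", "r1"),
                            randoms, main1)
            ml_c = comparison.bridge_log_ml(common, seed=seed + 5)
            log_bf = ml_full[0] - ml_c[0]
            out[effect] = _bfr(comparison.BayesFactorResult(
                log_bf, "unconstrained" if log_bf > 0 else "common_effects",
                "bridge", float(np.hypot(ml_full[1], ml_c[1])), full.n_draws))
        report["H4"] = {
            "question": "individual differences (unconstrained vs common-effects model)",
            **out,
        }
        stage_done("H4")

    # ---- H5: does everyone show the effects? -------------------------------
    if "H5" in hyps:
        stage("H5")
        rng = np.random.default_rng(np.random.SeedSequence([seed, 55]))
        n_prior = full.n_draws
        prior = full.model.sample_prior(n_prior, rng)
        out = {}
        for effect, term in (("hysteresis", "r1"), ("adaptation", "centered_ar")):
            post = full.flat(f"individual_{term}")
            res = comparison.encompassing_bf(post, prior[f"individual_{term}"], "positive")
            out[effect] = _bfr(res)
        report["H5"] = {
            "question": "everyone shows the effect (positive-effects vs unconstrained, encompassing)",
            **out,
        }
        stage_done("H5")

    # ---- H6: hysteresis-adaptation correlation -----------------------------
    if "H6" in hyps:
        stage("H6")
        corr_draws = full.flat("corr_centered_ar_r1")
        res = comparison.savage_dickey_onesided(corr_draws, direction="positive")
        from .hierarchical import hdci as _hdci

        lo, hi = _hdci(corr_draws, 0.95)
        hyst = individual_effect_summaries(full, "r1")
        adapt = individual_effect_summaries(full, "centered_ar")
        res2, summ2 = _corr_or_skip(
            hyst["mean"].to_numpy(), adapt["mean"].to_numpy(), "positive"
        )
        report["H6"] = {
            "question": "positive correlation between individual hysteresis and adaptation",
            **_bfr(res),
            "correlation_mean": float(corr_draws.mean()),
            "correlation_hdci": [lo, hi],
            "two_stage": {**(_bfr(res2) if res2 else {}), **summ2},
        }
        stage_done("H6")

    # ---- H7: control task ---------------------------------------------------
    if "H7" in hyps and len(control1):
        stage("H7")
        with_r1 = fit_l2("control_with_r1", ("intercept", "r1"), ("intercept", "r1"),
                         control1)
        without = fit_l2("control_without_r1", ("intercept",), ("intercept",), control1)
        ml_w = comparison.bridge_log_ml(with_r1, seed=seed + 7)
        ml_o = comparison.bridge_log_ml(without, seed=seed + 8)
        log_bf = ml_o[0] - ml_w[0]  # in favor of NO hysteresis, per the hypothesis
        report["H7"] = {
            "question": "absence of first-response carryover in the control task",
            **_bfr(comparison.BayesFactorResult(
                log_bf, "no_hysteresis" if log_bf > 0 else "hysteresis",
                "bridge", float(np.hypot(ml_w[1], ml_o[1])), with_r1.n_draws)),
            "control_effect": fixed_effect_summary(with_r1, "r1"),
        }
        stage_done("H7")

    # ---- orientation bias ----------------------------------------------------
    biases = circular.bias_per_participant(trials)
    bundle["biases"] = biases
    bias1 = biases[biases["session"] == 1]

    if "H8" in hyps and needs_full:
        stage("H8")
        out = {}
        for effect, term in (("hysteresis", "r1"), ("adaptation", "centered_ar")):
            summ = individual_effect_summaries(full, term)
            merged = bias1.merge(summ, on="participant")
            x = merged["vector_magnitude"].to_numpy(float)
            y = merged["mean"].to_numpy(float)
            res_neg, s_neg = _corr_or_skip(x, y, "negative")
            if res_neg is None:
                out[effect] = s_neg
                continue
            res_pos, _ = comparison.correlation_bf(x, y, "positive")
            lvq = comparison.linear_vs_quadratic_bf(x, y, seed=seed)
            out[effect] = {
                "negative": _bfr(res_neg),
                "positive": _bfr(res_pos),
                "correlation": s_neg,
                "quadratic_vs_linear": _bfr(lvq),
            }
        report["H8"] = {
            "question": "orientation-bias magnitude vs context-effect size (directed correlations)",
            **out,
        }
        stage_done("H8")

    # ---- H9: session stability of context effects -----------------------------
    if "H9" in hyps and len(main12) and main12["session"].nunique() == 2:
        stage("H9")
        out = {}
        for effect in ("hysteresis", "adaptation"):
            res = comparison.compare_session_models(
                main12, effect, config=sampler,
                base_spec=ModelSpec(prior_config=priors), seed=seed + 9,
            )
            out[effect] = {
                "correlated_vs_uncorrelated": _bfr(res["bf_correlated_vs_uncorrelated"]),
                "correlated_vs_fully_correlated": _bfr(
                    res["bf_correlated_vs_fully_correlated"]),
                "rho_mean": res["rho_mean"],
                "rho_hdci": list(res["rho_hdci"]),
            }
        report["H9"] = {
            "question": "cross-session stability of individual context effects",
            **out,
        }
        stage_done("H9")

    # ---- H10: session stability of orientation bias ----------------------------
    if "H10" in hyps and biases["session"].nunique() == 2:
        stage("H10")
        wide = biases.pivot(index="participant", columns="session",
                            values="vector_magnitude").dropna()
        res, summ = _corr_or_skip(wide[1].to_numpy(), wide[2].to_numpy(), "positive")
        dirs = biases.pivot(index="participant", columns="session",
                            values="vector_direction").dropna()
        circ_r = (
            circular.circular_circular_correlation(
                dirs[1].to_numpy(), dirs[2].to_numpy(), axial=True
            )
            if len(dirs) >= 3
            else float("nan")
        )
        report["H10"] = {
            "question": "cross-session stability of orientation-bias magnitude",
            **(_bfr(res) if res else {}),
            **summ,
            "direction_circular_correlation": circ_r,
        }
        stage_done("H10")

    # ---- exploratory: proximity and response-bias analyses ---------------------
    if "exploratory" in hyps:
        stage("exploratory")
        l1_spec = dict(outcome="l1_percept", fixed_terms=("intercept", "centered_ar"),
                       prior_config=priors)
        l1_full_spec = ModelSpec(random_terms=("intercept", "centered_ar"), **l1_spec)
        l1_common_spec = ModelSpec(random_terms=("intercept",), **l1_spec)
        m_full = build_model(l1_full_spec, main1)
        m_common = build_model(l1_common_spec, main1)
        d_full = fit(m_full, sampler)
        d_common = fit(m_common, sampler)
        ml_f = comparison.bridge_log_ml(d_full, seed=seed + 11)
        ml_c = comparison.bridge_log_ml(d_common, seed=seed + 12)
        log_bf = ml_f[0] - ml_c[0]
        rng = np.random.default_rng(np.random.SeedSequence([seed, 77]))
        prior = m_full.sample_prior(d_full.n_draws, rng)
        enc = comparison.encompassing_bf(
            d_full.flat("individual_centered_ar"), prior["individual_centered_ar"],
            "negative",
        )
        prox = individual_effect_summaries(d_full, "centered_ar")
        expl = {
            "proximity_random_vs_common": _bfr(comparison.BayesFactorResult(
                log_bf, "unconstrained" if log_bf > 0 else "common_effects",
                "bridge", float(np.hypot(ml_f[1], ml_c[1])), d_full.n_draws)),
            "proximity_negative_effects": _bfr(enc),
            "proximity_effect": fixed_effect_summary(d_full, "centered_ar"),
        }
        if needs_full:
            hyst = individual_effect_summaries(full, "r1")
            adapt = individual_effect_summaries(full, "centered_ar")
            for name, other in (("hysteresis", hyst), ("adaptation", adapt)):
                merged = prox.merge(other, on="participant", suffixes=("_prox", ""))
                _, summ = _corr_or_skip(
                    merged["mean_prox"].to_numpy(), merged["mean"].to_numpy(), "negative"
                )
                expl[f"proximity_vs_{name}"] = summ
        expl["response_bias"] = trial_io.response_bias_summary(trials).to_dict(
            orient="list"
        )
        report["exploratory"] = expl
        bundle["draws"]["l1_full"] = d_full
        stage_done("exploratory")

    manifest["total_seconds"] = time.perf_counter() - t_start
    report_clean = _round_floats(report)
    bundle["report"] = report_clean

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(
            json.dumps(report_clean, indent=2, sort_keys=True), encoding="utf-8"
        )
        (out / "manifest.json").write_text(
            json.dumps(_round_floats(manifest), indent=2, sort_keys=True, default=str),
            encoding="utf-8",
        )
        trial_io.write_trials(trials, out / "trials.csv")
    return bundle


# ---------------------------------------------------------------------------
# figures
# ---------------------------------------------------------------------------


def plot_suite(bundle: dict, out_dir: str | Path) -> list[Path]:
    """Produce the replica figure families from a ``run_replica`` bundle.

    Writes PNG files: logit-vs-aspect-ratio lines split by L1 percept,
    individual-effect forest plot, hysteresis-vs-adaptation scatter with
    HDCI bars, orientation-bias polar plot, and (when two sessions are
    present) a cross-session bias scatter.  Panels whose inputs are missing
    are skipped with a log entry.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    binary = bundle.get("binary")
    if binary is not None:
        sub = binary[(binary["task"] == "main") & (binary["session"] == 1)]
        fig, ax = plt.subplots(figsize=(5, 4))
        for r1, color in ((1, "tab:blue"), (0, "tab:orange")):
            per = trial_io.empirical_logits(sub[sub["r1"] == r1], by_participant=True)
            for _, g in per.groupby("participant"):
                ax.plot(g["centered_ar"] + 1, g["logit"], color=color, alpha=0.15, lw=0.6)
            avg = trial_io.empirical_logits(sub[sub["r1"] == r1], by_participant=False)
            ax.plot(avg["centered_ar"] + 1, avg["logit"], color=color, lw=2.5,
                    label=f"L1 percept {'0°' if r1 else '90°'}")
        ax.set_xlabel("aspect ratio of L1")
        ax.set_ylabel("logit p(L2 → 0°)")
        ax.legend()
        fig.tight_layout()
        p = out / "logit_by_aspect_ratio.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
    else:
        log.info("plot_suite: binary trials missing, skipping logit panel")

    full = bundle.get("draws", {}).get("l2_full")
    if full is not None:
        fig, axes = plt.subplots(1, 2, figsize=(8, 4), sharey=True)
        for ax, (label, term) in zip(
            axes, (("hysteresis", "r1"), ("adaptation", "centered_ar"))
        ):
            summ = individual_effect_summaries(full, term).sort_values("mean")
            ypos = np.arange(len(summ))
            ax.hlines(ypos, summ["hdci_low"], summ["hdci_high"], color="gray", lw=1)
            ax.plot(summ["mean"], ypos, "o", ms=3)
            ax.axvline(0, color="black", lw=0.8)
            ax.axvline(summ["mean"].mean(), color="tab:red", lw=1)
            ax.set_title(label)
            ax.set_xlabel("effect (logit)")
        fig.tight_layout()
        p = out / "individual_effects_forest.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)

        hyst = individual_effect_summaries(full, "r1", mass=0.80)
        adapt = individual_effect_summaries(full, "centered_ar", mass=0.80)
        fig, ax = plt.subplots(figsize=(4.5, 4.5))
        ax.errorbar(
            hyst["mean"], adapt["mean"],
            xerr=[hyst["mean"] - hyst["hdci_low"], hyst["hdci_high"] - hyst["mean"]],
            yerr=[adapt["mean"] - adapt["hdci_low"], adapt["hdci_high"] - adapt["mean"]],
            fmt="o", ms=3, alpha=0.7, lw=0.7,
        )
        ax.axhline(0, color="black", lw=0.8)
        ax.axvline(0, color="black", lw=0.8)
        ax.set_xlabel("individual hysteresis (logit)")
        ax.set_ylabel("individual adaptation (logit)")
        fig.tight_layout()
        p = out / "hysteresis_vs_adaptation.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
    else:
        log.info("plot_suite: full-model draws missing, skipping forest/scatter panels")

    biases = bundle.get("biases")
    if biases is not None and len(biases):
        b1 = biases[biases["session"] == 1].dropna()
        fig = plt.figure(figsize=(4.5, 4.5))
        ax = fig.add_subplot(111, projection="polar")
        ax.scatter(np.deg2rad(2.0 * b1["vector_direction"]), b1["vector_magnitude"], s=12)
        ax.set_title("orientation bias (angle doubled)")
        fig.tight_layout()
        p = out / "orientation_bias_polar.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
        if biases["session"].nunique() == 2:
            wide = biases.pivot(index="participant", columns="session",
                                values="vector_magnitude").dropna()
            fig, ax = plt.subplots(figsize=(4.5, 4.5))
            ax.plot(wide[1], wide[2], "o", ms=4)
            lim = max(wide.max()) * 1.05
            ax.plot([0, lim], [0, lim], color="black", lw=0.8)
            ax.set_xlabel("bias magnitude, session 1 (%)")
            ax.set_ylabel("bias magnitude, session 2 (%)")
            fig.tight_layout()
            p = out / "bias_cross_session.png"
            fig.savefig(p, dpi=120)
            plt.close(fig)
            written.append(p)
    else:
        log.info("plot_suite: bias table missing, skipping polar panels")
    return written
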