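"""Axial circular statistics for the absolute-orientation-bias task.

Orientations are axial data (defined modulo 180°): a lattice organization at
theta is the same axis as theta + 180°.  All statistics therefore work on
doubled angles, 2*theta, the standard device for axial data.  The bias of an
observer is summarized by the mean resultant vector of their chosen
orientations: its magnitude L (0-100%) is the strength of the absolute
orientation bias, its direction theta-bar the preferred orientation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trial_io import Task

__all__ = [
    "OrientationBias",
    "orientation_vector",
    "bias_per_participant",
    "circular_circular_correlation",
    "bias_effect_relation",
]

#: L2 response category -> orientation offset (degrees) from the base axis.
_RESPONSE_OFFSET = {"deg0": 0, "deg60": 60, "deg120": 120}


@dataclass(frozen=True)
class OrientationBias:
    """Orientation-bias summary for one participant x session."""

    participant: str
    session: int
    vector_magnitude: float  # percent, 0-100
    vector_direction: float  # degrees in [0, 180)
    n_trials_used: int


def orientation_vector(thetas_deg: np.ndarray) -> tuple[float, float]:
    """Mean resultant vector of axial orientations.

    L = 100 * sqrt((sum sin 2theta)^2 + (sum cos 2theta)^2) / n and
    theta-bar = 1/2 * atan2(sum sin 2theta, sum cos 2theta), mapped into
    [0, 180).  atan2 rather than a plain arctan ratio keeps the direction
    well defined in all quadrants.  Trials where the observer chose the
    unlikely 90° option must already be excluded.

    Returns ``(L, direction)`` with L in percent.  Raises on empty input.
    """
    thetas = np.asarray(thetas_deg, dtype=float)
    if thetas.size == 0:
        raise ValueError("orientation_vector requires at least one orientation")
    ang = np.deg2rad(2.0 * thetas)
    s, c = np.sin(ang).sum(), np.cos(ang).sum()
    L = 100.0 * math.hypot(s, c) / thetas.size
    direction = math.degrees(0.5 * math.atan2(s, c)) % 180.0
    if direction >= 180.0 - 1e-9:  # fold the floating-point wrap at 180°
        direction = 0.0
    return L, direction


def bias_per_participant(orientation_trials: pd.DataFrame) -> pd.DataFrame:
    """Orientation-bias vector per participant x session.

    Drops 90° responses, maps each remaining response to its chosen
    orientation ``(base_orientation + offset) mod 180`` and applies
    :func:`orientation_vector`.  Participants whose responses are all 90°
    get NaN magnitude/direction with ``n_trials_used = 0``.
    """
    ori = orientation_trials[orientation_trials["task"] == Task.ORIENTATION.value]
    rows = []
    for (pid, sess), g in ori.groupby(["participant", "session"], sort=True):
        kept = g[g["l2_response"].isin(_RESPONSE_OFFSET)]
        if len(kept) == 0:
            rows.append(
                {
                    "participant": pid,
                    "session": int(sess),
                    "vector_magnitude": math.nan,
                    "vector_direction": math.nan,
                    "n_trials_used": 0,
                }
            )
            continue
        offsets = kept["l2_response"].map(_RESPONSE_OFFSET).to_numpy(float)
        thetas = (kept["base_orientation"].to_numpy(float) + offsets) % 180.0
        L, direction = orientation_vector(thetas)
        rows.append(
            {
                "participant": pid,
                "session": int(sess),
                "vector_magnitude": L,
                "vector_direction": direction,
                "n_trials_used": int(len(kept)),
            }
        )
    return pd.DataFrame(rows)


def circular_circular_correlation(
    dirs_a: np.ndarray, dirs_b: np.ndarray, axial: bool = True
) -> float:
    """Jammalamadaka-SenGupta circular-circular correlation coefficient.

    ``sum sin(a - abar) sin(b - bbar) / sqrt(sum sin^2(a - abar) *
    sum sin^2(b - bbar))`` with circular means abar, bbar.  For axial data
    (``axial=True``) angles are doubled first, so the coefficient is
    invariant to rotating either sample and to 180° relabelings.
    """
    a = np.deg2rad(np.asarray(dirs_a, dtype=float))
    b = np.deg2rad(np.asarray(dirs_b, dtype=float))
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need at least 3 paired directions")
    if axial:
        a, b = 2.0 * a, 2.0 * b
    abar = math.atan2(np.sin(a).sum(), np.cos(a).sum())
    bbar = math.atan2(np.sin(b).sum(), np.cos(b).sum())
    sa, sb = np.sin(a - abar), np.sin(b - bbar)
    denom = math.sqrt((sa**2).sum() * (sb**2).sum())
    if denom == 0.0:
        return 0.0
    return float((sa * sb).sum() / denom)


def bias_effect_relation(
    biases: pd.DataFrame,
    effect_summaries: pd.DataFrame,
    direction_hypothesis: str = "negative",
    effect_col: str = "mean",
):
    """Bayes-factor test of a directed linear relation between bias strength and a context effect.

    Matches participants between the bias table (``vector_magnitude``) and an
    individual-effect summary table, then tests the one-sided hypothesis on
    the linear correlation via the Savage-Dickey ratio under a uniform prior
    on r.  Both directions are computable; the preregistered direction for
    context effects was negative (stronger absolute bias, weaker
    hysteresis/adaptation).

    Returns ``(BayesFactorResult, summary_dict)`` where the summary holds the
    posterior mean and 95% HDCI of r.
    """
    import warnings

    from .comparison import correlation_bf

    merged = biases.merge(effect_summaries, on="participant", suffixes=("_bias", ""))
    if len(merged) < 10:
        warnings.warn(
            f"only {len(merged)} matched participants; correlation estimate unstable",
            stacklevel=2,
        )
    x = merged["vector_magnitude"].to_numpy(float)
    y = merged[effect_col].to_numpy(float)
    ok = np.isfinite(x) & np.isfinite(y)
    return correlation_bf(x[ok], y[ok], direction=direction_hypothesis)
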