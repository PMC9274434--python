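"""Trial-level data model, CSV I/O, and preprocessing for dot-lattice experiments.

The experiment presents a rectangular dot lattice (L1) whose aspect ratio
|a|/|b| biases its perceived orientation (0° vs. 90°), followed by an
ambiguous hexagonal lattice (L2) with three dominant orientations
(0°, 60°, 120°).  Each trial yields two 4-AFC responses.  Analyses are
restricted to the response alternatives that are equally likely at aspect
ratio 1: L1 responses of 0°/90° and L2 responses of 0°/60°/120°.

Collections of trials are plain :class:`pandas.DataFrame` objects with the
documented column schema; :class:`TrialRecord` is the validated single-row
view.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Task",
    "TrialRecord",
    "ExclusionReport",
    "CSV_COLUMNS",
    "DESIGN_ASPECT_RATIOS",
    "MAIN_L1_RESPONSES",
    "CONTROL_L1_RESPONSES",
    "L2_RESPONSES",
    "read_trials",
    "write_trials",
    "validate_trials",
    "apply_participant_exclusions",
    "to_binary_trials",
    "empirical_logits",
    "response_bias_summary",
]


class Task(str, Enum):
    """The three experimental tasks."""

    MAIN = "main"
    CONTROL = "control"
    ORIENTATION = "orientation"


#: CSV schema (header order is fixed; empty string for inapplicable fields).
CSV_COLUMNS = [
    "participant",
    "session",
    "task",
    "block",
    "trial",
    "aspect_ratio",
    "base_orientation",
    "l1_response",
    "l2_response",
    "response_hand",
]

#: The seven design aspect ratios, 1.3**-1 ... 1.3.
DESIGN_ASPECT_RATIOS = tuple(
    round(v, 6) for v in (1 / 1.3, 1 / 1.2, 1 / 1.1, 1.0, 1.1, 1.2, 1.3)
)

MAIN_L1_RESPONSES = frozenset({"deg0", "deg90", "diag1", "diag2"})
CONTROL_L1_RESPONSES = frozenset({"deg0", "deg90", "deg45", "deg135"})
L2_RESPONSES = frozenset({"deg0", "deg60", "deg120", "deg90"})

#: L1 responses kept for binarization, and the L2 responses kept.
_L1_KEPT = frozenset({"deg0", "deg90"})
_L2_KEPT = frozenset({"deg0", "deg60", "deg120"})

#: Non-dominant ("diagonal") L1 options in the main task.
_L1_DIAGONAL = frozenset({"diag1", "diag2"})


@dataclass(frozen=True)
class TrialRecord:
    """One 4-AFC trial.

    ``aspect_ratio`` is present iff ``task == main``; ``l1_response`` is
    absent iff ``task == orientation``; ``base_orientation`` lies in 0-89°
    for main/control and 1-60° for the orientation task.
    """

    participant: str
    session: int
    task: Task
    block: int
    trial_index: int
    aspect_ratio: float | None
    base_orientation: int
    l1_response: str | None
    l2_response: str
    response_hand: str | None = None


@dataclass(frozen=True)
class ExclusionReport:
    """Per-participant exclusion decision.

    ``reason`` is ``"none"`` iff the participant is kept; ``diagonal_rate``
    is the largest per-session proportion of diagonal L1 responses in the
    main task across the required sessions.
    """

    participant: str
    excluded: bool
    reason: str  # incomplete_session | diagonal_rate_exceeded | none
    diagonal_rate: float


class SchemaError(ValueError):
    """A trial row violates the documented schema."""


def _check_row(row: pd.Series, i: int) -> None:
    task = row["task"]
    if task not in {t.value for t in Task}:
        raise SchemaError(f"row {i}: unknown task {task!r}")
    ar = row["aspect_ratio"]
    has_ar = ar == ar and ar != ""  # not NaN / empty
    if task == Task.MAIN.value:
        if not has_ar or float(ar) <= 0:
            raise SchemaError(f"row {i}: field aspect_ratio must be a positive real on main-task rows")
    elif has_ar:
        raise SchemaError(f"row {i}: field aspect_ratio must be empty on {task}-task rows")
    base = row["base_orientation"]
    try:
        base = int(base)
    except (TypeError, ValueError):
        raise SchemaError(f"row {i}: field base_orientation is not an integer") from None
    lo, hi = (1, 60) if task == Task.ORIENTATION.value else (0, 89)
    if not lo <= base <= hi:
        raise SchemaError(
            f"row {i}: field base_orientation {base} outside [{lo}, {hi}] for task {task}"
        )
    l1 = row["l1_response"]
    has_l1 = isinstance(l1, str) and l1 != ""
    if task == Task.ORIENTATION.value:
        if has_l1:
            raise SchemaError(f"row {i}: field l1_response must be empty on orientation-task rows")
    else:
        allowed = MAIN_L1_RESPONSES if task == Task.MAIN.value else CONTROL_L1_RESPONSES
        if l1 not in allowed:
            raise SchemaError(f"row {i}: field l1_response {l1!r} not in {sorted(allowed)}")
    l2 = row["l2_response"]
    if l2 not in L2_RESPONSES:
        raise SchemaError(f"row {i}: field l2_response {l2!r} not in {sorted(L2_RESPONSES)}")
    if int(row["session"]) not in (1, 2):
        raise SchemaError(f"row {i}: field session must be 1 or 2")
    if int(row["block"]) < 1 or int(row["trial"]) < 1:
        raise SchemaError(f"row {i}: fields block and trial must be positive")


def validate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Validate a trial table against the schema; returns the table unchanged.

    Raises :class:`SchemaError` naming the first offending row (0-based,
    data rows) and field.
    """
    missing = [c for c in CSV_COLUMNS if c not in trials.columns]
    if missing:
        raise SchemaError(f"missing columns: {missing}")
    for i, (_, row) in enumerate(trials.iterrows()):
        _check_row(row, i)
    return trials


def read_trials(path: str | Path) -> pd.DataFrame:
    """Read and validate a trial CSV.

    Row order is preserved.  Inapplicable fields (aspect ratio outside the
    main task, L1 response in the orientation task) must be empty.
    """
    df = pd.read_csv(
        path,
        dtype={
            "participant": str,
            "l1_response": str,
            "l2_response": str,
            "response_hand": str,
        },
        keep_default_na=False,
        na_values=[],
    )
    df["aspect_ratio"] = pd.to_numeric(df["aspect_ratio"], errors="coerce")
    validate_trials(df)
    for col in ("session", "block", "trial", "base_orientation"):
        df[col] = df[col].astype(int)
    return df.reset_index(drop=True)


def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    """Write a trial table to CSV in the documented schema (UTF-8, header)."""
    out = trials.loc[:, CSV_COLUMNS].copy()
    out["aspect_ratio"] = out["aspect_ratio"].map(
        lambda v: "" if v != v else format(float(v), ".6f")
    )
    out.to_csv(path, index=False, encoding="utf-8")


def records_to_frame(records: Iterable[TrialRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "participant": r.participant,
                "session": r.session,
                "task": r.task.value if isinstance(r.task, Task) else r.task,
                "block": r.block,
                "trial": r.trial_index,
                "aspect_ratio": np.nan if r.aspect_ratio is None else r.aspect_ratio,
                "base_orientation": r.base_orientation,
                "l1_response": r.l1_response or "",
                "l2_response": r.l2_response,
                "response_hand": r.response_hand or "",
            }
        )
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def apply_participant_exclusions(
    trials: pd.DataFrame,
    sessions_required: Sequence[int] = (1,),
    expected_main_trials: int = 630,
    diagonal_threshold: float = 0.40,
) -> pd.DataFrame:
    """Apply the preregistered exclusion rules.

    A participant is excluded iff (a) any required session has fewer than
    ``expected_main_trials`` main-task trials, or (b) the proportion of
    diagonal L1 responses in the main task is *strictly* greater than
    ``diagonal_threshold`` in any required session (read as an indication of
    random responding).

    Returns a DataFrame with columns
    ``participant, excluded, reason, diagonal_rate``; incomplete
    participation takes precedence over the diagonal-rate rule.
    """
    main = trials[trials["task"] == Task.MAIN.value]
    reports = []
    for pid in sorted(trials["participant"].unique()):
        pmain = main[main["participant"] == pid]
        rates = []
        reason = "none"
        for s in sessions_required:
            smain = pmain[pmain["session"] == int(s)]
            if len(smain) < expected_main_trials:
                reason = "incomplete_session"
            if len(smain):
                rates.append(smain["l1_response"].isin(_L1_DIAGONAL).mean())
        rate = float(max(rates)) if rates else math.nan
        if reason == "none" and rates and max(rates) > diagonal_threshold:
            reason = "diagonal_rate_exceeded"
        reports.append(
            ExclusionReport(
                participant=pid,
                excluded=reason != "none",
                reason=reason,
                diagonal_rate=rate,
            )
        )
    return pd.DataFrame([r.__dict__ for r in reports])


def to_binary_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Reduce main/control trials to the binary outcomes used for modeling.

    Keeps only trials where L1 was reported as 0° or 90° and L2 as 0°, 60°
    or 120° (the alternatives with equal likelihood at aspect ratio 1).
    Returns columns ``participant, session, task, centered_ar, r1, y2``
    with ``centered_ar = aspect_ratio - 1`` (0.0 in the control task, where
    the first lattice is random), ``r1 = 1`` iff L1 was seen at 0°, and
    ``y2 = 1`` iff L2 was seen at 0°.  Reapplying the filter to its own
    output-equivalent rows changes nothing.
    """
    sub = trials[trials["task"].isin([Task.MAIN.value, Task.CONTROL.value])]
    keep = sub["l1_response"].isin(_L1_KEPT) & sub["l2_response"].isin(_L2_KEPT)
    sub = sub[keep]
    ar = pd.to_numeric(sub["aspect_ratio"], errors="coerce")
    out = pd.DataFrame(
        {
            "participant": sub["participant"].to_numpy(),
            "session": sub["session"].astype(int).to_numpy(),
            "task": sub["task"].to_numpy(),
            "centered_ar": np.where(np.isnan(ar.to_numpy()), 0.0, ar.to_numpy() - 1.0),
            "r1": (sub["l1_response"] == "deg0").astype(int).to_numpy(),
            "y2": (sub["l2_response"] == "deg0").astype(int).to_numpy(),
        }
    )
    return out.reset_index(drop=True)


def empirical_logits(
    binary_trials: pd.DataFrame,
    by_participant: bool = True,
) -> pd.DataFrame:
    """Empirical logit[p(L2 -> 0°)] per (participant,) centered AR and L1 percept.

    ``p = (successes + c) / (n + 2c)`` with the Haldane-Anscombe continuity
    constant ``c = 0.5`` applied only when the cell is degenerate
    (0 or n successes); ``logit = ln(p / (1 - p))``.  Empty cells are
    omitted.  Used for the logit-vs-aspect-ratio visualizations, where the
    vertical separation of the two L1-percept lines shows hysteresis and
    their common slope shows adaptation.
    """
    keys = (["participant"] if by_participant else []) + ["centered_ar", "r1"]
    g = binary_trials.groupby(keys, sort=True)["y2"].agg(["count", "sum"]).reset_index()
    g = g[g["count"] > 0]
    n = g["count"].to_numpy(float)
    k = g["sum"].to_numpy(float)
    degenerate = (k == 0) | (k == n)
    p = np.where(degenerate, (k + 0.5) / (n + 1.0), k / n)
    g["p"] = p
    g["logit"] = np.log(p / (1.0 - p))
    return g.drop(columns=["sum"]).rename(columns={"count": "n"}).reset_index(drop=True)


def response_bias_summary(trials: pd.DataFrame) -> pd.DataFrame:
    """Non-dominant-response and left-right asymmetry summaries per participant x session.

    ``p_diagonal_l1`` is the proportion of diagonal L1 reports in the main
    task, ``p_deg90_l2`` the proportion of (impossible at AR approximately 1)
    90° L2 reports, and ``left_right_asymmetry`` the absolute deviation from
    chance of choosing a left-hand response option for L2
    (``|p(left) - 0.5|``; NaN when hand codes are absent).
    """
    main = trials[trials["task"] == Task.MAIN.value]
    rows = []
    for (pid, sess), g in main.groupby(["participant", "session"], sort=True):
        hands = g["response_hand"].astype(str)
        coded = hands.isin(["left", "right"])
        asym = (
            abs((hands[coded] == "left").mean() - 0.5) if coded.any() else math.nan
        )
        rows.append(
            {
                "participant": pid,
                "session": int(sess),
                "p_diagonal_l1": float(g["l1_response"].isin(_L1_DIAGONAL).mean()),
                "p_deg90_l2": float((g["l2_response"] == "deg90").mean()),
                "left_right_asymmetry": float(asym),
            }
        )
    return pd.DataFrame(rows)
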