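"""Classify learned gating strategies: remember-both, remember-one, other.

A trained run is classified from its final (criterion) session: for each
start side, the proportion of trials on which the guided-turn observation
was in memory at the choice point.  A side counts as "remembered" if its
proportion strictly exceeds a threshold (default 2/3); both sides above
threshold is "remember-both", exactly one is "remember-left"/"remember-
right" (jointly reported as remember-one), neither is "other".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .experiment import Criterion, RunResult, SessionSchedule, simulate_runs
from .presets import OperatingPoint
from .rl_core import (
    GATE_MAINTAIN,
    GATE_UPDATE,
    MEM_EMPTY,
    MEM_LEFT_TURN,
    MEM_RIGHT_TURN,
    OBS_LEFT_TURN,
    OBS_RIGHT_TURN,
    ValueTables,
    state_index,
)
from .task_env import LEFT, RIGHT

STRATEGY_LABELS = ("remember-both", "remember-left", "remember-right", "other")
REMEMBER_ONE_LABELS = ("remember-left", "remember-right")

DEFAULT_THRESHOLD = 2.0 / 3.0


@dataclass(frozen=True)
class MemoryAtChoiceSummary:
    p_left: float
    p_right: float
    n_left_trials: int
    n_right_trials: int


def memory_at_choice_summary(run: RunResult) -> MemoryAtChoiceSummary:
    """Per-side proportions of final-session trials with the guided turn in
    memory at the choice point."""
    guided = np.asarray(run.final_guided)
    memory = np.asarray(run.final_memory_at_choice)
    left = guided == LEFT
    right = guided == RIGHT
    n_left, n_right = int(left.sum()), int(right.sum())
    if n_left == 0 or n_right == 0:
        raise ValueError(
            "unclassifiable run: final session has no trials for one start side")
    return MemoryAtChoiceSummary(
        p_left=float((memory[left] == MEM_LEFT_TURN).mean()),
        p_right=float((memory[right] == MEM_RIGHT_TURN).mean()),
        n_left_trials=n_left,
        n_right_trials=n_right,
    )


def classify_strategy(summary: MemoryAtChoiceSummary,
                      threshold: float = DEFAULT_THRESHOLD) -> str:
    """Apply the strict above-threshold rule to both sides."""
    left_ok = summary.p_left > threshold
    right_ok = summary.p_right > threshold
    if left_ok and right_ok:
        return "remember-both"
    if left_ok:
        return "remember-left"
    if right_ok:
        return "remember-right"
    return "other"


def classify_strategy_from_values(tables: ValueTables,
                                  threshold: float = 0.5) -> str:
    """Cross-check classifier reading greedy gating preferences.

    A side is "remembered" if the gating agent prefers updating on that
    guided-turn observation (empty memory) and maintaining it on the central
    arm.  ``threshold`` is on the greedy preference, i.e. 0.5 means strict
    argmax.
    """
    def prefers_update(obs, mem):
        s = state_index(obs, mem)
        return tables.q_gating[s, GATE_UPDATE] > tables.q_gating[s, GATE_MAINTAIN]

    def prefers_maintain(obs, mem):
        s = state_index(obs, mem)
        return tables.q_gating[s, GATE_MAINTAIN] > tables.q_gating[s, GATE_UPDATE]

    from .task_env import OBS_CENTRAL_ARM

    left_ok = (prefers_update(OBS_LEFT_TURN, MEM_EMPTY)
               and prefers_maintain(OBS_CENTRAL_ARM, MEM_LEFT_TURN))
    right_ok = (prefers_update(OBS_RIGHT_TURN, MEM_EMPTY)
                and prefers_maintain(OBS_CENTRAL_ARM, MEM_RIGHT_TURN))
    if left_ok and right_ok:
        return "remember-both"
    if left_ok:
        return "remember-left"
    if right_ok:
        return "remember-right"
    return "other"


def strategy_frequencies(point: OperatingPoint, n_runs: int = 100,
                         schedule: SessionSchedule | None = None,
                         seed: int = 0,
                         threshold: float = DEFAULT_THRESHOLD,
                         criterion: Criterion | None = None) -> dict:
    """Train ``n_runs`` independent runs to criterion and tabulate labels.

    Returns percentages per label (summing to 100), the remember-one total,
    and the per-run labels.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    schedule = schedule or SessionSchedule()
    runs = simulate_runs(point, n_runs, schedule, seed, criterion)
    labels = [classify_strategy(memory_at_choice_summary(r), threshold) for r in runs]
    counts = {label: labels.count(label) for label in STRATEGY_LABELS}
    percentages = {label: 100.0 * c / n_runs for label, c in counts.items()}
    return {
        "percentages": percentages,
        "remember_one_percent": sum(percentages[l] for l in REMEMBER_ONE_LABELS),
        "labels": labels,
        "n_runs": n_runs,
    }
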