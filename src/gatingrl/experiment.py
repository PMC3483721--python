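"""Session scheduling, criterion detection and the reversal protocol.

A *session* is a fixed block of trials (default 40).  Training proceeds
session by session until a performance criterion is met: the default
acquisition ("pre") criterion is three consecutive sessions at >= 85%
correct; transfer comparisons use a single session at >= 80%.  Rule
reversal carries the agent's value tables over unchanged and retrains under
the flipped rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._kernel import draws_per_trial, run_trials_fast
from .presets import OperatingPoint
from .rl_core import (
    GatingAgent,
    OBS_CHOICE_TURN,
    ValueTables,
    run_trial,
    two_action_probability,
    GATE_UPDATE,
    GATE_MAINTAIN,
    TURN_LEFT,
    TURN_RIGHT,
)
from .seeding import ArrayRng, rng_from_seed, spawn_seeds
from .task_env import TaskConfig


@dataclass(frozen=True)
class Criterion:
    """Performance criterion: ``consecutive`` sessions at >= ``threshold``."""

    threshold: float = 0.85
    consecutive: int = 3

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold <= 1.0:
            raise ValueError("threshold must be in (0, 1]")
        if self.consecutive < 1:
            raise ValueError("consecutive must be >= 1")


@dataclass(frozen=True)
class SessionSchedule:
    trials_per_session: int = 40
    pre_criterion: Criterion = Criterion(0.85, 3)
    post_criterion: Criterion = Criterion(0.80, 1)
    session_cap: int = 200

    def __post_init__(self) -> None:
        if self.trials_per_session < 1:
            raise ValueError("trials_per_session must be >= 1")
        if self.session_cap < max(self.pre_criterion.consecutive,
                                  self.post_criterion.consecutive):
            raise ValueError("session_cap must allow the criterion to be met")


@dataclass
class SessionResult:
    accuracy: float
    rewards: np.ndarray
    memory_at_choice: np.ndarray
    guided: np.ndarray
    trial_logs: list | None = None


@dataclass
class RunResult:
    """Outcome of training one agent to criterion."""

    session_accuracies: np.ndarray
    sessions_to_criterion: int
    censored: bool
    final_memory_at_choice: np.ndarray
    final_guided: np.ndarray
    final_tables: ValueTables
    variant: str
    #: SARSA action values are expected to stay within [0, 1]; a violation is
    #: flagged here (never silently dropped) rather than raised.
    values_left_unit_interval: bool = False

    def first_session_at(self, threshold: float) -> int | None:
        """1-based index of the first session at/above ``threshold``."""
        hits = np.nonzero(self.session_accuracies >= threshold)[0]
        return int(hits[0]) + 1 if hits.size else None


@dataclass
class ReversalResult:
    pre: RunResult
    post: RunResult
    config: TaskConfig


def run_session(agent: GatingAgent, config: TaskConfig, schedule: SessionSchedule,
                rng, detailed: bool = False) -> SessionResult:
    """Run one session of trials, updating the agent in place.

    The uniform stream for the whole session is generated up front; with
    ``detailed=True`` the pure-Python trial loop replays the identical
    stream and returns per-step :class:`TrialLog` records.
    """
    n = schedule.trials_per_session
    uniforms = rng.random_sample(n * draws_per_trial(config.n_central))
    if detailed:
        stream = ArrayRng(uniforms)
        logs = [run_trial(agent, config, stream) for _ in range(n)]
        rewards = np.array([log.reward for log in logs], dtype=np.int8)
        mem = np.array([log.memory_at_choice for log in logs], dtype=np.int8)
        guided = np.array([log.guided_direction for log in logs], dtype=np.int8)
        return SessionResult(float(rewards.mean()), rewards, mem, guided, logs)
    rewards, mem, guided = run_trials_fast(agent, config, n, uniforms)
    return SessionResult(float(rewards.mean()), rewards, mem, guided)


def run_until_criterion(agent: GatingAgent, config: TaskConfig,
                        schedule: SessionSchedule, rng,
                        criterion: Criterion | None = None) -> RunResult:
    """Train session-by-session until the criterion or the session cap.

    ``sessions_to_criterion`` is the 1-based index of the last qualifying
    session (e.g. 3 for an immediately perfect agent under the 85% x 3
    criterion); censored runs report the cap.
    """
    crit = schedule.pre_criterion if criterion is None else criterion
    accuracies: list[float] = []
    streak = 0
    last: SessionResult | None = None
    met = False
    while len(accuracies) < schedule.session_cap:
        last = run_session(agent, config, schedule, rng)
        accuracies.append(last.accuracy)
        streak = streak + 1 if last.accuracy >= crit.threshold else 0
        if streak >= crit.consecutive:
            met = True
            break
    out_of_bounds = False
    if agent.variant.startswith("sarsa"):
        out_of_bounds = bool(
            agent.tables.q_motor.min() < 0.0 or agent.tables.q_motor.max() > 1.0
            or agent.tables.q_gating.min() < 0.0 or agent.tables.q_gating.max() > 1.0)
        if out_of_bounds:
            import logging

            logging.getLogger("gatingrl").warning(
                "SARSA value tables left [0, 1] during this run")
    return RunResult(
        session_accuracies=np.asarray(accuracies),
        sessions_to_criterion=len(accuracies),
        censored=not met,
        final_memory_at_choice=last.memory_at_choice,
        final_guided=last.guided,
        final_tables=agent.tables.copy(),
        variant=agent.variant,
        values_left_unit_interval=out_of_bounds,
    )


def simulate_runs(point: OperatingPoint, n_runs: int, schedule: SessionSchedule,
                  seed: int, criterion: Criterion | None = None,
                  rule: str = "match") -> list[RunResult]:
    """Independent seeded training runs from fresh agents."""
    config = point.task_config(rule)
    seeds = spawn_seeds(seed, n_runs)
    results = []
    for s in seeds:
        agent = point.fresh_agent()
        results.append(run_until_criterion(agent, config, schedule,
                                           rng_from_seed(s), criterion))
    return results


def sessions_to_criterion_array(results: list[RunResult]) -> np.ndarray:
    return np.array([r.sessions_to_criterion for r in results], dtype=float)


def run_reversal(point: OperatingPoint, schedule: SessionSchedule, seed: int,
                 rule: str = "match") -> ReversalResult:
    """Acquisition under ``rule``, then retraining under the reversed rule.

    The acquisition phase trains a fresh agent to the pre-criterion (as the
    animals were trained); the rule is then reversed for that run and
    training continues with the same value tables until the post-criterion
    or the cap.  Traces are reset at every trial start as always.
    """
    rng = rng_from_seed(seed)
    config = point.task_config(rule)
    agent = point.fresh_agent()
    pre = run_until_criterion(agent, config, schedule, rng, schedule.pre_criterion)
    post = run_until_criterion(agent, config.reversed(), schedule, rng,
                               schedule.post_criterion)
    return ReversalResult(pre=pre, post=post, config=config)


def run_reversals(point: OperatingPoint, n_runs: int, schedule: SessionSchedule,
                  seed: int, rule: str = "match") -> list[ReversalResult]:
    return [run_reversal(point, schedule, s, rule)
            for s in spawn_seeds(seed, n_runs, tag=1)]


def aggregate_learning_curves(results: list[RunResult],
                              max_sessions: int | None = None) -> pd.DataFrame:
    """Per-session mean/SD of accuracy over runs.

    Runs shorter than ``max_sessions`` contribute only to the sessions they
    actually ran; the ``n_runs`` column records how many runs back each
    session's mean.
    """
    if not results:
        raise ValueError("aggregate_learning_curves needs at least one run")
    longest = max(len(r.session_accuracies) for r in results)
    if max_sessions is not None:
        longest = min(longest, max_sessions)
    rows = []
    for i in range(longest):
        vals = np.array([r.session_accuracies[i] for r in results
                         if len(r.session_accuracies) > i])
        rows.append({"session": i + 1, "mean_accuracy": vals.mean(),
                     "sd_accuracy": vals.std(ddof=0) if vals.size > 1 else 0.0,
                     "n_runs": vals.size})
    return pd.DataFrame(rows)


def transfer_statistics(pre_counts, post_counts) -> dict:
    """Paired descriptive comparison of pre- vs post-reversal session counts.

    Returns the mean paired difference (pre - post; positive means faster
    post-reversal learning), its SD and standard error, and the fraction of
    pairs with pre > post.  No parametric test is claimed.
    """
    pre = np.asarray(pre_counts, dtype=float)
    post = np.asarray(post_counts, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and post samples must be paired (equal length)")
    diff = pre - post
    n = diff.size
    sd = diff.std(ddof=1) if n > 1 else 0.0
    return {
        "n": int(n),
        "mean_pre": float(pre.mean()),
        "mean_post": float(post.mean()),
        "mean_difference": float(diff.mean()),
        "sd_difference": float(sd),
        "sem_difference": float(sd / np.sqrt(n)) if n > 1 else 0.0,
        "sign_consistency": float((diff > 0).mean()),
    }


def policy_change_stats(before: ValueTables, after: ValueTables,
                        temperature: float) -> dict:
    """Mean absolute softmax-probability change, gating vs motor.

    Gating change is averaged over P(update | s) at the 12 pre-choice
    states; motor change over P(turn-left | s) at the 4 choice states.
    Used to quantify that reversal leaves the gating policy largely intact
    while the motor policy flips.
    """
    gating_changes = []
    motor_changes = []
    for s in range(16):
        obs = s // 4
        if obs == OBS_CHOICE_TURN:
            motor_changes.append(abs(
                two_action_probability(after.q_motor[s, TURN_LEFT],
                                       after.q_motor[s, TURN_RIGHT], temperature)
                - two_action_probability(before.q_motor[s, TURN_LEFT],
                                         before.q_motor[s, TURN_RIGHT], temperature)))
        else:
            gating_changes.append(abs(
                two_action_probability(after.q_gating[s, GATE_UPDATE],
                                       after.q_gating[s, GATE_MAINTAIN], temperature)
                - two_action_probability(before.q_gating[s, GATE_UPDATE],
                                         before.q_gating[s, GATE_MAINTAIN], temperature)))
    return {
        "mean_abs_gating_change": float(np.mean(gating_changes)),
        "mean_abs_motor_change": float(np.mean(motor_changes)),
    }
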