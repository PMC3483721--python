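"""Session scheduling, criterion detection, aggregation, transfer summaries."""

import numpy as np
import pytest

from gatingrl.experiment import (
    Criterion,
    RunResult,
    SessionSchedule,
    aggregate_learning_curves,
    run_session,
    run_until_criterion,
    simulate_runs,
    transfer_statistics,
)
from gatingrl.presets import SARSA_BEST_FIT, OperatingPoint
from gatingrl.rl_core import GatingAgent, HyperParams, ValueTables
from gatingrl.seeding import rng_from_seed
from gatingrl.task_env import TaskConfig


def _run_result(accuracies, stc=None, censored=False):
    acc = np.asarray(accuracies, dtype=float)
    return RunResult(acc, stc or len(acc), censored, np.zeros(1, dtype=np.int8),
                     np.zeros(1, dtype=np.int8), ValueTables.zeros("sarsa"), "sarsa")


def test_schedule_validation():
    with pytest.raises(ValueError):
        SessionSchedule(trials_per_session=0)
    with pytest.raises(ValueError):
        SessionSchedule(session_cap=2)  # cannot fit three consecutive sessions
    with pytest.raises(ValueError):
        Criterion(threshold=1.2)


def test_default_schedule_matches_protocol(schedule):
    assert schedule.trials_per_session == 40
    assert (schedule.pre_criterion.threshold, schedule.pre_criterion.consecutive) == (0.85, 3)
    assert (schedule.post_criterion.threshold, schedule.post_criterion.consecutive) == (0.80, 1)


def test_random_agent_session_accuracy_near_chance(schedule):
    agent = GatingAgent.fresh("sarsa", HyperParams(1e-9, 100.0, 0.5))
    config = TaskConfig(n_central=2)
    rng = rng_from_seed(0)
    accs = [run_session(agent, config, schedule, rng).accuracy for _ in range(50)]
    assert abs(np.mean(accs) - 0.5) < 0.03


def test_run_session_detailed_path_matches_fast_path(schedule):
    params = HyperParams(0.31, 0.13, 0.03)
    config = TaskConfig(n_central=3)
    fast = run_session(GatingAgent.fresh("sarsa", params), config, schedule,
                       rng_from_seed(9))
    detailed = run_session(GatingAgent.fresh("sarsa", params), config, schedule,
                           rng_from_seed(9), detailed=True)
    assert fast.accuracy == detailed.accuracy
    assert np.array_equal(fast.rewards, detailed.rewards)
    assert np.array_equal(fast.memory_at_choice, detailed.memory_at_choice)
    assert len(detailed.trial_logs) == schedule.trials_per_session


def test_criterion_requires_consecutive_sessions(monkeypatch, schedule):
    """[0.9, 0.8, 0.9, 0.9, 0.9] meets 0.85 x 3-consecutive at session 5."""
    scripted = iter([0.9, 0.8, 0.9, 0.9, 0.9, 1.0, 1.0])

    class Result:
        def __init__(self, acc):
            self.accuracy = acc
            self.memory_at_choice = np.zeros(1, dtype=np.int8)
            self.guided = np.zeros(1, dtype=np.int8)
            self.rewards = np.zeros(1, dtype=np.int8)

    monkeypatch.setattr("gatingrl.experiment.run_session",
                        lambda *a, **k: Result(next(scripted)))
    agent = GatingAgent.fresh("sarsa", HyperParams(0.3, 0.2, 0.1))
    result = run_until_criterion(agent, TaskConfig(n_central=1), schedule,
                                 rng_from_seed(0))
    assert result.sessions_to_criterion == 5
    assert not result.censored
    assert list(result.session_accuracies) == [0.9, 0.8, 0.9, 0.9, 0.9]


def test_nonlearning_agent_censored_at_cap():
    agent = GatingAgent.fresh("sarsa", HyperParams(1e-9, 100.0, 0.5))
    schedule = SessionSchedule(trials_per_session=10, session_cap=8)
    result = run_until_criterion(agent, TaskConfig(n_central=1), schedule,
                                 rng_from_seed(1))
    assert result.censored and result.sessions_to_criterion == 8


def test_first_session_at_threshold():
    run = _run_result([0.5, 0.7, 0.82, 0.9, 0.86])
    assert run.first_session_at(0.80) == 3
    assert run.first_session_at(0.99) is None


def test_simulate_runs_reproducible(schedule):
    point = OperatingPoint("sarsa", 2, 0.31, 0.13, 0.03)
    a = simulate_runs(point, 5, schedule, seed=42)
    b = simulate_runs(point, 5, schedule, seed=42)
    assert [r.sessions_to_criterion for r in a] == [r.sessions_to_criterion for r in b]
    c = simulate_runs(point, 5, schedule, seed=43)
    assert [r.sessions_to_criterion for r in a] != [r.sessions_to_criterion for r in c]


def test_aggregate_learning_curves_conventions():
    single = aggregate_learning_curves([_run_result([0.5, 0.7, 0.9])])
    assert list(single["mean_accuracy"]) == [0.5, 0.7, 0.9]
    assert list(single["sd_accuracy"]) == [0.0, 0.0, 0.0]

    identical = aggregate_learning_curves([_run_result([0.5, 0.9])] * 4)
    assert np.all(identical["sd_accuracy"] == 0.0)
    assert np.all(identical["n_runs"] == 4)

    ragged = aggregate_learning_curves([_run_result([0.5, 0.7, 0.9]),
                                        _run_result([0.5])])
    assert list(ragged["n_runs"]) == [2, 1, 1]

    with pytest.raises(ValueError):
        aggregate_learning_curves([])


def test_learning_curve_rises_from_chance_to_criterion(schedule):
    runs = simulate_runs(SARSA_BEST_FIT, 60, schedule, seed=2)
    curves = aggregate_learning_curves(runs, max_sessions=40)
    early = curves["mean_accuracy"].iloc[:2].mean()
    assert 0.4 < early < 0.62  # starts at chance
    mid = curves["mean_accuracy"].iloc[14:20].mean()
    assert mid > early + 0.1  # clear improvement by mid-training
    # every uncensored run ends its last three sessions at/above criterion
    assert all(np.all(r.session_accuracies[-3:] >= 0.85)
               for r in runs if not r.censored)


def test_transfer_statistics_paired_summaries():
    same = transfer_statistics([5, 6, 7], [5, 6, 7])
    assert same["mean_difference"] == 0.0
    shifted = transfer_statistics([10, 12, 14], [5, 7, 9])
    assert shifted["mean_difference"] == 5.0
    assert shifted["sign_consistency"] == 1.0
    with pytest.raises(ValueError):
        transfer_statistics([1, 2], [1])


def test_reversal_flips_motor_policy_but_spares_gating_policy(schedule):
    """Under SARSA, reacquiring the reversed rule changes choice-turn motor
    preferences far more than pre-choice gating preferences."""
    from gatingrl.experiment import policy_change_stats, run_reversals

    revs = run_reversals(SARSA_BEST_FIT, 30, schedule, seed=44)
    gating, motor = [], []
    for rev in revs:
        stats = policy_change_stats(rev.pre.final_tables, rev.post.final_tables,
                                    SARSA_BEST_FIT.temperature)
        gating.append(stats["mean_abs_gating_change"])
        motor.append(stats["mean_abs_motor_change"])
    assert np.mean(gating) < np.mean(motor)
    # SARSA values never left [0, 1] (flagged per run, asserted here)
    assert not any(r.pre.values_left_unit_interval or
                   r.post.values_left_unit_interval for r in revs)


def test_monotone_difficulty_in_n_central(schedule):
    """Mean sessions-to-criterion does not decrease as the arm gets deeper."""
    means = []
    for n in (1, 3, 5):
        point = OperatingPoint("sarsa", n, 0.31, 0.13, 0.03)
        runs = simulate_runs(point, 40, schedule, seed=8)
        means.append(np.mean([r.sessions_to_criterion for r in runs]))
    assert means[0] < means[1] < means[2]
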