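"""Agent mechanics: softmax, gating, TD errors, traces, updates, trials."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gatingrl.rl_core import (
    GATE_MAINTAIN,
    GATE_UPDATE,
    MEM_EMPTY,
    MEM_LEFT_TURN,
    GatingAgent,
    HyperParams,
    TDErrors,
    TraceTables,
    ValueTables,
    apply_gating,
    decay_traces,
    evaluate_policy_exact,
    greedy_policy_from_tables,
    remember_both_policy,
    remember_one_policy,
    run_trial,
    select_actions,
    set_replacing_traces,
    softmax_probabilities,
    state_index,
    td_error_actor_critic,
    td_errors_sarsa,
    uniform_policy,
    update_values,
)
from gatingrl.task_env import (
    GO_STRAIGHT,
    LEFT,
    OBS_CENTRAL_ARM,
    OBS_CHOICE_TURN,
    OBS_LEFT_TURN,
    RIGHT,
    TURN_LEFT,
    TURN_RIGHT,
    TaskConfig,
)

# ---------------------------------------------------------------------------
# softmax
# ---------------------------------------------------------------------------


def test_softmax_matches_direct_evaluation():
    p = softmax_probabilities([1.0, 0.0], temperature=1.0)
    assert p == pytest.approx([0.7311, 0.2689], abs=1e-4)


def test_softmax_equal_values_uniform():
    p = softmax_probabilities([2.0, 2.0, 2.0], temperature=0.37)
    assert p == pytest.approx([1 / 3] * 3)


def test_softmax_low_temperature_is_greedy():
    p = softmax_probabilities([1.0, 0.0], temperature=1e-4)
    assert p[0] > 1 - 1e-12


def test_softmax_rejects_bad_inputs():
    with pytest.raises(ValueError):
        softmax_probabilities([1.0, 0.0], temperature=0.0)
    with pytest.raises(ValueError):
        softmax_probabilities([], temperature=1.0)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    values=st.lists(st.floats(-50, 50), min_size=1, max_size=6),
    temperature=st.floats(0.01, 20),
    shift=st.floats(-100, 100),
)
def test_softmax_sums_to_one_and_shift_invariant(values, temperature, shift):
    p = softmax_probabilities(values, temperature)
    q = softmax_probabilities(np.asarray(values) + shift, temperature)
    assert abs(p.sum() - 1.0) < 1e-12
    assert np.all(p >= 0)
    assert np.allclose(p, q, atol=1e-9)


# ---------------------------------------------------------------------------
# selection and gating
# ---------------------------------------------------------------------------


def test_forced_motor_action_consumes_no_randomness(sarsa_agent, rng):
    s = state_index(OBS_CENTRAL_ARM, MEM_EMPTY)
    a, _ = select_actions(s, sarsa_agent.tables, sarsa_agent.params,
                          (GO_STRAIGHT,), rng)
    assert a == GO_STRAIGHT


def test_gating_choice_is_symmetric_with_equal_values(sarsa_agent, rng):
    s = state_index(OBS_LEFT_TURN, MEM_EMPTY)
    gates = [select_actions(s, sarsa_agent.tables, sarsa_agent.params,
                            (GO_STRAIGHT,), rng)[1] for _ in range(4000)]
    assert abs(np.mean([g == GATE_UPDATE for g in gates]) - 0.5) < 0.03


def test_strong_preference_is_near_deterministic(rng):
    agent = GatingAgent.fresh("sarsa", HyperParams(0.1, 0.01, 0.5))
    s = state_index(OBS_CHOICE_TURN, MEM_LEFT_TURN)
    agent.tables.q_motor[s, TURN_LEFT] = 1.0
    actions = [select_actions(s, agent.tables, agent.params,
                              (TURN_LEFT, TURN_RIGHT), rng)[0]
               for _ in range(200)]
    assert all(a == TURN_LEFT for a in actions)


def test_apply_gating_update_maintain_and_choice_discard():
    assert apply_gating(MEM_EMPTY, OBS_LEFT_TURN, GATE_UPDATE) == MEM_LEFT_TURN
    assert apply_gating(MEM_LEFT_TURN, OBS_CENTRAL_ARM, GATE_MAINTAIN) == MEM_LEFT_TURN
    assert apply_gating(MEM_EMPTY, OBS_CENTRAL_ARM, GATE_MAINTAIN) == MEM_EMPTY
    # choice-turn content is discarded with the trial, never stored
    assert apply_gating(MEM_LEFT_TURN, OBS_CHOICE_TURN, GATE_UPDATE) == MEM_LEFT_TURN


# ---------------------------------------------------------------------------
# TD errors, traces, updates
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("r, v_next, v_curr, expected", [
    (0.0, 0.0, 0.0, 0.0),
    (1.0, 0.0, 0.4, 0.6),
    (0.0, 0.8, 0.5, 0.3),
])
def test_actor_critic_td_error(r, v_next, v_curr, expected):
    assert td_error_actor_critic(r, v_next, v_curr) == pytest.approx(expected)


@pytest.mark.parametrize("args, expected", [
    ((0.0, 0.0, 0.0, 0.0, 0.0), (0.0, 0.0)),
    ((1.0, 0.0, 0.3, 0.0, 0.7), (0.7, 0.3)),
    ((0.0, 0.5, 0.5, 0.2, 0.2), (0.0, 0.0)),
])
def test_sarsa_td_errors(args, expected):
    assert td_errors_sarsa(*args) == pytest.approx(expected)


def test_replacing_traces_set_only_current_entries():
    traces = TraceTables.zeros("actor-critic")
    s = state_index(OBS_LEFT_TURN, MEM_EMPTY)
    set_replacing_traces(traces, s, GO_STRAIGHT, GATE_UPDATE, "actor-critic")
    assert traces.motor[s, GO_STRAIGHT] == 1.0
    assert traces.gating[s, GATE_UPDATE] == 1.0
    assert traces.state[s] == 1.0
    assert traces.motor.sum() == 1.0 and traces.gating.sum() == 1.0
    assert TraceTables.zeros("sarsa").state is None


def test_update_values_moves_only_traced_entries():
    tables = ValueTables.zeros("sarsa")
    traces = TraceTables.zeros("sarsa")
    s = state_index(OBS_CHOICE_TURN, MEM_LEFT_TURN)
    set_replacing_traces(traces, s, TURN_LEFT, GATE_MAINTAIN, "sarsa")
    update_values(tables, traces, TDErrors(delta_motor=1.0, delta_gating=0.5),
                  alpha=0.1, variant="sarsa")
    assert tables.q_motor[s, TURN_LEFT] == pytest.approx(0.1)
    assert tables.q_gating[s, GATE_MAINTAIN] == pytest.approx(0.05)
    assert tables.q_motor.sum() == pytest.approx(0.1)


def test_restricted_update_clips_to_unit_interval():
    tables = ValueTables.zeros("actor-critic-restricted")
    traces = TraceTables.zeros("actor-critic-restricted")
    s = state_index(OBS_CHOICE_TURN, MEM_LEFT_TURN)
    tables.q_motor[s, TURN_LEFT] = 0.95
    set_replacing_traces(traces, s, TURN_LEFT, GATE_UPDATE, "actor-critic-restricted")
    update_values(tables, traces, TDErrors(delta=1.0), alpha=0.10,
                  variant="actor-critic-restricted")
    assert tables.q_motor[s, TURN_LEFT] == 1.0  # clip(0.95 + 0.10)
    update_values(tables, traces, TDErrors(delta=-100.0), alpha=0.10,
                  variant="actor-critic-restricted")
    assert tables.q_motor.min() == 0.0 and tables.v.min() == 0.0


@pytest.mark.parametrize("lam, factor", [(0.0, 0.0), (1.0, 1.0), (0.93, 0.93)])
def test_trace_decay(lam, factor):
    traces = TraceTables.zeros("actor-critic")
    traces.motor[:] = 1.0
    traces.gating[:] = 1.0
    traces.state[:] = 1.0
    decay_traces(traces, gamma=1.0, lam=lam)
    assert np.all(traces.motor == factor)
    assert np.all(traces.state == factor)


# ---------------------------------------------------------------------------
# trials
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("variant", ["actor-critic", "sarsa"])
def test_trial_log_length_and_first_nonzero_td(variant, config5, rng):
    agent = GatingAgent.fresh(variant, HyperParams(0.3, 0.5, 0.5))
    rewards = []
    for _ in range(200):
        log = run_trial(agent, config5, rng)
        assert len(log.steps) == config5.n_steps == 7
        rewards.append(log.reward)
        if log.reward == 0 and not any(rewards[:-1]):
            # before the first rewarded trial, zero-initialized values stay zero
            assert np.all(agent.tables.q_motor == 0.0)
    assert any(rewards)


def test_untrained_agent_is_at_chance(config5, rng):
    agent = GatingAgent.fresh("sarsa", HyperParams(1e-9, 100.0, 0.5))
    rewards = [run_trial(agent, config5, rng).reward for _ in range(4000)]
    assert abs(np.mean(rewards) - 0.5) < 0.03


def test_traces_zero_at_trial_start(config5, rng, sarsa_agent):
    run_trial(sarsa_agent, config5, rng)
    assert sarsa_agent.traces.motor.max() > 0  # traces left over from the trial
    # the next trial resets them before any step
    log = run_trial(sarsa_agent, config5, rng)
    assert log.steps[0].step_index == 0


# ---------------------------------------------------------------------------
# exact policy evaluation oracle
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("n_central", range(1, 9))
@pytest.mark.parametrize("rule", ["match", "non-match"])
def test_handcoded_policies_are_exactly_optimal(n_central, rule):
    config = TaskConfig(n_central=n_central, rule=rule)
    for policy in (remember_both_policy(rule),
                   remember_one_policy(LEFT, rule),
                   remember_one_policy(RIGHT, rule)):
        assert evaluate_policy_exact(*policy, config) == pytest.approx(1.0)
    assert evaluate_policy_exact(*uniform_policy(), config) == pytest.approx(0.5)


def test_remember_one_fails_under_wrong_rule():
    config = TaskConfig(n_central=3, rule="non-match")
    motor, gating = remember_one_policy(RIGHT, "match")
    assert evaluate_policy_exact(motor, gating, config) == pytest.approx(0.0)


def test_greedy_policy_of_trained_agent_beats_criterion(config5):
    """After training to criterion, the greedy policy is reliably correct."""
    from gatingrl.experiment import SessionSchedule, run_until_criterion
    from gatingrl.seeding import rng_from_seed

    agent = GatingAgent.fresh("sarsa", HyperParams(0.31, 0.13, 0.03))
    config = TaskConfig(n_central=3)
    result = run_until_criterion(agent, config, SessionSchedule(), rng_from_seed(5))
    assert not result.censored
    motor, gating = greedy_policy_from_tables(result.final_tables)
    assert evaluate_policy_exact(motor, gating, config) > 0.85
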