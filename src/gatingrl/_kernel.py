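"""Compiled batch trial loop.

Numerically identical to :func:`gatingrl.rl_core.run_trial`, compiled with
numba for session-scale simulation.  Randomness enters only through a
pre-generated array of uniforms; each trial consumes exactly
``n_central + 4`` draws (one start draw, one gating draw per step, one motor
draw at the choice turn), in the same order as the reference path, so the
two implementations produce bit-identical trajectories from the same stream.
"""

from __future__ import annotations

import numpy as np
from numba import njit

DRAWS_PER_TRIAL_OFFSET = 4  # draws per trial = n_central + 4


def draws_per_trial(n_central: int) -> int:
    return n_central + DRAWS_PER_TRIAL_OFFSET


@njit(cache=True)
def _run_trials(sarsa, clip01, n_central, rule_match, p_left,
                alpha, temperature, lam, gamma,
                q_motor, q_gating, v, uniforms,
                rewards, mem_at_choice, guided_out):  # pragma: no cover
    n_trials = rewards.shape[0]
    e_motor = np.zeros((16, 3))
    e_gating = np.zeros((16, 2))
    e_state = np.zeros(16)
    stride = n_central + 4
    for t in range(n_trials):
        k = t * stride
        for i in range(16):
            e_state[i] = 0.0
            for j in range(3):
                e_motor[i, j] = 0.0
            for j in range(2):
                e_gating[i, j] = 0.0
        u = uniforms[k]
        k += 1
        guided = 0 if u < p_left else 1
        # action codes: 1 = turn-left, 2 = turn-right
        if rule_match:
            correct_a = 1 + guided
        else:
            correct_a = 2 - guided
        mem = 3  # empty
        obs = guided
        s = obs * 4 + mem
        a = 0
        g = 0
        if sarsa:
            # initial selection at s (obs is a guided turn: motor forced)
            p_upd = 1.0 / (1.0 + np.exp((q_gating[s, 1] - q_gating[s, 0]) / temperature))
            u = uniforms[k]
            k += 1
            g = 0 if u < p_upd else 1
        for step in range(n_central + 2):
            at_choice = obs == 3
            if not sarsa:
                if at_choice:
                    p_first = 1.0 / (1.0 + np.exp((q_motor[s, 2] - q_motor[s, 1]) / temperature))
                    u = uniforms[k]
                    k += 1
                    a = 1 if u < p_first else 2
                else:
                    a = 0
                p_upd = 1.0 / (1.0 + np.exp((q_gating[s, 1] - q_gating[s, 0]) / temperature))
                u = uniforms[k]
                k += 1
                g = 0 if u < p_upd else 1
            if at_choice:
                mem_at_choice[t] = mem
            if g == 0 and not at_choice:
                mem = obs
            a2 = 0
            g2 = 0
            sp = -1
            if at_choice:
                r = 1.0 if a == correct_a else 0.0
                terminal = True
            else:
                r = 0.0
                terminal = False
                obs2 = 2 if step + 1 <= n_central else 3
                sp = obs2 * 4 + mem
            if sarsa:
                if not terminal:
                    if sp // 4 == 3:
                        p_first = 1.0 / (1.0 + np.exp((q_motor[sp, 2] - q_motor[sp, 1]) / temperature))
                        u = uniforms[k]
                        k += 1
                        a2 = 1 if u < p_first else 2
                    else:
                        a2 = 0
                    p_upd = 1.0 / (1.0 + np.exp((q_gating[sp, 1] - q_gating[sp, 0]) / temperature))
                    u = uniforms[k]
                    k += 1
                    g2 = 0 if u < p_upd else 1
                qm_next = 0.0 if terminal else q_motor[sp, a2]
                qg_next = 0.0 if terminal else q_gating[sp, g2]
                d_m = r + gamma * qm_next - q_motor[s, a]
                d_g = r + gamma * qg_next - q_gating[s, g]
            else:
                v_next = 0.0 if terminal else v[sp]
                d = r + gamma * v_next - v[s]
            e_motor[s, a] = 1.0
            e_gating[s, g] = 1.0
            if not sarsa:
                e_state[s] = 1.0
            if sarsa:
                for i in range(16):
                    for j in range(3):
                        q_motor[i, j] += alpha * d_m * e_motor[i, j]
                    for j in range(2):
                        q_gating[i, j] += alpha * d_g * e_gating[i, j]
            else:
                for i in range(16):
                    for j in range(3):
                        q_motor[i, j] += alpha * d * e_motor[i, j]
                    for j in range(2):
                        q_gating[i, j] += alpha * d * e_gating[i, j]
                    v[i] += alpha * d * e_state[i]
                if clip01:
                    for i in range(16):
                        for j in range(3):
                            if q_motor[i, j] < 0.0:
                                q_motor[i, j] = 0.0
                            elif q_motor[i, j] > 1.0:
                                q_motor[i, j] = 1.0
                        for j in range(2):
                            if q_gating[i, j] < 0.0:
                                q_gating[i, j] = 0.0
                            elif q_gating[i, j] > 1.0:
                                q_gating[i, j] = 1.0
                        if v[i] < 0.0:
                            v[i] = 0.0
                        elif v[i] > 1.0:
                            v[i] = 1.0
            decay = gamma * lam
            for i in range(16):
                e_state[i] *= decay
                for j in range(3):
                    e_motor[i, j] *= decay
                for j in range(2):
                    e_gating[i, j] *= decay
            if terminal:
                rewards[t] = int(r)
                break
            s = sp
            obs = obs2
            if sarsa:
                a = a2
                g = g2
        guided_out[t] = guided


def run_trials_fast(agent, config, n_trials: int, uniforms: np.ndarray):
    """Run ``n_trials`` episodes with the compiled loop, mutating the agent.

    Returns (rewards, memory_at_choice, guided) int8 arrays of length
    ``n_trials``.  ``uniforms`` must hold exactly
    ``n_trials * draws_per_trial(config.n_central)`` values.
    """
    from .rl_core import is_sarsa, is_value_clipped

    expected = n_trials * draws_per_trial(config.n_central)
    if uniforms.shape[0] != expected:
        raise ValueError(f"need {expected} uniforms, got {uniforms.shape[0]}")
    rewards = np.zeros(n_trials, dtype=np.int8)
    mem_at_choice = np.zeros(n_trials, dtype=np.int8)
    guided = np.zeros(n_trials, dtype=np.int8)
    v = agent.tables.v
    if v is None:
        v = np.zeros(16)  # unused placeholder for SARSA variants
    _run_trials(
        is_sarsa(agent.variant),
        is_value_clipped(agent.variant),
        config.n_central,
        config.rule == "match",
        config.start_probability_left,
        agent.params.alpha,
        agent.params.temperature,
        agent.params.trace_decay,
        agent.params.discount,
        agent.tables.q_motor,
        agent.tables.q_gating,
        v,
        uniforms,
        rewards,
        mem_at_choice,
        guided,
    )
    return rewards, mem_at_choice, guided
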