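"""Tabular Actor-Critic and SARSA working-memory gating agents.

Two agents share one state space S = observations x memory contents
(4 x 4 = 16 states): a *motor* agent choosing overt movement and a *gating*
agent choosing whether to update or maintain a single working-memory slot.
Both select actions by softmax over tabular values with temperature ``T``,
learn from temporal-difference errors with replacing eligibility traces
(decay ``lambda``), and use discount ``gamma = 1`` (episodic task).

Variants
--------
``actor-critic``
    One critic TD error ``delta = r + gamma*V(s') - V(s)`` drives updates of
    motor preferences Q^M, gating preferences Q^G and state values V.
``sarsa``
    Two on-policy TD errors, one per agent, from successive state-action
    values; the next actions are chosen before the update and carried over.
``actor-critic-restricted``
    Actor-Critic with every table entry clipped into [0, 1] after each
    update.
``sarsa-restricted``
    SARSA with the trace decay forced to ``lambda = 1`` (no within-trial
    decay).

This module is the readable reference implementation; ``gatingrl._kernel``
contains a numerically identical compiled batch loop used for large
simulations.  Both consume uniform variates in exactly the same order, so
they produce bit-identical trajectories from the same stream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .task_env import (
    GO_STRAIGHT,
    LEFT,
    OBS_CHOICE_TURN,
    OBS_LEFT_TURN,
    OBS_RIGHT_TURN,
    RIGHT,
    TURN_LEFT,
    TURN_RIGHT,
    TaskConfig,
    available_motor_actions,
    correct_choice,
    observation_at,
    reset_trial,
    step_env,
)

# --- memory content codes (share 0..2 with observation codes) --------------
MEM_LEFT_TURN = 0
MEM_RIGHT_TURN = 1
MEM_CENTRAL_ARM = 2
MEM_EMPTY = 3
MEMORY_CONTENTS = ("left-turn", "right-turn", "central-arm", "empty")

# --- gating action codes ---------------------------------------------------
GATE_UPDATE = 0
GATE_MAINTAIN = 1
GATING_ACTIONS = ("update", "maintain")

N_STATES = 16  # 4 observations x 4 memory contents
N_MOTOR = 3
N_GATING = 2

VARIANTS = ("actor-critic", "sarsa", "actor-critic-restricted", "sarsa-restricted")


def state_index(observation: int, memory: int) -> int:
    """Flat index of the (observation, memory) pair; all 16 addressable."""
    return observation * 4 + memory


def state_label(index: int) -> str:
    from .task_env import OBSERVATIONS

    return f"{OBSERVATIONS[index // 4]}|{MEMORY_CONTENTS[index % 4]}"


def is_sarsa(variant: str) -> bool:
    _check_variant(variant)
    return variant.startswith("sarsa")


def uses_state_values(variant: str) -> bool:
    _check_variant(variant)
    return variant.startswith("actor-critic")


def is_value_clipped(variant: str) -> bool:
    _check_variant(variant)
    return variant == "actor-critic-restricted"


def _check_variant(variant: str) -> None:
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")


@dataclass(frozen=True)
class HyperParams:
    """Learning hyperparameters (alpha, T, lambda; gamma fixed at 1)."""

    alpha: float
    temperature: float
    trace_decay: float
    discount: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if not 0.0 <= self.trace_decay <= 1.0:
            raise ValueError("trace_decay must be in [0, 1]")
        if self.discount != 1.0:
            raise ValueError("discount is fixed at 1 for this episodic task")


@dataclass
class ValueTables:
    """Q^M (16x3), Q^G (16x2) and, for Actor-Critic variants, V (16)."""

    q_motor: np.ndarray
    q_gating: np.ndarray
    v: np.ndarray | None = None

    @classmethod
    def zeros(cls, variant: str) -> "ValueTables":
        return cls(
            q_motor=np.zeros((N_STATES, N_MOTOR)),
            q_gating=np.zeros((N_STATES, N_GATING)),
            v=np.zeros(N_STATES) if uses_state_values(variant) else None,
        )

    def copy(self) -> "ValueTables":
        return ValueTables(
            self.q_motor.copy(),
            self.q_gating.copy(),
            None if self.v is None else self.v.copy(),
        )


@dataclass
class TraceTables:
    """Replacing eligibility traces mirroring the value tables."""

    motor: np.ndarray
    gating: np.ndarray
    state: np.ndarray | None = None

    @classmethod
    def zeros(cls, variant: str) -> "TraceTables":
        return cls(
            motor=np.zeros((N_STATES, N_MOTOR)),
            gating=np.zeros((N_STATES, N_GATING)),
            state=np.zeros(N_STATES) if uses_state_values(variant) else None,
        )

    def reset(self) -> None:
        self.motor[:] = 0.0
        self.gating[:] = 0.0
        if self.state is not None:
            self.state[:] = 0.0


@dataclass
class TDErrors:
    """TD errors: ``delta`` (Actor-Critic) or ``delta_motor``/``delta_gating``."""

    delta: float | None = None
    delta_motor: float | None = None
    delta_gating: float | None = None


@dataclass
class GatingAgent:
    variant: str
    params: HyperParams
    tables: ValueTables
    traces: TraceTables

    @classmethod
    def fresh(cls, variant: str, params: HyperParams) -> "GatingAgent":
        """New agent with all-zero tables; sarsa-restricted forces lambda=1."""
        _check_variant(variant)
        if variant == "sarsa-restricted" and params.trace_decay != 1.0:
            params = HyperParams(params.alpha, params.temperature, 1.0, params.discount)
        return cls(variant, params, ValueTables.zeros(variant), TraceTables.zeros(variant))


# ---------------------------------------------------------------------------
# Action selection
# ---------------------------------------------------------------------------

def softmax_probabilities(values, temperature: float) -> np.ndarray:
    """Softmax with max-shift; invariant to adding a constant to all values."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("softmax needs at least one action value")
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    z = (values - values.max()) / temperature
    e = np.exp(z)
    return e / e.sum()


def two_action_probability(q_first: float, q_second: float, temperature: float) -> float:
    """P(first action) for a two-action softmax.

    Written as a logistic of the value difference so that the compiled kernel
    and this reference path compute the identical float.
    """
    return 1.0 / (1.0 + math.exp((q_second - q_first) / temperature))


def select_actions(state: int, tables: ValueTables, params: HyperParams,
                   legal_motor: tuple[int, ...], rng) -> tuple[int, int]:
    """Sample (motor, gating) actions by softmax over the legal sets.

    A singleton legal motor set is taken with probability 1 and consumes no
    randomness; the gating choice between update/maintain always consumes
    exactly one uniform draw.  Draw order: motor first (when free), then
    gating.
    """
    if len(legal_motor) == 0:
        raise ValueError("legal_motor must be nonempty")
    if len(legal_motor) == 1:
        a = legal_motor[0]
    elif len(legal_motor) == 2:
        p_first = two_action_probability(
            tables.q_motor[state, legal_motor[0]],
            tables.q_motor[state, legal_motor[1]],
            params.temperature,
        )
        a = legal_motor[0] if rng.random() < p_first else legal_motor[1]
    else:  # general fallback; not reached in this task
        probs = softmax_probabilities(
            [tables.q_motor[state, m] for m in legal_motor], params.temperature
        )
        a = legal_motor[int(np.searchsorted(np.cumsum(probs), rng.random()))]
    p_update = two_action_probability(
        tables.q_gating[state, GATE_UPDATE],
        tables.q_gating[state, GATE_MAINTAIN],
        params.temperature,
    )
    g = GATE_UPDATE if rng.random() < p_update else GATE_MAINTAIN
    return a, g


def apply_gating(memory: int, observation: int, g: int) -> int:
    """Update or maintain the memory slot.

    Updating with the choice-turn observation returns the memory unchanged:
    the trial terminates immediately afterwards, so such content is discarded
    with the trial and never enters a state.
    """
    if g == GATE_UPDATE and observation != OBS_CHOICE_TURN:
        return observation
    return memory


# ---------------------------------------------------------------------------
# TD errors / traces / updates
# ---------------------------------------------------------------------------

def td_error_actor_critic(r: float, v_next: float, v_curr: float,
                          gamma: float = 1.0) -> float:
    return r + gamma * v_next - v_curr


def td_errors_sarsa(r: float, q_m_next: float, q_m_curr: float,
                    q_g_next: float, q_g_curr: float,
                    gamma: float = 1.0) -> tuple[float, float]:
    return (r + gamma * q_m_next - q_m_curr, r + gamma * q_g_next - q_g_curr)


def set_replacing_traces(traces: TraceTables, s: int, a: int, g: int,
                         variant: str) -> TraceTables:
    """Set e^M(s,a)=1, e^G(s,g)=1 (and e^V(s)=1 for Actor-Critic)."""
    traces.motor[s, a] = 1.0
    traces.gating[s, g] = 1.0
    if uses_state_values(variant):
        traces.state[s] = 1.0
    return traces


def update_values(tables: ValueTables, traces: TraceTables, errors: TDErrors,
                  alpha: float, variant: str) -> ValueTables:
    """Trace-weighted value updates over every table entry."""
    if is_sarsa(variant):
        tables.q_motor += alpha * errors.delta_motor * traces.motor
        tables.q_gating += alpha * errors.delta_gating * traces.gating
    else:
        tables.q_motor += alpha * errors.delta * traces.motor
        tables.q_gating += alpha * errors.delta * traces.gating
        tables.v += alpha * errors.delta * traces.state
        if is_value_clipped(variant):
            np.clip(tables.q_motor, 0.0, 1.0, out=tables.q_motor)
            np.clip(tables.q_gating, 0.0, 1.0, out=tables.q_gating)
            np.clip(tables.v, 0.0, 1.0, out=tables.v)
    return tables


def decay_traces(traces: TraceTables, gamma: float, lam: float) -> TraceTables:
    decay = gamma * lam
    traces.motor *= decay
    traces.gating *= decay
    if traces.state is not None:
        traces.state *= decay
    return traces


# ---------------------------------------------------------------------------
# Running a trial (reference path)
# ---------------------------------------------------------------------------

@dataclass
class StepRecord:
    step_index: int
    observation: int
    memory: int
    motor_action: int
    gating_action: int
    reward: int


@dataclass
class TrialLog:
    guided_direction: int
    memory_at_choice: int
    reward: int
    steps: list[StepRecord] = field(default_factory=list)


def run_trial(agent: GatingAgent, config: TaskConfig, rng) -> TrialLog:
    """Run one episode, updating the agent in place.

    Step order per iteration: select actions for the current state (SARSA
    carries over the actions chosen during the previous TD computation),
    apply the gating action, execute the motor action and observe (r, s'),
    compute the variant's TD errors (SARSA selects a', g' first), set
    replacing traces for (s, a, g), update all values, decay all traces.
    Traces are zeroed and memory is emptied at trial start.
    """
    params, tables, traces = agent.params, agent.tables, agent.traces
    sarsa = is_sarsa(agent.variant)
    traces.reset()
    phase = reset_trial(config, rng)
    memory = MEM_EMPTY
    log = TrialLog(guided_direction=phase.guided_direction, memory_at_choice=-1, reward=0)

    s = state_index(phase.observation, memory)
    if sarsa:
        a, g = select_actions(s, tables, params, available_motor_actions(phase, config), rng)
    for step in range(config.n_steps):
        if not sarsa:
            a, g = select_actions(s, tables, params,
                                  available_motor_actions(phase, config), rng)
        obs = phase.observation
        at_choice = obs == OBS_CHOICE_TURN
        if at_choice:
            log.memory_at_choice = memory
        memory = apply_gating(memory, obs, g)
        next_obs, r = step_env(phase, a, config)
        log.steps.append(StepRecord(step, obs, s % 4, a, g, r))
        if phase.terminated:
            s_next, a_next, g_next = -1, -1, -1
        else:
            s_next = state_index(next_obs, memory)
            if sarsa:
                a_next, g_next = select_actions(
                    s_next, tables, params, available_motor_actions(phase, config), rng
                )
        if sarsa:
            dm, dg = td_errors_sarsa(
                r,
                0.0 if phase.terminated else tables.q_motor[s_next, a_next],
                tables.q_motor[s, a],
                0.0 if phase.terminated else tables.q_gating[s_next, g_next],
                tables.q_gating[s, g],
                params.discount,
            )
            errors = TDErrors(delta_motor=dm, delta_gating=dg)
        else:
            delta = td_error_actor_critic(
                r,
                0.0 if phase.terminated else tables.v[s_next],
                tables.v[s],
                params.discount,
            )
            errors = TDErrors(delta=delta)
        set_replacing_traces(traces, s, a, g, agent.variant)
        update_values(tables, traces, errors, params.alpha, agent.variant)
        decay_traces(traces, params.discount, params.trace_decay)
        if phase.terminated:
            log.reward = r
            break
        s = s_next
        if sarsa:
            a, g = a_next, g_next
    return log


# ---------------------------------------------------------------------------
# Exact policy evaluation (enumeration oracle) and hand-coded policies
# ---------------------------------------------------------------------------

def evaluate_policy_exact(motor_policy: np.ndarray, gating_policy: np.ndarray,
                          config: TaskConfig) -> float:
    """Exact expected per-trial reward of a fixed stochastic policy.

    Propagates the full memory-content distribution through the trial for
    each start side (no sampling).  Motor probabilities are renormalized over
    the legal actions at the choice turn; gating at the choice turn cannot
    affect reward and is ignored.
    """
    motor_policy = np.asarray(motor_policy, dtype=float)
    gating_policy = np.asarray(gating_policy, dtype=float)
    total = 0.0
    for start, weight in ((LEFT, config.start_probability_left),
                          (RIGHT, 1.0 - config.start_probability_left)):
        if weight == 0.0:
            continue
        mem_dist = np.zeros(4)
        mem_dist[MEM_EMPTY] = 1.0
        for step in range(config.n_central + 1):  # all pre-choice steps
            obs = observation_at(step, start, config)
            new_dist = np.zeros(4)
            for m in range(4):
                p = mem_dist[m]
                if p == 0.0:
                    continue
                s = state_index(obs, m)
                row = gating_policy[s]
                p_update = row[GATE_UPDATE] / row.sum()
                new_dist[obs] += p * p_update
                new_dist[m] += p * (1.0 - p_update)
            mem_dist = new_dist
        target = correct_choice(start, config.rule)
        p_correct = 0.0
        for m in range(4):
            if mem_dist[m] == 0.0:
                continue
            s = state_index(OBS_CHOICE_TURN, m)
            legal = motor_policy[s, [TURN_LEFT, TURN_RIGHT]]
            p_correct += mem_dist[m] * legal[target - TURN_LEFT] / legal.sum()
        total += weight * p_correct
    return total


def _deterministic_policies(motor_rule, gating_rule) -> tuple[np.ndarray, np.ndarray]:
    motor = np.zeros((N_STATES, N_MOTOR))
    gating = np.zeros((N_STATES, N_GATING))
    for s in range(N_STATES):
        obs, mem = divmod(s, 4)
        motor[s, motor_rule(obs, mem)] = 1.0
        gating[s, gating_rule(obs, mem)] = 1.0
    return motor, gating


def remember_both_policy(rule: str = "match") -> tuple[np.ndarray, np.ndarray]:
    """Greedy policy storing the guided turn on both sides.

    Gating updates on a guided-turn observation seen with empty memory and
    maintains otherwise; the motor agent turns according to the remembered
    side under the given rule.
    """

    def motor(obs, mem):
        if obs != OBS_CHOICE_TURN:
            return GO_STRAIGHT
        if mem == MEM_LEFT_TURN:
            return correct_choice(LEFT, rule)
        if mem == MEM_RIGHT_TURN:
            return correct_choice(RIGHT, rule)
        return TURN_LEFT  # unreachable under this gating policy

    def gating(obs, mem):
        if obs in (OBS_LEFT_TURN, OBS_RIGHT_TURN) and mem == MEM_EMPTY:
            return GATE_UPDATE
        return GATE_MAINTAIN

    return _deterministic_policies(motor, gating)


def remember_one_policy(side: int = RIGHT, rule: str = "match") -> tuple[np.ndarray, np.ndarray]:
    """Greedy policy storing only one guided-turn side.

    Memory stays empty on the other side's trials, which is itself
    informative: the motor agent infers the unstored side from a
    non-matching memory content at the choice point.
    """
    stored_obs = OBS_LEFT_TURN if side == LEFT else OBS_RIGHT_TURN
    stored_mem = MEM_LEFT_TURN if side == LEFT else MEM_RIGHT_TURN
    other = RIGHT if side == LEFT else LEFT

    def motor(obs, mem):
        if obs != OBS_CHOICE_TURN:
            return GO_STRAIGHT
        if mem == stored_mem:
            return correct_choice(side, rule)
        return correct_choice(other, rule)

    def gating(obs, mem):
        if obs == stored_obs and mem == MEM_EMPTY:
            return GATE_UPDATE
        return GATE_MAINTAIN

    return _deterministic_policies(motor, gating)


def uniform_policy() -> tuple[np.ndarray, np.ndarray]:
    """Uniform over legal actions everywhere (chance performance)."""
    motor = np.zeros((N_STATES, N_MOTOR))
    gating = np.full((N_STATES, N_GATING), 0.5)
    for s in range(N_STATES):
        obs = s // 4
        if obs == OBS_CHOICE_TURN:
            motor[s, TURN_LEFT] = motor[s, TURN_RIGHT] = 0.5
        else:
            motor[s, GO_STRAIGHT] = 1.0
    return motor, gating


def greedy_policy_from_tables(tables: ValueTables) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic argmax policy implied by learned value tables."""

    def motor(obs, mem):
        if obs != OBS_CHOICE_TURN:
            return GO_STRAIGHT
        s = state_index(obs, mem)
        pair = tables.q_motor[s, [TURN_LEFT, TURN_RIGHT]]
        return TURN_LEFT if pair[0] >= pair[1] else TURN_RIGHT

    def gating(obs, mem):
        s = state_index(obs, mem)
        row = tables.q_gating[s]
        return GATE_UPDATE if row[GATE_UPDATE] >= row[GATE_MAINTAIN] else GATE_MAINTAIN

    return _deterministic_policies(motor, gating)
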