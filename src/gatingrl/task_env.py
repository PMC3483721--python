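"""Abstract guided-turn maze task.

The environment is a schematic, episodic version of a rat T-maze rule task.
Each trial presents an initial guided-turn observation (left or right), a
fixed number ``n_central`` of identical central-arm "distractor" observations,
and a final choice-turn observation at which the agent turns left or right.
Reward is 1 if the choice is consistent with the current rule (match:
same side as the guided turn; non-match: opposite side), else 0; all earlier
steps yield reward 0.

Observations, motor actions and the rule are represented both as strings (the
public vocabulary) and small integer codes (used by the simulation kernel).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

# --- observation codes -----------------------------------------------------
OBS_LEFT_TURN = 0
OBS_RIGHT_TURN = 1
OBS_CENTRAL_ARM = 2
OBS_CHOICE_TURN = 3
OBSERVATIONS = ("left-turn", "right-turn", "central-arm", "choice-turn")

# --- motor action codes ----------------------------------------------------
GO_STRAIGHT = 0
TURN_LEFT = 1
TURN_RIGHT = 2
MOTOR_ACTIONS = ("go-straight", "turn-left", "turn-right")

# --- directions ------------------------------------------------------------
LEFT = 0
RIGHT = 1
DIRECTIONS = ("left", "right")

RULES = ("match", "non-match")


def reverse_rule(rule: str) -> str:
    """Map match <-> non-match (an involution)."""
    if rule not in RULES:
        raise ValueError(f"unknown rule {rule!r}")
    return "non-match" if rule == "match" else "match"


@dataclass(frozen=True)
class TaskConfig:
    """Task parameters.

    Parameters
    ----------
    n_central
        Number of identical central-arm observations between the guided and
        choice turns (the task's difficulty knob); must be >= 1.
    rule
        ``"match"`` or ``"non-match"``.
    start_probability_left
        Per-trial probability of a left start, drawn i.i.d. (starts are not
        balanced within a session).
    """

    n_central: int
    rule: str = "match"
    start_probability_left: float = 0.5

    def __post_init__(self) -> None:
        if int(self.n_central) != self.n_central or self.n_central < 1:
            raise ValueError("n_central must be a positive integer >= 1")
        if self.rule not in RULES:
            raise ValueError(f"rule must be one of {RULES}, got {self.rule!r}")
        if not 0.0 <= self.start_probability_left <= 1.0:
            raise ValueError("start_probability_left must be in [0, 1]")

    @property
    def n_steps(self) -> int:
        """Trial length in agent steps: guided + central arm + choice."""
        return self.n_central + 2

    def reversed(self) -> "TaskConfig":
        return replace(self, rule=reverse_rule(self.rule))


@dataclass
class TrialPhase:
    """Mutable position within a single trial."""

    step_index: int
    guided_direction: int  # LEFT or RIGHT
    observation: int
    terminated: bool = False
    reward_delivered: int = 0


def observation_at(step_index: int, guided_direction: int, config: TaskConfig) -> int:
    """Scheduled observation code at a given step of a trial."""
    if step_index == 0:
        return OBS_LEFT_TURN if guided_direction == LEFT else OBS_RIGHT_TURN
    if step_index <= config.n_central:
        return OBS_CENTRAL_ARM
    if step_index == config.n_central + 1:
        return OBS_CHOICE_TURN
    raise ValueError(f"step_index {step_index} outside trial of length {config.n_steps}")


def reset_trial(config: TaskConfig, rng) -> TrialPhase:
    """Start a new trial; the start side is drawn i.i.d. from the config.

    ``rng`` is any object with a ``random()`` method returning a uniform
    float in [0, 1); exactly one draw is consumed.
    """
    guided = LEFT if rng.random() < config.start_probability_left else RIGHT
    return TrialPhase(
        step_index=0,
        guided_direction=guided,
        observation=observation_at(0, guided, config),
    )


def available_motor_actions(phase: TrialPhase, config: TaskConfig) -> tuple[int, ...]:
    """Legal motor actions: forced go-straight before the choice turn."""
    if phase.terminated:
        raise RuntimeError("available_motor_actions called on a terminated trial")
    if phase.step_index <= config.n_central:
        return (GO_STRAIGHT,)
    return (TURN_LEFT, TURN_RIGHT)


def correct_choice(guided_direction: int, rule: str) -> int:
    """Rewarded choice-turn action under the rule."""
    if guided_direction not in (LEFT, RIGHT):
        raise ValueError("guided_direction must be LEFT (0) or RIGHT (1)")
    if rule == "match":
        return TURN_LEFT if guided_direction == LEFT else TURN_RIGHT
    if rule == "non-match":
        return TURN_RIGHT if guided_direction == LEFT else TURN_LEFT
    raise ValueError(f"unknown rule {rule!r}")


def step_env(phase: TrialPhase, action: int, config: TaskConfig) -> tuple[int | None, int]:
    """Advance the trial one step; returns (next observation or None, reward).

    Reward is possible only at the final (choice-turn) step; earlier steps
    return the next scheduled observation with reward 0.
    """
    if action not in available_motor_actions(phase, config):
        raise RuntimeError(
            f"illegal action {action} at step {phase.step_index}"
        )
    if phase.step_index == config.n_central + 1:
        reward = int(action == correct_choice(phase.guided_direction, config.rule))
        phase.terminated = True
        phase.reward_delivered = reward
        return None, reward
    phase.step_index += 1
    phase.observation = observation_at(phase.step_index, phase.guided_direction, config)
    return phase.observation, 0
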