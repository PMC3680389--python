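"""Norm-psychology agents: salience tracking, drives, and behaviour policies.

Each agent carries two motivational quantities in [0, 1]:

* an **individual drive** (ID) — a payoff-based propensity to cooperate,
  updated by a winner-stay-losers-change rule: actions that improved the
  agent's payoff are reinforced, actions that worsened it are inhibited, with
  a step proportional to the payoff change;
* a **normative drive** (ND) — the motivation to comply with the cooperation
  norm, read off the agent's current **norm salience**.

Norm salience is a scalar in [0, 1] tracking how prominent the cooperation
norm currently appears to the agent.  Every round it is nudged by a signed,
weighted sum of behavioural and communicative cues (own and observed
compliance/violations, punishments, sanctions, normative messages, violations
that went unpunished), normalised by ``lambda`` and clamped to [0, 1].  Cues
that evidence compliance or enforcement carry non-negative weights; cues that
evidence violation carry non-positive weights.  A sanction — punishment
accompanied by a normative message — is a stronger norm signal than bare
punishment.  When a round carries no enforcement or communication cues the
norm fades: salience decays by a small step scaled by the forgetting
probability.

The behaviour policies combine the drives linearly into a cooperation
probability, punish with a probability that is anchored at the initial
punishment probability for a single defector and declines with the number of
defectors, send messages with probability equal to salience, and pick a
binary punishment intensity (high for repeat offenders, low otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .game import ValidationError

__all__ = [
    "SalienceWeights",
    "CueVector",
    "SalienceState",
    "DriveState",
    "AgentParams",
    "FORGETTING_DECAY_STEP",
    "update_salience",
    "update_individual_drive",
    "cooperation_probability",
    "normative_drive",
    "punishment_probability",
    "message_probability",
    "choose_intensity",
]

#: Base salience decay per forgetting event, scaled by the forgetting probability.
FORGETTING_DECAY_STEP = 0.05

_COMPLIANCE_CUES = (
    "own_compliance",
    "observed_compliance",
    "punishments_observed",
    "sanctions_observed",
    "messages_received",
)
_VIOLATION_CUES = ("own_violation", "observed_violation", "unpunished_violations")
CUE_NAMES = _COMPLIANCE_CUES[:2] + _VIOLATION_CUES[:2] + _COMPLIANCE_CUES[2:] + _VIOLATION_CUES[2:]


def _clamp01(x: float) -> float:
    return 0.0 if x < 0.0 else 1.0 if x > 1.0 else x


@dataclass(frozen=True)
class SalienceWeights:
    """Signed weight per cue, plus the normaliser ``lam`` (> 0).

    Defaults follow the sign structure compliance/enforcement >= 0 >=
    violation, with sanction and message cues (explicit norm signals) weighted
    three times as heavily as bare behavioural observation, and
    ``lam = 3 * group_size`` for groups of four.
    """

    own_compliance: float = 0.99
    own_violation: float = -0.99
    observed_compliance: float = 0.33
    observed_violation: float = -0.33
    punishments_observed: float = 0.33
    sanctions_observed: float = 0.99
    messages_received: float = 0.99
    unpunished_violations: float = -0.66
    lam: float = 12.0

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValidationError("salience normaliser lam must be > 0")
        for name in _COMPLIANCE_CUES:
            if getattr(self, name) < 0:
                raise ValidationError(f"compliance-type cue weight {name} must be >= 0")
        for name in _VIOLATION_CUES:
            if getattr(self, name) > 0:
                raise ValidationError(f"violation-type cue weight {name} must be <= 0")


@dataclass(frozen=True)
class CueVector:
    """Counts of norm-relevant events one agent registered in one round."""

    own_compliance: int = 0
    own_violation: int = 0
    observed_compliance: int = 0
    observed_violation: int = 0
    punishments_observed: int = 0
    sanctions_observed: int = 0
    messages_received: int = 0
    unpunished_violations: int = 0

    def __post_init__(self) -> None:
        for name in CUE_NAMES:
            if getattr(self, name) < 0:
                raise ValidationError(f"cue count {name} must be >= 0")

    def weighted_sum(self, weights: SalienceWeights) -> float:
        return sum(getattr(self, name) * getattr(weights, name) for name in CUE_NAMES)

    @property
    def total(self) -> int:
        return sum(getattr(self, name) for name in CUE_NAMES)

    @property
    def enforcement_or_communication(self) -> int:
        """Events that explicitly signal the norm (as opposed to bare behaviour)."""
        return self.punishments_observed + self.sanctions_observed + self.messages_received


@dataclass(frozen=True)
class SalienceState:
    """Norm salience, clamped to [0, 1]."""

    value: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.value <= 1.0):
            raise ValidationError(f"salience {self.value} outside [0, 1]")


@dataclass
class DriveState:
    """Motivational state of one agent.

    ``last_payoff`` / ``prev_payoff`` are the agent's final payoffs in the two
    most recent rounds; the winner-stay-losers-change update compares them.
    """

    individual_drive: float = 0.5
    normative_drive: float = 0.5
    last_action: Optional[str] = None  # "C" or "D"
    last_payoff: Optional[float] = None
    prev_payoff: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("individual_drive", "normative_drive"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} {v} outside [0, 1]")


@dataclass(frozen=True)
class AgentParams:
    """Agent parameterisation.

    The four headline parameters default to the reference simulation setting:
    individual weight 0.5, normative weight 0.5, initial punishment
    probability 0.5, forgetting probability 0.3.  ``low_points``/``high_points``
    are the two punishment intensities (the cost of receiving even the low
    intensity must exceed the net cost of cooperating; checked against the
    game constants in the simulation config).
    """

    individual_weight: float = 0.5
    normative_weight: float = 0.5
    initial_punishment_probability: float = 0.5
    forgetting_probability: float = 0.3
    learning_rate: float = 0.1
    low_points: int = 5
    high_points: int = 10
    initial_drive: float = 0.5
    initial_salience: float = 0.5
    forgetting_mode: str = "decay"  # "decay" (deterministic) or "bernoulli"
    salience_weights: SalienceWeights = field(default_factory=SalienceWeights)

    def __post_init__(self) -> None:
        for name in (
            "individual_weight",
            "normative_weight",
            "initial_punishment_probability",
            "forgetting_probability",
            "initial_drive",
            "initial_salience",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} {v} outside [0, 1]")
        if abs(self.individual_weight + self.normative_weight - 1.0) > 1e-9:
            raise ValidationError("individual_weight + normative_weight must equal 1")
        if not (0.0 < self.learning_rate <= 1.0):
            raise ValidationError("learning_rate must be in (0, 1]")
        if not (0 < self.low_points < self.high_points):
            raise ValidationError("need 0 < low_points < high_points")
        if self.forgetting_mode not in ("decay", "bernoulli"):
            raise ValidationError("forgetting_mode must be 'decay' or 'bernoulli'")


def update_salience(
    state: SalienceState,
    cues: CueVector,
    weights: SalienceWeights,
    phi: float = 0.0,
    mode: str = "decay",
    rng: Optional[np.random.Generator] = None,
) -> SalienceState:
    """One salience update: ``value + (sum_c w_c x_c) / lam``, clamped to [0, 1].

    Forgetting: when the round carried no enforcement or communication cues
    (punishments, sanctions and messages all zero — in particular when every
    cue count is zero) the norm fades.  In ``"decay"`` mode salience drops by
    a deterministic ``phi * FORGETTING_DECAY_STEP``; in ``"bernoulli"`` mode it
    drops by ``FORGETTING_DECAY_STEP`` with probability ``phi`` (needs ``rng``).
    """
    if not (0.0 <= phi <= 1.0):
        raise ValidationError("forgetting probability phi must be in [0, 1]")
    delta = cues.weighted_sum(weights) / weights.lam
    if cues.enforcement_or_communication == 0 and phi > 0.0:
        if mode == "decay":
            delta -= phi * FORGETTING_DECAY_STEP
        elif mode == "bernoulli":
            if rng is None:
                raise ValidationError("bernoulli forgetting requires an rng")
            if rng.random() < phi:
                delta -= FORGETTING_DECAY_STEP
        else:
            raise ValidationError("mode must be 'decay' or 'bernoulli'")
    return SalienceState(_clamp01(state.value + delta))


def update_individual_drive(
    drive: DriveState, alpha: float, payoff_scale: float = 32.0
) -> DriveState:
    """Winner-stay-losers-change update of the individual drive.

    If the last payoff at least matched the previous one, the drive moves
    toward the propensity of the last action (1 for C, 0 for D) by
    ``alpha * |payoff change| / payoff_scale``; if the payoff worsened, it
    moves away symmetrically.  The result is clamped to [0, 1].
    """
    if not (0.0 < alpha <= 1.0):
        raise ValidationError("alpha must be in (0, 1]")
    if payoff_scale <= 0:
        raise ValidationError("payoff_scale must be > 0")
    if drive.last_action not in ("C", "D"):
        raise ValidationError("last_action must be 'C' or 'D'")
    if drive.last_payoff is None or drive.prev_payoff is None:
        raise ValidationError("two consecutive payoffs are required")
    change = drive.last_payoff - drive.prev_payoff
    step = alpha * abs(change) / payoff_scale
    toward_cooperation = (drive.last_action == "C") == (change >= 0)
    new = drive.individual_drive + (step if toward_cooperation else -step)
    return replace(drive, individual_drive=_clamp01(new))


def cooperation_probability(params: AgentParams, drive: DriveState) -> float:
    """``P(C) = wI * ID + wN * ND`` — a convex combination, hence in [0, 1]."""
    return (
        params.individual_weight * drive.individual_drive
        + params.normative_weight * drive.normative_drive
    )


def normative_drive(salience: SalienceState) -> float:
    """Normative drive as the identity map of norm salience."""
    return salience.value


def punishment_probability(params: AgentParams, n_defectors: int, group_size: int) -> float:
    """Probability of punishing a given defector.

    Zero with no defectors, anchored at the initial punishment probability for
    a single defector, and declining linearly with each further defector:
    ``P0 * (1 - (d - 1) / (group_size - 1))``.
    """
    if not (0 <= n_defectors <= group_size - 1):
        raise ValidationError(
            f"n_defectors {n_defectors} outside [0, {group_size - 1}]"
        )
    if n_defectors == 0:
        return 0.0
    p0 = params.initial_punishment_probability
    return p0 * (1.0 - (n_defectors - 1) / (group_size - 1))


def message_probability(salience: SalienceState) -> float:
    """Probability of sending a normative message: salience itself."""
    return salience.value


def choose_intensity(target_history: Sequence[bool], params: AgentParams) -> int:
    """Binary punishment intensity for a defector.

    ``target_history`` lists the target's defections per round (True =
    defected), last entry being the current round.  Repeat offenders — agents
    that also defected in the immediately preceding round — get
    ``high_points``; first-time defectors get ``low_points``.
    """
    if len(target_history) == 0 or not target_history[-1]:
        raise ValidationError("intensity is only chosen for a current-round defector")
    if len(target_history) >= 2 and target_history[-2]:
        return params.high_points
    return params.low_points
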