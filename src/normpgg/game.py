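"""Payoff accounting for a repeated public-goods game with costly punishment.

Groups of four players repeatedly split an integer endowment of 20 ECU
(experimental currency units) between a private account and a group account.
Every ECU contributed to the group account returns ``mpcr`` ECU to *each*
member, so stage-1 payoffs are

    E_i = endowment - c_i + mpcr * sum_j c_j .

With ``mpcr < 1 < mpcr * group_size`` contributing nothing is individually
dominant while full contribution maximises group earnings (a social dilemma).

In instrumented rounds players may, in a second stage, assign 0-10 punishment
points to each other member (1 ECU cost to the sender, 3 ECU damage to the
target) and/or send a costless normative message ("one should contribute X,
because ...").  The engine does exact accounting of both stages, validates
actions against the active treatment phase, and settles accumulated ECU into
currency at the end of an experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "GameConfig",
    "MessageReason",
    "NormMessage",
    "Phase",
    "RoundLedger",
    "ValidationError",
    "PhaseViolationError",
    "Violation",
    "stage1_payoffs",
    "apply_punishment",
    "validate_round",
    "settle_experiment",
]


class ValidationError(ValueError):
    """An action violates the rules of the game (range, integrality, ...)."""


class PhaseViolationError(ValidationError):
    """An instrument was used in a phase where it is disabled."""


@dataclass(frozen=True)
class GameConfig:
    """Economic constants of the experiment.

    Defaults are the laboratory parameterisation: endowment 20 ECU, marginal
    per-capita return 0.4, groups of 4, punishment capped at 10 points per
    target per round with a 1:3 sender:target cost ratio, 40 ECU = 1 unit of
    currency, 200 ECU show-up payment, 30 rounds.
    """

    endowment: int = 20
    mpcr: float = 0.4
    group_size: int = 4
    max_points: int = 10
    sender_cost: float = 1.0
    target_cost: float = 3.0
    exchange_rate: float = 40.0
    show_up: float = 200.0
    rounds: int = 30

    def __post_init__(self) -> None:
        if not isinstance(self.endowment, (int, np.integer)) or isinstance(self.endowment, bool):
            raise ValidationError("endowment must be an integer")
        if not isinstance(self.max_points, (int, np.integer)) or isinstance(self.max_points, bool):
            raise ValidationError("max_points must be an integer")
        if self.endowment <= 0 or self.max_points <= 0:
            raise ValidationError("endowment and max_points must be strictly positive")
        if self.group_size < 2:
            raise ValidationError("group_size must be at least 2")
        if self.rounds < 1:
            raise ValidationError("rounds must be at least 1")
        if min(self.sender_cost, self.target_cost, self.exchange_rate) <= 0:
            raise ValidationError("costs and exchange rate must be strictly positive")
        # social-dilemma condition: defection dominant, full contribution efficient
        if not (self.mpcr < 1.0 < self.mpcr * self.group_size):
            raise ValidationError(
                f"social-dilemma condition violated: need mpcr < 1 < mpcr*group_size, "
                f"got mpcr={self.mpcr}, group_size={self.group_size}"
            )

    def net_cooperation_cost(self, contribution: float | None = None) -> float:
        """Net ECU cost of contributing ``contribution`` (default: the full
        endowment) rather than nothing, holding others fixed."""
        c = self.endowment if contribution is None else contribution
        return c * (1.0 - self.mpcr)


class MessageReason(Enum):
    """The three reasons a normative message may give for contributing."""

    JOINT_BENEFIT = 1  # "in this way we are all better off"
    DUTY = 2           # "it is what one should do"
    THREAT = 3         # "if not it will have consequences for you"


@dataclass(frozen=True)
class NormMessage:
    """A costless message prescribing a contribution level, with a reason."""

    sender: int
    demanded_amount: int
    reason: MessageReason = MessageReason.JOINT_BENEFIT


@dataclass(frozen=True)
class Phase:
    """Which instruments are active in the current round."""

    punishment_allowed: bool
    messages_allowed: bool


@dataclass(frozen=True)
class Violation:
    """A single rule violation found by :func:`validate_round`."""

    member: Optional[int]
    kind: str  # "range" | "integrality" | "phase" | "self_punishment"
    detail: str


@dataclass
class RoundLedger:
    """One group-round: decisions plus the resulting payoff accounting.

    ``points[s, t]`` holds the punishment points member ``s`` assigned to
    member ``t`` (zero diagonal).  Stage-1 payoffs and the punishment totals
    are filled in by :func:`stage1_payoffs` / :func:`apply_punishment`.
    """

    round: int
    contributions: np.ndarray
    points: np.ndarray
    messages: list[NormMessage] = field(default_factory=list)
    stage1: Optional[np.ndarray] = None
    points_sent: Optional[np.ndarray] = None
    points_received: Optional[np.ndarray] = None
    final: Optional[np.ndarray] = None

    @classmethod
    def empty(cls, round: int, contributions: Sequence[int], group_size: int) -> "RoundLedger":
        return cls(
            round=round,
            contributions=np.asarray(contributions, dtype=int),
            points=np.zeros((group_size, group_size), dtype=int),
        )

    @property
    def settled(self) -> bool:
        return self.final is not None


def _check_contributions(contributions: np.ndarray, cfg: GameConfig) -> None:
    if contributions.shape != (cfg.group_size,):
        raise ValidationError(
            f"expected {cfg.group_size} contributions, got shape {contributions.shape}"
        )
    for i, c in enumerate(contributions):
        if float(c) != int(c):
            raise ValidationError(f"member {i}: contribution {c!r} is not an integer")
        if not (0 <= c <= cfg.endowment):
            raise ValidationError(
                f"member {i}: contribution {c} outside [0, {cfg.endowment}]"
            )


def stage1_payoffs(contributions: Sequence[int], cfg: GameConfig) -> np.ndarray:
    """Stage-1 payoff vector ``E_i = endowment - c_i + mpcr * sum_j c_j``.

    Raises :class:`ValidationError` naming the offending member for
    out-of-range or non-integer contributions.
    """
    c = np.asarray(contributions)
    _check_contributions(c, cfg)
    c = c.astype(float)
    return cfg.endowment - c + cfg.mpcr * c.sum()


def _check_points(points: np.ndarray, cfg: GameConfig) -> None:
    n = cfg.group_size
    if points.shape != (n, n):
        raise ValidationError(f"points matrix must be {n}x{n}, got {points.shape}")
    if np.any(points != points.astype(int)):
        raise ValidationError("punishment points must be integers")
    if np.any(np.diagonal(points) != 0):
        bad = int(np.flatnonzero(np.diagonal(points))[0])
        raise ValidationError(f"member {bad}: self-punishment is not allowed")
    if np.any(points < 0) or np.any(points > cfg.max_points):
        s, t = np.argwhere((points < 0) | (points > cfg.max_points))[0]
        raise ValidationError(
            f"member {s}: points[{s},{t}]={points[s, t]} outside [0, {cfg.max_points}]"
        )


def apply_punishment(
    ledger: RoundLedger, cfg: GameConfig, phase: Optional[Phase] = None
) -> RoundLedger:
    """Fill in punishment totals and final payoffs on ``ledger``.

    ``final_i = E_i - sender_cost * p_i - target_cost * p_r`` where ``p_i`` is
    the row sum (points sent) and ``p_r`` the column sum (points received) of
    the points matrix.  Final payoffs may be negative.  If ``phase`` is given
    and punishment is disabled, any nonzero points raise
    :class:`PhaseViolationError`.
    """
    if ledger.stage1 is None:
        raise ValidationError("stage-1 payoffs must be computed before punishment")
    points = np.asarray(ledger.points)
    _check_points(points, cfg)
    if phase is not None and not phase.punishment_allowed and points.any():
        raise PhaseViolationError(
            f"round {ledger.round}: punishment points assigned while the "
            "punishment instrument is disabled"
        )
    ledger.points_sent = points.sum(axis=1)
    ledger.points_received = points.sum(axis=0)
    ledger.final = (
        ledger.stage1
        - cfg.sender_cost * ledger.points_sent
        - cfg.target_cost * ledger.points_received
    )
    return ledger


def validate_round(ledger: RoundLedger, phase: Phase, cfg: GameConfig) -> list[Violation]:
    """Check a round's actions against the rules and the active phase.

    Returns a (possibly empty) list of :class:`Violation`; never raises, so
    the caller decides how to handle illegal input.
    """
    out: list[Violation] = []
    c = np.asarray(ledger.contributions)
    if c.shape != (cfg.group_size,):
        out.append(Violation(None, "range", f"expected {cfg.group_size} contributions"))
    else:
        for i, ci in enumerate(c):
            if float(ci) != int(ci):
                out.append(Violation(i, "integrality", f"contribution {ci!r} not integer"))
            elif not (0 <= ci <= cfg.endowment):
                out.append(
                    Violation(i, "range", f"contribution {ci} outside [0, {cfg.endowment}]")
                )

    points = np.asarray(ledger.points)
    n = cfg.group_size
    if points.shape != (n, n):
        out.append(Violation(None, "range", f"points matrix must be {n}x{n}"))
    else:
        if points.any() and not phase.punishment_allowed:
            senders = sorted(set(np.argwhere(points > 0)[:, 0].tolist()))
            for s in senders:
                out.append(
                    Violation(int(s), "phase", "punishment used while instrument disabled")
                )
        for s in range(n):
            if points[s, s] != 0:
                out.append(Violation(s, "self_punishment", "self-punishment not allowed"))
            for t in range(n):
                if s != t and not (0 <= points[s, t] <= cfg.max_points):
                    out.append(
                        Violation(
                            s,
                            "range",
                            f"points[{s},{t}]={points[s, t]} outside [0, {cfg.max_points}]",
                        )
                    )

    for msg in ledger.messages:
        if not phase.messages_allowed:
            out.append(Violation(msg.sender, "phase", "message sent while instrument disabled"))
        if not (0 <= msg.demanded_amount <= cfg.endowment):
            out.append(
                Violation(
                    msg.sender,
                    "range",
                    f"demanded amount {msg.demanded_amount} outside [0, {cfg.endowment}]",
                )
            )
        if not isinstance(msg.reason, MessageReason):
            out.append(Violation(msg.sender, "range", f"invalid reason {msg.reason!r}"))
    return out


def settle_experiment(ledgers: Sequence[RoundLedger], cfg: GameConfig) -> np.ndarray:
    """Convert accumulated ECU to currency per member.

    Returns ``(show_up + sum of final payoffs) / exchange_rate`` for each
    member.  Accepts any sequence of fully-settled ledgers (an empty sequence
    settles the show-up payment only); a ledger without final payoffs raises.
    """
    total = np.full(cfg.group_size, float(cfg.show_up))
    for ledger in ledgers:
        if not ledger.settled:
            raise ValidationError(
                f"round {ledger.round}: ledger not settled (final payoffs missing)"
            )
        total += ledger.final
    return total / cfg.exchange_rate
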