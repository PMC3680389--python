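"""Replicated, seeded simulation of the three-treatment experiment.

Each run plays fixed groups of four agents over thirty rounds split into
three blocks: rounds 1-10 (no instruments), 11-20 (treatment-specific
instruments), 21-30 (no instruments).  Treatments differ only in which
instruments are available in the middle block: *punishment* (punishment
points only), *message* (normative messages only), *sanction* (both; a
punishment accompanied by a message from the same sender is observed as a
sanction), plus a *control* treatment with no instruments at all.

Cooperation is binary: an agent either contributes ``cooperate_contribution``
ECU (default: the full endowment) or nothing.  The per-round event order is

1. each agent draws cooperate/defect from its cooperation probability;
2. contributions are revealed;
3. in instrumented rounds each agent draws a punish decision per defector and
   (if messages are on) a message decision;
4. the game engine computes payoffs;
5. each agent builds its cue vector from what it observed and updates its
   salience, normative drive, and individual drive.

Randomness is bit-reproducible: every (treatment, replication, group) gets an
independent child stream spawned deterministically from the master seed.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .game import (
    GameConfig,
    MessageReason,
    NormMessage,
    Phase,
    RoundLedger,
    ValidationError,
    apply_punishment,
    stage1_payoffs,
)
from .agents import (
    AgentParams,
    CueVector,
    DriveState,
    SalienceState,
    choose_intensity,
    cooperation_probability,
    message_probability,
    normative_drive,
    punishment_probability,
    update_individual_drive,
    update_salience,
)

__all__ = [
    "TreatmentSpec",
    "TREATMENTS",
    "SimulationConfig",
    "RunResult",
    "PANEL_COLUMNS",
    "play_round",
    "run_experiment",
]

PANEL_COLUMNS = [
    "treatment",
    "replication",
    "group",
    "round",
    "agent",
    "contribution",
    "points_sent",
    "points_received",
    "points_detail",
    "msg_amount",
    "msg_reason",
    "stage1_payoff",
    "final_payoff",
    "individual_drive",
    "salience",
]


@dataclass(frozen=True)
class TreatmentSpec:
    """A treatment: which instruments switch on in the instrumented block."""

    name: str
    punishment: bool
    messages: bool
    baseline1: tuple[int, int] = (1, 10)
    instrumented: tuple[int, int] = (11, 20)
    baseline2: tuple[int, int] = (21, 30)

    def __post_init__(self) -> None:
        b1, ins, b2 = self.baseline1, self.instrumented, self.baseline2
        if not (b1[0] == 1 and b1[1] + 1 == ins[0] and ins[1] + 1 == b2[0] and b2[0] <= b2[1]):
            raise ValidationError("blocks must partition 1..rounds in order")

    @property
    def rounds(self) -> int:
        return self.baseline2[1]

    def phase(self, round: int) -> Phase:
        if not (1 <= round <= self.rounds):
            raise ValidationError(f"round {round} outside 1..{self.rounds}")
        lo, hi = self.instrumented
        if lo <= round <= hi:
            return Phase(self.punishment, self.messages)
        return Phase(False, False)


TREATMENTS: dict[str, TreatmentSpec] = {
    "punishment": TreatmentSpec("punishment", punishment=True, messages=False),
    "message": TreatmentSpec("message", punishment=False, messages=True),
    "sanction": TreatmentSpec("sanction", punishment=True, messages=True),
    "control": TreatmentSpec("control", punishment=False, messages=False),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Full configuration of a replicated simulation experiment."""

    game: GameConfig = field(default_factory=GameConfig)
    agents: AgentParams = field(default_factory=AgentParams)
    treatments: tuple[str, ...] = ("punishment", "message", "sanction")
    n_groups: int = 12
    replications: int = 100
    master_seed: int = 0
    cooperate_contribution: Optional[int] = None  # default: full endowment

    def __post_init__(self) -> None:
        if self.n_groups < 1 or self.replications < 1:
            raise ValidationError("n_groups and replications must be >= 1")
        for t in self.treatments:
            if t not in TREATMENTS:
                raise ValidationError(
                    f"unknown treatment {t!r}; choose from {sorted(TREATMENTS)}"
                )
        c = self.contribution_when_cooperating
        if not (0 < c <= self.game.endowment):
            raise ValidationError(
                f"cooperate_contribution {c} outside (0, {self.game.endowment}]"
            )
        if self.agents.high_points > self.game.max_points:
            raise ValidationError("high_points exceeds the per-target punishment cap")
        # being punished even at low intensity must cost more than cooperating
        low_cost = self.game.target_cost * self.agents.low_points
        coop_cost = self.game.net_cooperation_cost(c)
        if not (low_cost > coop_cost):
            raise ValidationError(
                f"target_cost*low_points = {low_cost} must exceed the net cost of "
                f"cooperating = {coop_cost}"
            )

    @property
    def contribution_when_cooperating(self) -> int:
        return (
            self.game.endowment
            if self.cooperate_contribution is None
            else self.cooperate_contribution
        )

    @property
    def payoff_scale(self) -> float:
        """Normaliser for payoff changes in the drive update (max group return)."""
        return self.game.endowment * self.game.group_size * self.game.mpcr

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class _Agent:
    """Runtime state of one simulated agent."""

    drive: DriveState
    salience: SalienceState
    defect_history: list[bool] = field(default_factory=list)


def _new_group(cfg: SimulationConfig) -> list[_Agent]:
    p = cfg.agents
    return [
        _Agent(
            drive=DriveState(individual_drive=p.initial_drive, normative_drive=p.initial_salience),
            salience=SalienceState(p.initial_salience),
        )
        for _ in range(cfg.game.group_size)
    ]


def play_round(
    group: list[_Agent],
    round: int,
    phase: Phase,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> RoundLedger:
    """Play one round for one group, updating the agents in place."""
    game = cfg.game
    n = game.group_size
    params = cfg.agents
    contribute = cfg.contribution_when_cooperating

    # 1-2: binary cooperation decisions, contributions revealed
    cooperated = [rng.random() < cooperation_probability(params, a.drive) for a in group]
    contributions = np.array([contribute if c else 0 for c in cooperated])
    defected = [not c for c in cooperated]

    ledger = RoundLedger.empty(round, contributions, n)
    ledger.stage1 = stage1_payoffs(contributions, game)

    # 3: instruments
    if phase.punishment_allowed:
        for s in range(n):
            targets = [t for t in range(n) if t != s and defected[t]]
            d = len(targets)
            if d:
                p_pun = punishment_probability(params, d, n)
                for t in targets:
                    if rng.random() < p_pun:
                        ledger.points[s, t] = choose_intensity(
                            group[t].defect_history + [True], params
                        )
    if phase.messages_allowed:
        for s in range(n):
            if rng.random() < message_probability(group[s].salience):
                ledger.messages.append(
                    NormMessage(s, contribute, MessageReason.JOINT_BENEFIT)
                )

    # 4: payoff accounting
    apply_punishment(ledger, game, phase)

    # 5: observation and motivational updates
    msg_senders = {m.sender for m in ledger.messages}
    acts = np.argwhere(ledger.points > 0)
    n_sanctions = sum(1 for s, _ in acts if s in msg_senders)
    n_punishments = len(acts) - n_sanctions
    for i, agent in enumerate(group):
        others = [j for j in range(n) if j != i]
        obs_viol = sum(1 for j in others if defected[j])
        cues = CueVector(
            own_compliance=int(cooperated[i]),
            own_violation=int(defected[i]),
            observed_compliance=len(others) - obs_viol,
            observed_violation=obs_viol,
            punishments_observed=n_punishments,
            sanctions_observed=n_sanctions,
            messages_received=sum(1 for m in ledger.messages if m.sender != i),
            # a violation reads as "unpunished" only while the normative regime
            # is in play (some instrument active); in the message treatment this
            # is what erodes salience despite the messages
            unpunished_violations=(
                sum(1 for j in others if defected[j] and ledger.points_received[j] == 0)
                if (phase.punishment_allowed or phase.messages_allowed)
                else 0
            ),
        )
        agent.salience = update_salience(
            agent.salience,
            cues,
            params.salience_weights,
            phi=params.forgetting_probability,
            mode=params.forgetting_mode,
            rng=rng,
        )
        drive = agent.drive
        drive.prev_payoff = drive.last_payoff
        drive.last_payoff = float(ledger.final[i])
        drive.last_action = "C" if cooperated[i] else "D"
        if drive.prev_payoff is not None:
            drive = update_individual_drive(drive, params.learning_rate, cfg.payoff_scale)
        drive.normative_drive = normative_drive(agent.salience)
        agent.drive = drive
        agent.defect_history.append(defected[i])
    return ledger


@dataclass
class RunResult:
    """Long-format panel of a replicated experiment plus run metadata.

    ``rounds`` has one row per (treatment, replication, group, round, agent)
    with the decision record, payoff accounting, and the decision-time drive
    and salience traces.  ``points_detail`` encodes the sender's nonzero
    punishment allocations as ``"target:points;..."`` so the full points
    matrix round-trips through CSV.
    """

    rounds: pd.DataFrame
    meta: dict

    @property
    def n_ledgers(self) -> int:
        return len(self.rounds) // self.meta["group_size"]


def run_experiment(cfg: SimulationConfig) -> RunResult:
    """Run all configured treatments x replications x groups.

    Identical master seeds give identical results: each (treatment,
    replication, group) cell uses its own child stream spawned sequentially
    from the master seed, so results are independent of execution order.
    """
    t0 = time.time()
    n = cfg.game.group_size
    n_cells = len(cfg.treatments) * cfg.replications * cfg.n_groups
    children = np.random.SeedSequence(cfg.master_seed).spawn(n_cells)
    rows: list[tuple] = []
    cell = 0
    for tname in cfg.treatments:
        spec = TREATMENTS[tname]
        if spec.rounds != cfg.game.rounds:
            raise ValidationError(
                f"treatment {tname!r} spans {spec.rounds} rounds but the game "
                f"is configured for {cfg.game.rounds}"
            )
        for rep in range(cfg.replications):
            for g in range(cfg.n_groups):
                rng = np.random.default_rng(children[cell])
                cell += 1
                group = _new_group(cfg)
                for rnd in range(1, cfg.game.rounds + 1):
                    # decision-time traces: state the round's choices were drawn from
                    trace = [
                        (a.drive.individual_drive, a.salience.value) for a in group
                    ]
                    ledger = play_round(group, rnd, spec.phase(rnd), cfg, rng)
                    msg_by = {m.sender: m for m in ledger.messages}
                    for i in range(n):
                        detail = ";".join(
                            f"{t}:{ledger.points[i, t]}"
                            for t in range(n)
                            if ledger.points[i, t] > 0
                        )
                        msg = msg_by.get(i)
                        rows.append(
                            (
                                tname,
                                rep,
                                g,
                                rnd,
                                i,
                                int(ledger.contributions[i]),
                                int(ledger.points_sent[i]),
                                int(ledger.points_received[i]),
                                detail,
                                float(msg.demanded_amount) if msg else np.nan,
                                msg.reason.name if msg else "",
                                float(ledger.stage1[i]),
                                float(ledger.final[i]),
                                trace[i][0],
                                trace[i][1],
                            )
                        )
    panel = pd.DataFrame(rows, columns=PANEL_COLUMNS)
    meta = {
        "master_seed": cfg.master_seed,
        "config_hash": cfg.config_hash(),
        "group_size": n,
        "treatments": list(cfg.treatments),
        "replications": cfg.replications,
        "n_groups": cfg.n_groups,
        "rounds": cfg.game.rounds,
        "runtime_s": round(time.time() - t0, 3),
    }
    return RunResult(rounds=panel, meta=meta)
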