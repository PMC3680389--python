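# Methods

## The game

Fixed groups of `n = 4` play 30 rounds. Each round, member *i* chooses an
integer contribution `c_i ∈ [0, 20]`; stage-1 payoffs are

    E_i = endowment − c_i + mpcr · Σ_j c_j ,    endowment = 20, mpcr = 0.4.

The marginal per-capita return satisfies `mpcr < 1 < n·mpcr`, so defection is
individually dominant and full contribution socially efficient. In
instrumented rounds members may assign `0–10` punishment points per target
(sender pays 1 ECU per point, target loses 3) and/or broadcast a costless
normative message. Final payoffs `E_i − p_i − 3·p_r` may be negative; nothing
is clipped. Sessions settle at `(200 + Σ final) / 40` currency units per
member.

The MPCR value is not printed in the material this package works from; 0.4 is
the standard value for this 20-ECU, 4-member design and is configurable
(`GameConfig(mpcr=...)`).

## The agent model

Cooperation is binary: cooperate = contribute `cooperate_contribution`
(default: the full endowment, so simulated panels are on the same 0–20 token
scale as human contributions), defect = contribute 0. Each agent draws
cooperation from

    P(C) = w_I · ID + w_N · ND ,    w_I = w_N = 0.5 by default.

### Individual drive (winner-stay-losers-change)

`ID ∈ [0, 1]` is a payoff-learnt propensity to cooperate. After round *t* ≥ 2:

* payoff improved or equal (`π_t ≥ π_{t−1}`): ID moves toward the propensity
  of the last action (1 for C, 0 for D);
* payoff worsened: ID moves away from it;
* step size `α · |π_t − π_{t−1}| / payoff_scale`, clamped to [0, 1].

Defaults: `α = 0.1`; `payoff_scale = endowment · n · mpcr = 32` (the maximum
group return), keeping per-round movement well below 1. Equal payoffs give a
zero step, so "winner stays" exactly.

### Norm salience and the normative drive

Salience `S ∈ [0, 1]` is each agent's running estimate of how prominent the
cooperation norm is. Per round the agent registers a cue-count vector and
updates

    S ← clamp01( S + (Σ_c w_c · x_c) / λ ),    λ = 3n = 12.

Default weights (configurable; signs are enforced as invariants):

| cue | weight | fires when |
|---|---|---|
| own_compliance | +0.99 | the agent cooperated |
| own_violation | −0.99 | the agent defected |
| observed_compliance | +0.33 | per cooperating other |
| observed_violation | −0.33 | per defecting other |
| punishments_observed | +0.33 | per punishing act by a sender who sent no message |
| sanctions_observed | +0.99 | per punishing act by a sender who also messaged |
| messages_received | +0.99 | per message from another member |
| unpunished_violations | −0.66 | per defecting other with zero points received, **only in instrumented rounds** |

The table respects the intended ordering: explicit norm signals (sanctions,
messages) move salience three times as strongly as bare behavioural
observation, and a sanction is at least as strong upward as bare punishment.
The exact calibrated weight table from the original study is not available in
the material this package was built from; these defaults are declared
substitutes with the stated sign structure, and a replacement table can be
dropped in via `SalienceWeights`.

Two deliberate semantic choices:

* **Unpunished violations count only while the normative regime is active**
  (some instrument enabled this round). In the message treatment this is the
  mechanism that erodes salience — violations are visibly *not* being
  punished — while in the no-instrument baseline a violation is only an
  observed violation, not additionally an "unpunished" one. Counting the cue
  in baseline rounds double-charges every violation and drives salience to 0
  before the instruments ever switch on, which would make the message and
  sanction channels inert (both run on salience).
* **Forgetting**: when a round carries no enforcement or communication cues
  (punishments, sanctions, messages all zero — in particular when every cue
  count is zero), salience additionally decays by `φ · 0.05` with forgetting
  probability `φ = 0.3`. The named parameter has no printed definition in the
  source material; this deterministic-decay reading makes φ matter exactly
  where norms go unexpressed (baseline blocks, dead message rounds). A
  literal Bernoulli reading (full 0.05 step with probability φ) is available
  via `forgetting_mode="bernoulli"`.

The normative drive is the identity map `ND = S`, and the message-sending
probability is also `S` — the simplest monotone readings; any override must
stay monotone non-decreasing.

### Punishment policy

Per round, every agent considers each defecting other member and punishes
independently with probability

    P(punish | d defectors among the other n−1) = P0 · (1 − (d−1)/(n−1)) ,

zero at `d = 0` and anchored at `P0 = 0.5` for a lone defector: a deviant
minority is punished reliably, widespread defection much less (responsibility
diffuses and the norm is evidently weak). Intensity is binary: 5 points for a
first-time defector, 10 for one who also defected the previous round. Both
satisfy the constraint that being punished (≥ 15 ECU) costs more than the net
cost of cooperating (12 ECU); this is validated against the game constants.
In the message/sanction treatments, message senders broadcast a
pro-cooperation prescription (amount = the cooperation contribution, reason
"joint benefit" — choices are binary, so the amount carries no information).

### Initial state and schedule

`ID = S = 0.5` at round 1 (uninformative priors; configurable). Blocks:
rounds 1–10 and 21–30 have no instruments in every treatment; rounds 11–20
enable punishment (punishment treatment), messages (message), both
(sanction), or neither (control, used for ablations).

## Simulation protocol

Default experiment: 3 treatments × 100 replications × 12 groups × 30 rounds
(108,000 group-rounds, ≈ 12 s single-core). Each (treatment, replication,
group) cell gets its own child generator spawned sequentially from the master
seed (`numpy.random.SeedSequence`), so runs are bit-reproducible and
independent of execution order; identical master seeds give byte-identical
CSV exports. The replication count is a desk-scale choice for tight
Monte-Carlo error on treatment contrasts (the source experiments do not state
theirs).

## Measurement and statistics

* Block means average group-level means first, then across groups — the fixed
  group is the independent unit, matching group-level nonparametric practice.
* Punishment **frequency** = share of sender→target opportunities (12 per
  group-round) with any points sent; **intensity** = mean points per act with
  all zero-point instances excluded, explicitly undefined (None/NaN) when no
  acts occurred — never 0.
* Mann–Whitney U and Wilcoxon signed-rank use midranks and compute exact
  p-values by full enumeration (group assignments / sign patterns) for
  combined n ≤ 10 resp. ≤ 12 nonzero pairs — ties included — falling back to
  tie-corrected normal approximations; Kruskal–Wallis uses the tie-corrected
  H with its χ² approximation (scipy). Two-sided p-values are the default.
* `percent_excess(a, b) = round(100·(a−b)/b)`; the unrounded values satisfy
  `(1 + e(a,b)/100)·(1 + e(b,a)/100) = 1`.

## What the synthetic world does and does not establish

The built-in fixture table stores the human experiment's reported block-mean
contributions (message/punishment/sanction: 8.33/6.25/8.23 in rounds 1–10,
9.90/10.65/14.46 in 16–20, 5.05/3.75/9.08 in 21–30). The agent model is a
binary-choice abstraction calibrated only in sign structure, so the
comparison contract is **qualitative**: sanction > punishment and sanction >
message after round 10, baseline decline, and lower punishment frequency
under sanction than punishment. A green ordering report establishes that the
salience mechanism reproduces those trends; it does not establish numeric
agreement with human contribution levels, human p-values, or human earnings
percentages, and none is claimed. Known divergence: simulated cooperation
declines faster after round 20 than human cooperation does, and simulated
block-3 message-treatment cooperation falls below the punishment treatment,
unlike the human means.

## Numerical choices and degenerate inputs

Salience, ID, ND are clamped to [0, 1] after every update. Decision draws use
one scalar uniform per decision in fixed agent order (no float accumulation
order effects). Kruskal–Wallis on all-identical pooled data returns H = 0,
p = 1 (flagged degenerate); Wilcoxon with all-zero differences returns a
degenerate result rather than raising; punishment intensity over an actless
scope is None. Settlement accepts partial ledger sequences but refuses
ledgers whose final payoffs were never computed.

## Limitations

* No evolutionary dynamics, population turnover, or learning of the weight
  table; no interleaved treatment orders.
* Message content is degenerate by design (binary choices); the three-reason
  message menu exists in the data model for replaying hand-built games, not
  in the agent policy.
* Agents observe punisher identities but the default cues use only counts;
  identity-sensitive cues are an extension hook.
* The salience weight table and the forgetting/intensity semantics are
  declared substitutes for unavailable calibration details, not
  reconstructions of them.
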