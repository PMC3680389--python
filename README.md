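# normpgg

A simulator and analysis toolkit for a repeated **public-goods game with
costly punishment and norm-signalling**, built around a norm-psychology
agent-based model.

## The problem

In laboratory public-goods games, groups of 4 members each split an endowment
of 20 ECU between a private account and a group account every round; each ECU
contributed returns 0.4 ECU to *every* member (stage-1 payoff
`E_i = 20 − c_i + 0.4 Σ_j c_j`), so free-riding dominates individually while
full contribution maximises group earnings. Material punishment (assigning
0–10 points per target, costing the sender 1 ECU and the target 3 ECU per
point) can sustain cooperation, but it is expensive and often barely breaks
even. The question this package addresses: what changes when punishment is
combined with an explicit **normative message** ("one should contribute X,
because …") into a **sanction** — a materially identical act that also
signals the norm?

The package serves researchers in behavioural game theory and agent-based
social simulation who want to (a) do exact accounting of this experimental
economy, (b) simulate it with agents endowed with a norm psychology, and
(c) analyse the resulting panels with the field's group-level nonparametric
tests.

## The model

Agents make binary cooperate/defect choices with probability

    P(C) = w_I · ID + w_N · ND

* **ID (individual drive)** — payoff learning by winner-stay-losers-change:
  after each round the drive moves toward the propensity of the last action
  if the payoff improved, and away from it if the payoff worsened, by a step
  `α · |Δpayoff| / payoff_scale`, clamped to [0, 1].
* **ND (normative drive)** — equal to the agent's **norm salience**, a scalar
  in [0, 1] updated every round from signed, weighted cues: own and observed
  compliance/violations, punishments observed, sanctions observed (punishment
  whose sender also messaged), messages received, and violations that went
  unpunished while an instrument was active. With no enforcement or
  communication cues the norm fades (decay `φ · 0.05`).

Punishment probability is 0 with no defectors, anchors at `P0` for one
defector and declines linearly with more; message probability equals
salience; punishment intensity is binary (5 points for a first-time defector,
10 for a repeat offender — receiving even the low intensity costs more than
the 12 ECU net cost of cooperating).

Treatments share rounds 1–10 and 21–30 with no instruments; rounds 11–20
enable punishment only (*punishment*), messages only (*message*), or both
(*sanction*). A *control* treatment with no instruments is also available.

## Worked example

```sh
python examples/simulate_treatments.py
```

prints (abridged; 20 replications × 12 groups per treatment, seed 42):

```
 treatment block  mean_contribution  punishment_frequency  mean_intensity  mean_net_earnings
   message 16-20              4.975                 0.000             NaN             22.985
punishment 16-20              7.292                 0.165           8.529              7.488
  sanction 16-20              9.946                 0.155           8.117             10.897
   message 21-30              4.162                 0.000             NaN             22.498
punishment 21-30              7.283                 0.000             NaN             24.370
  sanction 21-30             10.512                 0.000             NaN             26.308
```

Mean contribution is in ECU out of 20; punishment frequency is the share of
the 12 sender→target opportunities per group-round in which any points were
sent; intensity is points per punishing act (zeros excluded, NaN = no acts);
net earnings are ECU per member per round. The sanction treatment reaches the
highest cooperation while punishing *less often* than the punishment
treatment, and its advantage survives the removal of the instruments —
because its agents have learned the norm (high salience), not merely dodged
punishment.

Other examples: `payoff_accounting.py` (exact engine arithmetic and
settlement), `nonparametric_tests.py` (Kruskal–Wallis, Mann–Whitney, Wilcoxon
on group-level means), `compare_to_human_fixture.py` (qualitative ordering
comparison against the built-in human block means, e.g. sanction exceeding
punishment by 36% in rounds 16–20 and 142% in rounds 21–30).

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the package's main computation from scratch: the full
default-parameter experiment (3 treatments × 100 replications × 12 groups ×
30 rounds), its block summaries, the ordering comparison against the human
block means, and the percent-excess arithmetic on those means, writing the
acceptance JSON to `--out`.
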