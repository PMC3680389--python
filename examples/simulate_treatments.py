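"""Replicated simulation of the three treatments with norm-psychology agents.

Runs a desk-scale experiment (20 replications of 12 groups per treatment,
30 rounds) at the reference agent parameterisation: individual weight 0.5,
normative weight 0.5, initial punishment probability 0.5, forgetting
probability 0.3.  Prints mean contributions, punishment frequency/intensity
and net earnings by treatment and round block.
"""

from normpgg import SimulationConfig, run_experiment, summarize

cfg = SimulationConfig(replications=20, n_groups=12, master_seed=42)
result = run_experiment(cfg)
print(f"simulated {result.n_ledgers} group-rounds in {result.meta['runtime_s']} s")

summary = summarize(result.rounds, blocks=("1-10", "11-15", "16-20", "21-30"))
print(summary.round(3).to_string(index=False))
print(
    "\nReading the table: cooperation declines in the no-instrument baseline"
    "\n(rounds 1-10) everywhere; in rounds 11-20 the sanction treatment -- where"
    "\npunishment doubles as a norm signal -- reaches and keeps the highest"
    "\ncontribution level while punishing *less* often than the punishment"
    "\ntreatment, and that advantage persists after the instruments are removed"
    "\n(rounds 21-30). Intensity is points per punishing act, zeros excluded;"
    "\nNaN marks blocks with no punishment opportunity used."
)
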