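"""Qualitative comparison of a simulated run against the human block means.

The agent model is a binary-choice abstraction of the laboratory game, so the
contract is ordering agreement, not numeric distance: the sanction treatment
must dominate in and after the instrumented block, cooperation must decline
in the baseline, and the punishment treatment must punish more often than the
sanction treatment.  Also reproduces the percent-excess arithmetic on the
human means.
"""

from normpgg import (
    HUMAN_BLOCK_MEANS,
    SimulationConfig,
    compare_to_fixtures,
    percent_excess,
    run_experiment,
    summarize,
)

cfg = SimulationConfig(replications=20, n_groups=12, master_seed=2)
panel = run_experiment(cfg).rounds
report = compare_to_fixtures(summarize(panel))
print(report)
print("\nall evaluated orderings pass:", report.all_pass)

h = HUMAN_BLOCK_MEANS
print("\nhuman means, sanction vs punishment:")
print(f"  rounds 16-20: {h.value('sanction', '16-20')} vs {h.value('punishment', '16-20')}"
      f" -> sanction higher by {percent_excess(h.value('sanction', '16-20'), h.value('punishment', '16-20'))}%")
print(f"  rounds 21-30: {h.value('sanction', '21-30')} vs {h.value('punishment', '21-30')}"
      f" -> sanction higher by {percent_excess(h.value('sanction', '21-30'), h.value('punishment', '21-30'))}%")
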