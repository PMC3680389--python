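"""Group-level nonparametric test battery on simulated panels.

The independent unit is the fixed group (or, across replications, the
replication mean).  Kruskal-Wallis compares the three treatments at once,
Mann-Whitney compares pairs, and Wilcoxon compares blocks within the same
treatment (paired by replication).
"""

from normpgg import (
    SimulationConfig,
    kruskal_wallis,
    mann_whitney,
    replication_means,
    run_experiment,
    wilcoxon_signed_rank,
)

cfg = SimulationConfig(replications=30, n_groups=12, master_seed=7)
panel = run_experiment(cfg).rounds

rm = replication_means(panel, "11-20")
by = {t: rm[rm.treatment == t].value.to_numpy() for t in ("message", "punishment", "sanction")}

kw = kruskal_wallis(*by.values())
print(f"Kruskal-Wallis, contributions 11-20 across treatments: "
      f"H = {kw.statistic:.2f}, p = {kw.pvalue:.2e}")

mw = mann_whitney(by["sanction"], by["punishment"])
print(f"Mann-Whitney, sanction vs punishment (11-20):          "
      f"U = {mw.statistic:.1f}, p = {mw.pvalue:.2e}")

b1 = replication_means(panel, "1-10")
b2 = rm
sanction_pairs = (
    b2[b2.treatment == "sanction"].value.to_numpy(),
    b1[b1.treatment == "sanction"].value.to_numpy(),
)
wx = wilcoxon_signed_rank(*sanction_pairs, alternative="greater")
print(f"Wilcoxon, sanction block 2 vs block 1 (paired):        "
      f"W = {wx.statistic:.1f}, p = {wx.pvalue:.2e}")

print(
    "\nSmall p-values mean the treatments genuinely separate cooperation levels"
    "\nin the instrumented block, and that the sanction treatment raises"
    "\ncooperation above its own no-instrument baseline."
)
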